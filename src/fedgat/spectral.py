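"""Structure-sensitive spectral features and their private client summaries.

Per graph: unnormalized Laplacian L = D - A, truncated eigendecomposition
keeping the M largest eigenvalues, sign-canonicalized eigenvectors padded
to a fixed (N_max, M) block and flattened row-major. Per client: the mean
of its graphs' features, privatized with the Gaussian mechanism
(sigma = sensitivity / epsilon) before transmission to the server.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralFeature",
    "PrivatizedClientSummary",
    "laplacian",
    "truncated_eigendecomposition",
    "spectral_feature",
    "graph_spectral_feature",
    "client_spectral_summary",
    "default_sensitivity",
    "privatize",
]


@dataclass
class SpectralFeature:
    g: np.ndarray  # flattened (N_max, M_spec) eigenvector block
    M_spec: int
    N_max: int

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=np.float64)
        if self.g.shape != (self.N_max * self.M_spec,):
            raise ValueError("spectral feature has wrong length")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("spectral feature must be finite")


@dataclass
class PrivatizedClientSummary:
    g_tilde: np.ndarray
    epsilon: float
    sigma: float
    delta_f: float

    def __post_init__(self):
        self.g_tilde = np.asarray(self.g_tilde, dtype=np.float64)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if abs(self.sigma - self.delta_f / self.epsilon) > 1e-12:
            raise ValueError("sigma must equal delta_f / epsilon")


def laplacian(A) -> np.ndarray:
    """Unnormalized graph Laplacian L = D - A (rows sum to zero)."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    return np.diag(A.sum(axis=1)) - A


def _canonicalize_sign(U: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude entry is positive.

    Eigensolvers return arbitrary signs; without a fixed convention the
    flattened features (and hence the server's cosine similarities) would
    not be reproducible. Ties break on the first maximal-magnitude index.
    """
    U = U.copy()
    for m in range(U.shape[1]):
        idx = int(np.argmax(np.abs(U[:, m])))
        if U[idx, m] < 0:
            U[:, m] = -U[:, m]
    return U


def truncated_eigendecomposition(L, M_spec: int):
    """Top-M eigenpairs of a symmetric matrix, eigenvalues descending.

    Returns (eigenvalues, eigenvectors) with unit-norm, sign-canonicalized
    columns. Degenerate eigenvalues are ordered by the canonicalized
    eigenvectors' lexicographic order so the result is deterministic.
    If M_spec > n all n pairs are returned (padding happens downstream).
    """
    L = np.asarray(L, dtype=np.float64)
    if not np.allclose(L, L.T):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(L)  # ascending
    vals, vecs = vals[::-1], vecs[:, ::-1]  # descending
    m = min(M_spec, L.shape[0])
    vals, vecs = vals[:m].copy(), _canonicalize_sign(vecs[:, :m])
    # deterministic order within (numerically) tied eigenvalues
    start = 0
    while start < m:
        end = start + 1
        while end < m and abs(vals[end] - vals[start]) <= 1e-10 * max(1.0, abs(vals[start])):
            end += 1
        if end - start > 1:
            block = vecs[:, start:end]
            order = np.lexsort(block[::-1])  # lexicographic by vector entries
            vecs[:, start:end] = block[:, order]
            vals[start:end] = vals[start:end][order]
        start = end
    return vals, vecs


def spectral_feature(U, M_spec: int, N_max: int) -> SpectralFeature:
    """Pad/truncate an n x m eigenvector block to (N_max, M_spec), flatten row-major."""
    U = np.asarray(U, dtype=np.float64)
    n, m = U.shape
    if m > M_spec:
        raise ValueError("more eigenvectors than M_spec")
    block = np.zeros((N_max, M_spec), dtype=np.float64)
    rows = min(n, N_max)
    block[:rows, :m] = U[:rows, :]
    return SpectralFeature(block.ravel(), M_spec, N_max)


def graph_spectral_feature(A, M_spec: int = 8, N_max: int = 32,
                           canonical_profile: bool = True) -> SpectralFeature:
    """Full per-graph pipeline: Laplacian -> truncated eig -> flattened feature.

    With ``canonical_profile`` (default) each eigenvector's entries are sorted
    in descending order and the resulting value profile is linearly resampled
    onto the fixed node budget N_max. Node labelings of random graphs are
    arbitrary, so with raw node order the flattened features of structurally
    alike graphs decorrelate and client means wash out; the resampled sorted
    profile is invariant under node relabeling and nearly invariant to graph
    size, which keeps the cross-client cosine similarities sensitive to
    structure rather than to bookkeeping. With ``canonical_profile=False``
    the raw eigenvector block is zero-padded/truncated in node order.
    """
    _, U = truncated_eigendecomposition(laplacian(A), M_spec)
    if canonical_profile:
        U = -np.sort(-U, axis=0)
        n = U.shape[0]
        if n != N_max and n > 1:
            xs = np.linspace(0.0, 1.0, N_max)
            xp = np.linspace(0.0, 1.0, n)
            U = np.column_stack([np.interp(xs, xp, col) for col in U.T])
        elif n == 1:
            U = np.repeat(U, N_max, axis=0)
        # keep columns unit-norm so the sensitivity bound ||g|| <= sqrt(M) holds
        norms = np.linalg.norm(U, axis=0)
        U = U / np.where(norms > 0, norms, 1.0)
    return spectral_feature(U, M_spec, N_max)


def client_spectral_summary(features) -> np.ndarray:
    """Arithmetic mean of a client's per-graph spectral features."""
    if not features:
        raise ValueError("need at least one spectral feature")
    vecs = [f.g if isinstance(f, SpectralFeature) else np.asarray(f, dtype=np.float64)
            for f in features]
    length = vecs[0].shape[0]
    if any(v.shape != (length,) for v in vecs):
        raise ValueError("spectral features have mismatched lengths")
    return np.mean(vecs, axis=0)


def default_sensitivity(M_spec: int, n_graphs: int) -> float:
    """Replace-one L2 sensitivity of the client mean.

    Each flattened eigenvector block has column-unit-norm columns, so
    ||g||_2 <= sqrt(M_spec); replacing one of n graphs moves the mean by at
    most 2 sqrt(M_spec) / n.
    """
    return 2.0 * np.sqrt(M_spec) / n_graphs


def privatize(summary, epsilon: float = 10.0, delta_f: float = 1.0,
              rng=None) -> PrivatizedClientSummary:
    """Gaussian mechanism: g̃ = summary + N(0, sigma^2 I), sigma = delta_f / epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    summary = np.asarray(summary, dtype=np.float64)
    rng = np.random.default_rng(rng)
    sigma = delta_f / epsilon
    noisy = summary + rng.normal(0.0, sigma, size=summary.shape)
    return PrivatizedClientSummary(noisy, epsilon, sigma, delta_f)
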