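"""SparCC: basis correlations from compositional count data.

Sequencing counts only carry relative information, so Pearson correlations
of fractions are distorted by the unit-sum constraint. SparCC instead works
from the log-ratio variances t_ij = Var[log(x_i/x_j)], which are invariant
to the closure, and solves for the variances w_i of the latent ("basis")
absolute abundances under a sparsity assumption (sum_j rho_ij ~ 0):

    t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

Summing over j gives a linear system for w, after which rho follows
directly. Strongly correlated pairs violate the sparsity assumption, so
the strongest pair above a threshold is iteratively excluded from the
system and the solve repeated. Sampling zeros are handled by drawing
fractions from a Dirichlet posterior with unit pseudocounts (or a
deterministic plug-in), and the final estimate is the element-wise median
over draws. Significance comes from a permutation null ("bootstrap"):
each ASV's counts are shuffled across samples independently, destroying
co-abundance while preserving marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CorrelationMatrix, FeatureTable

__all__ = [
    "SparccConfig",
    "SparccDiagnostics",
    "log_ratio_variances",
    "basis_correlations",
    "sparcc",
    "sparcc_pvalues",
]

_MIN_BASIS_VARIANCE = 1e-12


@dataclass
class SparccConfig:
    """Knobs of the SparCC procedure.

    n_dirichlet_draws: inner posterior resamplings whose estimates are
        median-aggregated (ignored in plug-in mode).
    n_exclusion_iters / exclusion_threshold: iterative removal of the
        strongest-|rho| pair violating the sparsity assumption.
    n_bootstrap: permutation replicates for pseudo p-values.
    zero_handling: 'dirichlet' (posterior draws) or 'plugin'
        ((count+1)/(total+D), deterministic).
    bootstrap_mode: 'permute' (independent within-ASV shuffles, the
        classical null) or 'resample' (samples with replacement).
    """

    n_dirichlet_draws: int = 20
    n_exclusion_iters: int = 10
    exclusion_threshold: float = 0.1
    n_bootstrap: int = 100
    rng_seed: int = 0
    zero_handling: str = "dirichlet"
    bootstrap_mode: str = "permute"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must be in (0, 1)")
        if self.zero_handling not in ("dirichlet", "plugin"):
            raise ValueError(f"unknown zero_handling {self.zero_handling!r}")
        if self.bootstrap_mode not in ("permute", "resample"):
            raise ValueError(f"unknown bootstrap_mode {self.bootstrap_mode!r}")
        if self.n_dirichlet_draws < 1:
            raise ValueError("n_dirichlet_draws must be >= 1")


@dataclass
class SparccDiagnostics:
    n_clamped: int = 0
    n_floored_variances: int = 0
    excluded_pairs_per_draw: list[int] = field(default_factory=list)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Sample variance of log(x_i / x_j) for every component pair.

    ``fractions`` is samples x D and must be strictly positive.
    Computed via the covariance of the logs:
    Var[log xi - log xj] = v_i + v_j - 2 c_ij.
    """
    F = np.asarray(fractions, dtype=float)
    if F.ndim != 2:
        raise ValueError("fractions must be a 2-D samples x components array")
    if np.any(F <= 0):
        raise ValueError("fractions must be strictly positive (resolve zeros upstream)")
    if F.shape[0] < 2:
        raise ValueError("need >= 2 samples to estimate variances")
    L = np.log(F)
    C = np.cov(L, rowvar=False, ddof=1)
    v = np.diag(C)
    T = v[:, None] + v[None, :] - 2.0 * C
    T = (T + T.T) / 2.0
    np.fill_diagonal(T, 0.0)
    np.clip(T, 0.0, None, out=T)
    return T


def basis_correlations(
    T: np.ndarray,
    excluded: set[tuple[int, int]] | None = None,
    diagnostics: SparccDiagnostics | None = None,
) -> np.ndarray:
    """Solve the sparsity approximation for basis variances and correlations.

    ``excluded`` pairs (i < j) are removed from the linear system (their
    t_ij dropped from the row sums and the coupling matrix). Requires
    D >= 4; below that the system for the basis variances is
    underdetermined. Negative solved variances are floored at a small
    positive constant; estimates are clamped to [-1, 1]. Both events are
    counted in ``diagnostics`` when provided.
    """
    T = np.asarray(T, dtype=float)
    D = T.shape[0]
    if D < 4:
        raise ValueError(
            "SparCC needs at least 4 components: the linear system for the "
            f"basis variances is underdetermined at D={D}"
        )
    excluded = excluded or set()
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    T_eff = T.copy()
    for i, j in excluded:
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        T_eff[i, j] = 0.0
        T_eff[j, i] = 0.0
    w = np.linalg.solve(M, T_eff.sum(axis=1))
    n_floored = int(np.sum(w < _MIN_BASIS_VARIANCE))
    w = np.maximum(w, _MIN_BASIS_VARIANCE)
    denom = 2.0 * np.sqrt(np.outer(w, w))
    rho = (w[:, None] + w[None, :] - T) / denom
    n_clamped = int(np.sum(np.abs(rho) > 1.0))  # diagonal is exactly 1, never counted
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    if diagnostics is not None:
        diagnostics.n_floored_variances += n_floored
        diagnostics.n_clamped += n_clamped
    return rho


def _estimate_with_exclusion(
    T: np.ndarray, cfg: SparccConfig, diagnostics: SparccDiagnostics | None = None
) -> np.ndarray:
    """One SparCC estimate: solve, then iteratively exclude strong pairs."""
    D = T.shape[0]
    excluded: set[tuple[int, int]] = set()
    excluded_mask = np.zeros((D, D), dtype=bool)
    excl_count = np.zeros(D, dtype=int)
    lower = np.tril_indices(D)
    rho = basis_correlations(T, excluded, diagnostics)
    for _ in range(cfg.n_exclusion_iters):
        A = np.abs(rho).copy()
        A[lower] = -np.inf  # consider each pair once, as (i < j)
        A[excluded_mask] = -np.inf
        capped = excl_count >= D - 3  # keep the system identifiable per component
        A[capped, :] = -np.inf
        A[:, capped] = -np.inf
        flat = int(np.argmax(A))  # row-major argmax = lexicographically first on ties
        i, j = divmod(flat, D)
        if not A[i, j] > cfg.exclusion_threshold:
            break
        excluded.add((i, j))
        excluded_mask[i, j] = excluded_mask[j, i] = True
        excl_count[i] += 1
        excl_count[j] += 1
        rho = basis_correlations(T, excluded, diagnostics)
    if diagnostics is not None:
        diagnostics.excluded_pairs_per_draw.append(len(excluded))
    return rho


def _fractions(counts: np.ndarray, cfg: SparccConfig, rng: np.random.Generator | None):
    if cfg.zero_handling == "plugin" or rng is None:
        D = counts.shape[1]
        pseudo = counts + 1.0
        return pseudo / pseudo.sum(axis=1, keepdims=True)
    g = rng.gamma(counts + 1.0)
    return g / g.sum(axis=1, keepdims=True)


def _sparcc_matrix(
    counts: np.ndarray, cfg: SparccConfig, seed_key: tuple[int, ...],
    diagnostics: SparccDiagnostics | None = None,
) -> np.ndarray:
    """Median-aggregated SparCC estimate on a raw count matrix."""
    if cfg.zero_handling == "plugin":
        T = log_ratio_variances(_fractions(counts, cfg, None))
        return _estimate_with_exclusion(T, cfg, diagnostics)
    draws = []
    for d in range(cfg.n_dirichlet_draws):
        rng = np.random.default_rng(np.random.SeedSequence(list(seed_key) + [d]))
        T = log_ratio_variances(_fractions(counts, cfg, rng))
        draws.append(_estimate_with_exclusion(T, cfg, diagnostics))
    rho = np.median(draws, axis=0)
    rho = (rho + rho.T) / 2.0
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc(
    table: FeatureTable, cfg: SparccConfig | None = None
) -> tuple[CorrelationMatrix, SparccDiagnostics]:
    """Full SparCC procedure on a (prevalence-filtered) count table."""
    cfg = cfg or SparccConfig()
    table.require_min_size(2, 4)
    diagnostics = SparccDiagnostics()
    rho = _sparcc_matrix(
        table.counts, cfg, (cfg.rng_seed & 0x7FFFFFFF, 1), diagnostics
    )
    return CorrelationMatrix(table.asv_ids, rho), diagnostics


def sparcc_pvalues(
    table: FeatureTable, observed: CorrelationMatrix, cfg: SparccConfig | None = None
) -> np.ndarray:
    """Two-sided permutation pseudo p-values for the observed correlations.

    p_ij = (1 + #{b : |rho_b[ij]| >= |obs[ij]|}) / (1 + n_bootstrap), so the
    minimum attainable value is 1/(n_bootstrap + 1). The diagonal is set
    to 1 and carries no meaning.
    """
    cfg = cfg or SparccConfig()
    if observed.ids != table.asv_ids:
        raise ValueError("observed correlation ids do not match the table")
    counts = table.counts
    n, D = counts.shape
    abs_obs = np.abs(observed.r)
    exceed = np.zeros((D, D), dtype=np.int64)
    master = cfg.rng_seed & 0x7FFFFFFF
    for b in range(cfg.n_bootstrap):
        rng = np.random.default_rng(np.random.SeedSequence([master, 2, b]))
        if cfg.bootstrap_mode == "permute":
            null_counts = np.empty_like(counts)
            for j in range(D):
                null_counts[:, j] = counts[rng.permutation(n), j]
        else:
            null_counts = counts[rng.integers(0, n, size=n), :]
        rho_b = _sparcc_matrix(null_counts, cfg, (master, 3, b))
        exceed += np.abs(rho_b) >= abs_obs
    p = (1.0 + exceed) / (1.0 + cfg.n_bootstrap)
    p = np.minimum(p, p.T)
    np.fill_diagonal(p, 1.0)
    return p
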