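"""Allele-specific expression (ASE) tests over a timecourse.

A hybrid diploid carries two parental alleles of every gene; comparing the
reads assigned to each allele isolates cis-acting regulatory variation from
trans effects.  Two questions are asked of each gene's allele-frequency
trajectory f_i (reference-allele share at timepoint i, weighted by read
depth w_i):

* **levels** — is the allelic imbalance constant but non-zero?  Tested with
  a weighted intercept-only linear model ``f_i = 0.5 + beta0 + e``.
* **dynamics** — does the imbalance change over time?  Tested with a
  weighted Durbin-Watson statistic on the residuals of the levels model,

      dw = sum_{i=1}^{T-1} (w_{i+1} e_{i+1} - w_i e_i)^2
           / sum_{i=1}^{T} (w_i e_i)^2

  whose null distribution is obtained by permuting the timepoint order
  (exact under exchangeability of the (f_i, w_i) pairs).

Counts are depth-normalized with median-of-ratios size factors before
frequencies are formed; raw totals serve as weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AlleleCountMatrix",
    "AlleleFrequencySeries",
    "LevelsResult",
    "DynamicsResult",
    "NormalizationError",
    "median_of_ratios",
    "normalize_counts",
    "filter_genes",
    "allele_frequency",
    "test_ase_levels",
    "test_ase_dynamics",
    "weighted_dw",
    "bh_fdr",
    "ase_test_table",
    "permutation_null_levels",
    "permutation_null_dynamics",
]

ALLELES = ("ref", "alt")


class NormalizationError(ValueError):
    """No gene has nonzero counts in every column; size factors undefined."""


@dataclass
class AlleleCountMatrix:
    """Raw allele-resolved read counts.

    ``counts`` has shape (n_genes, n_timepoints, 2); axis 2 is (ref, alt).
    """

    genes: np.ndarray
    timepoints: np.ndarray
    counts: np.ndarray
    hybrid: str = ""

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.timepoints = np.asarray(self.timepoints)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (genes, timepoints, 2)")
        if self.counts.shape[0] != len(self.genes):
            raise ValueError("gene axis mismatch")
        if self.counts.shape[1] != len(self.timepoints):
            raise ValueError("timepoint axis mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        """Per-gene, per-timepoint read totals over both alleles."""
        return self.counts.sum(axis=2)

    def subset(self, keep: np.ndarray) -> "AlleleCountMatrix":
        return AlleleCountMatrix(
            self.genes[keep], self.timepoints, self.counts[keep], self.hybrid
        )


@dataclass
class AlleleFrequencySeries:
    """Reference-allele frequencies with read-count weights.

    ``f`` is NaN wherever ``w`` is zero (frequency undefined without reads).
    """

    f: np.ndarray
    w: np.ndarray
    gene: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.f.shape != self.w.shape:
            raise ValueError("f and w must have equal length")
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def T(self) -> int:
        return len(self.f)

    @property
    def defined(self) -> np.ndarray:
        return (self.w > 0) & np.isfinite(self.f)


@dataclass
class LevelsResult:
    beta0: float
    se: float
    p: float
    q: float = np.nan
    untestable: bool = False


@dataclass
class DynamicsResult:
    dw: float
    p: float
    q: float = np.nan
    untestable: bool = False


# ---------------------------------------------------------------------------
# normalization and filtering


def median_of_ratios(matrix: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors for a (rows x columns) count matrix.

    The reference for each row is its geometric mean over columns; rows with
    a zero in any column are excluded from the reference set.  The size
    factor of column j is the median over reference rows of count_rj divided
    by the row's geometric mean.
    """
    matrix = np.asarray(matrix, dtype=float)
    ref = (matrix > 0).all(axis=1)
    if not ref.any():
        raise NormalizationError(
            "no row has nonzero counts in every column; "
            "median-of-ratios size factors are undefined"
        )
    sub = matrix[ref]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geomean)
    return np.median(ratios, axis=0)


def normalize_counts(matrix: AlleleCountMatrix):
    """Depth-normalize all 2T (timepoint, allele) columns jointly.

    Returns ``(normalized, size_factors)`` where ``normalized`` has the same
    (genes, timepoints, 2) shape and ``size_factors`` has shape
    (timepoints, 2).
    """
    flat = matrix.counts.reshape(matrix.n_genes, -1)
    sf = median_of_ratios(flat)
    normalized = (flat / sf).reshape(matrix.counts.shape)
    return normalized, sf.reshape(matrix.n_timepoints, 2)


def filter_genes(
    matrix: AlleleCountMatrix,
    min_mean_reads: float = 20.0,
    max_zero_timepoints: int = 7,
) -> np.ndarray:
    """Boolean mask of genes retained for testing.

    A gene is removed if its mean read total per timepoint is below
    ``min_mean_reads`` (strictly), or if more than ``max_zero_timepoints``
    timepoints have zero reads.  Both rules operate on raw counts.
    """
    totals = matrix.totals()
    low = totals.mean(axis=1) < min_mean_reads
    sparse = (totals == 0).sum(axis=1) > max_zero_timepoints
    return ~(low | sparse)


def allele_frequency(
    matrix: AlleleCountMatrix,
    gene: str,
    normalized: np.ndarray | None = None,
) -> AlleleFrequencySeries:
    """Normalized reference-allele frequency series for one gene.

    f_i uses normalized counts; the weights w_i are raw read totals.
    Timepoints without reads yield NaN frequencies.
    """
    idx = np.flatnonzero(matrix.genes == gene)
    if idx.size == 0:
        raise KeyError(f"gene {gene!r} not in matrix")
    if normalized is None:
        normalized, _ = normalize_counts(matrix)
    g = int(idx[0])
    norm = normalized[g]
    raw_tot = matrix.counts[g].sum(axis=1).astype(float)
    denom = norm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, norm[:, 0] / denom, np.nan)
    f = np.where(raw_tot > 0, f, np.nan)
    w = np.where(raw_tot > 0, raw_tot, 0.0)
    return AlleleFrequencySeries(f=f, w=w, gene=gene)


# ---------------------------------------------------------------------------
# levels test


def _levels_arrays(f: np.ndarray, w: np.ndarray):
    """Vectorized weighted intercept test on rows of (f, w).

    NaN frequencies / zero weights are treated as undefined timepoints.
    Returns (beta0, se, p, n_defined) arrays.
    """
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    defined = (w > 0) & np.isfinite(f)
    wv = np.where(defined, w, 0.0)
    dev = np.where(defined, f - 0.5, 0.0)
    n = defined.sum(axis=-1)
    sw = wv.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta0 = (wv * dev).sum(axis=-1) / sw
        resid = dev - beta0[..., None]
        resid = np.where(defined, resid, 0.0)
        s2 = (wv * resid**2).sum(axis=-1) / np.maximum(n - 1, 1)
        se = np.sqrt(s2 / sw)
        t = np.where(se > 0, beta0 / np.where(se > 0, se, 1.0), np.inf * np.sign(beta0))
    p = np.where(
        se > 0,
        2.0 * stats.t.sf(np.abs(np.where(se > 0, t, 0.0)), np.maximum(n - 1, 1)),
        np.where(beta0 == 0, 1.0, 0.0),
    )
    return beta0, se, p, n


def test_ase_levels(series: AlleleFrequencySeries) -> LevelsResult:
    """Weighted test of constant allelic imbalance (beta0 != 0).

    beta0 is the weighted mean of (f_i - 0.5); its standard error uses the
    weighted residual variance with T_defined - 1 degrees of freedom.
    Fewer than two defined timepoints is untestable.
    """
    if series.defined.sum() < 2:
        return LevelsResult(np.nan, np.nan, np.nan, untestable=True)
    beta0, se, p, _ = _levels_arrays(series.f[None, :], series.w[None, :])
    return LevelsResult(float(beta0[0]), float(se[0]), float(p[0]))


# ---------------------------------------------------------------------------
# dynamics test


def weighted_dw(e: np.ndarray, w: np.ndarray) -> float:
    """The weighted Durbin-Watson statistic on residuals e with weights w.

    With unit weights this reduces to the classical Durbin-Watson statistic.
    All-zero weighted residuals return 2.0 (the no-autocorrelation center).
    """
    v = np.asarray(w, dtype=float) * np.asarray(e, dtype=float)
    den = (v**2).sum()
    if den == 0:
        return 2.0
    return float((np.diff(v) ** 2).sum() / den)


def _dw_from_products(v: np.ndarray) -> np.ndarray:
    """dw over the last axis of an array of weighted residuals w*e."""
    den = (v**2).sum(axis=-1)
    num = (np.diff(v, axis=-1) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 2.0)
    return out


def _dynamics_products(f: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted residuals v_i = w_i e_i of the levels model, rows of (f, w)."""
    defined = (w > 0) & np.isfinite(f)
    wv = np.where(defined, w, 0.0)
    dev = np.where(defined, f - 0.5, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta0 = (wv * dev).sum(axis=-1) / wv.sum(axis=-1)
    resid = np.where(defined, dev - beta0[..., None], 0.0)
    return wv * resid


def _permutation_p(
    v: np.ndarray, n_perm: int, rng: np.random.Generator, chunk: int = 100
):
    """Permutation p-values for dw on rows of weighted residuals v.

    One shared set of ``n_perm`` random orderings of the T positions is
    applied to every row; the p-value is the smoothed two-sided fraction of
    permuted statistics at least as far from the permutation mean as the
    observed one.  Returns (dw_obs, p).
    """
    n_rows, T = v.shape
    dw_obs = _dw_from_products(v)
    perms = np.empty((n_perm, T), dtype=np.intp)
    base = np.arange(T)
    for j in range(n_perm):
        perms[j] = rng.permutation(base)
    sums = np.zeros(n_rows)
    stats_chunks = []
    for lo in range(0, n_perm, chunk):
        block = perms[lo : lo + chunk]
        vp = v[:, block]  # (rows, chunk, T)
        stats_chunks.append(_dw_from_products(vp))
    all_stats = np.concatenate(stats_chunks, axis=1)  # (rows, n_perm)
    center = all_stats.mean(axis=1)
    obs_dist = np.abs(dw_obs - center)
    count = (np.abs(all_stats - center[:, None]) >= obs_dist[:, None] - 1e-12).sum(
        axis=1
    )
    p = (count + 1.0) / (n_perm + 1.0)
    # degenerate rows: all weighted residuals zero
    degenerate = (v == 0).all(axis=1)
    p = np.where(degenerate, 1.0, p)
    return np.where(degenerate, 2.0, dw_obs), p


def dynamics_test_matrix(
    f: np.ndarray,
    w: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "permutation",
):
    """Dynamics (weighted Durbin-Watson) test for many genes at once.

    ``f`` and ``w`` are (genes x timepoints).  Genes with undefined
    timepoints (w=0 or NaN f) are tested on their defined subset; genes with
    fewer than 4 defined timepoints are flagged untestable (NaN p).

    Returns (dw, p, untestable) arrays.
    """
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    rng = np.random.default_rng(seed)
    defined = (w > 0) & np.isfinite(f)
    n_def = defined.sum(axis=1)
    untestable = n_def < 4
    complete = defined.all(axis=1) & ~untestable

    dw = np.full(f.shape[0], np.nan)
    p = np.full(f.shape[0], np.nan)

    if complete.any():
        v = _dynamics_products(f[complete], w[complete])
        if method == "permutation":
            dw_c, p_c = _permutation_p(v, n_perm, rng)
        elif method == "normal":
            dw_c, p_c = _normal_approx_p(v, n_perm, rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        dw[complete] = dw_c
        p[complete] = p_c

    # incomplete genes: per-gene on the defined subset (rare after filtering)
    for g in np.flatnonzero(~complete & ~untestable):
        mask = defined[g]
        v = _dynamics_products(f[g, mask][None, :], w[g, mask][None, :])
        if method == "permutation":
            dw_g, p_g = _permutation_p(v, n_perm, rng)
        else:
            dw_g, p_g = _normal_approx_p(v, n_perm, rng)
        dw[g], p[g] = dw_g[0], p_g[0]
    return dw, p, untestable


def _normal_approx_p(v, n_perm, rng):
    """Normal approximation to the permutation null from its first 2 moments."""
    n_rows, T = v.shape
    dw_obs = _dw_from_products(v)
    perms = np.stack([rng.permutation(T) for _ in range(n_perm)])
    all_stats = _dw_from_products(v[:, perms])
    mu = all_stats.mean(axis=1)
    sd = all_stats.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (dw_obs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = (v == 0).all(axis=1)
    return np.where(degenerate, 2.0, dw_obs), np.where(degenerate, 1.0, np.minimum(p, 1.0))


def test_ase_dynamics(
    series: AlleleFrequencySeries,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "permutation",
) -> DynamicsResult:
    """Weighted Durbin-Watson test for ASE dynamics on one gene.

    The statistic is computed on the weighted residuals of the levels model
    in timepoint order; the p-value comes from permuting the timepoint order
    (``n_perm`` draws, two-sided around the permutation mean, with
    (count+1)/(N+1) smoothing).  Undefined timepoints are dropped; fewer
    than 4 defined timepoints is untestable.
    """
    mask = series.defined
    if mask.sum() < 4:
        return DynamicsResult(np.nan, np.nan, untestable=True)
    dw, p, _ = dynamics_test_matrix(
        series.f[mask][None, :], series.w[mask][None, :], n_perm, seed, method
    )
    return DynamicsResult(float(dw[0]), float(p[0]))


# ---------------------------------------------------------------------------
# FDR and pipeline


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (NaNs propagated)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def ase_test_table(
    matrix: AlleleCountMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Run both ASE tests on every (filtered) gene of a count matrix.

    Returns a tidy frame with columns gene, beta0, se, p_levels, q_levels,
    dw, p_dyn, q_dyn, untestable_levels, untestable_dyn.
    """
    work = matrix.subset(filter_genes(matrix)) if apply_filter else matrix
    if work.n_genes == 0:
        return pd.DataFrame(
            columns=[
                "gene", "beta0", "se", "p_levels", "q_levels",
                "dw", "p_dyn", "q_dyn", "untestable_levels", "untestable_dyn",
            ]
        )
    normalized, _ = normalize_counts(work)
    denom = normalized.sum(axis=2)
    raw_tot = work.totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, normalized[:, :, 0] / denom, np.nan)
    f = np.where(raw_tot > 0, f, np.nan)
    w = np.where(raw_tot > 0, raw_tot, 0.0)

    beta0, se, p_lvl, n_def = _levels_arrays(f, w)
    unt_lvl = n_def < 2
    p_lvl = np.where(unt_lvl, np.nan, p_lvl)
    dw, p_dyn, unt_dyn = dynamics_test_matrix(f, w, n_perm=n_perm, seed=seed)
    return pd.DataFrame(
        {
            "gene": work.genes,
            "beta0": np.where(unt_lvl, np.nan, beta0),
            "se": np.where(unt_lvl, np.nan, se),
            "p_levels": p_lvl,
            "q_levels": bh_fdr(p_lvl),
            "dw": dw,
            "p_dyn": p_dyn,
            "q_dyn": bh_fdr(p_dyn),
            "untestable_levels": unt_lvl,
            "untestable_dyn": unt_dyn,
        }
    )


def permutation_null_levels(
    matrix: AlleleCountMatrix,
    n_perm: int = 10,
    seed: int | None = None,
    fdr: float = 0.01,
) -> np.ndarray:
    """False-positive counts of the levels test under allele permutation.

    For each of ``n_perm`` replicates the two allele labels of every gene
    are swapped independently at each timepoint with probability 0.5; the
    full levels pipeline (normalization, weighted test, BH adjustment) is
    re-run and genes with q < ``fdr`` are counted.  The matrix is expected
    to be pre-filtered.
    """
    rng = np.random.default_rng(seed)
    counts = matrix.counts
    out = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        swap = rng.random(counts.shape[:2]) < 0.5
        permuted = counts.copy()
        permuted[swap] = permuted[swap][:, ::-1]
        pm = AlleleCountMatrix(matrix.genes, matrix.timepoints, permuted)
        normalized, _ = normalize_counts(pm)
        denom = normalized.sum(axis=2)
        raw_tot = pm.totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom > 0, normalized[:, :, 0] / denom, np.nan)
        f = np.where(raw_tot > 0, f, np.nan)
        w = np.where(raw_tot > 0, raw_tot, 0.0)
        _, _, p, n_def = _levels_arrays(f, w)
        p = np.where(n_def < 2, np.nan, p)
        out[r] = int(np.nansum(bh_fdr(p) < fdr))
    return out


def permutation_null_dynamics(
    matrix: AlleleCountMatrix,
    n_perm: int = 10,
    seed: int | None = None,
    fdr: float = 0.01,
    n_inner: int = 1000,
) -> np.ndarray:
    """False-positive counts of the dynamics test under timepoint permutation.

    Each replicate applies one random reordering of the timepoint labels to
    all genes (keeping allele pairs together), re-runs the weighted
    Durbin-Watson test (``n_inner`` permutation draws for its p-values) and
    BH adjustment, and counts genes with q < ``fdr``.
    """
    rng = np.random.default_rng(seed)
    normalized, _ = normalize_counts(matrix)
    denom = normalized.sum(axis=2)
    raw_tot = matrix.totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, normalized[:, :, 0] / denom, np.nan)
    f = np.where(raw_tot > 0, f, np.nan)
    w = np.where(raw_tot > 0, raw_tot, 0.0)
    out = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        order = rng.permutation(matrix.n_timepoints)
        inner_seed = int(rng.integers(0, 2**31 - 1))
        _, p, _ = dynamics_test_matrix(
            f[:, order], w[:, order], n_perm=n_inner, seed=inner_seed
        )
        out[r] = int(np.nansum(bh_fdr(p) < fdr))
    return out
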