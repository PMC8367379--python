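"""Reporter-assay (CRE-seq) expression analysis.

The activity of each synthetic regulatory element is the ratio of its
barcode's RNA reads to its DNA abundance.  After perfect-match barcode
counting, low-coverage barcodes are filtered, counts are depth-normalized
(median-of-ratios, blind to design), and per-barcode RNA/DNA ratios over
the timecourse form the expression series.  Allele, single-variant and
chimera comparisons reuse the ASE machinery: a barcode-mean level test
(one summary value per barcode, so that a single aberrant barcode cannot
masquerade as an allele effect) and the weighted Durbin-Watson dynamics
test on the allele-1 expression share over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ase import (
    AlleleFrequencySeries,
    DynamicsResult,
    bh_fdr,
    median_of_ratios,
    test_ase_dynamics,
)

__all__ = [
    "CreCounts",
    "CreExpressionSeries",
    "ChimeraResult",
    "count_barcodes",
    "filter_cres",
    "cre_expression",
    "map_timepoints",
    "correlate_with_endogenous",
    "test_cre_levels",
    "test_cre_dynamics",
    "test_variant",
    "map_chimera",
    "classify_chimera_range",
]


@dataclass
class CreCounts:
    """Barcode-level RNA and DNA count tables (barcodes x samples)."""

    rna: pd.DataFrame
    dna: pd.DataFrame
    manifest: pd.DataFrame
    discarded_reads: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.rna.to_numpy() < 0).any() or (self.dna.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def subset(self, barcodes) -> "CreCounts":
        return CreCounts(
            self.rna.loc[barcodes],
            self.dna.loc[barcodes],
            self.manifest[self.manifest["barcode"].isin(barcodes)],
            self.discarded_reads,
        )


@dataclass
class CreExpressionSeries:
    """Per-barcode RNA/DNA expression ratios over the timecourse.

    ``expression`` is barcodes x timepoints (NaN where the barcode had zero
    RNA reads); ``weights`` are raw total read counts per timepoint used by
    the dynamics test; ``dropped_zero_dna`` lists barcodes excluded because
    their DNA reference was zero.
    """

    expression: pd.DataFrame
    weights: pd.DataFrame
    manifest: pd.DataFrame
    dropped_zero_dna: list = field(default_factory=list)

    def construct_mean(self, construct_id: str) -> pd.Series:
        bcs = self.manifest.loc[
            self.manifest["construct_id"] == construct_id, "barcode"
        ]
        return self.expression.loc[self.expression.index.intersection(bcs)].mean(
            axis=0, skipna=True
        )


def count_barcodes(reads: dict, manifest: pd.DataFrame) -> CreCounts:
    """Tally perfect barcode matches per sample.

    ``reads`` maps sample name (``RNA_t*`` / ``DNA_*``) to an iterable of
    read sequences; a read counts for a barcode iff the barcode occurs in
    it as an exact substring (first match wins); everything else is
    discarded and tallied.  Duplicate barcodes in the manifest are an
    error.
    """
    barcodes = manifest["barcode"].tolist()
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in manifest")
    bc_set = set(barcodes)
    L = len(barcodes[0]) if barcodes else 0
    counts = {s: dict.fromkeys(barcodes, 0) for s in reads}
    discarded = {}
    for sample, seqs in reads.items():
        miss = 0
        tally = counts[sample]
        for read in seqs:
            hit = None
            for i in range(len(read) - L + 1):
                sub = read[i : i + L]
                if sub in bc_set:
                    hit = sub
                    break
            if hit is None:
                miss += 1
            else:
                tally[hit] += 1
        discarded[sample] = miss
    frame = pd.DataFrame(counts)
    frame.index.name = "barcode"
    rna_cols = [c for c in frame.columns if c.startswith("RNA")]
    dna_cols = [c for c in frame.columns if c.startswith("DNA")]
    return CreCounts(frame[rna_cols], frame[dna_cols], manifest, discarded)


def filter_cres(
    counts: CreCounts,
    min_mean_reads: float = 100.0,
    max_zero_fraction: float = 1.0 / 3.0,
) -> pd.Index:
    """Barcodes passing the coverage filters.

    A barcode is removed iff it has zero reads in more than a third of the
    RNA timepoint samples, or a mean below ``min_mean_reads`` (strictly) in
    either the RNA or the DNA samples.
    """
    rna, dna = counts.rna, counts.dna
    zero_frac_bad = (rna == 0).sum(axis=1) > max_zero_fraction * rna.shape[1]
    low_rna = rna.mean(axis=1) < min_mean_reads
    low_dna = dna.mean(axis=1) < min_mean_reads
    return rna.index[~(zero_frac_bad | low_rna | low_dna)]


def cre_expression(counts: CreCounts) -> CreExpressionSeries:
    """Normalized RNA/DNA expression ratios per barcode and timepoint.

    All RNA and DNA columns are normalized jointly with median-of-ratios
    size factors; the DNA reference per barcode is the mean of its
    normalized DNA samples (taken at the first and last timepoints of the
    experiment).  Zero RNA counts are missing data; barcodes with a zero
    DNA reference are dropped with a flag.
    """
    joint = pd.concat([counts.rna, counts.dna], axis=1)
    sf = median_of_ratios(joint.to_numpy(dtype=float))
    norm = joint / sf
    dna_ref = norm[counts.dna.columns].mean(axis=1)
    dropped = dna_ref.index[dna_ref == 0].tolist()
    keep = dna_ref > 0
    rna_norm = norm.loc[keep, counts.rna.columns]
    expr = rna_norm.div(dna_ref[keep], axis=0)
    expr = expr.mask(counts.rna.loc[keep] == 0)  # zero counts are missing
    weights = counts.rna.loc[keep].astype(float)
    return CreExpressionSeries(
        expression=expr,
        weights=weights,
        manifest=counts.manifest[counts.manifest["barcode"].isin(expr.index)],
        dropped_zero_dna=dropped,
    )


# ---------------------------------------------------------------------------
# endogenous correlation


def map_timepoints(cre_times, rna_times) -> np.ndarray:
    """Index into ``cre_times`` nearest to each RNA-seq time (ties earlier)."""
    cre_times = np.asarray(cre_times, dtype=float)
    rna_times = np.asarray(rna_times, dtype=float)
    out = np.empty(len(rna_times), dtype=int)
    for j, t in enumerate(rna_times):
        d = np.abs(cre_times - t)
        out[j] = int(np.argmin(d))  # argmin takes the first (earlier) tie
    return out


def correlate_with_endogenous(
    region_series: pd.DataFrame,
    rnaseq: pd.Series | np.ndarray | pd.DataFrame,
    timepoint_map: np.ndarray | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each region's mean CRE series with RNA-seq.

    ``region_series`` is regions x CRE timepoints (barcode means);
    ``rnaseq`` is either one endogenous series shared by all regions or a
    frame with a row per region.  ``timepoint_map`` selects the CRE
    timepoints nearest the RNA-seq samples when the clocks differ.
    Returns r, p and BH q per region (NaN and a flag for zero-variance
    series).
    """
    X = region_series.to_numpy(dtype=float)
    if timepoint_map is not None:
        X = X[:, timepoint_map]
    if isinstance(rnaseq, pd.DataFrame):
        Y = rnaseq.loc[region_series.index].to_numpy(dtype=float)
    else:
        Y = np.broadcast_to(np.asarray(rnaseq, dtype=float), X.shape)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 shared timepoints")
    r = np.full(len(X), np.nan)
    p = np.full(len(X), np.nan)
    flag = np.full(len(X), "", dtype=object)
    for i in range(len(X)):
        ok = np.isfinite(X[i]) & np.isfinite(Y[i])
        if ok.sum() < 3:
            flag[i] = "too_few_timepoints"
            continue
        if X[i, ok].std() == 0 or Y[i, ok].std() == 0:
            flag[i] = "zero_variance"
            continue
        r[i], p[i] = stats.pearsonr(X[i, ok], Y[i, ok])
    q = bh_fdr(p)
    return pd.DataFrame(
        {"r": r, "p": p, "q": q, "significant": q < fdr, "flag": flag},
        index=region_series.index,
    )


# ---------------------------------------------------------------------------
# level / dynamics tests between allele groups


def test_cre_levels(
    expr: pd.DataFrame, labels: pd.Series, log: bool = True
) -> dict:
    """Allele-difference test on per-barcode mean expression.

    Each barcode contributes one value — its mean expression across
    timepoints (natural log by default) — and a two-group linear model
    (equivalently a pooled-variance t test) compares the alleles.  Fewer
    than 2 barcodes in either group is untestable.
    """
    means = expr.mean(axis=1, skipna=True)
    groups = labels.loc[means.index]
    names = groups.unique()
    if len(names) != 2:
        return {"p": np.nan, "diff": np.nan, "untestable": True}
    a = means[groups == names[0]].dropna()
    b = means[groups == names[1]].dropna()
    if len(a) < 2 or len(b) < 2:
        return {"p": np.nan, "diff": np.nan, "untestable": True}
    if log:
        if (a <= 0).any() or (b <= 0).any():
            return {"p": np.nan, "diff": np.nan, "untestable": True}
        a, b = np.log(a), np.log(b)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "p": float(p),
        "diff": float(np.mean(a) - np.mean(b)),
        "untestable": False,
    }


def _allele_share_series(
    expr: pd.DataFrame, weights: pd.DataFrame, labels: pd.Series
) -> AlleleFrequencySeries:
    groups = labels.loc[expr.index]
    names = sorted(groups.unique())
    m1 = expr[groups == names[0]].mean(axis=0, skipna=True)
    m2 = expr[groups == names[1]].mean(axis=0, skipna=True)
    tot = m1 + m2
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot > 0, m1 / tot, np.nan)
    w = weights.loc[expr.index].sum(axis=0).to_numpy(dtype=float)
    share = np.where(np.isfinite(share), share, np.nan)
    return AlleleFrequencySeries(f=share, w=np.where(np.isfinite(share), w, 0.0))


def test_cre_dynamics(
    expr: pd.DataFrame,
    weights: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DynamicsResult:
    """Allele dynamics test on the expression share over time.

    Per timepoint the allele-1 share mean1/(mean1+mean2) of the barcode-mean
    expressions is formed, weighted by total raw reads, and the weighted
    Durbin-Watson permutation test is applied.  Needs >= 4 timepoints with
    both alleles defined.
    """
    if labels.loc[expr.index].nunique() != 2:
        return DynamicsResult(np.nan, np.nan, untestable=True)
    series = _allele_share_series(expr, weights, labels)
    return test_ase_dynamics(series, n_perm=n_perm, seed=seed)


def _genotype_at_variant(manifest: pd.DataFrame, variant_id: str) -> pd.Series:
    """Allele (P1/P2) carried at a focal variant by each construct.

    Parentals carry their own allele everywhere.  A swap construct carries
    the swapped-in allele at its own variant and the background allele at
    every other variant of the region; shared (invariant) constructs and
    chimeras are excluded (ambiguous).
    """
    out = {}
    for cid, sub in manifest.groupby("construct_id"):
        label = sub["allele_label"].iloc[0]
        if label == "P1":
            out[cid] = "P1"
        elif label == "P2":
            out[cid] = "P2"
        elif label.startswith("swap("):
            inner = label[5:-1]
            vid, direction = inner.split(",")
            src, dst = direction.split("->")
            if vid == str(variant_id):
                out[cid] = src  # swapped-in allele at the focal variant
            else:
                out[cid] = dst  # background allele elsewhere
    return pd.Series(out, name="genotype")


def test_variant(
    expr_series: CreExpressionSeries,
    region_manifest: pd.DataFrame,
    variant_id: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Level and dynamics tests for one variant of a multi-variant region.

    Constructs are pooled by the allele they carry at the focal variant
    (parentals plus swap constructs with an unambiguous genotype there);
    the two genotype groups are then compared exactly like parental
    alleles.  A genotype group emptied by filtering is untestable.
    """
    genotype = _genotype_at_variant(region_manifest, variant_id)
    bc2geno = (
        region_manifest.set_index("barcode")["construct_id"].map(genotype).dropna()
    )
    shared = expr_series.expression.index.intersection(bc2geno.index)
    labels = bc2geno.loc[shared]
    if labels.nunique() < 2:
        return {
            "variant": variant_id, "p_level": np.nan, "p_dyn": np.nan,
            "dw": np.nan, "untestable": True,
        }
    expr = expr_series.expression.loc[shared]
    lev = test_cre_levels(expr, labels)
    dyn = test_cre_dynamics(
        expr, expr_series.weights, labels, n_perm=n_perm, seed=seed
    )
    return {
        "variant": variant_id,
        "p_level": lev["p"],
        "p_dyn": dyn.p,
        "dw": dyn.dw,
        "untestable": bool(lev["untestable"] and dyn.untestable),
    }


# ---------------------------------------------------------------------------
# chimera mapping


@dataclass
class ChimeraResult:
    region: str
    p_parental: float
    p_proximal: float
    p_distal: float
    classification: str  # proximal | distal | both | neither | NA
    range_class: str  # inside | outside | NA
    d_pp: float
    d_cp_mean: float
    n_outside_timepoints: int


def _half_labels(manifest: pd.DataFrame, half: str) -> pd.Series:
    """Genotype of the proximal or distal half for each construct.

    Windows are written distal (left) to proximal (right), so
    ``chimera(left=P1)`` carries P1 in its distal half and P2 proximally.
    """
    out = {}
    for cid, sub in manifest.groupby("construct_id"):
        label = sub["allele_label"].iloc[0]
        if label in ("P1", "P2"):
            out[cid] = label
        elif label.startswith("chimera(left="):
            left = label[len("chimera(left=") : -1]
            right = "P2" if left == "P1" else "P1"
            out[cid] = left if half == "distal" else right
    return pd.Series(out)


def map_chimera(
    expr_series: CreExpressionSeries,
    region_manifest: pd.DataFrame,
    region: str = "",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ChimeraResult:
    """Locate a parental expression difference with chimeric constructs.

    Three dynamics tests are run: parents only, then all constructs grouped
    by the genotype of the proximal half, and by the distal half.  The
    difference maps to the proximal region if the proximal but not the
    distal genotype is significant (and conversely); significance in both
    or neither is reported as such.  The chimera series is also classified
    against the parental range (see :func:`classify_chimera_range`).
    """
    bc_construct = region_manifest.set_index("barcode")["construct_id"]
    parental = _half_labels(region_manifest, "proximal")
    parents_only = parental[
        parental.index.map(
            lambda cid: region_manifest.loc[
                region_manifest["construct_id"] == cid, "allele_label"
            ].iloc[0]
            in ("P1", "P2")
        )
    ]

    def run(geno: pd.Series) -> float:
        bc_lab = bc_construct.map(geno).dropna()
        shared = expr_series.expression.index.intersection(bc_lab.index)
        if len(shared) == 0 or bc_lab.loc[shared].nunique() < 2:
            return np.nan
        return test_cre_dynamics(
            expr_series.expression.loc[shared],
            expr_series.weights,
            bc_lab.loc[shared],
            n_perm=n_perm,
            seed=seed,
        ).p

    p_par = run(parents_only)
    p_prox = run(_half_labels(region_manifest, "proximal"))
    p_dist = run(_half_labels(region_manifest, "distal"))

    has_chimera = region_manifest["allele_label"].str.startswith("chimera").any()
    if not has_chimera or np.isnan(p_prox) or np.isnan(p_dist):
        classification = "NA"
    elif p_prox < alpha and p_dist >= alpha:
        classification = "proximal"
    elif p_dist < alpha and p_prox >= alpha:
        classification = "distal"
    elif p_prox < alpha and p_dist < alpha:
        classification = "both"
    else:
        classification = "neither"

    range_class, d_pp, d_cp, n_out = "NA", np.nan, np.nan, 0
    if has_chimera:
        def mean_of(label):
            cids = region_manifest.loc[
                region_manifest["allele_label"] == label, "construct_id"
            ].unique()
            if len(cids) == 0:
                return None
            bcs = region_manifest.loc[
                region_manifest["construct_id"].isin(cids), "barcode"
            ]
            rows = expr_series.expression.index.intersection(bcs)
            if len(rows) == 0:
                return None
            return expr_series.expression.loc[rows].mean(axis=0, skipna=True).to_numpy()

        p1s, p2s = mean_of("P1"), mean_of("P2")
        chims = [
            mean_of(lab)
            for lab in region_manifest.loc[
                region_manifest["allele_label"].str.startswith("chimera"),
                "allele_label",
            ].unique()
        ]
        chims = [c for c in chims if c is not None]
        if p1s is not None and p2s is not None and chims:
            per = [classify_chimera_range(p1s, p2s, c) for c in chims]
            d_pp = per[0][1]
            d_cp = float(np.mean([r[2] for r in per]))
            n_out = int(np.mean([r[3] for r in per]).round())
            range_class = "outside" if d_cp > d_pp else "inside"

    return ChimeraResult(
        region=region,
        p_parental=p_par,
        p_proximal=p_prox,
        p_distal=p_dist,
        classification=classification,
        range_class=range_class,
        d_pp=d_pp,
        d_cp_mean=d_cp,
        n_outside_timepoints=n_out,
    )


def classify_chimera_range(parent1, parent2, chimera):
    """Is a chimera's expression inside or outside the parental range?

    On the common defined timepoints, ``d_pp`` is the Euclidean distance
    between the parent series and ``d_cp_mean`` the mean of the chimera's
    distances to each parent; the chimera is ``outside`` iff
    d_cp_mean > d_pp.  Also counts timepoints where the chimera value lies
    strictly outside [min(parents), max(parents)].

    Returns (label, d_pp, d_cp_mean, n_outside_timepoints).
    """
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    c = np.asarray(chimera, dtype=float)
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(c)
    p1, p2, c = p1[ok], p2[ok], c[ok]
    d_pp = float(np.linalg.norm(p1 - p2))
    d_cp = float((np.linalg.norm(c - p1) + np.linalg.norm(c - p2)) / 2.0)
    lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
    n_out = int(((c < lo) | (c > hi)).sum())
    label = "outside" if d_cp > d_pp else "inside"
    return label, d_pp, d_cp, n_out
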