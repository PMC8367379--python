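"""Variant-burden association with ASE status.

Each gene gets three regions on its coding strand — the upstream
intergenic gap to the adjacent coding sequence (extended past short or
overlapping neighbours), the coding span, and 80 bp downstream of the stop
codon — and per-region SNP and InDel counts.  Logistic regressions
``logit p = b0 + b1 x`` then ask whether the burden ``x`` in a region
predicts significant ASE, with Bonferroni control over the battery of
6 predictors x 10 responses = 60 fits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegionSet",
    "AssociationResult",
    "define_regions",
    "count_region_variants",
    "logistic_association",
    "association_battery",
    "snp_indel_ratio",
]

REGION_TYPES = ("upstream", "coding", "downstream")
MIN_GAP = 5  # gaps shorter than this extend the upstream region further
DOWNSTREAM_LEN = 80


@dataclass
class RegionSet:
    """Per-gene genomic intervals, 0-based half-open on the reference.

    ``table`` columns: gene, contig, region (upstream/coding/downstream),
    start, end, clipped (bool, interval truncated at a contig edge).
    """

    table: pd.DataFrame

    def intervals(self, gene: str) -> pd.DataFrame:
        return self.table[self.table["gene"] == gene]


@dataclass
class AssociationResult:
    b0: float
    b1: float
    or_: float
    ci95: tuple
    p: float
    n: int
    significant: bool | None = None
    flag: str = ""


def define_regions(genes: pd.DataFrame, contig_lengths: dict) -> RegionSet:
    """Region intervals for every gene from a CDS annotation table.

    ``genes`` needs columns gene, contig, strand, cds_start, cds_end
    (0-based half-open).  The upstream region is the gap between the gene's
    CDS and the adjacent CDS on its 5' side; if that gap is shorter than
    5 bp (or the neighbour overlaps), the region extends past the neighbour
    to the next gene upstream.  Downstream is 80 bp 3' of the stop codon,
    clipped at contig ends.
    """
    rows = []
    for contig, group in genes.groupby("contig"):
        length = contig_lengths[contig]
        ordered = group.sort_values("cds_start").reset_index(drop=True)
        starts = ordered["cds_start"].to_numpy()
        ends = ordered["cds_end"].to_numpy()
        for i, rec in ordered.iterrows():
            if rec["cds_end"] <= rec["cds_start"]:
                raise ValueError(f"gene {rec['gene']} has an empty CDS")
            plus = rec["strand"] == "+"
            # --- upstream: walk 5' past short/overlapping neighbours
            if plus:
                bound = 0
                for j in range(i - 1, -1, -1):
                    gap = rec["cds_start"] - ends[j]
                    if gap >= MIN_GAP:
                        bound = ends[j]
                        break
                up = (bound, rec["cds_start"])
            else:
                bound = length
                for j in range(i + 1, len(ordered)):
                    gap = starts[j] - rec["cds_end"]
                    if gap >= MIN_GAP:
                        bound = starts[j]
                        break
                up = (rec["cds_end"], bound)
            # --- downstream: 80 bp past the stop codon
            if plus:
                down = (rec["cds_end"], min(rec["cds_end"] + DOWNSTREAM_LEN, length))
                clipped = down[1] - down[0] < DOWNSTREAM_LEN
            else:
                down = (max(rec["cds_start"] - DOWNSTREAM_LEN, 0), rec["cds_start"])
                clipped = down[1] - down[0] < DOWNSTREAM_LEN
            for region, (s, e), cl in (
                ("upstream", up, False),
                ("coding", (rec["cds_start"], rec["cds_end"]), False),
                ("downstream", down, clipped),
            ):
                rows.append(
                    {
                        "gene": rec["gene"],
                        "contig": contig,
                        "region": region,
                        "start": max(int(s), 0),
                        "end": min(int(e), length),
                        "clipped": cl,
                    }
                )
    return RegionSet(pd.DataFrame(rows))


def count_region_variants(variants: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Per gene x region x variant-class counts.

    ``variants`` columns: contig, pos (1-based leftmost reference base),
    type (SNP/INS/DEL).  A variant counts in a region iff its leftmost base
    lies in the interval; INS and DEL are pooled as InDels.  Returns a
    frame indexed by gene with columns like ``upstream_snps``.
    """
    known = set(regions.table["contig"])
    bad = set(variants["contig"]) - known
    if bad:
        raise KeyError(f"variants on unknown contig(s): {sorted(bad)}")
    klass = np.where(variants["type"].str.upper() == "SNP", "snps", "indels")
    pos0 = variants["pos"].to_numpy() - 1  # internal 0-based
    genes = regions.table["gene"].unique()
    cols = [f"{r}_{c}" for r in REGION_TYPES for c in ("snps", "indels")]
    out = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=cols)
    for _, reg in regions.table.iterrows():
        inside = (
            (variants["contig"] == reg["contig"]).to_numpy()
            & (pos0 >= reg["start"])
            & (pos0 < reg["end"])
        )
        if inside.any():
            for c in ("snps", "indels"):
                out.loc[reg["gene"], f"{reg['region']}_{c}"] += int(
                    (inside & (klass == c)).sum()
                )
    return out


def logistic_association(ase_status, x, alpha: float = 0.05) -> AssociationResult:
    """Fit ``logit p = b0 + b1 x`` by IRLS and report the odds ratio.

    Returns Wald CI and p for b1; complete separation or a constant
    predictor is flagged and the Wald interval withheld.
    """
    y = np.asarray(ase_status, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(y)) < 2:
        return AssociationResult(
            np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, len(y),
            flag="single_outcome_class",
        )
    if np.ptp(x) == 0:
        return AssociationResult(
            np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, len(y),
            flag="constant_predictor",
        )
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception:
            return AssociationResult(
                np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, len(y),
                flag="separation",
            )
    b0, b1 = fit.params
    se1 = fit.bse[1]
    if not np.isfinite(se1) or se1 > 100:  # Wald breakdown under separation
        return AssociationResult(
            float(b0), float(b1), float(np.exp(b1)), (np.nan, np.nan), np.nan,
            len(y), flag="separation",
        )
    lo, hi = np.exp(b1 - 1.959963984540054 * se1), np.exp(b1 + 1.959963984540054 * se1)
    return AssociationResult(
        b0=float(b0),
        b1=float(b1),
        or_=float(np.exp(b1)),
        ci95=(float(lo), float(hi)),
        p=float(fit.pvalues[1]),
        n=len(y),
    )


def association_battery(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Every response column regressed on every predictor column.

    ``responses`` holds binary ASE calls (one column per hybrid x test,
    10 in the full study), ``predictors`` the per-region variant counts
    (6 columns).  Genes missing from either table are dropped from the
    affected fits.  The Bonferroni threshold is ``alpha`` divided by the
    number of fits (0.05/60 for the full battery).
    """
    shared = responses.index.intersection(predictors.index)
    n_fits = responses.shape[1] * predictors.shape[1]
    rows = []
    for resp, pred in itertools.product(responses.columns, predictors.columns):
        sub = pd.concat(
            [responses.loc[shared, resp], predictors.loc[shared, pred]], axis=1
        ).dropna()
        res = logistic_association(sub.iloc[:, 0], sub.iloc[:, 1])
        rows.append(
            {
                "response": resp,
                "predictor": pred,
                "b0": res.b0,
                "b1": res.b1,
                "or": res.or_,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
                "p": res.p,
                "n": res.n,
                "flag": res.flag,
                "significant": bool(res.p < alpha / n_fits)
                if np.isfinite(res.p)
                else False,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_fits"] = n_fits
    out.attrs["bonferroni_alpha"] = alpha / n_fits
    return out


def snp_indel_ratio(n_significant_snps: int, n_significant_indels: int) -> float:
    """Ratio of significant SNPs to significant InDels in a result summary."""
    if n_significant_indels == 0:
        return float("inf") if n_significant_snps else float("nan")
    return n_significant_snps / n_significant_indels
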