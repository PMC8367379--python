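"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a diauxic-shift ASE study: a
19-timepoint allele-resolved expression timecourse over ~4700 genes, a
small two-haplotype genome fixture with annotated coding sequences and
TSSs, per-gene variant burdens linked to ASE status through a logistic
model, and DNA/RNA barcode counts for a reporter (CRE-seq) library.

Expression trajectories are anchored logistic curves in time: the logistic
is linearly rescaled so that it attains exactly ``baseline`` at the first
timepoint and ``baseline + amplitude`` at the last (peak/trough shapes use
a difference of two logistics rescaled to unit maximum).  Anchoring makes
the endpoint allele frequencies of delay- and rate-type effects exactly 0.5
in expectation, which is the defining feature of dynamics-only ASE.

Allele-specific effects transform allele 1's curve into allele 2's:

* ``level`` — constant 2**magnitude fold change at every timepoint;
* ``delay`` — the shift midpoint t50 moved by ``magnitude`` timepoints;
* ``rate`` — the logistic slope multiplied by ``magnitude``;
* ``condition`` — the post-shift plateau changed by 2**magnitude while the
  pre-shift plateau is shared.

Counts are negative binomial with variance mu + dispersion * mu^2
(dispersion 0 degenerates to Poisson).  One root seed feeds fixed
per-generator child streams, so adding a generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ase import AlleleCountMatrix

__all__ = [
    "TrajectoryParams",
    "AseEffect",
    "SimulationConfig",
    "GenomeFixture",
    "simulate_ase_counts",
    "simulate_cre_counts",
    "simulate_genome_fixture",
    "simulate_variant_burden",
    "trajectory_curve",
    "allele_curves",
]

SHAPES = ("increase", "decrease", "peak", "trough", "flat")
EFFECT_KINDS = ("none", "level", "delay", "rate", "condition")

# fixed child-stream labels; never renumber
_STREAMS = {"ase": 11, "cre": 23, "genome": 37, "burden": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class TrajectoryParams:
    """Shape of one gene's expression trajectory over the timecourse."""

    baseline: float = 1.0
    amplitude: float = 0.0
    t50: float = 7.0
    slope: float = 1.0
    shape: str = "flat"

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "flat" and self.amplitude != 0:
            raise ValueError("flat trajectories require amplitude = 0")


@dataclass
class AseEffect:
    """Cis-acting difference between the two alleles of a gene."""

    kind: str = "none"
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "none" and self.magnitude != 0:
            raise ValueError("kind 'none' requires magnitude 0")


@dataclass
class SimulationConfig:
    """Study-scale settings for the allele-count generator.

    ``depth`` is the mean total (both alleles) read count per gene per
    timepoint.  ``effect_mix`` maps effect kinds to gene fractions; any
    remainder is effect-free.  ``depth_sigma`` is the lognormal sd of
    per-timepoint library-size variation.
    """

    n_genes: int = 4703
    n_timepoints: int = 19
    depth: float = 600.0
    dispersion: float = 0.01
    effect_mix: dict = field(default_factory=dict)
    effect_magnitude: dict = field(default_factory=dict)
    shift_index: int = 7
    depth_sigma: float = 0.2
    flat_trajectories: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ValueError("need at least 4 timepoints")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        total = sum(self.effect_mix.values())
        if total > 1 + 1e-12:
            raise ValueError("effect fractions sum to more than 1")
        for kind in self.effect_mix:
            if kind not in EFFECT_KINDS:
                raise ValueError(f"unknown effect kind {kind!r}")


def _anchored_logistic(t: np.ndarray, t50: float, slope: float) -> np.ndarray:
    """Logistic in t rescaled to run exactly from 0 (t[0]) to 1 (t[-1])."""
    raw = 1.0 / (1.0 + np.exp(-slope * (t - t50)))
    lo, hi = raw[0], raw[-1]
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def trajectory_curve(params: TrajectoryParams, n_timepoints: int) -> np.ndarray:
    """Noise-free expression curve on the integer timepoint grid."""
    t = np.arange(n_timepoints, dtype=float)
    if params.shape == "flat":
        return np.full(n_timepoints, params.baseline)
    if params.shape in ("increase", "decrease"):
        amp = params.amplitude
        curve = params.baseline + amp * _anchored_logistic(t, params.t50, params.slope)
    else:  # peak / trough: difference of two logistics, unit-max rescaled
        half_width = max(n_timepoints / 6.0, 1.0)
        bump = 1.0 / (1.0 + np.exp(-params.slope * (t - (params.t50 - half_width)))) - 1.0 / (
            1.0 + np.exp(-params.slope * (t - (params.t50 + half_width)))
        )
        # detrend so both endpoints sit exactly at zero; shifted or rescaled
        # variants of the curve then stay endpoint-balanced
        bump = bump - (bump[0] + (bump[-1] - bump[0]) * t / (n_timepoints - 1))
        m = np.abs(bump).max()
        if m > 0:
            bump = bump / m
        curve = params.baseline + params.amplitude * bump
    return np.maximum(curve, 0.01 * params.baseline)


def apply_effect(params: TrajectoryParams, effect: AseEffect) -> TrajectoryParams:
    """Trajectory of allele 2 given allele 1's parameters and the effect.

    ``level`` is applied at sampling time as a constant multiplier (the
    parameters are unchanged); the other kinds reparameterize the curve.
    """
    if effect.kind in ("none", "level"):
        return params
    if effect.kind == "delay":
        return TrajectoryParams(
            params.baseline, params.amplitude, params.t50 + effect.magnitude,
            params.slope, params.shape,
        )
    if effect.kind == "rate":
        return TrajectoryParams(
            params.baseline, params.amplitude, params.t50,
            params.slope * effect.magnitude, params.shape,
        )
    if effect.kind == "condition":
        top = (params.baseline + params.amplitude) * 2.0**effect.magnitude
        return TrajectoryParams(
            params.baseline, top - params.baseline, params.t50,
            params.slope, params.shape,
        )
    raise ValueError(effect.kind)


def allele_curves(
    params: TrajectoryParams, effect: AseEffect, n_timepoints: int
):
    """Noise-free mean curves (allele1, allele2) before depth scaling."""
    c1 = trajectory_curve(params, n_timepoints)
    c2 = trajectory_curve(apply_effect(params, effect), n_timepoints)
    if effect.kind == "level":
        c2 = c2 * 2.0**effect.magnitude
    return c1, c2


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def _draw_trajectory(rng: np.random.Generator, shift: int, T: int) -> TrajectoryParams:
    shape = rng.choice(["increase", "decrease", "peak", "trough"])
    baseline = float(rng.lognormal(0.0, 0.5))
    if shape in ("increase", "peak"):
        amplitude = baseline * float(rng.uniform(0.5, 3.0))
    else:
        # downward moves are bounded so the curve stays positive
        amplitude = -baseline * float(rng.uniform(0.3, 0.85))
    t50 = float(shift + rng.normal(0, 1.0))
    t50 = min(max(t50, 1.0), T - 2.0)
    slope = float(rng.uniform(0.7, 1.5))
    return TrajectoryParams(baseline, amplitude, t50, slope, shape)


_DEFAULT_MAGNITUDE = {"level": 1.0, "delay": 2.0, "rate": 2.0, "condition": 1.0}


def simulate_ase_counts(config: SimulationConfig):
    """Simulate an allele-count timecourse plus its generating truth table.

    Returns ``(AlleleCountMatrix, truth)`` where ``truth`` is a DataFrame
    with one row per gene: effect kind and magnitude plus the trajectory
    parameters of allele 1.  Effect genes are the leading genes in
    effect-mix order; the remainder are effect-free with random (shared
    between alleles) trajectories.
    """
    rng = _rng(config.seed, "ase")
    G, T = config.n_genes, config.n_timepoints

    kinds = np.array(["none"] * G, dtype=object)
    pos = 0
    for kind, frac in config.effect_mix.items():
        n = int(round(frac * G))
        kinds[pos : pos + n] = kind
        pos += n

    lib = np.exp(rng.normal(0.0, config.depth_sigma, size=T)) if config.depth_sigma > 0 else np.ones(T)

    counts = np.empty((G, T, 2), dtype=np.int64)
    rows = []
    for g in range(G):
        if config.flat_trajectories:
            params = TrajectoryParams(float(rng.lognormal(0.0, 0.5)), 0.0,
                                      float(config.shift_index), 1.0, "flat")
        else:
            params = _draw_trajectory(rng, config.shift_index, T)
        kind = str(kinds[g])
        mag = config.effect_magnitude.get(kind, _DEFAULT_MAGNITUDE.get(kind, 0.0))
        # either allele can be the stronger/earlier one; direction-balanced
        # effects keep the normalization reference symmetric, as in real
        # hybrids where roughly half the imbalances favor each parent
        if kind in ("level", "condition", "delay") and rng.random() < 0.5:
            mag = -mag
        elif kind == "rate" and rng.random() < 0.5:
            mag = 1.0 / mag
        effect = AseEffect(kind, mag if kind != "none" else 0.0)
        c1, c2 = allele_curves(params, effect, T)
        scale = config.depth / (c1 + c2).mean()
        mu1 = scale * c1 * lib
        mu2 = scale * c2 * lib
        counts[g, :, 0] = _nb_draw(rng, mu1, config.dispersion)
        counts[g, :, 1] = _nb_draw(rng, mu2, config.dispersion)
        rows.append(
            {
                "gene": f"g{g:05d}",
                "kind": kind,
                "magnitude": effect.magnitude,
                "baseline": params.baseline,
                "amplitude": params.amplitude,
                "t50": params.t50,
                "slope": params.slope,
                "shape": params.shape,
            }
        )
    truth = pd.DataFrame(rows)
    matrix = AlleleCountMatrix(
        genes=truth["gene"].to_numpy(),
        timepoints=np.arange(T),
        counts=counts,
        hybrid="synthetic",
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# CRE-seq counts


@dataclass
class CreSimulationConfig:
    """Scale settings for the reporter-assay count generator."""

    n_timepoints: int = 19
    rna_depth: float = 1000.0
    dna_depth: float = 1000.0
    n_dna_samples: int = 2
    dispersion: float = 0.01
    abundance_sigma: float = 0.5
    seed: int = 0


def simulate_cre_counts(
    manifest: pd.DataFrame,
    construct_effects: dict,
    config: CreSimulationConfig,
    exact: bool = False,
):
    """Simulate DNA and RNA barcode count tables for a reporter library.

    ``manifest`` needs columns ``construct_id`` and ``barcode``;
    ``construct_effects`` maps construct_id to an expression curve: either a
    TrajectoryParams or an array of length n_timepoints (relative
    expression, the RNA/DNA ratio scale).  Each barcode's DNA abundance is
    drawn once (lognormal) and held constant across samples up to counting
    noise; RNA means are abundance x expression(t).

    Returns ``(dna, rna)`` DataFrames indexed by barcode, with columns
    ``DNA_0..`` and ``RNA_t0..``.  With ``exact=True`` the expected counts
    are returned instead of sampled ones.
    """
    unknown = set(construct_effects) - set(manifest["construct_id"])
    if unknown:
        raise KeyError(f"unknown construct ids in effects: {sorted(unknown)[:5]}")
    by_construct = manifest.groupby("construct_id")["barcode"].apply(list)
    if (by_construct.str.len() < 1).any():
        raise ValueError("every construct needs at least one barcode")

    rng = _rng(config.seed, "cre")
    T = config.n_timepoints
    barcodes = manifest["barcode"].to_numpy()
    construct_of = manifest["construct_id"].to_numpy()

    abundance = np.exp(rng.normal(0.0, config.abundance_sigma, size=len(barcodes)))
    expr = np.empty((len(barcodes), T))
    for i, cid in enumerate(construct_of):
        eff = construct_effects.get(cid)
        if eff is None:
            expr[i] = 1.0
        elif isinstance(eff, TrajectoryParams):
            expr[i] = trajectory_curve(eff, T)
        else:
            arr = np.asarray(eff, dtype=float)
            if arr.shape != (T,):
                raise ValueError(f"expression curve for {cid!r} has wrong length")
            expr[i] = arr

    mu_dna = abundance[:, None] * config.dna_depth * np.ones((1, config.n_dna_samples))
    mu_rna = abundance[:, None] * expr * config.rna_depth
    if exact:
        dna_counts, rna_counts = mu_dna, mu_rna
    else:
        dna_counts = _nb_draw(rng, mu_dna, config.dispersion)
        rna_counts = _nb_draw(rng, mu_rna, config.dispersion)
    dna = pd.DataFrame(
        dna_counts, index=pd.Index(barcodes, name="barcode"),
        columns=[f"DNA_{j}" for j in range(config.n_dna_samples)],
    )
    rna = pd.DataFrame(
        rna_counts, index=pd.Index(barcodes, name="barcode"),
        columns=[f"RNA_t{j}" for j in range(T)],
    )
    return dna, rna


# ---------------------------------------------------------------------------
# genome fixture


@dataclass
class GenomeFixture:
    """A toy two-haplotype genome with gene annotations and variants.

    ``sequences`` maps haplotype name -> {contig -> sequence}; ``genes`` is
    a table (gene, contig, strand, cds_start, cds_end, tss; 0-based
    half-open, tss 0-based position) in haplotype-1 coordinates;
    ``variants`` lists differences (contig, pos 1-based, ref, alt, type) in
    haplotype-1 coordinates.
    """

    sequences: dict
    genes: pd.DataFrame
    variants: pd.DataFrame
    contig: str = "chrS"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_genome_fixture(
    n_genes: int = 6,
    intergenic_len: int = 400,
    cds_len: int = 300,
    variant_rates: dict | None = None,
    seed: int = 0,
) -> GenomeFixture:
    """Build a small annotated genome pair differing by SNPs and InDels.

    Genes alternate on a single contig separated by ``intergenic_len``
    intergenic stretches; each gene's TSS sits 30 bp upstream of its CDS on
    the coding strand.  Haplotype 2 is derived from haplotype 1 by applying
    per-bp Bernoulli variants at the given rates (keys ``snp``, ``ins``,
    ``del``; defaults 0.01/0.001/0.001).  Variant positions are 1-based in
    haplotype-1 coordinates; insertions report the base after which the
    insert occurs, deletions the first deleted base.
    """
    rates = {"snp": 0.01, "ins": 0.001, "del": 0.001}
    if variant_rates is not None:
        rates.update(variant_rates)
    for k, v in rates.items():
        if not 0 <= v <= 1:
            raise ValueError(f"rate {k}={v} outside [0, 1]")
    rng = _rng(seed, "genome")

    parts = []
    genes = []
    pos = 0
    for g in range(n_genes):
        inter = _random_seq(rng, intergenic_len)
        parts.append(inter)
        pos += intergenic_len
        strand = "+" if g % 2 == 0 else "-"
        cds = "ATG" + _random_seq(rng, cds_len - 6) + "TAA"
        parts.append(cds)
        cds_start, cds_end = pos, pos + cds_len
        tss = cds_start - 30 if strand == "+" else cds_end + 29
        genes.append(
            {
                "gene": f"gene{g:03d}",
                "contig": "chrS",
                "strand": strand,
                "cds_start": cds_start,
                "cds_end": cds_end,
                "tss": tss,
            }
        )
        pos += cds_len
    parts.append(_random_seq(rng, intergenic_len))
    hap1 = "".join(parts)

    # mutate into haplotype 2, walking left to right in hap1 coordinates
    bases = "ACGT"
    out = []
    variants = []
    i = 0
    while i < len(hap1):
        r = rng.random()
        if r < rates["del"] and i + 4 < len(hap1):
            d = int(rng.integers(1, 5))
            variants.append(
                {"contig": "chrS", "pos": i + 1, "ref": hap1[i : i + d], "alt": "-",
                 "type": "DEL"}
            )
            i += d
            continue
        if r < rates["del"] + rates["ins"]:
            ins = _random_seq(rng, int(rng.integers(1, 5)))
            out.append(hap1[i])
            out.append(ins)
            variants.append(
                {"contig": "chrS", "pos": i + 1, "ref": "-", "alt": ins, "type": "INS"}
            )
            i += 1
            continue
        if r < rates["del"] + rates["ins"] + rates["snp"]:
            alt = bases[(bases.index(hap1[i]) + int(rng.integers(1, 4))) % 4]
            out.append(alt)
            variants.append(
                {"contig": "chrS", "pos": i + 1, "ref": hap1[i], "alt": alt,
                 "type": "SNP"}
            )
            i += 1
            continue
        out.append(hap1[i])
        i += 1
    hap2 = "".join(out)

    variants_df = pd.DataFrame(
        variants, columns=["contig", "pos", "ref", "alt", "type"]
    )
    return GenomeFixture(
        sequences={"hap1": {"chrS": hap1}, "hap2": {"chrS": hap2}},
        genes=pd.DataFrame(genes),
        variants=variants_df,
    )


# ---------------------------------------------------------------------------
# variant burden


def simulate_variant_burden(
    n_genes: int,
    b0: float = -2.0,
    b1: float = 0.5,
    burden_mean: float = 2.0,
    x: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-gene variant burdens and ASE status from a logistic model.

    ``x`` (the burden) is Poisson(``burden_mean``) unless given; ASE status
    is Bernoulli(expit(b0 + b1 * x)).  Used for parameter recovery of the
    association stage.
    """
    rng = _rng(seed, "burden")
    if x is None:
        x = rng.poisson(burden_mean, size=n_genes)
    x = np.asarray(x)
    if len(x) != n_genes:
        raise ValueError("x must have length n_genes")
    logit = b0 + b1 * x
    p = 1.0 / (1.0 + np.exp(-logit))
    status = rng.random(n_genes) < p
    return pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(n_genes)],
            "x": x,
            "ase": status.astype(int),
            "p_true": p,
        }
    )
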