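"""Variant annotation: conservation scores and binding-change scores.

Variants are annotated two ways.  PhastCons conservation probabilities
are read off a per-base score track — directly for SNPs, and for InDels
as the mean of the two flanking sites plus any sites inside the InDel.
Binding changes are scored with position weight matrices: each 30 bp
variant context is scanned with every motif (log2 likelihood ratio
against a 36% GC background, best placement over both strands, negative
best scores floored at zero, the convention under which a score of zero
means "no better than background"), and a variant's annotation is the
maximum across motifs of the absolute score difference between its two
alleles.  One-way ANOVA then asks whether the scores differ between
variants with positive, negative, and no measured expression effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Pwm",
    "VariantAnnotation",
    "background_frequencies",
    "pwm_scan",
    "binding_change_score",
    "phastcons_annotate",
    "score_group_anova",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
DEFAULT_GC = 0.36
PSEUDOCOUNT = 1e-3


def background_frequencies(gc: float = DEFAULT_GC) -> dict:
    """Base frequencies for a background of the given GC fraction.

    GC = 0.36 gives p(C) = p(G) = 0.18 and p(A) = p(T) = 0.32.
    """
    if not 0 < gc < 1:
        raise ValueError("GC fraction must lie in (0, 1)")
    at = (1.0 - gc) / 2.0
    return {"A": at, "C": gc / 2.0, "G": gc / 2.0, "T": at}


@dataclass
class Pwm:
    """Position probability matrix with a GC-parameterized background.

    ``matrix`` is (positions x 4), column order ACGT.  Zero probabilities
    are floored at a pseudocount and the row renormalized, so log ratios
    are always finite; rows without zeros are left untouched.
    """

    name: str
    matrix: np.ndarray
    gc: float = DEFAULT_GC

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be positions x 4 (ACGT)")
        if (m < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")
        floored = np.maximum(m, PSEUDOCOUNT)
        changed = (floored != m).any(axis=1)
        floored[changed] /= floored[changed].sum(axis=1, keepdims=True)
        self.matrix = floored
        bg = background_frequencies(self.gc)
        self._bg = np.array([bg[b] for b in _BASES])
        # log2 odds per position x base; used additively over placements
        self._logodds = np.log2(self.matrix / self._bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to ACGT indices; ambiguous bases become -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def _revcomp(sequence: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(sequence.upper()))


def _scan_one_strand(codes: np.ndarray, logodds: np.ndarray) -> tuple[float, int]:
    """Best placement score on one strand; ambiguous bases contribute 0."""
    L, n = logodds.shape[0], len(codes)
    best, best_pos = -np.inf, -1
    for start in range(n - L + 1):
        window = codes[start : start + L]
        ok = window >= 0
        score = float(logodds[np.arange(L)[ok], window[ok]].sum())
        if score > best:
            best, best_pos = score, start
    return best, best_pos


def pwm_scan(sequence: str, pwm: Pwm) -> dict:
    """Best motif placement over both strands, floored at zero.

    The score of a placement is the sum over motif positions of
    log2(p_motif(base) / p_background(base)); the best placement over all
    offsets and both strands is reported, and a negative best score — a
    site no more likely under the motif than under background — is set to
    zero.  Returns ``{"score", "raw_score", "position", "strand"}`` where
    ``position`` is the 0-based offset on the forward sequence.
    """
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than the motif")
    fwd_score, fwd_pos = _scan_one_strand(_encode(sequence), pwm._logodds)
    rc = _revcomp(sequence)
    rev_score, rev_pos = _scan_one_strand(_encode(rc), pwm._logodds)
    if rev_score > fwd_score:
        raw, strand = rev_score, "-"
        position = len(sequence) - pwm.length - rev_pos
    else:
        raw, strand = fwd_score, "+"
        position = fwd_pos
    return {
        "score": max(raw, 0.0),
        "raw_score": raw,
        "position": position,
        "strand": strand,
    }


@dataclass
class VariantAnnotation:
    variant_id: str
    phastcons: float = np.nan
    binding_delta: float = np.nan
    best_motif: str = ""


def binding_change_score(
    allele1_context: str,
    allele2_context: str,
    motifs: list,
    signed: bool = False,
) -> tuple[float, str]:
    """Maximum across motifs of the score difference between two alleles.

    Each allele's context (30 bp flanks around the variant, clipped at
    contig ends) is scanned with every motif; per motif the (absolute, or
    signed allele1-minus-allele2 when ``signed``) difference of the floored
    best scores is taken, and the maximum over motifs is returned with the
    motif achieving it.
    """
    if not motifs:
        raise ValueError("empty motif set")
    best_delta, best_name = -np.inf, ""
    for pwm in motifs:
        s1 = pwm_scan(allele1_context, pwm)["score"]
        s2 = pwm_scan(allele2_context, pwm)["score"]
        delta = (s1 - s2) if signed else abs(s1 - s2)
        if delta > best_delta:
            best_delta, best_name = delta, pwm.name
    return best_delta, best_name


def phastcons_annotate(variant: dict, track: dict) -> float:
    """Conservation score for one variant from a per-base score track.

    ``track`` maps 1-based position to score (one contig's worth).  SNPs
    take the score at their site; InDels take the mean of the two flanking
    sites plus any sites interior to the InDel.  For a deletion, ``pos``
    is the first deleted base and ``ref`` the deleted bases; for an
    insertion the insert goes after ``pos`` so the flanks are ``pos`` and
    ``pos + 1``.  Positions absent from the track are skipped; a variant
    with no covered site at all returns NaN.
    """
    pos = int(variant["pos"])
    vtype = str(variant["type"]).upper()
    if vtype == "SNP":
        return float(track.get(pos, np.nan))
    if vtype == "INS":
        sites = [pos, pos + 1]
    else:  # DEL
        ref = variant.get("ref", "")
        span = len(ref) if ref and ref != "-" else 1
        sites = [pos - 1] + list(range(pos, pos + span)) + [pos + span]
    scores = [track[s] for s in sites if s in track]
    return float(np.mean(scores)) if scores else float("nan")


def score_group_anova(scores, groups) -> tuple[float, float]:
    """One-way ANOVA of annotation scores across effect groups.

    ``groups`` labels each score (e.g. positive / negative / other);
    every group needs at least two members and at least two groups are
    required.  Returns (F, p).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(scores)
    scores, groups = scores[ok], groups[ok]
    samples = [scores[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 members each")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)
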