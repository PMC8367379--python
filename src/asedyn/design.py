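"""Reporter (CRE-seq) library design.

Each target promoter is tiled with 130 bp windows stepping 30 bp across
the 250 bp upstream of the TSS (five windows when the full region is
clear of upstream coding sequence), numbered 0 (proximal) to 4 (distal).
For every window both parental alleles are synthesized, plus — when the
window holds two or more variants — single-variant swap constructs that
place one strain's allele in the other strain's background, and optionally
chimeras joining the two parents at the alignment midpoint.  Constructs
are assembled into fixed-length 200 bp oligos:

    forward primer, RS1, CRE, RS2, [pad], RS3, RS4, barcode, RS5, reverse primer

where RS1-5 are restriction sites and the pad keeps InDel-gapped alleles
at constant length.  Barcodes are random 10-mers at pairwise Hamming
distance >= 2, free of restriction sites on either strand, with near-
uniform base composition; four barcode replicates tag every construct.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "LibraryDesign",
    "CreConstruct",
    "make_windows",
    "generate_barcodes",
    "build_alleles",
    "build_chimeras",
    "assemble_oligo",
    "disassemble_oligo",
    "design_library",
    "DEFAULT_PARTS",
]

OLIGO_LEN = 200
CRE_LEN = 130
BARCODE_LEN = 10

# placeholder sites/primers for the fixture; any restriction-site set works
DEFAULT_PARTS = {
    "fwd_primer": "ACGACGCTCTTCCGA",  # 15
    "rev_primer": "TCGGAAGAGCGTCGT",  # 15
    "RS1": "GAATTC",
    "RS2": "GGATCC",
    "RS3": "AAGCTT",
    "RS4": "CTGCAG",
    "RS5": "GTCGAC",
}


def restriction_sites(parts: dict) -> list:
    return [parts[k] for k in ("RS1", "RS2", "RS3", "RS4", "RS5")]


@dataclass
class CreConstruct:
    construct_id: str
    gene: str
    region_index: int
    allele_label: str
    cre_seq: str
    variant_ids: str = ""
    barcode: str = ""
    oligo: str = ""
    pad: int = 0


@dataclass
class LibraryDesign:
    constructs: list
    parts: dict

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "construct_id": c.construct_id,
                    "gene": c.gene,
                    "region_index": c.region_index,
                    "allele_label": c.allele_label,
                    "variant_ids": c.variant_ids,
                    "barcode": c.barcode,
                    "oligo_seq": c.oligo,
                }
                for c in self.constructs
            ]
        )


# ---------------------------------------------------------------------------
# windows


def make_windows(
    tss: int,
    strand: str,
    upstream_len: int = 250,
    window: int = CRE_LEN,
    step: int = 30,
    cds_mask: list | None = None,
    contig_len: int | None = None,
) -> list:
    """Tile the upstream promoter region with sliding windows.

    ``tss`` is the 0-based TSS position.  Windows of ``window`` bp step
    ``step`` bp away from the TSS on the coding strand, numbered
    proximal (0) to distal; windows overlapping an interval in
    ``cds_mask`` (0-based half-open coding spans of other genes) are
    dropped.  Returns (region_index, start, end) genomic intervals.
    """
    if upstream_len < window:
        warnings.warn("upstream region shorter than the window; no windows")
        return []
    n = (upstream_len - window) // step + 1
    out = []
    for i in range(n):
        if strand == "+":
            start, end = tss - window - i * step, tss - i * step
        else:
            start, end = tss + 1 + i * step, tss + 1 + window + i * step
        if start < 0 or (contig_len is not None and end > contig_len):
            continue
        if cds_mask and any(s < end and start < e for s, e in cds_mask):
            continue
        out.append((i, start, end))
    return out


# ---------------------------------------------------------------------------
# barcodes


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _contains_site(seq: str, sites) -> bool:
    rc = _revcomp(seq)
    return any(site in seq or site in rc for site in sites)


def generate_barcodes(
    n: int,
    length: int = BARCODE_LEN,
    min_dist: int = 2,
    forbidden_sites=(),
    seed: int | None = None,
    max_tries: int = 2_000_000,
    composition_tol: float = 0.10,
) -> list:
    """Random barcodes at pairwise Hamming distance >= ``min_dist``.

    No barcode contains a forbidden site on either strand, and the pooled
    base composition stays within ``composition_tol`` of uniform (checked,
    with resampling of the most skewed base if violated).
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    tries = 0
    while count < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"barcode space exhausted after {max_tries} tries "
                f"({count}/{n} accepted)"
            )
        cand = bases[rng.integers(0, 4, size=length)]
        seq = cand.tobytes().decode()
        if forbidden_sites and _contains_site(seq, forbidden_sites):
            continue
        if count and (accepted[:count] != cand).sum(axis=1).min() < min_dist:
            continue
        accepted[count] = cand
        count += 1
    # composition bias is only meaningful for sets large enough to average
    if n * length >= 400:
        freqs = np.array([(accepted == b).mean() for b in bases])
        if np.abs(freqs - 0.25).max() > composition_tol:
            raise RuntimeError("barcode base composition biased beyond tolerance")
    return [row.tobytes().decode() for row in accepted]


# ---------------------------------------------------------------------------
# alleles and swaps


def apply_variants(seq: str, variants: pd.DataFrame, subset=None) -> str:
    """Apply a subset of variants to a window sequence.

    ``variants`` rows carry ``offset`` (0-based within the window, leftmost
    affected base; for insertions the base after which the insert goes),
    ``ref``, ``alt`` and ``type``; ``-`` denotes an empty allele.  Variants
    are applied right to left so offsets stay valid.
    """
    if subset is None:
        subset = range(len(variants))
    chosen = variants.iloc[sorted(subset, key=lambda i: -variants.iloc[i]["offset"])]
    s = seq
    for _, v in chosen.iterrows():
        off = int(v["offset"])
        ref = "" if v["ref"] == "-" else v["ref"]
        alt = "" if v["alt"] == "-" else v["alt"]
        if off < 0 or off + len(ref) > len(s):
            raise ValueError(f"variant at offset {off} outside the window")
        if v["type"] == "INS":
            s = s[: off + 1] + alt + s[off + 1 :]
        else:
            if ref and s[off : off + len(ref)] != ref:
                raise ValueError(f"reference mismatch at offset {off}")
            s = s[:off] + alt + s[off + len(ref) :]
    return s


def build_alleles(
    window_seq: str,
    variants: pd.DataFrame,
    gene: str = "",
    region_index: int = 0,
    p1: str = "P1",
    p2: str = "P2",
) -> list:
    """Parental and single-variant-swap constructs for one window.

    ``window_seq`` is the P1 allele; the P2 allele applies all ``variants``.
    No variants -> one shared construct; one variant -> the two parents;
    k >= 2 variants -> two parents plus, per variant, the P2 allele in the
    P1 background and the P1 allele in the P2 background (2 + 2k total).
    """
    k = len(variants)
    base = f"{gene}_r{region_index}"
    if k == 0:
        return [
            CreConstruct(f"{base}_shared", gene, region_index, f"{p1}={p2}", window_seq)
        ]
    p2_seq = apply_variants(window_seq, variants)
    out = [
        CreConstruct(f"{base}_{p1}", gene, region_index, p1, window_seq,
                     variant_ids=""),
        CreConstruct(f"{base}_{p2}", gene, region_index, p2, p2_seq,
                     variant_ids=";".join(map(str, variants.index))),
    ]
    if k >= 2:
        for j in range(k):
            vid = str(variants.index[j])
            out.append(
                CreConstruct(
                    f"{base}_swap{j}_{p2}in{p1}", gene, region_index,
                    f"swap({vid},{p2}->{p1})",
                    apply_variants(window_seq, variants, [j]),
                    variant_ids=vid,
                )
            )
            out.append(
                CreConstruct(
                    f"{base}_swap{j}_{p1}in{p2}", gene, region_index,
                    f"swap({vid},{p1}->{p2})",
                    apply_variants(window_seq, variants,
                                   [i for i in range(k) if i != j]),
                    variant_ids=vid,
                )
            )
    return out


# ---------------------------------------------------------------------------
# chimeras


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


def build_chimeras(
    p1_seq: str,
    p2_seq: str,
    gene: str = "",
    region_index: int = 0,
    min_identity: float = 0.5,
) -> list:
    """Two chimeric constructs recombining the parents at the CRE center.

    The parents are globally aligned; the split is at the middle alignment
    column, so "center" is well defined even with InDels.  Chimera A takes
    the left (distal on a + strand window) half from P1 and the right from
    P2; chimera B is the converse.  Alignment identity below
    ``min_identity`` raises (likely mis-paired regions).
    """
    aln = _aligner().align(p1_seq, p2_seq)[0]
    ncol = aln.length
    idx = aln.indices  # 2 x ncol, -1 at gaps
    matches = sum(
        1
        for c in range(ncol)
        if idx[0, c] >= 0 and idx[1, c] >= 0 and p1_seq[idx[0, c]] == p2_seq[idx[1, c]]
    )
    if matches / ncol < min_identity:
        raise ValueError(
            f"alignment identity {matches / ncol:.2f} below {min_identity}; "
            "refusing to build chimeras from dissimilar sequences"
        )
    mid = ncol // 2
    n1_left = int((idx[0, :mid] >= 0).sum())
    n2_left = int((idx[1, :mid] >= 0).sum())
    base = f"{gene}_r{region_index}"
    return [
        CreConstruct(
            f"{base}_chimAB", gene, region_index, "chimera(left=P1)",
            p1_seq[:n1_left] + p2_seq[n2_left:],
        ),
        CreConstruct(
            f"{base}_chimBA", gene, region_index, "chimera(left=P2)",
            p2_seq[:n2_left] + p1_seq[n1_left:],
        ),
    ]


# ---------------------------------------------------------------------------
# oligo assembly


def _pad_sequence(length: int, construct_id: str, sites) -> str:
    """Deterministic filler for gapped alleles, free of restriction sites."""
    if length == 0:
        return ""
    digest = zlib.crc32(construct_id.encode()) % (2**31)
    rng = np.random.default_rng([97, digest])
    bases = "ACGT"
    for _ in range(1000):
        pad = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if not _contains_site(pad, sites):
            return pad
    raise RuntimeError("could not build a site-free pad")


def assemble_oligo(
    construct: CreConstruct,
    barcode: str,
    parts: dict = DEFAULT_PARTS,
    oligo_len: int = OLIGO_LEN,
    cre_ref_len: int = CRE_LEN,
) -> str:
    """Assemble the fixed-length oligo for one construct + barcode.

    Layout: fwd, RS1, CRE, RS2, pad, RS3, RS4, barcode, RS5, rev.  The pad
    compensates alleles whose CRE is shorter than ``cre_ref_len`` (InDel
    gaps).  Restriction sites inside the CRE or barcode, or a final length
    other than ``oligo_len``, raise.
    """
    sites = restriction_sites(parts)
    if _contains_site(construct.cre_seq, sites):
        raise ValueError(
            f"{construct.construct_id}: restriction site inside the CRE"
        )
    if _contains_site(barcode, sites):
        raise ValueError(f"barcode {barcode} contains a restriction site")
    if len(barcode) != BARCODE_LEN:
        raise ValueError("barcode must be 10 bp")
    pad_len = cre_ref_len - len(construct.cre_seq)
    if pad_len < 0:
        raise ValueError(
            f"{construct.construct_id}: CRE longer than the reference length"
        )
    pad = _pad_sequence(pad_len, construct.construct_id, sites)
    oligo = (
        parts["fwd_primer"] + parts["RS1"] + construct.cre_seq + parts["RS2"]
        + pad + parts["RS3"] + parts["RS4"] + barcode + parts["RS5"]
        + parts["rev_primer"]
    )
    if len(oligo) != oligo_len:
        raise ValueError(
            f"{construct.construct_id}: oligo length {len(oligo)} != {oligo_len}"
        )
    construct.pad = pad_len
    return oligo


def disassemble_oligo(oligo: str, parts: dict = DEFAULT_PARTS) -> dict:
    """Parse an oligo back into its parts (inverse of assemble_oligo)."""
    fwd, rev = parts["fwd_primer"], parts["rev_primer"]
    if not (oligo.startswith(fwd + parts["RS1"]) and oligo.endswith(parts["RS5"] + rev)):
        raise ValueError("oligo does not match the library layout")
    core = oligo[len(fwd) + len(parts["RS1"]) : -(len(parts["RS5"]) + len(rev))]
    i = core.find(parts["RS2"])
    if i < 0:
        raise ValueError("RS2 not found")
    cre = core[:i]
    rest = core[i + len(parts["RS2"]) :]
    j = rest.find(parts["RS3"])
    if j < 0:
        raise ValueError("RS3 not found")
    pad = rest[:j]
    tail = rest[j + len(parts["RS3"]) :]
    if not tail.startswith(parts["RS4"]):
        raise ValueError("RS4 not found")
    barcode = tail[len(parts["RS4"]) : len(parts["RS4"]) + BARCODE_LEN]
    return {"cre_seq": cre, "pad": pad, "barcode": barcode}


# ---------------------------------------------------------------------------
# whole-library driver


def design_library(
    sequences: dict,
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    upstream_len: int = 250,
    barcodes_per_construct: int = 4,
    chimeras: bool = False,
    parts: dict = DEFAULT_PARTS,
    seed: int | None = None,
) -> LibraryDesign:
    """Design the full library for a genome fixture.

    ``sequences`` maps contig -> haplotype-1 sequence; ``genes`` as in the
    genome fixture (needs tss, strand, cds spans); ``variants`` in 1-based
    haplotype-1 coordinates.  Windows overlapping another gene's CDS are
    dropped, as are windows whose P1 sequence contains a restriction site.
    Every construct receives ``barcodes_per_construct`` barcode replicates.
    """
    sites = restriction_sites(parts)
    constructs = []
    for _, g in genes.iterrows():
        contig_seq = sequences[g["contig"]]
        mask = [
            (r["cds_start"], r["cds_end"])
            for _, r in genes.iterrows()
            if r["gene"] != g["gene"] and r["contig"] == g["contig"]
        ]
        for region_index, start, end in make_windows(
            int(g["tss"]), g["strand"], upstream_len,
            cds_mask=mask, contig_len=len(contig_seq),
        ):
            window_seq = contig_seq[start:end]
            if g["strand"] == "-":
                window_seq = _revcomp(window_seq)
            if _contains_site(window_seq, sites):
                continue
            inside = variants[
                (variants["contig"] == g["contig"])
                & (variants["pos"] - 1 >= start)
                & (variants["pos"] - 1 < end)
            ].copy()
            if g["strand"] == "+":
                inside["offset"] = inside["pos"] - 1 - start
                window_variants = inside
            else:
                # project onto the reverse-complemented window
                rows = []
                for _, v in inside.iterrows():
                    ref = "" if v["ref"] == "-" else v["ref"]
                    alt = "" if v["alt"] == "-" else v["alt"]
                    right = v["pos"] - 1 + max(len(ref), 1) - 1
                    off = end - 1 - right
                    rows.append(
                        {
                            "offset": off if v["type"] != "INS" else off - 1,
                            "ref": _revcomp(ref) if ref else "-",
                            "alt": _revcomp(alt) if alt else "-",
                            "type": v["type"],
                        }
                    )
                window_variants = pd.DataFrame(
                    rows, columns=["offset", "ref", "alt", "type"],
                    index=inside.index,
                )
            window_variants = window_variants[
                (window_variants["offset"] >= 0)
                & (window_variants["offset"] < len(window_seq))
            ]
            group = build_alleles(
                window_seq, window_variants, g["gene"], region_index
            )
            group = [
                c for c in group if not _contains_site(c.cre_seq, sites)
            ]
            if chimeras and len(window_variants) > 0 and len(group) >= 2:
                p1c = next(c for c in group if c.allele_label == "P1")
                p2c = next(c for c in group if c.allele_label == "P2")
                group.extend(
                    build_chimeras(p1c.cre_seq, p2c.cre_seq, g["gene"], region_index)
                )
            constructs.extend(group)

    bcs = generate_barcodes(
        len(constructs) * barcodes_per_construct,
        forbidden_sites=sites,
        seed=seed,
    )
    replicated = []
    for i, c in enumerate(constructs):
        for r in range(barcodes_per_construct):
            bc = bcs[i * barcodes_per_construct + r]
            rep = CreConstruct(
                f"{c.construct_id}", c.gene, c.region_index, c.allele_label,
                c.cre_seq, c.variant_ids, bc,
            )
            rep.oligo = assemble_oligo(rep, bc, parts)
            replicated.append(rep)
    return LibraryDesign(replicated, parts)
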