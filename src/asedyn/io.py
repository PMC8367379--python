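"""Readers and writers for the pipeline's file formats.

Conventions: internal coordinates are 0-based half-open everywhere;
conversion from the 1-based closed GFF3/VCF world happens only here.
Floats are serialized at 6 significant digits so re-written tables diff
cleanly.  ``.gz`` paths are handled transparently on read and write.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Pwm
from .ase import AlleleCountMatrix
from .cre import CreCounts

__all__ = [
    "ParseError",
    "read_counts",
    "write_counts",
    "read_cre_counts",
    "write_cre_counts",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_variants",
    "write_variants",
    "read_meme_motifs",
    "read_bedgraph",
    "read_config",
    "write_config",
    "write_table",
]

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """A malformed input row, reported with its 1-based line number."""


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_table(frame: pd.DataFrame, path, sep: str = "\t", index: bool = False):
    with _open(path, "wt") as fh:
        frame.to_csv(fh, sep=sep, index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# allele count matrices (long TSV: gene, timepoint, allele, count)


def read_counts(path, hybrid: str = "") -> AlleleCountMatrix:
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = ["gene", "timepoint", "allele", "count"]
    if list(df.columns[:4]) != required:
        raise ParseError(
            f"{path}: expected columns {required}, found {list(df.columns)}"
        )
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts % 1 != 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: malformed count on line {line}")
    df["count"] = counts.astype(np.int64)
    bad_allele = ~df["allele"].isin(["ref", "alt"])
    if bad_allele.any():
        line = int(bad_allele.idxmax()) + 2
        raise ParseError(f"{path}: allele must be ref/alt on line {line}")
    genes = df["gene"].unique()
    tps = df["timepoint"].unique()
    wide = df.pivot_table(
        index="gene", columns=["timepoint", "allele"], values="count",
        fill_value=0, aggfunc="sum",
    ).reindex(genes)
    arr = np.zeros((len(genes), len(tps), 2), dtype=np.int64)
    for j, tp in enumerate(tps):
        for k, al in enumerate(("ref", "alt")):
            if (tp, al) in wide.columns:
                arr[:, j, k] = wide[(tp, al)].to_numpy()
    return AlleleCountMatrix(genes=genes, timepoints=tps, counts=arr, hybrid=hybrid)


def write_counts(matrix: AlleleCountMatrix, path) -> None:
    rows = []
    for g, gene in enumerate(matrix.genes):
        for t, tp in enumerate(matrix.timepoints):
            for k, al in enumerate(("ref", "alt")):
                rows.append((gene, tp, al, matrix.counts[g, t, k]))
    frame = pd.DataFrame(rows, columns=["gene", "timepoint", "allele", "count"])
    write_table(frame, path)


# ---------------------------------------------------------------------------
# CRE barcode counts (long TSV: barcode, sample, count)


def read_cre_counts(path, manifest: pd.DataFrame) -> CreCounts:
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if list(df.columns[:3]) != ["barcode", "sample", "count"]:
        raise ParseError(f"{path}: expected columns barcode, sample, count")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0)
    if bad.any():
        raise ParseError(f"{path}: malformed count on line {int(bad.idxmax()) + 2}")
    df["count"] = counts
    wide = df.pivot_table(
        index="barcode", columns="sample", values="count", fill_value=0,
        aggfunc="sum",
    )
    rna_cols = sorted(
        [c for c in wide.columns if c.startswith("RNA")],
        key=lambda c: (len(c), c),
    )
    dna_cols = sorted([c for c in wide.columns if c.startswith("DNA")])
    return CreCounts(wide[rna_cols], wide[dna_cols], manifest)


def write_cre_counts(counts: CreCounts, path) -> None:
    joint = pd.concat([counts.rna, counts.dna], axis=1)
    long = joint.stack().rename_axis(["barcode", "sample"]).reset_index(name="count")
    write_table(long, path)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3 (1-based closed on disk, 0-based half-open in memory)


def read_gff(path) -> pd.DataFrame:
    """Parse CDS features into a gene table.

    Returns columns gene, contig, strand, cds_start, cds_end (0-based
    half-open) and tss (0-based position) when a ``TSS`` attribute is
    present.
    """
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: expected 9 GFF columns on line {lineno}")
            contig, _source, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: bad coordinates on line {lineno}") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene = attr.get("ID") or attr.get("Parent") or attr.get("gene_id")
            if gene is None:
                raise ParseError(f"{path}: CDS without an ID on line {lineno}")
            row = {
                "gene": gene,
                "contig": contig,
                "strand": strand,
                "cds_start": start_i - 1,  # 1-based closed -> 0-based half-open
                "cds_end": end_i,
            }
            if "TSS" in attr:
                row["tss"] = int(attr["TSS"]) - 1
            rows.append(row)
    return pd.DataFrame(rows)


def write_gff(genes: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene']}"
            if "tss" in g and pd.notna(g.get("tss")):
                attrs += f";TSS={int(g['tss']) + 1}"
            fh.write(
                "\t".join(
                    [
                        g["contig"], "asedyn", "CDS",
                        str(int(g["cds_start"]) + 1), str(int(g["cds_end"])),
                        ".", g["strand"], "0", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# variants (TSV dialect or minimal VCF)


def read_variants(path) -> pd.DataFrame:
    """Read a variant table (contig, pos 1-based, ref, alt, type).

    Accepts the native TSV dialect or a minimal VCF (``.vcf`` suffix;
    CHROM/POS/REF/ALT with the type inferred from allele lengths; VCF
    InDel anchor bases are stripped so ``pos`` points at the first
    affected base and ``-`` marks an empty allele).
    """
    path = Path(path)
    if path.name.endswith((".vcf", ".vcf.gz")):
        rows = []
        with _open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 5:
                    raise ParseError(f"{path}: short VCF row on line {lineno}")
                contig, pos, _vid, ref, alt = fields[:5]
                pos = int(pos)
                if len(ref) == len(alt) == 1:
                    vtype = "SNP"
                elif len(ref) > len(alt):
                    vtype = "DEL"
                    pos, ref, alt = pos + len(alt), ref[len(alt):], "-"
                else:
                    vtype = "INS"
                    pos, ref, alt = pos + len(ref) - 1, "-", alt[len(ref):]
                rows.append(
                    {"contig": contig, "pos": pos, "ref": ref, "alt": alt,
                     "type": vtype}
                )
        return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "type"])
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    required = ["contig", "pos", "ref", "alt", "type"]
    if list(df.columns[: len(required)]) != required:
        raise ParseError(f"{path}: expected columns {required}")
    if not df["type"].isin(["SNP", "INS", "DEL"]).all():
        raise ParseError(f"{path}: variant type must be SNP/INS/DEL")
    return df


def write_variants(variants: pd.DataFrame, path) -> None:
    write_table(variants[["contig", "pos", "ref", "alt", "type"]], path)


# ---------------------------------------------------------------------------
# MEME minimal motifs


def read_meme_motifs(path, gc: float = 0.36) -> list:
    """Read position probability matrices from MEME minimal text format."""
    with _open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        pwm = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        out.append(Pwm(name=m.name, matrix=pwm, gc=gc))
    return out


# ---------------------------------------------------------------------------
# bedGraph score tracks


def read_bedgraph(path) -> dict:
    """Expand a bedGraph into {contig: {1-based position: score}}."""
    track: dict = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}: expected 4 bedGraph columns on line {lineno}")
            contig, start, end, score = fields
            start, end, score = int(start), int(end), float(score)
            per = track.setdefault(contig, {})
            for pos0 in range(start, end):  # bedGraph is 0-based half-open
                per[pos0 + 1] = score
    return track


# ---------------------------------------------------------------------------
# pipeline configuration


def read_config(path) -> dict:
    with _open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ParseError(f"{path}: config must be a mapping with a 'seed' key")
    return cfg


def write_config(config: dict, path) -> None:
    if "seed" not in config:
        raise ValueError("config must carry a 'seed' key")
    with _open(path, "wt") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
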