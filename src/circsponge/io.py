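"""Readers and writers for the standard formats the pipeline touches.

GTF is parsed directly (tab-delimited, 1-based inclusive coordinates converted
to 0-based half-open internally) so that malformed lines can be reported by
line number, which is part of this module's contract. FASTA goes through
Bio.SeqIO with duplicate-id / empty-record checks layered on top. Count,
junction and sample-metadata tables are plain TSV via pandas; write-then-read
of any table reproduces the object exactly.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    BackspliceJunction,
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    MiRNA,
    ParseError,
    Transcript,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

JUNCTION_FIXED_COLS = ["circ_id", "chrom", "strand", "acceptor", "donor"]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path) -> GenomeAnnotation:
    """Parse a GTF into a :class:`GenomeAnnotation`.

    Recognised feature types: ``gene``, ``transcript``, ``exon``,
    ``three_prime_utr``; all others are ignored. Transcripts absent as
    explicit lines are inferred from their exons.
    """
    genes: dict[str, Gene] = {}
    tx_info: dict[str, dict] = {}

    def _tx(tid, gid, chrom, strand):
        info = tx_info.setdefault(
            tid, {"gene_id": gid, "chrom": chrom, "strand": strand,
                  "exons": [], "utr3": None})
        return info

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ParseError(f"{path}: line {lineno}: end < start")
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            tid = attr.get("transcript_id")
            if feature == "gene":
                if gid is None:
                    raise ParseError(f"{path}: line {lineno}: gene line without gene_id")
                genes[gid] = Gene(gid, chrom, strand, start, end)
            elif feature == "transcript":
                if tid is None or gid is None:
                    raise ParseError(f"{path}: line {lineno}: transcript line missing ids")
                _tx(tid, gid, chrom, strand)
            elif feature == "exon":
                if tid is None or gid is None:
                    raise ParseError(f"{path}: line {lineno}: exon line missing ids")
                _tx(tid, gid, chrom, strand)["exons"].append((start, end))
            elif feature == "three_prime_utr":
                if tid is None:
                    raise ParseError(f"{path}: line {lineno}: UTR line missing transcript_id")
                _tx(tid, gid, chrom, strand)["utr3"] = (start, end)

    ann = GenomeAnnotation(genes=genes)
    for tid, info in tx_info.items():
        exons = sorted(info["exons"])
        if not exons:
            continue
        t = Transcript(tid, info["gene_id"], info["chrom"], info["strand"],
                       exons, info["utr3"])
        ann.transcripts[tid] = t
        if info["gene_id"] not in ann.genes:  # infer gene record from the transcript
            ann.genes[info["gene_id"]] = Gene(
                info["gene_id"], info["chrom"], info["strand"], exons[0][0], exons[-1][1])
    ann.validate()
    return ann


def write_gtf(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write("\t".join([g.chrom, "circsponge", "gene", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", f'gene_id "{g.gene_id}";']) + "\n")
            for t in sorted(ann.transcripts_of(g.gene_id), key=lambda t: t.transcript_id):
                base = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                s, e = t.span
                fh.write("\t".join([t.chrom, "circsponge", "transcript", str(s + 1), str(e),
                                    ".", t.strand, ".", base]) + "\n")
                for (es, ee) in t.exons:
                    fh.write("\t".join([t.chrom, "circsponge", "exon", str(es + 1), str(ee),
                                        ".", t.strand, ".", base]) + "\n")
                if t.utr3 is not None:
                    us, ue = t.utr3
                    fh.write("\t".join([t.chrom, "circsponge", "three_prime_utr",
                                        str(us + 1), str(ue), ".", t.strand, ".", base]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{id: uppercased sequence}`` (U/T preserved as read)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_mirnas(path) -> list[MiRNA]:
    """miRNA FASTA -> validated :class:`MiRNA` list (DNA input mapped to RNA)."""
    return [MiRNA(name, seq) for name, seq in read_fasta(path).items()]


# ---------------------------------------------------------------------------
# Count matrices and sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "condition"}
    if not required.issubset(meta.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def read_counts(path, sample_meta_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"{path}: non-numeric count in sample {col!r}")
        if (vals < 0).any():
            raise ParseError(f"{path}: negative count in sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ParseError(f"{path}: non-integer count in sample {col!r}")
    meta = read_sample_meta(sample_meta_path) if sample_meta_path is not None else None
    if meta is not None:
        missing = set(df.columns) - set(meta.index)
        if missing:
            raise ParseError(f"{path}: samples absent from metadata: {sorted(missing)}")
    return ExpressionMatrix(df.astype(np.int64), meta)


def write_counts(em: ExpressionMatrix, path, meta_path=None) -> None:
    em.counts.rename_axis("feature_id").to_csv(path, sep="\t")
    if meta_path is not None and em.sample_meta is not None:
        em.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Back-splice junction tables
# ---------------------------------------------------------------------------

def read_junctions(path, sample_meta_path=None):
    """Junction TSV -> (list of BackspliceJunction, circ ExpressionMatrix).

    Columns: circ_id, chrom, strand, acceptor, donor, then one integer count
    column per sample. Structural class is left unset (filled by
    :mod:`circsponge.annotate`).
    """
    df = pd.read_csv(path, sep="\t", dtype={"circ_id": str, "chrom": str, "strand": str})
    missing = [c for c in JUNCTION_FIXED_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: junction table missing columns {missing}")
    if df["circ_id"].duplicated().any():
        dup = df.loc[df["circ_id"].duplicated(), "circ_id"].iloc[0]
        raise ParseError(f"{path}: duplicate circ_id {dup!r}")
    junctions = []
    for _, row in df.iterrows():
        if row["acceptor"] >= row["donor"]:
            raise ParseError(
                f"{path}: junction {row['circ_id']}: acceptor >= donor")
        junctions.append(BackspliceJunction(
            circ_id=row["circ_id"], chrom=row["chrom"], strand=row["strand"],
            acceptor=int(row["acceptor"]), donor=int(row["donor"])))
    sample_cols = [c for c in df.columns if c not in JUNCTION_FIXED_COLS]
    counts = df.set_index("circ_id")[sample_cols]
    meta = read_sample_meta(sample_meta_path) if sample_meta_path is not None else None
    return junctions, ExpressionMatrix(counts, meta)


def write_junctions(junctions, counts: pd.DataFrame, path) -> None:
    rows = []
    for j in junctions:
        rows.append({"circ_id": j.circ_id, "chrom": j.chrom, "strand": j.strand,
                     "acceptor": j.acceptor, "donor": j.donor})
    left = pd.DataFrame(rows).set_index("circ_id")
    out = left.join(counts)
    out.reset_index().to_csv(path, sep="\t", index=False)


def write_annotated_junctions(junctions, path) -> None:
    rows = []
    for j in junctions:
        rows.append({
            "circ_id": j.circ_id, "chrom": j.chrom, "strand": j.strand,
            "acceptor": j.acceptor, "donor": j.donor,
            "host_gene": j.host_gene if j.host_gene is not None else "",
            "transcript_id": j.transcript_id if j.transcript_id is not None else "",
            "structural_class": j.structural_class or "",
            "exon_indices": ",".join(map(str, j.exon_indices)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
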