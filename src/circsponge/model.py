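"""Core domain types for the circRNA sponge-network pipeline.

Coordinate convention: all intervals are genomic, 0-based, half-open
``[start, end)``. GTF input/output converts at the boundary (GTF is 1-based
inclusive). Back-splice junctions store ``acceptor``/``donor`` as the genomic
min/max of the circularized span regardless of strand; strand is kept for
sequence extraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STRUCTURAL_CLASSES = ("single_exonic", "multi_exonic", "intergenic")


class PipelineError(Exception):
    """Base error for all circsponge failures."""


class ParseError(PipelineError):
    """Malformed input file."""


class ValidationError(PipelineError):
    """Object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based
    end: int    # half-open

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: bad span [{self.start}, {self.end})")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]            # sorted by genomic start, non-overlapping
    utr3: tuple[int, int] | None = None     # one interval within the transcript span

    def validate(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if not s < e:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon [{s}, {e}) has start >= end")
            if s < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping")
            prev_end = e
        if self.utr3 is not None:
            s, e = self.utr3
            if not (self.span[0] <= s < e <= self.span[1]):
                raise ValidationError(
                    f"transcript {self.transcript_id}: 3'UTR outside transcript span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript (reversed for '-')."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class GenomeAnnotation:
    """Gene/transcript/exon hierarchy with strand-aware half-open coordinates."""
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def validate(self) -> None:
        for t in self.transcripts.values():
            t.validate()
            if t.gene_id not in self.genes:
                raise ValidationError(f"transcript {t.transcript_id}: unknown gene {t.gene_id}")

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]


# ---------------------------------------------------------------------------
# Back-splice junctions
# ---------------------------------------------------------------------------

@dataclass
class BackspliceJunction:
    """A circRNA identified by its back-splice junction.

    ``acceptor`` is the genomic 5' boundary of the circularized span and
    ``donor`` its 3' boundary (acceptor < donor always). ``exon_indices`` are
    1-based exon ordinals in *transcript* order (so "exons 2 to 4" of a
    five-exon host reads [2, 3, 4] on either strand).
    """
    circ_id: str
    chrom: str
    strand: str
    acceptor: int
    donor: int
    exon_indices: list[int] = field(default_factory=list)
    host_gene: str | None = None
    transcript_id: str | None = None
    structural_class: str | None = None

    def __post_init__(self):
        if self.acceptor >= self.donor:
            raise ValidationError(
                f"junction {self.circ_id}: acceptor ({self.acceptor}) must be < donor ({self.donor})")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"junction {self.circ_id}: bad strand {self.strand!r}")

    def validate_class(self) -> None:
        c = self.structural_class
        if c is None:
            return
        if c not in STRUCTURAL_CLASSES:
            raise ValidationError(f"junction {self.circ_id}: unknown class {c!r}")
        if (c == "intergenic") != (self.host_gene is None):
            raise ValidationError(
                f"junction {self.circ_id}: intergenic iff host gene absent violated")
        if c == "multi_exonic" and len(self.exon_indices) < 2:
            raise ValidationError(f"junction {self.circ_id}: multi_exonic needs >= 2 exons")
        # single_exonic normally carries exactly one exon ordinal; a junction
        # inside a gene whose boundaries contain no full exon is still classed
        # single_exonic with empty indices (see circ_annotate).
        if c == "single_exonic" and len(self.exon_indices) > 1:
            raise ValidationError(f"junction {self.circ_id}: single_exonic with > 1 exon")

    def with_annotation(self, **kw) -> "BackspliceJunction":
        j = replace(self, **kw)
        j.validate_class()
        return j


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Integer count matrix (features x samples) with optional paired design.

    ``sample_meta`` is indexed by sample_id with columns ``subject_id`` and
    ``condition``; paired operations require every subject to contribute
    exactly one sample per condition.
    """
    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.number):
                raise ValidationError("non-numeric counts")
            if np.any(vals < 0):
                raise ValidationError("negative counts")
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "feature_id"
        self.counts.columns.name = None
        if self.sample_meta is not None:
            self.sample_meta.index.name = "sample_id"
        if self.sample_meta is not None:
            missing = set(self.counts.columns) - set(self.sample_meta.index)
            if missing:
                raise ValidationError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def _require_meta(self) -> pd.DataFrame:
        if self.sample_meta is None:
            raise ValidationError("operation requires sample metadata")
        return self.sample_meta.loc[list(self.counts.columns)]

    def samples_in(self, condition: str) -> list[str]:
        meta = self._require_meta()
        return list(meta.index[meta["condition"] == condition])

    def pairs(self, cond_a: str, cond_b: str) -> list[tuple[str, str]]:
        """(sample_a, sample_b) per subject; error unless exactly one of each."""
        meta = self._require_meta()
        out = []
        for subject, grp in meta.groupby("subject_id", sort=True):
            a = list(grp.index[grp["condition"] == cond_a])
            b = list(grp.index[grp["condition"] == cond_b])
            if len(a) != 1 or len(b) != 1:
                raise ValidationError(
                    f"subject {subject}: needs exactly one {cond_a!r} and one {cond_b!r} sample")
            out.append((a[0], b[0]))
        return out

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[list(features)], self.sample_meta)


# ---------------------------------------------------------------------------
# miRNA and DE results
# ---------------------------------------------------------------------------

_RNA_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3' RNA sequence (T is accepted and mapped to U)."""
    mirna_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValidationError(f"miRNA {self.mirna_id}: length {len(seq)} < 8")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValidationError(f"miRNA {self.mirna_id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    log2fc: float
    p: float
    padj: float

    def __post_init__(self):
        if self.padj + 1e-12 < self.p:
            raise ValidationError(f"{self.feature_id}: padj < p")

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"
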