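"""Structural annotation of back-splice junctions and CPM normalization.

A back-splice junction is mapped to its host gene by matching the acceptor and
donor coordinates against annotated exon boundaries: a transcript whose exon
set carries an exon starting exactly at the acceptor and one ending exactly at
the donor is preferred; otherwise the junction is assigned to the overlapping
gene with the largest span overlap (ties broken by gene_id). Junctions that
overlap no gene are intergenic. Structural classes follow the number of exons
fully contained in the circularized span: >= 2 -> multi_exonic, 1 ->
single_exonic, none (but inside a gene) -> single_exonic over the containing
region, with a warning.
"""
from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import (
    BackspliceJunction,
    ExpressionMatrix,
    GenomeAnnotation,
    PipelineError,
    Transcript,
)

log = logging.getLogger(__name__)


def cpm_normalize(matrix) -> pd.DataFrame:
    """Counts-per-million: each cell scaled so every sample sums to 1e6.

    Accepts an :class:`ExpressionMatrix` or a plain DataFrame. Raises if any
    sample has a zero total, naming the sample.
    """
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise PipelineError(f"zero-total sample(s): {list(zero)}")
    return counts * 1e6 / totals


def log2_cpm(matrix, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(cpm_normalize(matrix) + pseudocount)


# ---------------------------------------------------------------------------
# Junction classification
# ---------------------------------------------------------------------------

def _contained_ordinals(t: Transcript, acceptor: int, donor: int) -> list[int]:
    """1-based transcript-order ordinals of exons fully inside [acceptor, donor)."""
    ordered = t.exons_in_transcript_order()
    return [i + 1 for i, (s, e) in enumerate(ordered) if acceptor <= s and e <= donor]


def _boundary_match(t: Transcript, acceptor: int, donor: int) -> bool:
    starts = {s for s, _ in t.exons}
    ends = {e for _, e in t.exons}
    return acceptor in starts and donor in ends


def classify_junction(j: BackspliceJunction, ann: GenomeAnnotation) -> BackspliceJunction:
    """Return a copy of ``j`` with host gene, exon ordinals and class filled in."""
    overlapping = [g for g in ann.genes_on(j.chrom)
                   if g.start < j.donor and j.acceptor < g.end]
    if not overlapping:
        return j.with_annotation(host_gene=None, transcript_id=None,
                                 exon_indices=[], structural_class="intergenic")

    # Rank candidate (gene, transcript): exact boundary match first, then
    # overlap length, then most contained exons; deterministic id tie-breaks.
    best = None
    for g in overlapping:
        overlap = min(g.end, j.donor) - max(g.start, j.acceptor)
        for t in ann.transcripts_of(g.gene_id):
            exact = _boundary_match(t, j.acceptor, j.donor)
            ordinals = _contained_ordinals(t, j.acceptor, j.donor)
            key = (not exact, -overlap, -len(ordinals), g.gene_id, t.transcript_id)
            if best is None or key < best[0]:
                best = (key, g, t, ordinals)
        if not ann.transcripts_of(g.gene_id):
            key = (True, -overlap, 0, g.gene_id, "")
            if best is None or key < best[0]:
                best = (key, g, None, [])

    _, gene, tx, ordinals = best
    if len(ordinals) >= 2:
        cls = "multi_exonic"
    elif len(ordinals) == 1:
        cls = "single_exonic"
    else:
        log.warning("junction %s lies in gene %s but contains no full exon; "
                    "classing single_exonic over the containing region",
                    j.circ_id, gene.gene_id)
        cls = "single_exonic"
    return j.with_annotation(host_gene=gene.gene_id,
                             transcript_id=tx.transcript_id if tx else None,
                             exon_indices=ordinals, structural_class=cls)


def classify_all(junctions, ann: GenomeAnnotation) -> list[BackspliceJunction]:
    return [classify_junction(j, ann) for j in junctions]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def class_composition(junctions) -> dict:
    """Counts and fractions per structural class (fractions sum to 1)."""
    junctions = list(junctions)
    if not junctions:
        raise PipelineError("class_composition: empty junction list")
    counts = Counter(j.structural_class for j in junctions)
    unknown = set(counts) - {"single_exonic", "multi_exonic", "intergenic"}
    if unknown:
        raise PipelineError(f"unclassified junctions present: {unknown}")
    n = len(junctions)
    return {
        "counts": {c: counts.get(c, 0) for c in ("single_exonic", "multi_exonic", "intergenic")},
        "fractions": {c: counts.get(c, 0) / n for c in ("single_exonic", "multi_exonic", "intergenic")},
        "n": n,
    }


def chrom_distribution(junctions) -> dict[str, int]:
    """Junction count per chromosome; values sum to the number of junctions."""
    return dict(sorted(Counter(j.chrom for j in junctions).items()))


# ---------------------------------------------------------------------------
# Mature circRNA sequence
# ---------------------------------------------------------------------------

def circ_sequence(j: BackspliceJunction, ann: GenomeAnnotation,
                  genome: dict[str, str]) -> str:
    """Mature (intron-free) circRNA sequence in DNA alphabet, 5'->3'.

    Concatenates the included exon sequences in transcript order; minus-strand
    hosts are reverse-complemented. ``genome`` maps chromosome -> sequence.
    """
    if j.structural_class == "intergenic" or j.host_gene is None:
        raise PipelineError(f"junction {j.circ_id}: intergenic, no exon model")
    if j.transcript_id is None or not j.exon_indices:
        raise PipelineError(f"junction {j.circ_id}: no exon model for sequence extraction")
    t = ann.transcripts[j.transcript_id]
    chrom_seq = genome[t.chrom]
    ordered = t.exons_in_transcript_order()
    parts = []
    for ordinal in j.exon_indices:
        s, e = ordered[ordinal - 1]
        exon_seq = chrom_seq[s:e]
        if t.strand == "-":
            exon_seq = str(Seq(exon_seq).reverse_complement())
        parts.append(exon_seq)
    return "".join(parts)


def utr3_sequence(t: Transcript, genome: dict[str, str]) -> str:
    """Annotated 3'UTR sequence in transcript orientation (DNA alphabet)."""
    if t.utr3 is None:
        raise PipelineError(f"transcript {t.transcript_id}: no annotated 3'UTR")
    s, e = t.utr3
    seq = genome[t.chrom][s:e]
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
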