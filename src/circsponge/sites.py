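"""Canonical miRNA seed-site detection on linear and circular targets.

Site definitions follow the canonical TargetScan classes, built from the
miRNA seed (nucleotides 2-8, 5'->3'):

* ``7mer-m8``: perfect Watson-Crick match to nt 2-8,
* ``7mer-A1``: match to nt 2-7 followed by an adenosine opposite nt 1,
* ``8mer``: match to nt 2-8 followed by the A1 adenosine.

Scanning works in DNA space (RNA targets are mapped U->T at the boundary).
On circular sequences the target is extended by its own first
``site length - 1`` bases so sites that straddle the back-splice junction are
found; their positions are reported modulo the circle length and flagged
``spans_junction``. When an 8mer matches, the 7mer-m8 at the same seed
position and the 7mer-A1 one base downstream are the same physical site and
are suppressed, so no position carries two reported types.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .model import MiRNA, PipelineError

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
MIN_SITE_LEN = 7
MAX_SITE_LEN = 8


@dataclass(frozen=True)
class SeedSiteHit:
    mirna_id: str
    target_id: str
    target_kind: str            # "circ" or "utr3"
    position: int               # 0-based start in the target's linear representation
    site_type: str
    spans_junction: bool = False

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise PipelineError(f"unknown site type {self.site_type!r}")
        if self.target_kind not in ("circ", "utr3"):
            raise PipelineError(f"unknown target kind {self.target_kind!r}")
        if self.target_kind == "utr3" and self.spans_junction:
            raise PipelineError("a linear 3'UTR site cannot span a junction")


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def site_strings(m: MiRNA) -> dict[str, str]:
    """Target-site DNA strings for each canonical site type of ``m``."""
    seq = _dna(m.sequence)
    if len(seq) < 8:
        raise PipelineError(f"miRNA {m.mirna_id}: needs >= 8 nt for seed sites")
    seed_2_8 = seq[1:8]
    seed_2_7 = seq[1:7]
    rc = lambda s: str(Seq(s).reverse_complement())
    return {
        "8mer": rc(seed_2_8) + "A",
        "7mer-m8": rc(seed_2_8),
        "7mer-A1": rc(seed_2_7) + "A",
    }


def _find_all(haystack: str, needle: str, max_start: int | None = None) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        if max_start is not None and i >= max_start:
            break
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _collapse(pos_by_type: dict[str, list[int]], length: int | None) -> list[tuple[int, str]]:
    """Apply 8mer > 7mer-m8 > 7mer-A1 precedence at a shared seed match.

    ``length`` is the circle length for modular neighbor lookup, or None for
    linear targets.
    """
    p8 = set(pos_by_type.get("8mer", ()))
    hits = [(p, "8mer") for p in p8]
    for p in pos_by_type.get("7mer-m8", ()):
        if p not in p8:
            hits.append((p, "7mer-m8"))
    for p in pos_by_type.get("7mer-A1", ()):
        prev = (p - 1) % length if length is not None else p - 1
        if prev not in p8:
            hits.append((p, "7mer-A1"))
    return sorted(hits)


def scan_linear(target_seq: str, m: MiRNA, target_id: str = "",
                target_kind: str = "utr3") -> list[SeedSiteHit]:
    """All canonical seed sites of ``m`` in a linear target sequence."""
    seq = _dna(target_seq)
    strings = site_strings(m)
    pos_by_type = {t: _find_all(seq, w) for t, w in strings.items() if len(w) <= len(seq)}
    return [SeedSiteHit(m.mirna_id, target_id, target_kind, p, t)
            for p, t in _collapse(pos_by_type, None)]


def scan_circular(circ_seq: str, m: MiRNA, target_id: str = "") -> list[SeedSiteHit]:
    """All canonical seed sites of ``m`` on a circular target.

    The circle is scanned as ``seq + seq[:max_site_len - 1]`` with match starts
    restricted to one period, so each physical site is reported once; sites
    crossing the origin are flagged ``spans_junction``. Site types longer than
    the circle are skipped; a circle shorter than the shortest site is an
    error.
    """
    seq = _dna(circ_seq)
    n = len(seq)
    if n < MIN_SITE_LEN:
        raise PipelineError(f"circular target shorter than the shortest site ({MIN_SITE_LEN} nt)")
    extended = seq + seq[:MAX_SITE_LEN - 1]
    strings = site_strings(m)
    pos_by_type = {t: _find_all(extended, w, max_start=n)
                   for t, w in strings.items() if len(w) <= n}
    hits = []
    for p, t in _collapse(pos_by_type, n):
        spans = p + len(strings[t]) > n
        hits.append(SeedSiteHit(m.mirna_id, target_id, "circ", p, t, spans))
    return hits


def site_count_table(targets: dict[str, tuple[str, str]],
                     mirnas: list[MiRNA]) -> pd.DataFrame:
    """Count canonical sites for every (target, miRNA) combination.

    ``targets`` maps target_id -> (kind, sequence) with kind "circ" or
    "utr3"; circ targets use the circular scanner. Zero-count pairs are
    omitted. Returns a DataFrame with columns target_id, target_kind,
    mirna_id, n_sites.
    """
    rows = []
    for target_id, (kind, seq) in targets.items():
        for m in mirnas:
            if kind == "circ":
                hits = scan_circular(seq, m, target_id)
            elif kind == "utr3":
                hits = scan_linear(seq, m, target_id, "utr3")
            else:
                raise PipelineError(f"target {target_id}: unknown kind {kind!r}")
            if hits:
                rows.append({"target_id": target_id, "target_kind": kind,
                             "mirna_id": m.mirna_id, "n_sites": len(hits)})
    return pd.DataFrame(rows, columns=["target_id", "target_kind", "mirna_id", "n_sites"])
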