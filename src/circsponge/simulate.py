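"""Synthetic tumor/normal cohort with a recorded ground truth.

The generator emits a complete, self-consistent study: a gene annotation with
exon structure and 3'UTRs, chromosome sequences, a back-splice junction table
with per-sample counts, an mRNA count matrix over the same paired samples, a
miRNA set, and a knockdown experiment — plus the planted truth every
downstream stage must recover.

Count model. Counts are negative binomial via Gamma-Poisson:
``counts ~ Poisson(Gamma(1/phi, phi * mu))`` with dispersion ``phi``, giving
``Var = mu + phi mu^2``. The log-mean per feature f and sample j is

    log mu_fj = log base_f + lfc_f * [tumor_j] * ln 2
                + sd_subject * a_subj(j) + sd_bio * w_fj + log sf_j  (centred)

where ``a`` is a subject effect shared by both samples of a subject (so the
paired contrast removes it), ``sf`` is a log-uniform library size factor, and
``w`` is the biological latent that plants co-expression: each circRNA owns an
i.i.d. standard-normal latent per sample, and a gene planted to correlate with
circ ``c`` at strength rho and sign s uses
``w_g = s*sqrt(rho)*z_c + sqrt(1-rho)*u_g``. With rho -> 1 and dispersion -> 0
the sample correlation of log-CPM approaches +-1.

Sequence model. Planted sponge triplets carry exactly two canonical seed
sites for their miRNA in the circRNA (one spanning the back-splice junction
with configurable probability) and one site in the mRNA 3'UTR. Every scanned
sequence is scrubbed of accidental seed matches for every simulated miRNA
(rewrite-and-rescan loop, verified with the production scanner), so planted
site counts are exact by construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as csio
from .model import (
    BackspliceJunction,
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    MiRNA,
    PipelineError,
    Transcript,
)
from . import sites as sitemod

_DNA = "ACGT"
_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults match the emulated study design: 39 matched tumor/normal pairs,
    20 planted sponge triplets at correlation strength 0.9, planted circRNA
    |log2 fold change| of 2, NB dispersion 0.2, and 100+100 decoy correlated
    pairs without shared seed sites.
    """
    n_subjects: int = 39
    n_circ: int = 150
    n_mrna: int = 400
    n_mirna: int = 20
    n_planted_triplets: int = 20
    n_planted_dec_extra: int = 10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    bio_sd: float = 0.7
    subject_sd: float = 0.3
    rho: float = 0.9
    host_rho: float = 0.6
    n_decoy_pos: int = 100
    n_decoy_neg: int = 100
    n_kd_pos: int = 8
    n_kd_neg: int = 4
    kd_log2fc: float = 2.0
    kd_dispersion: float = 0.05
    kd_replicates: int = 3
    p_junction_site: float = 0.5
    frac_single: float = 0.08
    frac_intergenic: float = 0.04
    exon_len: tuple[int, int] = (90, 180)
    circ_exons: tuple[int, int] = (2, 4)
    utr_len: tuple[int, int] = (150, 300)
    lib_size: tuple[float, float] = (3e5, 1e6)
    circ_mean: tuple[float, float] = (100, 1000)
    mrna_mean: tuple[float, float] = (50, 500)
    kd_mean: tuple[float, float] = (100, 800)
    n_chroms: int = 6
    mirna_len: int = 22


@dataclass
class SyntheticTruth:
    """Everything the pipeline is supposed to recover."""
    seed: int
    n_subjects: int
    nb_dispersion: float
    planted_dec: dict[str, float]                       # circ -> true log2fc
    planted_corr: dict[tuple[str, str], tuple[int, float]]  # (circ, mrna) -> (sign, rho)
    planted_triplets: list[tuple[str, str, str]]        # (circ, mirna, mrna)
    planted_kd_targets: dict[str, str]                  # gene -> expected KD direction
    kd_circ: str
    circ_ids: list[str]
    mrna_ids: list[str]

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "nb_dispersion": self.nb_dispersion,
            "planted_dec": self.planted_dec,
            "planted_corr": {f"{c}|{g}": list(v) for (c, g), v in self.planted_corr.items()},
            "planted_triplets": [list(t) for t in self.planted_triplets],
            "planted_kd_targets": self.planted_kd_targets,
            "kd_circ": self.kd_circ,
            "circ_ids": self.circ_ids,
            "mrna_ids": self.mrna_ids,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        corr = {tuple(k.split("|")): (int(v[0]), float(v[1]))
                for k, v in d["planted_corr"].items()}
        return cls(
            seed=d["seed"], n_subjects=d["n_subjects"],
            nb_dispersion=d["nb_dispersion"], planted_dec=d["planted_dec"],
            planted_corr=corr,
            planted_triplets=[tuple(t) for t in d["planted_triplets"]],
            planted_kd_targets=d["planted_kd_targets"], kd_circ=d["kd_circ"],
            circ_ids=d["circ_ids"], mrna_ids=d["mrna_ids"])


@dataclass
class Cohort:
    """Bundle of all simulated inputs plus the truth."""
    annotation: GenomeAnnotation
    genome: dict[str, str]
    junctions: list[BackspliceJunction]
    circ_matrix: ExpressionMatrix
    mrna_matrix: ExpressionMatrix
    mirnas: list[MiRNA]
    utr_seqs: dict[str, str]        # gene_id -> 3'UTR sequence (transcript orientation)
    circ_seqs: dict[str, str]       # circ_id -> mature sequence (non-intergenic only)
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# miRNA generation
# ---------------------------------------------------------------------------

def _mirna_set_ok(strings_list: list[dict[str, str]]) -> bool:
    # Cross-miRNA: no site string of one may occur inside any string of another
    # (such a nesting would make planted sites ambiguous and unscrubbable).
    for i, si in enumerate(strings_list):
        for jdx, sj in enumerate(strings_list):
            if i == jdx:
                continue
            for wi in si.values():
                for wj in sj.values():
                    if wj in wi:
                        return False
    # Self-consistency: inside the 8mer, the 7mer-m8 occurs only at offset 0
    # and the 7mer-A1 only at offset 1 (otherwise planted counts inflate).
    for s in strings_list:
        e = s["8mer"]
        if [p for p in range(2) if e[p:p + 7] == s["7mer-m8"]] != [0]:
            return False
        if [p for p in range(2) if e[p:p + 7] == s["7mer-A1"]] != [1]:
            return False
    return True


def _make_mirnas(cfg: CohortConfig, rng: np.random.Generator) -> list[MiRNA]:
    for _ in range(500):
        mirnas = []
        for i in range(cfg.n_mirna):
            seq = "".join(rng.choice(list("ACGU"), size=cfg.mirna_len))
            mirnas.append(MiRNA(f"miR-{i + 1:03d}", seq))
        if _mirna_set_ok([sitemod.site_strings(m) for m in mirnas]):
            return mirnas
    raise PipelineError("could not generate a conflict-free miRNA set")


# ---------------------------------------------------------------------------
# Sequence planting and scrubbing
# ---------------------------------------------------------------------------

def _find_all(hay: str, needle: str, max_start=None) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1 and (max_start is None or i < max_start):
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _scrub(seq: list[str], all_strings: list[str], protected: np.ndarray,
           circular: bool, rng: np.random.Generator, max_iter: int = 300) -> None:
    """Rewrite unprotected bases until no site string occurs outside protected ranges."""
    n = len(seq)
    for _ in range(max_iter):
        hay = "".join(seq)
        if circular:
            hay = hay + hay[:sitemod.MAX_SITE_LEN - 1]
        dirty = False
        for w in all_strings:
            if len(w) > n:
                continue
            for p in _find_all(hay, w, max_start=n if circular else None):
                cover = [(p + k) % n if circular else p + k for k in range(len(w))]
                if all(protected[q] for q in cover):
                    continue
                dirty = True
                for q in cover:
                    if not protected[q]:
                        seq[q] = _DNA[rng.integers(0, 4)]
        if not dirty:
            return
    raise PipelineError("sequence scrubbing did not converge; config likely infeasible")


def _plant_positions(n: int, site_lens: list[int], rng: np.random.Generator,
                     junction_first: bool) -> list[int]:
    """Non-overlapping (buffer 2) site start positions; first may wrap the origin."""
    if n < sum(site_lens) + 4 * len(site_lens):
        raise PipelineError(f"sequence of length {n} too short for requested sites")
    for _ in range(500):
        starts, covered = [], set()
        ok = True
        for idx, wl in enumerate(site_lens):
            if idx == 0 and junction_first:
                s = int(rng.integers(n - wl + 1, n))
            else:
                s = int(rng.integers(0, n - wl + 1))
            cover = {(s + k) % n for k in range(-2, wl + 2)}
            if cover & covered:
                ok = False
                break
            starts.append(s)
            covered |= cover
        if ok:
            return starts
    raise PipelineError("could not place non-overlapping seed sites")


def _plant(seq: list[str], strings: list[str], starts: list[int]) -> np.ndarray:
    n = len(seq)
    protected = np.zeros(n, dtype=bool)
    for w, s in zip(strings, starts):
        for k, ch in enumerate(w):
            seq[(s + k) % n] = ch
            protected[(s + k) % n] = True
    return protected


def _prepare_target(seq: list[str], mirna: MiRNA | None, n_sites: int,
                    all_strings: list[str], rng: np.random.Generator,
                    circular: bool, junction_site: bool) -> list[int]:
    """Plant ``n_sites`` sites of ``mirna`` (or none) and scrub everything else.

    Returns the planted start positions. Verified with the production scanner;
    retried with fresh positions on the rare planting conflict.
    """
    n = len(seq)
    for _ in range(20):
        if mirna is not None and n_sites > 0:
            strs = sitemod.site_strings(mirna)
            # alternate site types for variety: 8mer first, then 7mer-m8
            chosen = [strs["8mer"] if k % 2 == 0 else strs["7mer-m8"] for k in range(n_sites)]
            starts = _plant_positions(n, [len(w) for w in chosen], rng, junction_site)
            protected = _plant(seq, chosen, starts)
        else:
            starts = []
            protected = np.zeros(n, dtype=bool)
        try:
            _scrub(seq, all_strings, protected, circular, rng)
        except PipelineError:
            continue
        if mirna is None:
            return starts
        text = "".join(seq)
        hits = (sitemod.scan_circular(text, mirna) if circular
                else sitemod.scan_linear(text, mirna))
        if sorted(h.position for h in hits) == sorted(starts):
            return starts
    raise PipelineError("site planting failed to verify; config likely infeasible")


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

class _GeneDraft:
    """Mutable per-gene scaffold: genomic exon intervals + sequence arrays."""

    def __init__(self, gene_id, chrom, strand, exons, exon_seqs, utr_len):
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.exons = exons              # genomic order
        self.exon_seqs = exon_seqs      # genomic orientation, list[list[char]]
        # 3'UTR sits at the transcript 3' end: genomic-last exon on '+',
        # genomic-first exon on '-'.
        if strand == "+":
            s, e = exons[-1]
            self.utr3 = (e - utr_len, e)
        else:
            s, e = exons[0]
            self.utr3 = (s, s + utr_len)

    def _genomic_index(self, ordinal: int) -> int:
        return ordinal - 1 if self.strand == "+" else len(self.exons) - ordinal

    def get_mature(self, ordinals: list[int]) -> list[str]:
        parts = []
        for o in ordinals:
            gi = self._genomic_index(o)
            chunk = self.exon_seqs[gi]
            if self.strand == "-":
                chunk = list(str(Seq("".join(chunk)).reverse_complement()))
            parts.extend(chunk)
        return parts

    def set_mature(self, ordinals: list[int], seq: list[str]) -> None:
        pos = 0
        for o in ordinals:
            gi = self._genomic_index(o)
            ln = len(self.exon_seqs[gi])
            chunk = seq[pos:pos + ln]
            if self.strand == "-":
                chunk = list(str(Seq("".join(chunk)).reverse_complement()))
            self.exon_seqs[gi] = chunk
            pos += ln

    def get_utr(self) -> list[str]:
        gi = len(self.exons) - 1 if self.strand == "+" else 0
        es, _ = self.exons[gi]
        s, e = self.utr3
        chunk = self.exon_seqs[gi][s - es:e - es]
        if self.strand == "-":
            chunk = list(str(Seq("".join(chunk)).reverse_complement()))
        return chunk

    def set_utr(self, seq: list[str]) -> None:
        gi = len(self.exons) - 1 if self.strand == "+" else 0
        es, _ = self.exons[gi]
        s, e = self.utr3
        chunk = seq
        if self.strand == "-":
            chunk = list(str(Seq("".join(chunk)).reverse_complement()))
        self.exon_seqs[gi][s - es:e - es] = chunk


def _loguniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> Cohort:
    cfg = config
    rng = np.random.default_rng(seed)

    n_inter = int(round(cfg.frac_intergenic * cfg.n_circ))
    n_single = int(round(cfg.frac_single * cfg.n_circ))
    n_trip = cfg.n_planted_triplets
    if n_trip + n_inter + n_single > cfg.n_circ:
        raise PipelineError("infeasible config: class fractions leave no room for planted circRNAs")

    # structural class per circ: planted-triplet circs are multi-exonic (they
    # need an exon model); singles and intergenics drawn from the rest.
    classes = ["multi_exonic"] * cfg.n_circ
    rest = list(range(n_trip, cfg.n_circ))
    special = rng.choice(rest, size=n_single + n_inter, replace=False)
    for i in special[:n_single]:
        classes[i] = "single_exonic"
    for i in special[n_single:]:
        classes[i] = "intergenic"

    circ_ids = [f"circ{i + 1:04d}" for i in range(cfg.n_circ)]
    mrna_ids = [f"G{i + 1:04d}" for i in range(cfg.n_mrna)]
    hosted = [i for i in range(cfg.n_circ) if classes[i] != "intergenic"]
    n_host = len(hosted)
    need = n_host + n_trip + cfg.n_kd_pos + cfg.n_kd_neg + cfg.n_decoy_pos + cfg.n_decoy_neg
    if need > cfg.n_mrna:
        raise PipelineError(f"infeasible config: need {need} mRNA genes, have {cfg.n_mrna}")
    host_gene_of = {}                      # circ index -> gene index
    for k, ci in enumerate(hosted):
        host_gene_of[ci] = k
    trip_genes = list(range(n_host, n_host + n_trip))
    kd_pos_genes = list(range(n_host + n_trip, n_host + n_trip + cfg.n_kd_pos))
    kd_neg_genes = list(range(n_host + n_trip + cfg.n_kd_pos,
                              n_host + n_trip + cfg.n_kd_pos + cfg.n_kd_neg))
    decoy_start = n_host + n_trip + cfg.n_kd_pos + cfg.n_kd_neg
    decoy_pos_genes = list(range(decoy_start, decoy_start + cfg.n_decoy_pos))
    decoy_neg_genes = list(range(decoy_start + cfg.n_decoy_pos,
                                 decoy_start + cfg.n_decoy_pos + cfg.n_decoy_neg))

    mirnas = _make_mirnas(cfg, rng)
    all_strings = [w for m in mirnas for w in sitemod.site_strings(m).values()]
    trip_mirna_idx = [i % cfg.n_mirna for i in range(n_trip)]

    # ---- gene layout --------------------------------------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cursors = {c: 0 for c in chroms}
    drafts: list[_GeneDraft] = []
    circ_exon_count = {}
    for ci in hosted:
        circ_exon_count[ci] = (1 if classes[ci] == "single_exonic"
                               else int(rng.integers(cfg.circ_exons[0], cfg.circ_exons[1] + 1)))
    for gi, gid in enumerate(mrna_ids):
        chrom = chroms[gi % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        is_host_of = next((ci for ci, k in host_gene_of.items() if k == gi), None)
        if is_host_of is not None:
            n_exons = circ_exon_count[is_host_of] + 2  # one flanking exon each side
        else:
            n_exons = int(rng.integers(2, 4))
        utr_len = int(rng.integers(cfg.utr_len[0], cfg.utr_len[1] + 1))
        lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1)) for _ in range(n_exons)]
        # the transcript-last exon must contain the full 3'UTR
        last_gi = n_exons - 1 if strand == "+" else 0
        lens[last_gi] = utr_len + int(rng.integers(20, 61))
        pos = cursors[chrom] + int(rng.integers(150, 301))
        exons, seqs = [], []
        for ln in lens:
            exons.append((pos, pos + ln))
            seqs.append([_DNA[b] for b in rng.integers(0, 4, size=ln)])
            pos += ln + int(rng.integers(60, 151))
        cursors[chrom] = exons[-1][1]
        drafts.append(_GeneDraft(gid, chrom, strand, exons, seqs, utr_len))

    # ---- junctions ----------------------------------------------------
    junctions: list[BackspliceJunction] = []
    circ_ordinals = {}
    for i, cid in enumerate(circ_ids):
        if classes[i] == "intergenic":
            chrom = chroms[i % cfg.n_chroms]
            start = cursors[chrom] + 500
            length = int(rng.integers(200, 401))
            cursors[chrom] = start + length
            junctions.append(BackspliceJunction(cid, chrom, "+", start, start + length))
            continue
        d = drafts[host_gene_of[i]]
        k = circ_exon_count[i]
        ordinals = list(range(2, 2 + k))       # transcript ordinals: exons 2..k+1, flanked on both sides
        circ_ordinals[cid] = ordinals
        gidx = [d._genomic_index(o) for o in ordinals]
        acc = min(d.exons[g][0] for g in gidx)
        don = max(d.exons[g][1] for g in gidx)
        junctions.append(BackspliceJunction(cid, d.chrom, d.strand, acc, don))

    # ---- site planting ------------------------------------------------
    truth_triplets, planted_corr = [], {}
    for t in range(n_trip):
        ci, gi, m = t, trip_genes[t], mirnas[trip_mirna_idx[t]]
        d = drafts[host_gene_of[ci]]
        mature = d.get_mature(circ_ordinals[circ_ids[ci]])
        junction_site = bool(rng.random() < cfg.p_junction_site)
        _prepare_target(mature, m, 2, all_strings, rng, circular=True,
                        junction_site=junction_site)
        d.set_mature(circ_ordinals[circ_ids[ci]], mature)
        utr = drafts[gi].get_utr()
        _prepare_target(utr, m, 1, all_strings, rng, circular=False, junction_site=False)
        drafts[gi].set_utr(utr)
        truth_triplets.append((circ_ids[ci], m.mirna_id, mrna_ids[gi]))
        planted_corr[(circ_ids[ci], mrna_ids[gi])] = (1, cfg.rho)

    # scrub everything else that the pipeline will scan
    for ci in hosted:
        if ci < n_trip:
            continue
        d = drafts[host_gene_of[ci]]
        mature = d.get_mature(circ_ordinals[circ_ids[ci]])
        _prepare_target(mature, None, 0, all_strings, rng, circular=True, junction_site=False)
        d.set_mature(circ_ordinals[circ_ids[ci]], mature)
    for gi, d in enumerate(drafts):
        if gi in trip_genes:
            continue
        utr = d.get_utr()
        _prepare_target(utr, None, 0, all_strings, rng, circular=False, junction_site=False)
        d.set_utr(utr)

    # ---- correlation structure ----------------------------------------
    kd_circ = circ_ids[0]
    for ci in hosted:
        planted_corr[(circ_ids[ci], mrna_ids[host_gene_of[ci]])] = (1, cfg.host_rho)
    planted_kd_targets = {mrna_ids[trip_genes[0]]: "down"}
    for gi in kd_pos_genes:
        planted_corr[(kd_circ, mrna_ids[gi])] = (1, cfg.rho)
        planted_kd_targets[mrna_ids[gi]] = "down"
    for gi in kd_neg_genes:
        planted_corr[(kd_circ, mrna_ids[gi])] = (-1, cfg.rho)
        planted_kd_targets[mrna_ids[gi]] = "up"

    dec_idx = list(range(n_trip + cfg.n_planted_dec_extra))
    planted_dec = {}
    for k, i in enumerate(dec_idx):
        sign = 1 if (i == 0 or k % 2 == 0) else -1
        planted_dec[circ_ids[i]] = sign * cfg.planted_log2fc
    dec_pool = [c for c in planted_dec if c != kd_circ]
    for gi in decoy_pos_genes:
        c = dec_pool[int(rng.integers(0, len(dec_pool)))]
        planted_corr[(c, mrna_ids[gi])] = (1, cfg.rho)
    for gi in decoy_neg_genes:
        c = dec_pool[int(rng.integers(0, len(dec_pool)))]
        planted_corr[(c, mrna_ids[gi])] = (-1, cfg.rho)

    # ---- counts --------------------------------------------------------
    subjects = [f"P{i + 1:02d}" for i in range(cfg.n_subjects)]
    sample_ids, subj_of, cond_of = [], [], []
    for s in subjects:
        for cond, suffix in (("tumor", "T"), ("normal", "N")):
            sample_ids.append(f"{s}{suffix}")
            subj_of.append(s)
            cond_of.append(cond)
    n_s = len(sample_ids)
    is_tumor = np.array([c == "tumor" for c in cond_of], dtype=float)
    subj_index = np.array([subjects.index(s) for s in subj_of])
    a_subj = rng.normal(size=cfg.n_subjects)
    sf = _loguniform(rng, *cfg.lib_size, size=n_s)
    sf = sf / np.exp(np.mean(np.log(sf)))

    z_circ = rng.normal(size=(cfg.n_circ, n_s))
    u_mrna = rng.normal(size=(cfg.n_mrna, n_s))
    w_mrna = u_mrna.copy()
    circ_pos = {c: k for k, c in enumerate(circ_ids)}
    gene_pos = {g: k for k, g in enumerate(mrna_ids)}
    for (c, g), (sign, rho) in planted_corr.items():
        w_mrna[gene_pos[g]] = (sign * np.sqrt(rho) * z_circ[circ_pos[c]]
                               + np.sqrt(1.0 - rho) * u_mrna[gene_pos[g]])

    base_circ = _loguniform(rng, *cfg.circ_mean, size=cfg.n_circ)
    base_mrna = _loguniform(rng, *cfg.mrna_mean, size=cfg.n_mrna)
    lfc_circ = np.array([planted_dec.get(c, 0.0) for c in circ_ids])

    common = (cfg.subject_sd * a_subj[subj_index] - cfg.subject_sd ** 2 / 2.0
              + np.log(sf))

    def _draw(base, lfc, w, disp):
        log_mu = (np.log(base)[:, None] + _LN2 * np.outer(lfc, is_tumor)
                  + cfg.bio_sd * w - cfg.bio_sd ** 2 / 2.0 + common[None, :])
        mu = np.exp(log_mu)
        if disp > 1e-12:
            lam = rng.gamma(shape=1.0 / disp, scale=disp * mu)
        else:
            lam = mu
        return rng.poisson(lam)

    circ_counts = _draw(base_circ, lfc_circ, z_circ, cfg.nb_dispersion)
    mrna_counts = _draw(base_mrna, np.zeros(cfg.n_mrna), w_mrna, cfg.nb_dispersion)

    meta = pd.DataFrame({"subject_id": subj_of, "condition": cond_of},
                        index=pd.Index(sample_ids, name="sample_id"))
    circ_matrix = ExpressionMatrix(
        pd.DataFrame(circ_counts, index=circ_ids, columns=sample_ids), meta)
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(mrna_counts, index=mrna_ids, columns=sample_ids), meta)

    # ---- assemble annotation + genome ---------------------------------
    ann = GenomeAnnotation()
    for d in drafts:
        span = (d.exons[0][0], d.exons[-1][1])
        ann.genes[d.gene_id] = Gene(d.gene_id, d.chrom, d.strand, *span)
        tid = d.gene_id + ".t1"
        ann.transcripts[tid] = Transcript(tid, d.gene_id, d.chrom, d.strand,
                                          list(d.exons), d.utr3)
    ann.validate()

    chrom_len = {c: cursors[c] + 200 for c in chroms}
    genome_arr = {c: [_DNA[b] for b in rng.integers(0, 4, size=chrom_len[c])]
                  for c in chroms}
    for d in drafts:
        for (s, e), seq in zip(d.exons, d.exon_seqs):
            genome_arr[d.chrom][s:e] = seq
    genome = {c: "".join(arr) for c, arr in genome_arr.items()}

    utr_seqs = {d.gene_id: "".join(d.get_utr()) for d in drafts}
    circ_seqs = {circ_ids[ci]: "".join(drafts[host_gene_of[ci]]
                                       .get_mature(circ_ordinals[circ_ids[ci]]))
                 for ci in hosted}

    truth = SyntheticTruth(
        seed=seed, n_subjects=cfg.n_subjects, nb_dispersion=cfg.nb_dispersion,
        planted_dec=planted_dec, planted_corr=planted_corr,
        planted_triplets=truth_triplets, planted_kd_targets=planted_kd_targets,
        kd_circ=kd_circ, circ_ids=circ_ids, mrna_ids=mrna_ids)
    return Cohort(ann, genome, junctions, circ_matrix, mrna_matrix, mirnas,
                  utr_seqs, circ_seqs, truth)


# ---------------------------------------------------------------------------
# Knockdown experiment
# ---------------------------------------------------------------------------

def simulate_knockdown(truth: SyntheticTruth, config: CohortConfig = CohortConfig(),
                       seed: int = 1, circ_id: str | None = None):
    """Simulate a control-vs-knockdown experiment for one circRNA.

    Planted targets move as their patient co-expression sign dictates:
    positively correlated genes go DOWN on knockdown, negatively correlated
    genes go UP, by the configured |log2fc|. Returns the count matrix and the
    planted direction map.
    """
    cfg = config
    circ_id = circ_id or truth.kd_circ
    if circ_id not in truth.circ_ids:
        raise PipelineError(f"knockdown subject {circ_id!r} not in the simulated truth")
    rng = np.random.default_rng(seed)
    genes = truth.mrna_ids
    directions = dict(truth.planted_kd_targets) if circ_id == truth.kd_circ else {}
    shift = np.zeros(len(genes))
    for k, g in enumerate(genes):
        if g in directions:
            shift[k] = -cfg.kd_log2fc if directions[g] == "down" else cfg.kd_log2fc
    base = _loguniform(rng, *cfg.kd_mean, size=len(genes))
    n_rep = cfg.kd_replicates
    sample_ids = [f"CTRL{i + 1}" for i in range(n_rep)] + [f"KD{i + 1}" for i in range(n_rep)]
    cond = ["control"] * n_rep + ["knockdown"] * n_rep
    is_kd = np.array([c == "knockdown" for c in cond], dtype=float)
    mu = base[:, None] * np.exp(_LN2 * np.outer(shift, is_kd))
    if cfg.kd_dispersion > 1e-12:
        lam = rng.gamma(shape=1.0 / cfg.kd_dispersion, scale=cfg.kd_dispersion * mu)
    else:
        lam = mu
    counts = rng.poisson(lam)
    meta = pd.DataFrame({"subject_id": [f"R{i + 1}" for i in range(2 * n_rep)],
                         "condition": cond},
                        index=pd.Index(sample_ids, name="sample_id"))
    em = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), meta)
    return em, directions


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write the full fixture set (GTF, FASTAs, TSVs, truth JSON) to a directory."""
    out = csio.ensure_dir(out_dir)
    paths = {
        "gtf": out / "annotation.gtf",
        "genome": out / "genome.fa",
        "utr3": out / "utr3.fa",
        "mirna": out / "mirna.fa",
        "junctions": out / "junctions.tsv",
        "mrna_counts": out / "mrna_counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    csio.write_gtf(cohort.annotation, paths["gtf"])
    csio.write_fasta(cohort.genome, paths["genome"])
    csio.write_fasta(cohort.utr_seqs, paths["utr3"])
    csio.write_fasta({m.mirna_id: m.sequence for m in cohort.mirnas}, paths["mirna"])
    csio.write_junctions(cohort.junctions, cohort.circ_matrix.counts, paths["junctions"])
    csio.write_counts(cohort.mrna_matrix, paths["mrna_counts"], paths["samples"])
    paths["truth"].write_text(cohort.truth.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
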