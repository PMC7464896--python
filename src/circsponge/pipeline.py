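"""Config-driven orchestration of the full analysis, plus small closed-form
utilities (xenograft tumor volume, RNA-stability normalization).

Stage order: simulate (or load inputs) -> annotate -> circRNA differential
expression -> seed-site scan -> co-expression -> sponge network ->
[knockdown DE -> target intersection]. Every stage's table is persisted as
TSV/JSON when an output directory is given, and a JSON report collects the
counts at every filter, the seed and a config hash; the same config and seed
produce a byte-identical report.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotate as ann_mod
from . import diffexpr as de_mod
from . import io as csio
from . import network as net_mod
from . import simulate as sim_mod
from . import sites as sites_mod
from .model import PipelineError

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "dec": {"min_fold_change": 2.0, "max_p": 0.05, "max_padj": 0.001},
    "kd": {"min_fold_change": 1.5, "max_p": 0.05},
    "coexpr": {"mode": "p", "alpha": 0.05, "method": "pearson"},
    "triplet": {"min_circ_sites": 2, "min_utr_sites": 1},
}


# ---------------------------------------------------------------------------
# Closed-form utilities
# ---------------------------------------------------------------------------

def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Xenograft tumor volume in mm^3: length x width^2 x 0.52."""
    if length_mm < 0 or width_mm < 0:
        raise PipelineError("tumor_volume: dimensions must be non-negative")
    if width_mm > length_mm:
        log.warning("tumor_volume: width > length; swapping inputs")
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 * 0.52


def stability_normalize(series: dict) -> dict:
    """Normalize an RNA-abundance time course relative to the initial (t=0) point."""
    if 0 not in series:
        raise PipelineError("stability_normalize: series has no t=0 point")
    v0 = series[0]
    if v0 == 0:
        raise PipelineError("stability_normalize: abundance at t=0 is zero")
    return {t: v / v0 for t, v in sorted(series.items())}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(config) -> dict:
    """Accept a YAML path or a dict; merge threshold defaults."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(config)
    thr = {k: dict(v) for k, v in DEFAULT_THRESHOLDS.items()}
    for stage, block in (cfg.get("thresholds") or {}).items():
        if stage not in thr:
            raise PipelineError(f"unknown threshold block {stage!r}")
        thr[stage].update(block)
    cfg["thresholds"] = thr
    cfg.setdefault("seed", 0)
    cfg.setdefault("knockdown", {"enabled": True})
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _cohort_config(cfg: dict) -> sim_mod.CohortConfig:
    block = dict(cfg.get("simulate") or {})
    known = {f.name for f in fields(sim_mod.CohortConfig)}
    unknown = set(block) - known
    if unknown:
        raise PipelineError(f"unknown simulate option(s): {sorted(unknown)}")
    for key in ("exon_len", "circ_exons", "utr_len", "lib_size",
                "circ_mean", "mrna_mean", "kd_mean"):
        if key in block:
            block[key] = tuple(block[key])
    return sim_mod.CohortConfig(**block)


# ---------------------------------------------------------------------------
# Recovery metrics against a known truth
# ---------------------------------------------------------------------------

def recovery_metrics(truth: sim_mod.SyntheticTruth, dec_called: pd.DataFrame,
                     triplets: pd.DataFrame, target_calls: pd.DataFrame | None) -> dict:
    """Precision/recall of planted structure; computable only on synthetic runs."""
    called = set(dec_called.index)
    planted = set(truth.planted_dec)
    out = {
        "dec_recall": len(called & planted) / len(planted) if planted else 1.0,
        "dec_false_discoveries": len(called - planted),
        "dec_fdr": (len(called - planted) / len(called)) if called else 0.0,
    }
    found = set(map(tuple, triplets[["circ_id", "mirna_id", "mrna_id"]].itertuples(index=False))) \
        if len(triplets) else set()
    planted_t = set(truth.planted_triplets)
    out["triplet_recall"] = len(found & planted_t) / len(planted_t) if planted_t else 1.0
    out["triplet_precision"] = len(found & planted_t) / len(found) if found else 1.0
    if target_calls is not None:
        want = {g: ("positively_regulated" if d == "down" else "negatively_regulated")
                for g, d in truth.planted_kd_targets.items()}
        got = dict(zip(target_calls["gene_id"], target_calls["call_class"]))
        n_ok = sum(1 for g, cls in want.items() if got.get(g) == cls)
        cross = sum(1 for g, cls in want.items() if g in got and got[g] != cls)
        out["kd_target_recall"] = n_ok / len(want) if want else 1.0
        out["kd_target_cross_class_errors"] = cross
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config, out_dir=None) -> dict:
    """Run the full analysis from a config (YAML path or dict); return the report.

    With ``simulate`` in the config a synthetic cohort is generated from the
    configured seed; otherwise ``inputs`` must name the junction table, GTF,
    genome/UTR/miRNA FASTAs and the mRNA count + sample tables.
    """
    cfg = load_config(config)
    thr = cfg["thresholds"]
    seed = int(cfg["seed"])
    out = csio.ensure_dir(out_dir) if out_dir is not None else None
    report: dict = {"tool": "circsponge", "version": __version__,
                    "seed": seed, "config_hash": config_hash(cfg)}

    truth = None
    if "simulate" in cfg or "inputs" not in cfg:
        cohort = sim_mod.simulate_cohort(_cohort_config(cfg), seed=seed)
        truth = cohort.truth
        ann = cohort.annotation
        genome = cohort.genome
        junctions = cohort.junctions
        circ_matrix = cohort.circ_matrix
        mrna_matrix = cohort.mrna_matrix
        mirnas = cohort.mirnas
        utr_seqs = cohort.utr_seqs
        if out is not None:
            sim_mod.write_cohort(cohort, out / "data")
    else:
        inp = cfg["inputs"]
        for key in ("junctions", "gtf", "genome", "utr3", "mirna", "mrna_counts", "samples"):
            if key not in inp:
                raise PipelineError(f"stage inputs: missing {key!r}")
        ann = csio.read_gtf(inp["gtf"])
        genome = csio.read_fasta(inp["genome"])
        junctions, circ_matrix = csio.read_junctions(inp["junctions"], inp["samples"])
        mrna_matrix = csio.read_counts(inp["mrna_counts"], inp["samples"])
        mirnas = csio.read_mirnas(inp["mirna"])
        utr_seqs = csio.read_fasta(inp["utr3"])

    # ---- annotate ------------------------------------------------------
    junctions = ann_mod.classify_all(junctions, ann)
    composition = ann_mod.class_composition(junctions)
    chrom_dist = ann_mod.chrom_distribution(junctions)
    report["annotate"] = {"n_junctions": len(junctions),
                          "class_composition": composition,
                          "chrom_distribution": chrom_dist}
    if out is not None:
        csio.write_annotated_junctions(junctions, out / "junctions_annotated.tsv")
        (out / "annotate_summary.json").write_text(
            json.dumps(report["annotate"], indent=2, sort_keys=True) + "\n")

    # ---- circRNA differential expression -------------------------------
    de_circ = de_mod.de_paired(circ_matrix, "tumor", "normal")
    dec = de_mod.call_dec(de_circ, **thr["dec"])
    n_up = int((dec["direction"] == "up").sum())
    n_down = int((dec["direction"] == "down").sum())
    report["diff_expr"] = {"n_tested": int(len(de_circ)), "n_dec": int(len(dec)),
                           "n_up": n_up, "n_down": n_down}
    if out is not None:
        de_circ.to_csv(out / "de_circ.tsv", sep="\t")
        dec.to_csv(out / "dec.tsv", sep="\t")

    # ---- seed-site scan -------------------------------------------------
    dec_ids = list(dec.index)
    targets: dict[str, tuple[str, str]] = {}
    junc_by_id = {j.circ_id: j for j in junctions}
    n_skipped = 0
    for cid in dec_ids:
        j = junc_by_id[cid]
        if j.structural_class == "intergenic" or not j.exon_indices:
            log.warning("DEC %s has no exon model; excluded from site scan", cid)
            n_skipped += 1
            continue
        targets[cid] = ("circ", ann_mod.circ_sequence(j, ann, genome))
    for gid, seq in utr_seqs.items():
        targets[gid] = ("utr3", seq)
    site_table = sites_mod.site_count_table(targets, mirnas)
    report["scan"] = {"n_circ_scanned": len(dec_ids) - n_skipped,
                      "n_circ_skipped": n_skipped,
                      "n_utr_scanned": len(utr_seqs),
                      "n_nonzero_pairs": int(len(site_table))}
    if out is not None:
        site_table.to_csv(out / "site_counts.tsv", sep="\t", index=False)

    # ---- co-expression --------------------------------------------------
    coexpr_cfg = net_mod.CoexprConfig(**thr["coexpr"])
    edges = net_mod.coexpression_map(circ_matrix, mrna_matrix, coexpr_cfg,
                                     circ_features=dec_ids) \
        if len(dec_ids) else pd.DataFrame(columns=net_mod.EDGE_COLUMNS)
    host_corr = net_mod.host_correlation_map(circ_matrix, mrna_matrix, junctions)
    report["coexpression"] = {"n_pairs_tested": int(len(edges)),
                              "n_edges_retained": int(edges["retained"].sum()) if len(edges) else 0,
                              "n_host_pairs": int(len(host_corr))}
    if out is not None:
        edges.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
        host_corr.to_csv(out / "host_correlation.tsv", sep="\t", index=False)

    # ---- sponge network -------------------------------------------------
    triplets = net_mod.build_triplets(edges, site_table, **thr["triplet"]) \
        if len(edges) else pd.DataFrame(columns=net_mod.TRIPLET_COLUMNS)
    report["network"] = net_mod.network_summary(triplets)
    if out is not None:
        net_mod.export_network(triplets, out / "triplets.tsv", "tsv")
        net_mod.export_network(triplets, out / "network.graphml", "graphml")

    # ---- knockdown ------------------------------------------------------
    target_calls = None
    kd_block = cfg.get("knockdown") or {}
    if kd_block.get("enabled", True) and truth is not None:
        kd_matrix, _dirs = sim_mod.simulate_knockdown(
            truth, _cohort_config(cfg), seed=seed + 1)
        de_kd = de_mod.de_unpaired(kd_matrix, "knockdown", "control")
        kd_degs = de_mod.call_kd_degs(de_kd, **thr["kd"])
        kd_circ = kd_block.get("circ_id", truth.kd_circ)
        if len(edges) and kd_circ in set(edges["circ_id"]):
            target_calls = net_mod.call_targets(kd_circ, edges, kd_degs)
        else:
            log.warning("knockdown subject %s absent from the co-expression map; "
                        "no target calls made", kd_circ)
            target_calls = pd.DataFrame(columns=["gene_id", "call_class", "r", "kd_log2fc"])
        n_pos = int((target_calls["call_class"] == "positively_regulated").sum())
        n_neg = int((target_calls["call_class"] == "negatively_regulated").sum())
        report["knockdown"] = {
            "circ_id": kd_circ,
            "n_degs": int(len(kd_degs)),
            "n_degs_up": int((kd_degs["direction"] == "up").sum()),
            "n_degs_down": int((kd_degs["direction"] == "down").sum()),
            "n_targets": int(len(target_calls)),
            "n_targets_positively_regulated": n_pos,
            "n_targets_negatively_regulated": n_neg,
        }
        if out is not None:
            de_kd.to_csv(out / "de_knockdown.tsv", sep="\t")
            kd_degs.to_csv(out / "kd_degs.tsv", sep="\t")
            target_calls.to_csv(out / "target_calls.tsv", sep="\t", index=False)

    if truth is not None:
        report["recovery"] = recovery_metrics(truth, dec, triplets, target_calls)

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
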