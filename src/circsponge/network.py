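"""Co-expression mapping and three-tier ceRNA sponge-network assembly.

Edges are Pearson correlations of log2(CPM + 1) between differentially
expressed circRNAs and mRNAs across shared samples. The default retention
rule keeps pairs with p < 0.05; an alternative mode keeps padj < 0.05 with
r > 0 (BH is computed over all tested pairs either way). A sponge triplet
(circRNA, miRNA, mRNA) requires a retained, positively correlated pair in
which the circRNA carries at least two seed sites for the miRNA and the mRNA
3'UTR at least one. Knockdown target calls intersect the patient
co-expression sign with the knockdown response direction: positively
correlated genes that go down on knockdown, and negatively correlated genes
that go up.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotate import log2_cpm
from .diffexpr import bh_adjust
from .model import ExpressionMatrix, PipelineError

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["circ_id", "mrna_id", "r", "p", "padj", "n", "retained"]
TRIPLET_COLUMNS = ["circ_id", "mirna_id", "mrna_id", "n_sites_circ", "n_sites_utr", "r", "p", "padj"]


@dataclass(frozen=True)
class CoexprConfig:
    mode: str = "p"        # "p": p < alpha; "padj": padj < alpha and r > 0
    alpha: float = 0.05
    method: str = "pearson"  # or "spearman"

    def __post_init__(self):
        if self.mode not in ("p", "padj"):
            raise PipelineError(f"unknown edge-retention mode {self.mode!r}")
        if self.method not in ("pearson", "spearman"):
            raise PipelineError(f"unknown correlation method {self.method!r}")


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise PipelineError("pearson_with_p: length mismatch")
    if n < 3:
        raise PipelineError("pearson_with_p: needs n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0:
        raise PipelineError("pearson_with_p: zero variance, correlation undefined")
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-14:
        return (1.0 if r > 0 else -1.0), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix between two (features x samples) arrays."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((az ** 2).sum(axis=1))
    sb = np.sqrt((bz ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az @ bz.T) / np.outer(sa, sb)
    return np.clip(r, -1.0, 1.0)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0 - 1e-14] = 0.0
    return p


# ---------------------------------------------------------------------------
# Co-expression maps
# ---------------------------------------------------------------------------

def coexpression_map(circ_matrix: ExpressionMatrix, mrna_matrix: ExpressionMatrix,
                     config: CoexprConfig = CoexprConfig(),
                     circ_features=None) -> pd.DataFrame:
    """Test every circRNA x mRNA pair on log2(CPM+1) across shared samples.

    CPM is always computed on the full matrices (library totals must reflect
    the whole junction library, not a filtered subset); ``circ_features``
    then restricts the tested circRNAs, typically to the DEC set. Returns one
    row per tested pair with r, p, BH padj (over all tested pairs) and the
    configured ``retained`` flag. Constant features are excluded with a
    warning.
    """
    if set(circ_matrix.sample_ids) != set(mrna_matrix.sample_ids):
        raise PipelineError("coexpression_map: matrices must share identical sample sets")
    samples = list(circ_matrix.sample_ids)
    lc = log2_cpm(circ_matrix)[samples]
    lm = log2_cpm(mrna_matrix)[samples]
    if circ_features is not None:
        lc = lc.loc[list(circ_features)]
    if config.method == "spearman":
        lc = lc.rank(axis=1)
        lm = lm.rank(axis=1)

    keep_c = lc.std(axis=1) > 0
    keep_m = lm.std(axis=1) > 0
    if (~keep_c).any() or (~keep_m).any():
        log.warning("excluding %d circRNA(s) and %d mRNA(s) with constant expression",
                    int((~keep_c).sum()), int((~keep_m).sum()))
    lc, lm = lc.loc[keep_c], lm.loc[keep_m]
    n = len(samples)
    r = _pairwise_corr(lc.to_numpy(), lm.to_numpy())
    p = _p_from_r(r, n)
    circ_ids = np.repeat(lc.index.to_numpy(), len(lm.index))
    mrna_ids = np.tile(lm.index.to_numpy(), len(lc.index))
    edges = pd.DataFrame({
        "circ_id": circ_ids, "mrna_id": mrna_ids,
        "r": r.ravel(), "p": p.ravel(), "padj": bh_adjust(p.ravel()), "n": n,
    })
    if config.mode == "p":
        edges["retained"] = edges["p"] < config.alpha
    else:
        edges["retained"] = (edges["padj"] < config.alpha) & (edges["r"] > 0)
    return edges


def host_correlation_map(circ_matrix: ExpressionMatrix, mrna_matrix: ExpressionMatrix,
                         junctions) -> pd.DataFrame:
    """Correlate each annotated circRNA with its host (parental) gene."""
    samples = list(circ_matrix.sample_ids)
    if set(samples) != set(mrna_matrix.sample_ids):
        raise PipelineError("host_correlation_map: matrices must share samples")
    lc = log2_cpm(circ_matrix)[samples]
    lm = log2_cpm(mrna_matrix)[samples]
    rows = []
    for j in junctions:
        if j.host_gene is None or j.structural_class == "intergenic":
            log.warning("skipping intergenic junction %s in host correlation", j.circ_id)
            continue
        if j.circ_id not in lc.index:
            continue
        if j.host_gene not in lm.index:
            log.warning("host gene %s of %s absent from mRNA matrix; skipped",
                        j.host_gene, j.circ_id)
            continue
        try:
            r, p = pearson_with_p(lc.loc[j.circ_id], lm.loc[j.host_gene])
        except PipelineError:
            log.warning("constant expression for %s/%s; skipped", j.circ_id, j.host_gene)
            continue
        rows.append({"circ_id": j.circ_id, "host_gene": j.host_gene, "r": r, "p": p})
    return pd.DataFrame(rows, columns=["circ_id", "host_gene", "r", "p"])


# ---------------------------------------------------------------------------
# Triplets and targets
# ---------------------------------------------------------------------------

def build_triplets(edges: pd.DataFrame, site_table: pd.DataFrame,
                   min_circ_sites: int = 2, min_utr_sites: int = 1) -> pd.DataFrame:
    """Assemble circRNA-miRNA-mRNA sponge axes.

    One triplet per retained, positively correlated edge and miRNA with
    >= ``min_circ_sites`` sites in the circRNA and >= ``min_utr_sites`` in
    the mRNA 3'UTR; unique on (circ, miRNA, mRNA).
    """
    if site_table.empty:
        return pd.DataFrame(columns=TRIPLET_COLUMNS)
    circ_sites = site_table[(site_table["target_kind"] == "circ")
                            & (site_table["n_sites"] >= min_circ_sites)]
    utr_sites = site_table[(site_table["target_kind"] == "utr3")
                           & (site_table["n_sites"] >= min_utr_sites)]
    circ_map = {tid: dict(zip(g["mirna_id"], g["n_sites"]))
                for tid, g in circ_sites.groupby("target_id")}
    utr_map = {tid: dict(zip(g["mirna_id"], g["n_sites"]))
               for tid, g in utr_sites.groupby("target_id")}
    rows = []
    kept = edges[edges["retained"] & (edges["r"] > 0)]
    for edge in kept.itertuples(index=False):
        c_sites = circ_map.get(edge.circ_id)
        u_sites = utr_map.get(edge.mrna_id)
        if not c_sites or not u_sites:
            continue
        for mirna_id in sorted(set(c_sites) & set(u_sites)):
            rows.append({
                "circ_id": edge.circ_id, "mirna_id": mirna_id, "mrna_id": edge.mrna_id,
                "n_sites_circ": c_sites[mirna_id], "n_sites_utr": u_sites[mirna_id],
                "r": edge.r, "p": edge.p, "padj": edge.padj,
            })
    out = pd.DataFrame(rows, columns=TRIPLET_COLUMNS)
    return out.drop_duplicates(subset=["circ_id", "mirna_id", "mrna_id"]).reset_index(drop=True)


def network_summary(triplets: pd.DataFrame) -> dict[str, int]:
    return {
        "n_triplets": int(len(triplets)),
        "n_unique_circ": int(triplets["circ_id"].nunique()) if len(triplets) else 0,
        "n_unique_mirna": int(triplets["mirna_id"].nunique()) if len(triplets) else 0,
        "n_unique_mrna": int(triplets["mrna_id"].nunique()) if len(triplets) else 0,
    }


def call_targets(circ_id: str, edges: pd.DataFrame, kd_results: pd.DataFrame) -> pd.DataFrame:
    """Intersect the patient co-expression sign with the knockdown response.

    ``kd_results`` are called knockdown DEGs (feature_id index, log2fc,
    direction). Positively correlated genes (r > 0, retained edge) in the
    down-regulated DEG set are called ``positively_regulated``; negatively
    correlated genes in the up-regulated set ``negatively_regulated``.
    """
    mine = edges[(edges["circ_id"] == circ_id) & edges["retained"]]
    if circ_id not in set(edges["circ_id"]):
        raise PipelineError(f"circRNA {circ_id!r} absent from the co-expression map")
    down = set(kd_results.index[kd_results["direction"] == "down"])
    up = set(kd_results.index[kd_results["direction"] == "up"])
    rows = []
    for edge in mine.itertuples(index=False):
        if edge.r > 0 and edge.mrna_id in down:
            call = "positively_regulated"
        elif edge.r < 0 and edge.mrna_id in up:
            call = "negatively_regulated"
        else:
            continue
        rows.append({"gene_id": edge.mrna_id, "call_class": call, "r": edge.r,
                     "kd_log2fc": float(kd_results.loc[edge.mrna_id, "log2fc"])})
    return pd.DataFrame(rows, columns=["gene_id", "call_class", "r", "kd_log2fc"]) \
        .sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(triplets: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write the three-tier network as a triplet TSV or a bipartite GraphML."""
    if fmt == "tsv":
        triplets.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph()
        for t in triplets.itertuples(index=False):
            g.add_node(t.circ_id, kind="circRNA")
            g.add_node(t.mirna_id, kind="miRNA")
            g.add_node(t.mrna_id, kind="mRNA")
            g.add_edge(t.circ_id, t.mirna_id, role="circRNA-miRNA",
                       n_sites=int(t.n_sites_circ))
            g.add_edge(t.mirna_id, t.mrna_id, role="miRNA-mRNA",
                       n_sites=int(t.n_sites_utr))
        nx.write_graphml(g, path)
    else:
        raise PipelineError(f"unknown export format {fmt!r}")


def read_network_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIPLET_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError(f"{path}: triplet table missing columns {missing}")
    return df
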