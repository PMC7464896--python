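"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: BH by an O(n^2) definition
chase, Pearson by the raw covariance formula and by permutation, circular
seed scanning by checking every rotation character by character.
"""
import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def bh_oracle(pvals):
    """O(n^2) Benjamini-Hochberg: padj_i = min over {j: p_j >= p_i} of p_j*n/rank_j."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    q = p * n / ranks
    ge = p[None, :] >= p[:, None]          # ge[i, j]: p_j >= p_i
    out = np.where(ge, q[None, :], np.inf).min(axis=1)
    return np.minimum(out, 1.0)


def pearson_oracle(x, y):
    """Pearson r straight from the covariance definition (plain Python sums)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def permutation_p(x, y, n_perm, rng):
    """Two-sided permutation p-value for the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = abs(pearson_oracle(x, y))
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    perms = np.stack([rng.permutation(yz) for _ in range(n_perm)])
    r_perm = np.abs(perms @ xz) / len(x)
    return float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1))


def _revcomp(seq):
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def mirna_site_strings_oracle(mirna_seq):
    """Site strings rebuilt independently from the seed definition."""
    seq = mirna_seq.upper().replace("U", "T")
    return {"8mer": _revcomp(seq[1:8]) + "A",
            "7mer-m8": _revcomp(seq[1:8]),
            "7mer-A1": _revcomp(seq[1:7]) + "A"}


def circular_scan_oracle(circ_seq, mirna_seq):
    """All (position, site_type) pairs on a circle, by checking every rotation.

    Precedence applied independently: an 8mer suppresses the 7mer-m8 at the
    same position and the 7mer-A1 one base after it (modulo length).
    """
    seq = circ_seq.upper().replace("U", "T")
    n = len(seq)
    strings = mirna_site_strings_oracle(mirna_seq)
    raw = {}
    for site_type, w in strings.items():
        if len(w) > n:
            continue
        hits = []
        for p in range(n):
            if all(seq[(p + k) % n] == w[k] for k in range(len(w))):
                hits.append(p)
        raw[site_type] = hits
    p8 = set(raw.get("8mer", ()))
    out = [(p, "8mer") for p in p8]
    out += [(p, "7mer-m8") for p in raw.get("7mer-m8", ()) if p not in p8]
    out += [(p, "7mer-A1") for p in raw.get("7mer-A1", ()) if (p - 1) % n not in p8]
    return sorted(out)


def triplet_count_oracle(edges, site_table, min_circ=2, min_utr=1):
    """Brute-force triple loop over (circ, miRNA, mRNA) combinations."""
    circ_ids = sorted({r["target_id"] for r in site_table if r["target_kind"] == "circ"})
    mirna_ids = sorted({r["mirna_id"] for r in site_table})
    count = 0
    sites = {(r["target_id"], r["mirna_id"]): r["n_sites"] for r in site_table}
    kinds = {r["target_id"]: r["target_kind"] for r in site_table}
    retained = {(e["circ_id"], e["mrna_id"]) for e in edges
                if e["retained"] and e["r"] > 0}
    mrna_ids = sorted({e["mrna_id"] for e in edges})
    for c in circ_ids:
        for m in mirna_ids:
            for g in mrna_ids:
                if (c, g) not in retained:
                    continue
                if sites.get((c, m), 0) >= min_circ and kinds.get(c) == "circ" \
                        and sites.get((g, m), 0) >= min_utr and kinds.get(g, "") == "utr3":
                    count += 1
    return count
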