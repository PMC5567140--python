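"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, deliberately sharing no
code with the package: literal per-position running sums, the literal
BH step-up rule, an independently coded moment-matching fit for the
moderated t (brentq root-finding instead of Newton), and plain
group-and-count loops.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats


def brute_force_es(ids, scores, members, p_w):
    """Running sum evaluated literally at every position."""
    members = set(members)
    n = len(ids)
    n_hit = sum(1 for g in ids if g in members)
    n_r = sum(abs(s) ** p_w for g, s in zip(ids, scores) if g in members)
    running = []
    acc_hit = acc_miss = 0.0
    for g, s in zip(ids, scores):
        if g in members:
            acc_hit += (abs(s) ** p_w) / n_r if n_r > 0 else 1.0 / n_hit
        else:
            acc_miss += 1.0 / (n - n_hit)
        running.append(acc_hit - acc_miss)
    es = max(running, key=lambda r: (abs(r), r))
    return es, running


def brute_force_bh(p):
    """Literal BH step-up: padj_(i) = min_{j >= i} m p_(j) / j, capped."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def moderated_t_oracle(x_ctrl, x_trt):
    """Independent moderated-t: brentq trigamma inversion, literal
    posterior-variance and p computation.  Returns dict of arrays."""
    x_ctrl = np.asarray(x_ctrl, float)
    x_trt = np.asarray(x_trt, float)
    n1, n2 = x_ctrl.shape[1], x_trt.shape[1]
    d = n1 + n2 - 2
    lfc = x_trt.mean(1) - x_ctrl.mean(1)
    s2 = (
        ((x_ctrl - x_ctrl.mean(1, keepdims=True)) ** 2).sum(1)
        + ((x_trt - x_trt.mean(1, keepdims=True)) ** 2).sum(1)
    ) / d
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, d / 2)
    if excess > 0:
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - excess, 1e-6, 1e8
        )
        d0 = 2 * half_d0
        s0 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = min(d0 + d, s2.size * d)
    else:
        d0 = np.inf
        s0 = s2.mean()
        s2_post = np.full_like(s2, s0)
        df_total = s2.size * d
    t = lfc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return {"d0": d0, "s0_sq": s0, "t": t, "p": p, "log2fc": lfc}


def brute_force_consensus(rows, threshold):
    """rows: iterable of (mirna, gene, database, validated)."""
    pairs = {}
    for mirna, gene, db, val in rows:
        rec = pairs.setdefault((mirna, gene), {"dbs": set(), "val": False})
        rec["dbs"].add(str(db).lower())
        rec["val"] = rec["val"] or bool(val)
    return {
        pair: {
            "hit_score": len(rec["dbs"]),
            "validated": rec["val"],
            "kept": rec["val"] or len(rec["dbs"]) >= threshold,
        }
        for pair, rec in pairs.items()
    }


def brute_force_de_filter(table, fc_threshold, p_threshold, col):
    out = []
    for _, row in table.iterrows():
        if abs(row["fc_signed"]) >= fc_threshold and row[col] < p_threshold:
            out.append("up" if row["fc_signed"] > 0 else "down")
        else:
            out.append("ns")
    return out


def brute_force_size_filter(sets, universe, min_size, max_size):
    universe = set(universe)
    survivors = []
    for name, members in sets:
        inter = [m for m in members if m in universe]
        if min_size <= len(inter) <= max_size:
            survivors.append(name)
    return survivors
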