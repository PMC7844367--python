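"""Independent brute-force oracles.

Every function here applies the defining rule of an operation directly,
with plain Python loops over genes and samples, independent of the
vectorized/chunked implementation paths it is used to check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def oracle_count_directions(matrix):
    """Per-pair (n_greater, n_less, n_tie, n_unevaluable) by double loop."""
    genes = sorted(matrix.gene_ids)
    rows = {g: [float(v) for v in matrix.data.loc[g]] for g in genes}
    out = {}
    for a, b in combinations(genes, 2):
        g = l = t = u = 0
        for va, vb in zip(rows[a], rows[b]):
            if math.isnan(va) or math.isnan(vb):
                u += 1
            elif va > vb:
                g += 1
            elif va < vb:
                l += 1
            else:
                t += 1
        out[(a, b)] = (g, l, t, u)
    return out


def oracle_stable_pairs(matrix, threshold):
    """{(gene_a, gene_b): (direction, frequency, n_evaluable)} by the
    definition: one direction in >= threshold of greater+less+tie."""
    out = {}
    for key, (g, l, t, u) in oracle_count_directions(matrix).items():
        denom = g + l + t
        if denom == 0:
            continue
        if g / denom >= threshold:
            out[key] = ("greater", g / denom, denom)
        elif l / denom >= threshold:
            out[key] = ("less", l / denom, denom)
    return out


def oracle_reversal(stable_normal: dict, stable_cancer: dict) -> dict:
    """Pairs in both stable sets with opposite directions; cancer direction
    stored."""
    out = {}
    for key, (dir_c, _, _) in stable_cancer.items():
        if key in stable_normal:
            dir_n = stable_normal[key][0]
            if dir_n != dir_c:
                out[key] = dir_c
    return out


def oracle_intersect(signature_dicts: list[dict]) -> dict:
    """Multiway same-direction intersection of {key: direction} dicts."""
    out = {}
    for key, direction in signature_dicts[0].items():
        if all(d.get(key) == direction for d in signature_dicts[1:]):
            out[key] = direction
    return out


def oracle_consistency(candidate: dict, cohorts, threshold) -> dict:
    """Per-pair per-cohort recount of the cancer-direction fraction."""
    out = {}
    for (a, b), direction in candidate.items():
        ok = True
        for cohort in cohorts:
            if a not in cohort.data.index or b not in cohort.data.index:
                ok = False
                break
            g = l = t = 0
            va_row = [float(v) for v in cohort.data.loc[a]]
            vb_row = [float(v) for v in cohort.data.loc[b]]
            for va, vb in zip(va_row, vb_row):
                if math.isnan(va) or math.isnan(vb):
                    continue
                if va > vb:
                    g += 1
                elif va < vb:
                    l += 1
                else:
                    t += 1
            denom = g + l + t
            count = g if direction == "greater" else l
            if denom == 0 or count / denom < threshold:
                ok = False
                break
        if ok:
            out[(a, b)] = direction
    return out


def oracle_score(matrix, sample, signature):
    """(n, m) for one sample by looping signature pairs."""
    n = m = 0
    for pair in signature:
        if pair.gene_a not in matrix.data.index or pair.gene_b not in matrix.data.index:
            continue
        va = matrix.data.at[pair.gene_a, sample]
        vb = matrix.data.at[pair.gene_b, sample]
        if math.isnan(va) or math.isnan(vb) or va == vb:
            continue
        m += 1
        observed = "greater" if va > vb else "less"
        if observed == pair.direction:
            n += 1
    return n, m


def oracle_rank_sum_permutation_p(a, b, n_resamples, seed):
    """Two-sided permutation p-value for the rank-sum statistic."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = a.size
    observed = ranks[:n_a].sum()
    expected = n_a * (pooled.size + 1) / 2.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(ranks)
        if abs(perm[:n_a].sum() - expected) >= abs(observed - expected) - 1e-9:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


def oracle_hypergeom_upper_tail(N, K, n, k):
    """P[X >= k] by exhaustive tail sum over binomial coefficients."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def oracle_benjamini_hochberg(p_values):
    """Step-up formula applied directly: adj_i = min over rank >= rank(i)
    of p_j * m / rank_j, capped at 1."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adjusted[i] = min(running, 1.0)
    return adjusted
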