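"""Group comparison and pathway-enrichment statistics.

Two-group score comparisons use the Wilcoxon rank-sum (Mann-Whitney) test:
exact enumeration when the combined sample size is at most 20 and the data
are tie-free, otherwise the normal approximation with tie and continuity
corrections. Pathway enrichment uses the upper-tail hypergeometric
probability P[X >= k] with Benjamini-Hochberg adjustment across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

_EXACT_MAX_COMBINED_N = 20


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum of group a
    n_a: int
    n_b: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx_tie_corrected"


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    universe_size: int  # N
    pathway_size: int  # K
    query_size: int  # n
    overlap: int  # k
    p_hypergeometric: float
    p_adjusted: float


def wilcoxon_rank_sum(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test on two groups of reals.

    The reported statistic is the rank-sum of group ``a`` in the pooled
    ranking. The exact null distribution is used for small tie-free inputs;
    larger or tied inputs fall back to the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("groups must not contain missing values")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    exact = (a.size + b.size <= _EXACT_MAX_COMBINED_N) and not has_ties
    method = "exact" if exact else "normal_approx_tie_corrected"
    res = sps.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank-sum
    p = float(min(res.pvalue, 1.0))
    return RankSumResult(statistic=w, n_a=int(a.size), n_b=int(b.size),
                         p_two_sided=p, method=method)


def benjamini_hochberg(p_values) -> list[float]:
    """Step-up FDR adjustment; output order matches input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeometric_enrichment(
    query_genes, pathways, universe=None
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of a gene set in pathways.

    Parameters
    ----------
    query_genes
        Genes of interest (e.g. the signature's member genes).
    pathways
        Iterable of (pathway_id, gene set) as read from a GMT file.
    universe
        Background gene universe; defaults to the union of all pathway
        genes. Query genes outside the universe are dropped with a warning,
        pathway sets are intersected with the universe.

    Rows are returned for every pathway, in input order, with
    Benjamini-Hochberg adjusted p-values alongside the raw ones.
    """
    pathways = list(pathways)
    if universe is None:
        universe = set().union(*(set(g) for _, g in pathways)) if pathways else set()
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    query = set(query_genes)
    dropped = query - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    query &= universe
    if not query:
        raise ValidationError("no query gene lies in the universe")
    n_universe = len(universe)
    n_query = len(query)
    raw: list[float] = []
    rows_partial = []
    for pid, genes in pathways:
        in_universe = set(genes) & universe
        k_pathway = len(in_universe)
        overlap = len(query & in_universe)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(overlap - 1, n_universe, k_pathway, n_query))
        p = min(max(p, 0.0), 1.0)
        raw.append(p)
        rows_partial.append((pid, k_pathway, overlap))
    adjusted = benjamini_hochberg(raw)
    return [
        EnrichmentRow(
            pathway_id=pid,
            universe_size=n_universe,
            pathway_size=k_pathway,
            query_size=n_query,
            overlap=overlap,
            p_hypergeometric=p,
            p_adjusted=float(p_adj),
        )
        for (pid, k_pathway, overlap), p, p_adj in zip(rows_partial, raw, adjusted)
    ]
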