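"""Per-sample incidence-risk scores against a reversal signature.

For one sample, with m the signature pairs evaluable there (both genes
measured and not tied) and n the subset whose within-sample ordering
matches the stored cancer direction, the risk score is

    score = n / m,

the fraction of the qualitative signature the sample already exhibits in
its cancer orientation. Scores lie in [0, 1], near 0 for normal tissue and
near 1 for carcinoma, and are invariant to any strictly increasing
transform of a sample's values — hence robust to scaling/normalization
batch effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .matrix import ExpressionMatrix
from .pairs import GREATER, ReversalSignature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskScore:
    sample_id: str
    n: int
    m: int
    score: float
    coverage: float
    low_coverage_flag: bool


@dataclass(frozen=True)
class ScoreSummary:
    count: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


def _signature_value_arrays(matrix: ExpressionMatrix, signature: ReversalSignature):
    genes_a = [p.gene_a for p in signature]
    genes_b = [p.gene_b for p in signature]
    a = matrix.data.reindex(genes_a).to_numpy()
    b = matrix.data.reindex(genes_b).to_numpy()
    cancer_is_greater = np.array([p.direction == GREATER for p in signature])
    return a, b, cancer_is_greater


def _score_columns(matrix: ExpressionMatrix, signature: ReversalSignature):
    """Vectorized (n, m) per sample; missing genes reindex to NaN rows."""
    a, b, up = _signature_value_arrays(matrix, signature)
    valid = ~(np.isnan(a) | np.isnan(b))
    gt = (a > b) & valid
    lt = (a < b) & valid
    m = (gt | lt).sum(axis=0)
    match = np.where(up[:, None], gt, lt)
    n = match.sum(axis=0)
    return n, m


def _make_score(
    sample_id: str, n: int, m: int, sig_size: int, min_coverage: float
) -> RiskScore:
    if m == 0:
        raise ComputationError(
            f"sample {sample_id!r}: no evaluable signature pair (m = 0)"
        )
    coverage = m / sig_size
    return RiskScore(
        sample_id=sample_id,
        n=int(n),
        m=int(m),
        score=n / m,
        coverage=coverage,
        low_coverage_flag=coverage < min_coverage,
    )


def score_sample(
    matrix: ExpressionMatrix,
    sample: str,
    signature: ReversalSignature,
    min_coverage: float = 0.5,
) -> RiskScore:
    """Risk score for one sample.

    Ties and pairs with a missing measurement count in neither n nor m.
    ``low_coverage_flag`` is set when fewer than ``min_coverage`` of the
    signature's pairs were evaluable, so panel-restricted samples are
    visibly flagged rather than silently scored. m = 0 is a hard error.
    """
    if len(signature) == 0:
        raise ValidationError("signature is empty")
    if sample not in matrix.data.columns:
        raise ValidationError(f"unknown sample id: {sample!r}")
    sub = ExpressionMatrix(matrix.data[[sample]], matrix.cohort_label)
    n, m = _score_columns(sub, signature)
    return _make_score(sample, int(n[0]), int(m[0]), len(signature), min_coverage)


def score_cohort(
    matrix: ExpressionMatrix,
    signature: ReversalSignature,
    min_coverage: float = 0.5,
) -> list[RiskScore]:
    """Score every sample; a sample with no evaluable pair is logged and
    skipped rather than aborting the cohort. Sample order is preserved.
    All samples unevaluable is a hard error."""
    if len(signature) == 0:
        raise ValidationError("signature is empty")
    n, m = _score_columns(matrix, signature)
    scores: list[RiskScore] = []
    skipped: list[str] = []
    for j, sample in enumerate(matrix.sample_ids):
        if m[j] == 0:
            skipped.append(sample)
            logger.warning("sample %r has no evaluable signature pair; skipped", sample)
            continue
        scores.append(_make_score(sample, n[j], m[j], len(signature), min_coverage))
    if not scores:
        raise ComputationError("no sample had an evaluable signature pair")
    return scores


def summarize_scores(scores: list[RiskScore]) -> ScoreSummary:
    """Median (midpoint convention for even counts), quartiles and range."""
    if not scores:
        raise ValidationError("no scores to summarize")
    vals = np.array([s.score for s in scores])
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return ScoreSummary(
        count=len(vals),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
    )


def signature_gene_frequencies(signature: ReversalSignature) -> list[tuple[str, int]]:
    """Genes ranked by how many signature pairs contain them (descending,
    ties broken lexicographically). The highest-frequency genes are the
    hubs of the qualitative signature."""
    if len(signature) == 0:
        raise ValidationError("signature is empty")
    counts: dict[str, int] = {}
    for p in signature:
        counts[p.gene_a] = counts.get(p.gene_a, 0) + 1
        counts[p.gene_b] = counts.get(p.gene_b, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def scores_to_frame(scores: list[RiskScore]) -> pd.DataFrame:
    """Score report table: sample_id, n, m, coverage, score, flag."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "n": [s.n for s in scores],
            "m": [s.m for s in scores],
            "coverage": [s.coverage for s in scores],
            "score": [s.score for s in scores],
            "low_coverage_flag": [int(s.low_coverage_flag) for s in scores],
        }
    )
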