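"""Feature-selection cascade for reversal gene-pair signatures.

Within each sample, only the ordering of two genes' values matters:
comparing raw values is equivalent to comparing within-sample ranks because
ranks are a strictly monotone function of values apart from ties. The
cascade is:

1. tally per-pair orderings across a cohort's samples;
2. keep *stable* pairs — one direction in at least a threshold fraction
   (default 90%) of evaluable samples, ties supporting neither direction;
3. keep *reversal* pairs — stable in both the normal and the cancer cohort
   with opposite directions; the cancer-cohort direction is stored;
4. intersect reversal lists across platforms (same direction required);
5. keep pairs whose cancer direction holds in at least the threshold
   fraction of each additional cancer cohort (e.g. RNA-seq cohorts).

Everything is deterministic; the pair-block chunk size only bounds memory
and never affects results.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .matrix import ExpressionMatrix
from .pairs import (
    GREATER,
    LESS,
    DirectedGenePair,
    ReversalSignature,
    StablePairEntry,
    StablePairParams,
    StablePairSet,
    flip,
)

logger = logging.getLogger(__name__)

# target elements (pairs x samples) per chunk when the caller does not fix
# a chunk size; purely a memory bound
_TARGET_CHUNK_ELEMS = 4_000_000


def compare_within_sample(
    matrix: ExpressionMatrix, sample: str, pair: tuple[str, str]
) -> str:
    """Ordering of an unordered gene pair inside one sample.

    Returns ``greater``/``less`` for the canonical pair (gene_a < gene_b
    lexicographically), ``tie`` for equal values, ``unevaluable`` if either
    measurement is missing.
    """
    a, b = sorted(pair)
    if a == b:
        raise ValidationError(f"gene pair with identical genes: {a!r}")
    va = matrix.value(a, sample)
    vb = matrix.value(b, sample)
    if np.isnan(va) or np.isnan(vb):
        return "unevaluable"
    if va > vb:
        return GREATER
    if va < vb:
        return LESS
    return "tie"


def _canonical_gene_order(matrix: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
    genes = sorted(matrix.gene_ids)
    values = matrix.data.loc[genes].to_numpy()
    return genes, values


def _iter_index_pairs(n: int, chunk: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (ia, ib) blocks covering all i < j over range(n), each block of
    at most ``chunk`` pairs."""
    buf_a: list[np.ndarray] = []
    buf_b: list[np.ndarray] = []
    size = 0
    for i in range(n - 1):
        j = np.arange(i + 1, n, dtype=np.intp)
        start = 0
        while start < j.size:
            take = min(j.size - start, chunk - size)
            buf_a.append(np.full(take, i, dtype=np.intp))
            buf_b.append(j[start : start + take])
            size += take
            start += take
            if size >= chunk:
                yield np.concatenate(buf_a), np.concatenate(buf_b)
                buf_a, buf_b, size = [], [], 0
    if size:
        yield np.concatenate(buf_a), np.concatenate(buf_b)


def _chunk_size(n_samples: int, chunk_pairs: int | None) -> int:
    if chunk_pairs is not None:
        if chunk_pairs < 1:
            raise ValidationError("chunk_pairs must be positive")
        return chunk_pairs
    return max(1024, _TARGET_CHUNK_ELEMS // max(1, n_samples))


def _tally_block(values: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    a = values[ia]
    b = values[ib]
    valid = ~(np.isnan(a) | np.isnan(b))
    n_greater = ((a > b) & valid).sum(axis=1).astype(np.int64)
    n_less = ((a < b) & valid).sum(axis=1).astype(np.int64)
    n_unevaluable = (~valid).sum(axis=1).astype(np.int64)
    n_tie = values.shape[1] - n_greater - n_less - n_unevaluable
    return n_greater, n_less, n_tie, n_unevaluable


def _pair_indices(
    genes: list[str], pairs: Iterable[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    pos = {g: i for i, g in enumerate(genes)}
    ia, ib, keys = [], [], []
    for pair in pairs:
        a, b = sorted(pair)
        if a == b:
            raise ValidationError(f"gene pair with identical genes: {a!r}")
        if a in pos and b in pos:
            ia.append(pos[a])
            ib.append(pos[b])
            keys.append((a, b))
    return np.asarray(ia, dtype=np.intp), np.asarray(ib, dtype=np.intp), keys


def count_pair_directions(
    matrix: ExpressionMatrix,
    pairs: Iterable[tuple[str, str]] | None = None,
    chunk_pairs: int | None = None,
) -> pd.DataFrame:
    """Per-pair ordering tallies across all samples.

    Returns a DataFrame with columns gene_a, gene_b (canonical order),
    n_greater, n_less, n_tie, n_unevaluable; the four counts sum to the
    number of samples for every pair. Without a restriction set all
    C(G, 2) unordered pairs are tallied in bounded-memory blocks; beware
    that materializing the full table for very large gene universes is the
    caller's memory responsibility (use :func:`find_stable_pairs`, which
    filters block-by-block, for genome-scale universes).
    """
    if matrix.n_samples == 0:
        raise ValidationError("matrix has no samples")
    genes, values = _canonical_gene_order(matrix)
    frames = []
    if pairs is None:
        if len(genes) < 2:
            raise ValidationError("gene universe must contain at least 2 genes")
        chunk = _chunk_size(matrix.n_samples, chunk_pairs)
        for ia, ib in _iter_index_pairs(len(genes), chunk):
            g, l, t, u = _tally_block(values, ia, ib)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_a": [genes[i] for i in ia],
                        "gene_b": [genes[i] for i in ib],
                        "n_greater": g,
                        "n_less": l,
                        "n_tie": t,
                        "n_unevaluable": u,
                    }
                )
            )
    else:
        ia, ib, keys = _pair_indices(genes, pairs)
        if len(keys) == 0:
            return pd.DataFrame(
                columns=["gene_a", "gene_b", "n_greater", "n_less", "n_tie", "n_unevaluable"]
            )
        g, l, t, u = _tally_block(values, ia, ib)
        frames.append(
            pd.DataFrame(
                {
                    "gene_a": [k[0] for k in keys],
                    "gene_b": [k[1] for k in keys],
                    "n_greater": g,
                    "n_less": l,
                    "n_tie": t,
                    "n_unevaluable": u,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def find_stable_pairs(
    matrix: ExpressionMatrix,
    params: StablePairParams,
    pairs: Iterable[tuple[str, str]] | None = None,
    chunk_pairs: int | None = None,
) -> StablePairSet:
    """Pairs with one ordering in >= threshold of evaluable samples.

    The denominator is n_greater + n_less + n_tie (missing measurements are
    excluded; ties stay in the denominator but support neither direction).
    The boundary is inclusive. Pairs with no evaluable sample are skipped.
    """
    if matrix.n_samples < 2:
        raise ValidationError("stable-pair detection needs at least 2 samples")
    genes, values = _canonical_gene_order(matrix)
    if len(genes) < 2:
        raise ValidationError("gene universe must contain at least 2 genes")
    entries: list[StablePairEntry] = []

    def _consume(ia: np.ndarray, ib: np.ndarray) -> None:
        g, l, t, u = _tally_block(values, ia, ib)
        denom = g + l + t
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_g = np.where(denom > 0, g / np.maximum(denom, 1), 0.0)
            freq_l = np.where(denom > 0, l / np.maximum(denom, 1), 0.0)
        hit_g = (denom > 0) & (freq_g >= params.threshold)
        hit_l = (denom > 0) & (freq_l >= params.threshold) & ~hit_g
        for idx in np.flatnonzero(hit_g):
            entries.append(
                StablePairEntry(
                    DirectedGenePair(genes[ia[idx]], genes[ib[idx]], GREATER),
                    float(freq_g[idx]),
                    int(denom[idx]),
                )
            )
        for idx in np.flatnonzero(hit_l):
            entries.append(
                StablePairEntry(
                    DirectedGenePair(genes[ia[idx]], genes[ib[idx]], LESS),
                    float(freq_l[idx]),
                    int(denom[idx]),
                )
            )

    if pairs is None:
        chunk = _chunk_size(matrix.n_samples, chunk_pairs)
        for ia, ib in _iter_index_pairs(len(genes), chunk):
            _consume(ia, ib)
    else:
        ia, ib, keys = _pair_indices(genes, pairs)
        if len(keys):
            _consume(ia, ib)
    entries.sort(key=lambda e: e.pair.key)
    return StablePairSet(matrix.cohort_label, params, entries)


def find_reversal_pairs(
    stable_normal: StablePairSet, stable_cancer: StablePairSet
) -> ReversalSignature:
    """Pairs stable in both cohorts with opposite directions.

    The stored direction is the cancer-cohort ordering (the signature
    characterizes the cancer class).
    """
    normal_dir = stable_normal.direction_by_key()
    entries = [
        e.pair
        for e in stable_cancer
        if normal_dir.get(e.pair.key) == flip(e.pair.direction)
    ]
    provenance = (
        f"reversal({stable_normal.cohort_label} vs {stable_cancer.cohort_label}, "
        f"threshold={stable_cancer.params.threshold})"
    )
    return ReversalSignature(sorted(entries, key=lambda p: p.key), provenance)


def intersect_signatures(signatures: Sequence[ReversalSignature]) -> ReversalSignature:
    """Pairs present in every signature with the same cancer direction;
    direction conflicts are excluded."""
    if len(signatures) < 2:
        raise ValidationError("intersection needs at least 2 signatures")
    common = signatures[0].direction_by_key()
    for sig in signatures[1:]:
        other = sig.direction_by_key()
        common = {
            k: d for k, d in common.items() if other.get(k) == d
        }
    entries = [DirectedGenePair(a, b, common[(a, b)]) for a, b in sorted(common)]
    provenance = "intersection of: " + "; ".join(s.provenance or "?" for s in signatures)
    return ReversalSignature(entries, provenance)


def filter_by_cohort_consistency(
    candidate: ReversalSignature,
    cohorts: Sequence[ExpressionMatrix],
    params: StablePairParams,
) -> ReversalSignature:
    """Retain pairs whose cancer direction holds in >= threshold of each
    cohort's evaluable samples, each cohort judged separately.

    Cohorts are single-class (cancer) matrices. A pair missing a gene in a
    cohort has no evaluable samples there and is removed. A cohort in which
    no candidate pair has both genes present is a hard error.
    """
    if len(candidate) == 0:
        return ReversalSignature([], candidate.provenance)
    keep = dict(candidate.direction_by_key())
    for cohort in cohorts:
        present = set(cohort.gene_ids)
        evaluable_keys = [k for k in keep if k[0] in present and k[1] in present]
        if not keep:
            break
        if not evaluable_keys and len(keep) > 0:
            raise ComputationError(
                f"cohort {cohort.cohort_label!r} contains no candidate pair"
            )
        tallies = count_pair_directions(cohort, pairs=evaluable_keys)
        ok: set[tuple[str, str]] = set()
        for row in tallies.itertuples(index=False):
            key = (row.gene_a, row.gene_b)
            denom = row.n_greater + row.n_less + row.n_tie
            if denom == 0:
                continue
            count = row.n_greater if keep[key] == GREATER else row.n_less
            if count / denom >= params.threshold:
                ok.add(key)
        keep = {k: d for k, d in keep.items() if k in ok}
    entries = [DirectedGenePair(a, b, keep[(a, b)]) for a, b in sorted(keep)]
    provenance = (
        f"{candidate.provenance}; consistency>= {params.threshold} in "
        + ", ".join(c.cohort_label or "?" for c in cohorts)
    )
    return ReversalSignature(entries, provenance)


def build_signature(
    normal_by_platform: Mapping[str, ExpressionMatrix],
    cancer_by_platform: Mapping[str, ExpressionMatrix],
    consistency_cohorts: Sequence[ExpressionMatrix] = (),
    params: StablePairParams = StablePairParams(),
    chunk_pairs: int | None = None,
) -> ReversalSignature:
    """Full cascade: per-platform stable pairs -> reversal pairs ->
    cross-platform intersection -> cancer-cohort consistency filter.

    Each platform supplies one pooled normal and one pooled cancer matrix;
    within a platform the gene universe is the intersection of the two
    matrices' gene sets (a pair with a gene unmeasured on a platform cannot
    be selected there). An empty final signature is returned with a warning
    rather than raised.
    """
    if not normal_by_platform:
        raise ValidationError("at least one platform group is required")
    if set(normal_by_platform) != set(cancer_by_platform):
        raise ValidationError("normal and cancer platform labels differ")
    per_platform: list[ReversalSignature] = []
    stage_counts: list[str] = []
    for platform in sorted(normal_by_platform):
        normal = normal_by_platform[platform]
        cancer = cancer_by_platform[platform]
        universe = sorted(set(normal.gene_ids) & set(cancer.gene_ids))
        if len(universe) < 2:
            raise ValidationError(
                f"platform {platform!r}: shared gene universe has <2 genes"
            )
        normal_u = normal.subset_genes(universe)
        cancer_u = cancer.subset_genes(universe)
        stable_n = find_stable_pairs(normal_u, params, chunk_pairs=chunk_pairs)
        stable_c = find_stable_pairs(cancer_u, params, chunk_pairs=chunk_pairs)
        reversal = find_reversal_pairs(stable_n, stable_c)
        reversal.provenance = (
            f"platform={platform} threshold={params.threshold} "
            f"stable_normal={len(stable_n)} stable_cancer={len(stable_c)} "
            f"reversal={len(reversal)}"
        )
        logger.info(
            "platform %s: %d stable normal, %d stable cancer, %d reversal pairs",
            platform, len(stable_n), len(stable_c), len(reversal),
        )
        stage_counts.append(reversal.provenance)
        per_platform.append(reversal)
    if len(per_platform) == 1:
        merged = ReversalSignature(list(per_platform[0].entries), per_platform[0].provenance)
    else:
        merged = intersect_signatures(per_platform)
    logger.info("cross-platform intersection: %d pairs", len(merged))
    stage_counts.append(f"intersection={len(merged)}")
    if consistency_cohorts:
        final = filter_by_cohort_consistency(merged, consistency_cohorts, params)
    else:
        final = merged
    logger.info("after cancer-cohort consistency filter: %d pairs", len(final))
    stage_counts.append(f"final={len(final)}")
    final = final.sorted()
    final.provenance = " | ".join(stage_counts)
    if len(final) == 0:
        logger.warning("signature is empty under threshold %s", params.threshold)
    return final
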