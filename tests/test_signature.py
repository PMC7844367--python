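"""Unit and oracle tests for the stable/reversal pair cascade."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reoscore import (
    DirectedGenePair,
    ExpressionMatrix,
    ReversalSignature,
    StablePairParams,
    ValidationError,
    build_signature,
    compare_within_sample,
    count_pair_directions,
    filter_by_cohort_consistency,
    find_reversal_pairs,
    find_stable_pairs,
    generate_two_class_cohorts,
    intersect_signatures,
    SyntheticCohortSpec,
)
import _oracles as oracles
from conftest import make_matrix


def _matrix(rows: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


def _stable_as_dict(stable_set):
    return {
        e.pair.key: (e.pair.direction, e.frequency, e.n_evaluable) for e in stable_set
    }


class TestCompareWithinSample:
    def test_basic_orderings(self):
        m = _matrix({"A": [5.0, 3.0, np.nan], "B": [3.0, 3.0, 1.0]}, ["s1", "s2", "s3"])
        assert compare_within_sample(m, "s1", ("A", "B")) == "greater"
        assert compare_within_sample(m, "s2", ("A", "B")) == "tie"
        assert compare_within_sample(m, "s3", ("A", "B")) == "unevaluable"

    def test_pair_order_is_canonicalized(self):
        m = _matrix({"A": [5.0], "B": [3.0]}, ["s1"])
        # ("B", "A") refers to the same canonical pair (A, B)
        assert compare_within_sample(m, "s1", ("B", "A")) == "greater"

    def test_unknown_ids_are_hard_errors(self):
        m = _matrix({"A": [5.0], "B": [3.0]}, ["s1"])
        with pytest.raises(ValidationError):
            compare_within_sample(m, "s1", ("A", "Z"))
        with pytest.raises(ValidationError):
            compare_within_sample(m, "nope", ("A", "B"))


class TestCountPairDirections:
    def test_constant_ordering(self):
        m = _matrix({"A": [2.0] * 5, "B": [1.0] * 5}, [f"s{i}" for i in range(5)])
        row = count_pair_directions(m).iloc[0]
        assert (row.n_greater, row.n_less, row.n_tie, row.n_unevaluable) == (5, 0, 0, 0)

    def test_counts_sum_to_sample_count(self, rng):
        m = make_matrix(rng, 15, 9, missing_frac=0.2, tie_frac=0.3)
        tallies = count_pair_directions(m)
        total = tallies[["n_greater", "n_less", "n_tie", "n_unevaluable"]].sum(axis=1)
        assert (total == 9).all()

    def test_column_permutation_leaves_tallies_unchanged(self, rng):
        m = make_matrix(rng, 10, 7)
        perm = rng.permutation(m.sample_ids)
        m2 = ExpressionMatrix(m.data[perm])
        t1 = count_pair_directions(m).set_index(["gene_a", "gene_b"])
        t2 = count_pair_directions(m2).set_index(["gene_a", "gene_b"])
        pd.testing.assert_frame_equal(t1, t2)

    def test_matches_double_loop_oracle(self, rng):
        m = make_matrix(rng, 50, 30, missing_frac=0.1, tie_frac=0.2)
        tallies = count_pair_directions(m)
        expected = oracles.oracle_count_directions(m)
        assert len(tallies) == len(expected)
        for row in tallies.itertuples(index=False):
            assert expected[(row.gene_a, row.gene_b)] == (
                row.n_greater, row.n_less, row.n_tie, row.n_unevaluable
            )

    def test_chunk_size_does_not_affect_results(self, rng):
        m = make_matrix(rng, 30, 10)
        full = count_pair_directions(m).set_index(["gene_a", "gene_b"])
        for chunk in (1, 7, 100, 10_000):
            chunked = count_pair_directions(m, chunk_pairs=chunk).set_index(
                ["gene_a", "gene_b"]
            )
            pd.testing.assert_frame_equal(full, chunked.loc[full.index])

    def test_single_gene_universe_rejected(self):
        m = _matrix({"A": [1.0, 2.0]}, ["s1", "s2"])
        with pytest.raises(ValidationError):
            count_pair_directions(m)


class TestFindStablePairs:
    def test_unanimous_pair_has_frequency_one(self):
        m = _matrix(
            {"A": [2.0] * 10, "B": [1.0] * 10}, [f"s{i}" for i in range(10)]
        )
        stable = find_stable_pairs(m, StablePairParams(0.9))
        assert _stable_as_dict(stable) == {("A", "B"): ("greater", 1.0, 10)}

    def test_threshold_boundary_is_inclusive(self):
        vals = [2.0] * 9 + [0.0]  # A > B in exactly 9/10 samples
        m = _matrix({"A": vals, "B": [1.0] * 10}, [f"s{i}" for i in range(10)])
        stable = find_stable_pairs(m, StablePairParams(0.9))
        assert _stable_as_dict(stable)[("A", "B")] == ("greater", 0.9, 10)

    def test_ties_stay_in_denominator_and_support_neither(self):
        # A > B in 9 samples, tie in 1: frequency 0.9 still qualifies;
        # A > B in 8, ties in 2: 0.8 does not
        m9 = _matrix({"A": [2.0] * 9 + [1.0], "B": [1.0] * 10}, [f"s{i}" for i in range(10)])
        assert len(find_stable_pairs(m9, StablePairParams(0.9))) == 1
        m8 = _matrix({"A": [2.0] * 8 + [1.0] * 2, "B": [1.0] * 10}, [f"s{i}" for i in range(10)])
        assert len(find_stable_pairs(m8, StablePairParams(0.9))) == 0

    def test_unevaluable_samples_are_excluded_from_denominator(self):
        m = _matrix(
            {"A": [2.0] * 9 + [np.nan], "B": [1.0] * 10}, [f"s{i}" for i in range(10)]
        )
        stable = find_stable_pairs(m, StablePairParams(0.9))
        assert _stable_as_dict(stable)[("A", "B")] == ("greater", 1.0, 9)

    def test_matches_exhaustive_oracle(self, rng):
        m = make_matrix(rng, 20, 40, missing_frac=0.1, tie_frac=0.2)
        stable = find_stable_pairs(m, StablePairParams(0.8))
        assert _stable_as_dict(stable) == oracles.oracle_stable_pairs(m, 0.8)

    def test_threshold_monotonicity(self, rng):
        m = make_matrix(rng, 15, 20, tie_frac=0.2)
        loose = set(_stable_as_dict(find_stable_pairs(m, StablePairParams(0.7))))
        tight = set(_stable_as_dict(find_stable_pairs(m, StablePairParams(0.9))))
        assert tight <= loose

    def test_threshold_at_or_below_half_rejected(self):
        with pytest.raises(ValidationError):
            StablePairParams(0.5)
        with pytest.raises(ValidationError):
            StablePairParams(0.4)


class TestReversalAndIntersection:
    def test_reversal_stores_cancer_direction(self):
        normal = _matrix({"A": [2.0] * 5, "B": [1.0] * 5}, [f"s{i}" for i in range(5)])
        cancer = _matrix({"A": [1.0] * 5, "B": [2.0] * 5}, [f"t{i}" for i in range(5)])
        sig = find_reversal_pairs(
            find_stable_pairs(normal, StablePairParams(0.9)),
            find_stable_pairs(cancer, StablePairParams(0.9)),
        )
        assert sig.direction_by_key() == {("A", "B"): "less"}

    def test_same_direction_pair_excluded(self):
        normal = _matrix({"A": [2.0] * 5, "B": [1.0] * 5}, [f"s{i}" for i in range(5)])
        cancer = _matrix({"A": [3.0] * 5, "B": [1.0] * 5}, [f"t{i}" for i in range(5)])
        sig = find_reversal_pairs(
            find_stable_pairs(normal, StablePairParams(0.9)),
            find_stable_pairs(cancer, StablePairParams(0.9)),
        )
        assert len(sig) == 0

    def test_reversal_matches_oracle_on_random_cohorts(self, rng):
        normal = make_matrix(rng, 25, 30, tie_frac=0.1)
        cancer = make_matrix(rng, 25, 30, tie_frac=0.1)
        sp_n = find_stable_pairs(normal, StablePairParams(0.7))
        sp_c = find_stable_pairs(cancer, StablePairParams(0.7))
        sig = find_reversal_pairs(sp_n, sp_c)
        expected = oracles.oracle_reversal(
            oracles.oracle_stable_pairs(normal, 0.7),
            oracles.oracle_stable_pairs(cancer, 0.7),
        )
        assert sig.direction_by_key() == expected

    def test_intersection_idempotent_and_conflict_excluding(self):
        a = ReversalSignature([DirectedGenePair("A", "B", "less"),
                               DirectedGenePair("C", "D", "greater")])
        same = intersect_signatures([a, a])
        assert same.direction_by_key() == a.direction_by_key()
        b = ReversalSignature([DirectedGenePair("A", "B", "greater"),
                               DirectedGenePair("C", "D", "greater")])
        mixed = intersect_signatures([a, b])
        assert mixed.direction_by_key() == {("C", "D"): "greater"}

    def test_multiway_intersection_matches_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(20)]
        sigs = []
        for _ in range(3):
            from conftest import make_random_signature
            sigs.append(make_random_signature(rng, genes, 40))
        result = intersect_signatures(sigs)
        expected = oracles.oracle_intersect([s.direction_by_key() for s in sigs])
        assert result.direction_by_key() == expected


class TestCohortConsistencyFilter:
    def test_full_agreement_retained_partial_removed(self):
        sig = ReversalSignature([DirectedGenePair("A", "B", "greater")])
        full = _matrix({"A": [2.0] * 10, "B": [1.0] * 10}, [f"s{i}" for i in range(10)])
        partial = _matrix(
            {"A": [2.0] * 8 + [0.0] * 2, "B": [1.0] * 10}, [f"t{i}" for i in range(10)]
        )
        kept = filter_by_cohort_consistency(sig, [full], StablePairParams(0.9))
        assert len(kept) == 1
        removed = filter_by_cohort_consistency(sig, [full, partial], StablePairParams(0.9))
        assert len(removed) == 0

    def test_matches_recount_oracle(self, rng):
        genes = [f"g{i:03d}" for i in range(20)]
        from conftest import make_random_signature
        sig = make_random_signature(rng, genes, 30)
        cohorts = [make_matrix(rng, 20, 15, tie_frac=0.2) for _ in range(2)]
        kept = filter_by_cohort_consistency(sig, cohorts, StablePairParams(0.6))
        expected = oracles.oracle_consistency(
            sig.direction_by_key(), cohorts, 0.6
        )
        assert kept.direction_by_key() == expected

    def test_cohort_without_any_candidate_pair_is_hard_error(self):
        sig = ReversalSignature([DirectedGenePair("A", "B", "greater")])
        other = _matrix({"X": [1.0, 2.0], "Y": [2.0, 1.0]}, ["s1", "s2"])
        from reoscore import ComputationError
        with pytest.raises(ComputationError):
            filter_by_cohort_consistency(sig, [other], StablePairParams(0.9))


class TestBuildSignature:
    def test_single_platform_self_consistency_is_identity(self):
        spec = SyntheticCohortSpec(
            n_genes=40, n_planted_pairs=5, n_normal=10, n_cancer=10,
            noise_sd=0.0, platform_labels=("p1",), seed=5,
        )
        cohorts, truth = generate_two_class_cohorts(spec)
        normal, cancer = cohorts["p1"]
        direct = find_reversal_pairs(
            find_stable_pairs(normal, StablePairParams(0.9)),
            find_stable_pairs(cancer, StablePairParams(0.9)),
        )
        built = build_signature({"p1": normal}, {"p1": cancer}, [cancer])
        assert built.direction_by_key() == direct.direction_by_key()
        assert built.direction_by_key() == truth.direction_by_key()

    def test_provenance_records_cascade_counts(self):
        spec = SyntheticCohortSpec(
            n_genes=30, n_planted_pairs=3, n_normal=6, n_cancer=6,
            noise_sd=0.0, platform_labels=("p1", "p2"), seed=1,
        )
        cohorts, _ = generate_two_class_cohorts(spec)
        sig = build_signature(
            {p: nm for p, (nm, ca) in cohorts.items()},
            {p: ca for p, (nm, ca) in cohorts.items()},
            [ca for _, ca in cohorts.values()],
        )
        assert "reversal=" in sig.provenance
        assert "intersection=" in sig.provenance
        assert "final=3" in sig.provenance

    def test_mismatched_platform_labels_rejected(self, rng):
        m = make_matrix(rng, 10, 4)
        with pytest.raises(ValidationError):
            build_signature({"a": m}, {"b": m})

    def test_gene_row_permutation_does_not_change_result(self, rng):
        normal = make_matrix(rng, 20, 12)
        cancer = make_matrix(rng, 20, 12)
        sig1 = build_signature({"p": normal}, {"p": cancer})
        perm = rng.permutation(normal.gene_ids)
        sig2 = build_signature(
            {"p": ExpressionMatrix(normal.data.loc[perm])},
            {"p": ExpressionMatrix(cancer.data.loc[perm])},
        )
        assert sig1.direction_by_key() == sig2.direction_by_key()
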