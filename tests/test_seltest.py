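import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bindsel.ancestral import AlignedSiteTriple
from bindsel.seltest import (
    NullModel,
    draw_null_substitutions,
    robustness_partition,
    sample_null_deltas,
    selection_p_value,
    summarize_positive,
)
from bindsel.seltest import test_site as run_site_test
from bindsel.seltest import test_sites as run_sites_test
from bindsel.weights import delta_svm, encode_sequence
from conftest import random_dna

BASES = "ACGT"


class TestSampleNullDeltas:
    def test_zero_substitutions_all_zero(self, k2_table):
        model = NullModel(n_permutations=50, seed=1)
        deltas = sample_null_deltas("ACGTACGTAC", 0, k2_table, model)
        assert np.all(deltas == 0.0)

    def test_deterministic_given_seed(self, k3_table):
        model = NullModel(n_permutations=200, seed=9)
        a = sample_null_deltas("ACGTACGTACGT", 3, k3_table, model)
        b = sample_null_deltas("ACGTACGTACGT", 3, k3_table, model)
        assert np.array_equal(a, b)

    def test_too_many_substitutions_raise(self, k2_table):
        with pytest.raises(ValueError, match="mutable"):
            sample_null_deltas("ACGT", 5, k2_table, NullModel(n_permutations=10))

    def test_single_sub_deltas_lie_in_enumerated_set(self, k3_table):
        """Every sampled delta equals one of the exhaustively enumerated
        single-substitution deltas, and the sample mean matches enumeration."""
        anc = "ACGTTGCAGGTA"
        exact = []
        for p in range(len(anc)):
            for b in BASES:
                if b != anc[p]:
                    foc = anc[:p] + b + anc[p + 1 :]
                    exact.append(delta_svm(anc, foc, k3_table))
        exact = np.array(exact)
        model = NullModel(n_permutations=5000, seed=3)
        deltas = sample_null_deltas(anc, 1, k3_table, model)
        for d in deltas[:500]:
            assert np.min(np.abs(exact - d)) < 1e-9
        se = exact.std() / math.sqrt(len(deltas))
        assert abs(deltas.mean() - exact.mean()) < 4 * se + 1e-12

    def test_two_sub_deltas_match_pairwise_enumeration_mean(self, k3_table):
        anc = "ACGTTGCAGG"
        singles = {}
        for p in range(len(anc)):
            for b in BASES:
                if b != anc[p]:
                    foc = anc[:p] + b + anc[p + 1 :]
                    singles[(p, b)] = foc
        exact = []
        keys = list(singles)
        for i, (p1, b1) in enumerate(keys):
            for p2, b2 in keys:
                if p2 <= p1:
                    continue
                foc = list(anc)
                foc[p1], foc[p2] = b1, b2
                exact.append(delta_svm(anc, "".join(foc), k3_table))
        exact = np.array(exact)
        model = NullModel(n_permutations=8000, seed=13)
        deltas = sample_null_deltas(anc, 2, k3_table, model)
        se = exact.std() / math.sqrt(len(deltas))
        assert abs(deltas.mean() - exact.mean()) < 4 * se + 1e-12

    def test_positions_are_distinct_and_bases_change(self):
        codes = encode_sequence("ACGTACGTACGTACGT")
        mutable = np.flatnonzero(codes < 4)
        model = NullModel(n_permutations=500, seed=2)
        pos, old, new = draw_null_substitutions(
            codes, mutable, 4, 500, model, np.random.default_rng(0)
        )
        assert all(len(set(row)) == 4 for row in pos.tolist())
        assert np.all(old != new)

    def test_tstv_weighted_transition_fraction(self):
        """With a 4:1 transition:transversion weighting, transitions are
        drawn with probability 4/(4+2) = 2/3."""
        codes = encode_sequence(random_dna(np.random.default_rng(1), 200))
        mutable = np.flatnonzero(codes < 4)
        model = NullModel(kind="ts_tv_weighted", ts_tv_ratio=4.0, n_permutations=1, seed=0)
        pos, old, new = draw_null_substitutions(
            codes, mutable, 4, 12_000, model, np.random.default_rng(6)
        )
        is_ts = (new == (old ^ 2))
        frac = is_ts.mean()
        n = is_ts.size
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(frac - 2 / 3) < 3 * se

    def test_n_positions_masked_from_mutation(self, k2_table):
        anc = "ACGTNNACGTAC"
        model = NullModel(n_permutations=100, seed=5)
        deltas = sample_null_deltas(anc, 3, k2_table, model)
        assert np.isfinite(deltas).all()


class TestSelectionPValue:
    def test_observed_above_all_nulls(self):
        null = list(range(9999))
        assert selection_p_value(1e9, null, "higher") == pytest.approx(1 / 10000)

    def test_observed_below_all_nulls_higher_tail(self):
        assert selection_p_value(-1e9, list(range(99)), "higher") == 1.0

    def test_plain_proportion_flag(self):
        null = [0.0, 1.0, 2.0, 3.0]
        assert selection_p_value(2.5, null, "higher", pseudo_count=False) == 0.25

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=200),
        st.floats(-10, 10),
        st.sampled_from(["higher", "lower"]),
    )
    def test_matches_counting_oracle(self, null, observed, tail):
        if tail == "higher":
            count = sum(1 for x in null if x >= observed)
        else:
            count = sum(1 for x in null if x <= observed)
        expected = (1 + count) / (1 + len(null))
        assert selection_p_value(observed, null, tail) == pytest.approx(expected)
        assert 0 < selection_p_value(observed, null, tail) <= 1

    def test_monotone_in_observed_higher_tail(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=500)
        ps = [selection_p_value(o, null, "higher") for o in np.linspace(-3, 3, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_null_raises(self):
        with pytest.raises(ValueError, match="empty"):
            selection_p_value(0.0, [], "higher")


def triple_with_subs(n_subs, length=30, seed=0, category="conserved"):
    rng = np.random.default_rng(seed)
    anc = random_dna(rng, length)
    foc = list(anc)
    for p in rng.choice(length, size=n_subs, replace=False):
        foc[p] = [b for b in BASES if b != foc[p]][int(rng.integers(3))]
    return AlignedSiteTriple(
        site_id=f"s{seed}", focal="".join(foc), sister=anc, outgroup=anc, category=category
    )


class TestTestSite:
    def test_one_substitution_filtered(self, k3_table):
        r = run_site_test(triple_with_subs(1), k3_table, NullModel(n_permutations=50, seed=1))
        assert not r.tested and r.filter_reason == "min_subs" and r.p_value is None

    def test_identical_triple_filtered(self, k3_table):
        r = run_site_test(triple_with_subs(0), k3_table, NullModel(n_permutations=50, seed=1))
        assert not r.tested and r.n_substitutions == 0

    def test_short_site_filtered(self, k3_table):
        t = AlignedSiteTriple(site_id="x", focal="AC", sister="AC", outgroup="AC")
        r = run_site_test(t, k3_table, NullModel(n_permutations=50, seed=1))
        assert not r.tested and r.filter_reason == "short"

    def test_loss_category_uses_lower_tail(self, k3_table):
        r = run_site_test(
            triple_with_subs(3, category="loss"), k3_table, NullModel(n_permutations=100, seed=1)
        )
        assert r.tail == "lower"
        r2 = run_site_test(
            triple_with_subs(3, category="gain"), k3_table, NullModel(n_permutations=100, seed=1)
        )
        assert r2.tail == "higher"

    def test_reproducible_across_processing_order(self, k3_table):
        model = NullModel(n_permutations=300, seed=7)
        triples = [triple_with_subs(3, seed=s) for s in range(5)]
        fwd = run_sites_test(triples, k3_table, model)
        rev = run_sites_test(list(reversed(triples)), k3_table, model)
        by_id = {r.site_id: r.p_value for r in rev}
        assert all(r.p_value == by_id[r.site_id] for r in fwd)


class TestSummaries:
    def _results(self, ps, category="conserved"):
        from bindsel.seltest import SelectionTestResult

        out = []
        for i, p in enumerate(ps):
            out.append(
                SelectionTestResult(
                    site_id=f"s{i}", category=category, tested=p is not None, p_value=p
                )
            )
        return out

    def test_proportion_positive(self):
        ps = [0.001] * 7 + [0.5] * 93
        assert summarize_positive(self._results(ps)) == {"conserved": 0.07}

    def test_threshold_one_counts_everything(self):
        ps = [0.2, 0.9, 0.005]
        assert summarize_positive(self._results(ps), alpha_threshold=1.0) == {"conserved": 1.0}

    def test_untested_excluded_and_empty_groups_absent(self):
        results = self._results([0.001, None, 0.5])
        grouping = {"s0": "a", "s1": "b", "s2": "a"}
        out = summarize_positive(results, grouping=grouping)
        assert out == {"a": 0.5}  # group b had only an untested site

    def test_two_group_hand_computation(self):
        results = self._results([0.001, 0.02, 0.001, 0.9])
        grouping = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
        assert summarize_positive(results, grouping=grouping) == {"x": 0.5, "y": 0.5}

    def test_robustness_partition_strata(self):
        from bindsel.seltest import SelectionTestResult

        results = [
            SelectionTestResult("a", tested=True, p_value=0.001, has_cpg_substitution=True),
            SelectionTestResult("b", tested=True, p_value=0.5),
            SelectionTestResult("c", tested=True, p_value=0.001),
        ]
        out = robustness_partition(results)
        assert out["cpg_or_dinucleotide"] == 1.0
        assert out["clean"] == 0.5

    def test_robustness_partition_empty_stratum_absent(self):
        from bindsel.seltest import SelectionTestResult

        results = [SelectionTestResult("a", tested=True, p_value=0.5)]
        assert "cpg_or_dinucleotide" not in robustness_partition(results)
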