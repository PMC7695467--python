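import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from bindsel.ancestral import GenomicInterval, SubstitutionSet, extract_substitutions
from bindsel.popgen import (
    MkCounts,
    Snp,
    alpha_mk,
    count_div_poly,
    per_group_rate,
    ratio_test,
    substitution_rates,
)

BASES = "ACGT"


def fisher_enumeration(table):
    """Oracle: two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, K + n - N), min(K, n)
    p_obs = hypergeom.pmf(a, N, n, K)
    return sum(
        hypergeom.pmf(x, N, n, K)
        for x in range(lo, hi + 1)
        if hypergeom.pmf(x, N, n, K) <= p_obs * (1 + 1e-9)
    )


class TestAlpha:
    def test_worked_example(self):
        assert alpha_mk(MkCounts(D_p=50, P_p=10, D_np=100, P_np=40)) == 0.5

    def test_equal_ratios_give_zero(self):
        assert alpha_mk(MkCounts(D_p=20, P_p=10, D_np=40, P_np=20)) == pytest.approx(0.0)

    def test_no_pbs_polymorphism_gives_one(self):
        assert alpha_mk(MkCounts(D_p=50, P_p=0, D_np=100, P_np=40)) == 1.0

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50),
           st.integers(1, 5))
    def test_invariant_under_count_scaling(self, dp, pp, dnp, pnp, scale):
        base = alpha_mk(MkCounts(D_p=dp, P_p=pp, D_np=dnp, P_np=pnp))
        scaled = alpha_mk(
            MkCounts(D_p=dp * scale, P_p=pp * scale, D_np=dnp * scale, P_np=pnp * scale)
        )
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_undefined_when_no_pbs_divergence(self):
        with pytest.raises(ValueError, match="undefined"):
            alpha_mk(MkCounts(D_p=0, P_p=1, D_np=1, P_np=1))


class TestRatioTest:
    def test_symmetric_table(self):
        odds, p = ratio_test(MkCounts(D_p=10, P_p=10, D_np=10, P_np=10))
        assert odds == 1.0 and p == pytest.approx(1.0)

    def test_enumeration_oracle_strong_table(self):
        counts = MkCounts(D_p=20, P_p=5, D_np=5, P_np=20)
        odds, p = ratio_test(counts)
        assert odds == 16.0
        assert p == pytest.approx(fisher_enumeration(counts.table()), rel=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            counts = MkCounts(D_p=a, P_p=b, D_np=c, P_np=d)
            odds, p = ratio_test(counts)
            if min(a + b, c + d, a + c, b + d) == 0:
                assert p == 1.0
            else:
                assert p == pytest.approx(fisher_enumeration(counts.table()), rel=1e-9)

    def test_swapping_rows_inverts_odds_ratio(self):
        o1, _ = ratio_test(MkCounts(D_p=20, P_p=5, D_np=5, P_np=20))
        o2, _ = ratio_test(MkCounts(D_p=5, P_p=20, D_np=20, P_np=5))
        assert o1 == pytest.approx(1 / o2)

    def test_zero_margin_flagged(self):
        odds, p = ratio_test(MkCounts(D_p=0, P_p=0, D_np=5, P_np=5))
        assert odds is None and p == 1.0


def site(start, end, name):
    return name, GenomicInterval("chr1", start, end)


class TestCountDivPoly:
    def toy(self):
        # 3 sites: two PBS with 2+1 substitutions, one non-PBS with 3
        intervals = dict([site(0, 100, "a"), site(200, 300, "b"), site(400, 500, "c")])
        subs = {
            "a": extract_substitutions("AAAA", "TTAA", "a"),
            "b": extract_substitutions("AAAA", "ATAA", "b"),
            "c": extract_substitutions("AAAA", "TTTA", "c"),
        }
        labels = {"a": "PBS", "b": "PBS", "c": "non-PBS"}
        snps = [
            Snp("chr1", 10, "A", "T"),   # in a (PBS)
            Snp("chr1", 250, "C", "G"),  # in b (PBS)
            Snp("chr1", 450, "G", "A"),  # in c (non-PBS)
            Snp("chr1", 460, "G", "C"),  # in c
            Snp("chr1", 999, "T", "A"),  # outside all sites
        ]
        return intervals, subs, snps, labels

    def test_hand_tally(self):
        intervals, subs, snps, labels = self.toy()
        counts = count_div_poly(intervals, subs, snps, labels)
        assert (counts.D_p, counts.P_p, counts.D_np, counts.P_np) == (3, 2, 3, 2)
        assert counts.n_snps_outside_sites == 1

    def test_empty_inputs_all_zero(self):
        counts = count_div_poly({}, {}, [], {})
        assert (counts.D_p, counts.P_p, counts.D_np, counts.P_np) == (0, 0, 0, 0)

    def test_disjoint_doubling_doubles_counts(self):
        intervals, subs, snps, labels = self.toy()
        intervals2 = dict(intervals)
        subs2 = dict(subs)
        labels2 = dict(labels)
        snps2 = list(snps)
        for name, iv in intervals.items():
            shifted = GenomicInterval(iv.chrom, iv.start + 10_000, iv.end + 10_000)
            intervals2[name + "_dup"] = shifted
            subs2[name + "_dup"] = subs[name]
            labels2[name + "_dup"] = labels[name]
        snps2 += [Snp(s.chrom, s.pos + 10_000, s.ref, s.alt) for s in snps]
        c1 = count_div_poly(intervals, subs, snps, labels)
        c2 = count_div_poly(intervals2, subs2, snps2, labels2)
        assert (c2.D_p, c2.P_p, c2.D_np, c2.P_np) == (
            2 * c1.D_p, 2 * c1.P_p, 2 * c1.D_np, 2 * c1.P_np,
        )

    def test_snp_counted_once_per_position_under_overlap(self):
        intervals = dict([site(0, 100, "a"), site(50, 150, "b")])
        subs = {n: SubstitutionSet(n) for n in intervals}
        labels = {"a": "PBS", "b": "non-PBS"}
        counts = count_div_poly(intervals, subs, [Snp("chr1", 60, "A", "C")], labels)
        assert counts.P_p + counts.P_np == 1


class TestSubstitutionRates:
    def test_identical_pairs_zero(self):
        mats = substitution_rates([("ACGT", "ACGT")])
        assert np.nansum(mats["all"]) == 0.0

    def test_direct_count(self):
        mats = substitution_rates([("CCCC", "CTCC")])
        assert mats["all"][1, 3] == pytest.approx(0.25)  # C->T = 1 of 4 C

    def test_zero_base_count_is_nan(self):
        mats = substitution_rates([("CCCC", "CTCC")])
        assert np.isnan(mats["all"][0]).all()  # no A in the ancestor

    def test_recovery_under_known_rates(self):
        rng = np.random.default_rng(44)
        n = 100_000
        anc = "".join(rng.choice(list(BASES), size=n))
        r_ts, r_tv = 0.03, 0.0075
        foc = []
        ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for ch in anc:
            u = rng.random()
            if u < r_ts:
                foc.append(ts_partner[ch])
            elif u < r_ts + 2 * r_tv:
                tv = [b for b in BASES if b != ch and b != ts_partner[ch]]
                foc.append(tv[int(rng.integers(2))])
            else:
                foc.append(ch)
        mats = substitution_rates([(anc, "".join(foc))])
        m = mats["all"]
        for i, a in enumerate(BASES):
            n_a = anc.count(a)
            for j, b in enumerate(BASES):
                if i == j:
                    continue
                true = r_ts if ts_partner[a] == b else r_tv
                se = np.sqrt(true * (1 - true) / n_a)
                assert abs(m[i, j] - true) < 3.5 * se

    def test_pure_transition_simulation_has_zero_transversions(self):
        anc = "ACGT" * 500
        foc = "".join({"A": "G", "C": "T", "G": "A", "T": "C"}[c] for c in anc)
        m = substitution_rates([(anc, foc)])["all"]
        assert m[0, 2] == 1.0 and m[1, 3] == 1.0
        assert m[0, 1] == m[0, 3] == m[1, 0] == m[1, 2] == 0.0

    def test_cpg_stratification(self):
        # ancestor CG at 0-1: C->T at 0 is a CpG-context substitution
        mats = substitution_rates([("CGAA", "TGAA")], stratify_cpg=True)
        assert mats["cpg"][1, 3] == pytest.approx(1.0)  # 1 CpG C, 1 C->T
        assert np.nansum(mats["non_cpg"]) == 0.0

    def test_rows_within_unit_interval(self):
        rng = np.random.default_rng(2)
        anc = "".join(rng.choice(list(BASES), size=500))
        foc = "".join(rng.choice(list(BASES), size=500))
        m = substitution_rates([(anc, foc)])["all"]
        assert np.nanmin(m) >= 0.0 and np.nanmax(m) <= 1.0


class TestPerGroupRate:
    def test_hand_tally(self):
        subs = {
            "a": extract_substitutions("AAAA" * 25, "TTAA" + "AAAA" * 24, "a"),
            "b": extract_substitutions("AAAA" * 25, "AAAA" * 25, "b"),
        }
        lengths = {"a": 100, "b": 100}
        rates = per_group_rate(subs, lengths, {"a": "g1", "b": "g1"})
        assert rates == {"g1": 2 / 200}

    def test_zero_substitutions(self):
        subs = {"a": SubstitutionSet("a")}
        assert per_group_rate(subs, {"a": 50}, {"a": "g"}) == {"g": 0.0}
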