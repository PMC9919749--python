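"""Activity ratios, rank statistics, BH control, correlation screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sipscreen.ecology import (
    CorrelationScreen,
    activity_ratio,
    activity_table,
    bh_adjust,
    correlation_screen,
    group_compare,
    spearman,
)
from sipscreen.simulate import simulate_metadata

from _oracles import oracle_bh, oracle_mannwhitney_p, oracle_wilcoxon_p


class TestActivityRatio:
    def test_transcript_vs_gene_quotient(self):
        # 17.5% transcript vs 5.4% gene abundance -> ratio 3.24
        assert activity_ratio(0.175, 0.054) == pytest.approx(3.24, abs=0.005)

    def test_identity(self):
        assert activity_ratio(0.2, 0.2) == 1.0

    def test_zero_denominator_undefined(self):
        assert math.isnan(activity_ratio(0.1, 0.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            activity_ratio(1.2, 0.5)

    def test_table_over_union_of_taxa(self):
        t = activity_table({"a": 0.3}, {"a": 0.1, "b": 0.2})
        assert set(t["taxon"]) == {"a", "b"}
        assert t.set_index("taxon").loc["a", "ratio"] == pytest.approx(3.0)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [math.exp(v) for v in x]
        r, p = spearman(x, y)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_perfect_inverse(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        r, _ = spearman(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        assert spearman(x, x)[0] == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x), y ** 3)
        assert r1 == pytest.approx(r2)

    def test_constant_vector_undefined(self):
        r, p = spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert math.isnan(r) and math.isnan(p)

    def test_small_n_exact_p_extremes(self):
        # n=5 perfect monotone: 2 of 120 permutations reach |r|=1
        _, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert p == pytest.approx(2 / 120)

    def test_requires_n_at_least_4(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestBHAdjust:
    def test_hand_step_up_m4(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_computation_m2(self):
        assert bh_adjust([0.001, 1.0]) == pytest.approx([0.002, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_matches_oracle_and_dominates_raw_p(self, pvals):
        got = bh_adjust(pvals)
        want = oracle_bh(pvals)
        assert got == pytest.approx(want, abs=1e-12)
        assert np.all(got >= np.asarray(pvals) - 1e-12)
        assert np.all((got >= 0) & (got <= 1))

    def test_reordering_consistency(self, rng):
        p = rng.uniform(size=10)
        perm = rng.permutation(10)
        assert bh_adjust(p[perm]) == pytest.approx(bh_adjust(p)[perm])

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.uniform(size=15))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)


class TestGroupCompare:
    def test_identical_paired_vectors_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = group_compare(a, a, paired=True)
        assert p == 1.0

    def test_smallest_attainable_3v3_p(self):
        # complete separation of 3 vs 3: U = 0, exact two-sided p = 0.1
        _, p = group_compare([1, 2, 3], [10, 11, 12], paired=False)
        assert p == pytest.approx(0.1)

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3, 4, 5], [1, 2, 3], paired=True)

    def test_exact_mw_matches_enumeration(self, rng):
        """Exact Mann-Whitney p equals full enumeration for n <= 6."""
        for _ in range(10):
            n1, n2 = rng.integers(3, 7, size=2)
            vals = rng.permutation(1000)[: n1 + n2].astype(float)
            a, b = vals[:n1], vals[n1:]
            _, p = group_compare(a, b, paired=False)
            assert p == pytest.approx(oracle_mannwhitney_p(a, b), abs=1e-12)

    def test_exact_wilcoxon_matches_enumeration(self, rng):
        """Exact signed-rank p equals sign-flip enumeration for n <= 6."""
        done = 0
        while done < 10:
            n = int(rng.integers(5, 7))
            a = rng.normal(size=n) * 10
            b = a + rng.normal(size=n) * 3
            d = a - b
            if (d == 0).any() or len(set(np.abs(d))) < n:
                continue
            _, p = group_compare(a, b, paired=True)
            assert p == pytest.approx(oracle_wilcoxon_p(a, b), abs=1e-12)
            done += 1

    def test_shifted_distributions_detected(self, rng):
        """Power check: a 2-SD location shift at n = 30 is detected."""
        hits = 0
        for _ in range(20):
            a = rng.normal(size=30)
            b = rng.normal(loc=2.0, size=30)
            _, p = group_compare(a, b, paired=False)
            hits += p < 0.05
        assert hits >= 19


class TestCorrelationScreen:
    def test_planted_positive_link_recovered(self):
        ab, md, truth = simulate_metadata(
            200, [("tax_001", "BOD_removal", +1, 0.9)], seed=7
        )
        res = correlation_screen(ab, md)
        row = res.set_index(["taxon", "variable"]).loc[("tax_001", "BOD_removal")]
        assert row["significant"]
        assert row["r_s"] > 0.6
        assert row["n"] == 200

    def test_planted_negative_link_sign(self):
        ab, md, _ = simulate_metadata(
            200, [("tax_002", "conductivity", -1, 0.8)], seed=8, n_variables=8
        )
        res = correlation_screen(ab, md)
        row = res.set_index(["taxon", "variable"]).loc[("tax_002", "conductivity")]
        assert row["r_s"] < 0

    def test_constant_taxon_skipped_and_logged(self):
        ab, md, _ = simulate_metadata(30, [], seed=9, n_taxa=3, n_variables=2)
        ab.loc["tax_001"] = 0.0
        screen = CorrelationScreen().fit(ab, md)
        reasons = {(t, v): r for t, v, r in screen.skipped_}
        assert any(t == "tax_001" for t, _ in reasons)
        assert "tax_001" not in set(screen.results_["taxon"])

    def test_pairwise_complete_n_reported(self):
        ab, md, _ = simulate_metadata(40, [], seed=10, n_taxa=2, n_variables=2)
        md.iloc[:5, 0] = np.nan
        res = correlation_screen(ab, md)
        n_by_var = res.groupby("variable")["n"].first()
        assert n_by_var[md.columns[0]] == 35
        assert n_by_var[md.columns[1]] == 40

    def test_per_variable_family_adjusts_within_variable(self):
        ab, md, _ = simulate_metadata(50, [], seed=11, n_taxa=8, n_variables=3)
        res = correlation_screen(ab, md, family="per_variable")
        # within each variable, BH of that variable's raw p-values
        for var, sub in res.groupby("variable"):
            assert sub["p_adj"].to_numpy() == pytest.approx(
                oracle_bh(sub["p"].tolist()), abs=1e-12
            )

    def test_significance_threshold_is_strict(self):
        ab, md, _ = simulate_metadata(60, [], seed=12, n_taxa=5, n_variables=2)
        res = correlation_screen(ab, md, alpha=0.05)
        assert ((res["p_adj"] < 0.05) == res["significant"]).all()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_no_overlapping_samples_rejected(self):
        ab = pd.DataFrame([[1.0, 2.0]], index=["t"], columns=["s1", "s2"])
        md = pd.DataFrame([[1.0]], index=["other"], columns=["v"])
        with pytest.raises(ValueError):
            CorrelationScreen().fit(ab, md)
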