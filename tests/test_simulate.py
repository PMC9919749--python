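"""Simulator ground truth, determinism, and physical plausibility."""

import numpy as np
import pandas as pd
import pytest

from sipscreen.enrichment import ef_table
from sipscreen.gradient import GradientMeta, HEAVY_WINDOW, LIGHT_WINDOW
from sipscreen.simulate import (
    CommunityTruth,
    SimConfig,
    plant_incorporators,
    simulate_community,
    simulate_experiment,
    simulate_gradient,
    simulate_metadata,
    simulate_sequences,
)


def small_cfg(seed=1, **kw):
    kw.setdefault("n_taxa", 40)
    kw.setdefault("reads_per_fraction", 20000)
    return SimConfig(seed=seed, **kw)


class TestSimConfig:
    def test_defaults_place_modes_inside_windows(self):
        cfg = SimConfig(seed=0)
        assert LIGHT_WINDOW.contains(cfg.mu0)
        assert HEAVY_WINDOW.contains(cfg.mu0 + cfg.atom_pct * cfg.delta_max)

    def test_grid_must_cover_labeled_mode(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, density_hi=1.84)

    def test_thirteen_fraction_grid(self):
        cfg = SimConfig(seed=0)
        assert len(cfg.bin_mids) == 13
        widths = np.diff(cfg.bin_edges)
        assert widths == pytest.approx(np.full(13, widths[0]))


class TestSimulateCommunity:
    def test_same_seed_identical(self):
        cfg = small_cfg()
        t1 = simulate_community(cfg, preys=("E_coli",))
        t2 = simulate_community(cfg, preys=("E_coli",))
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_role_counts_deterministic_rounding(self):
        cfg = small_cfg(n_taxa=50)
        truth = simulate_community(cfg, roles={"predator": 0.1, "inactive": 0.9})
        assert (truth.table["role"] == "predator").sum() == 5
        assert (truth.table["role"] == "inactive").sum() == 45

    def test_amendment_time_spike_share(self):
        # with prey_relab=None the spike draws the amendment-time share
        cfg = small_cfg()
        truth = simulate_community(cfg, preys=("E_coli",), prey_relab=None)
        spike = truth.table[truth.table["role"] == "prey_spike"]
        assert 0.40 <= spike["baseline_relab"].sum() <= 0.50

    def test_baseline_sums_to_one(self):
        truth = simulate_community(small_cfg(), preys=("E_coli", "P_putida"))
        assert truth.table["baseline_relab"].sum() == pytest.approx(1.0)

    def test_inactive_taxa_alpha_zero_enforced(self):
        truth = simulate_community(small_cfg())
        bad = truth.table.copy()
        bad.loc[bad["role"] == "inactive", "alpha"] = 0.5
        with pytest.raises(ValueError):
            CommunityTruth(bad)

    def test_invalid_role_mix_rejected(self):
        with pytest.raises(ValueError):
            simulate_community(small_cfg(), roles={"predator": 0.5, "inactive": 0.3})

    def test_plant_incorporators_fixed_relab(self):
        truth = simulate_community(small_cfg())
        planted, names = plant_incorporators(truth, [0.0, 0.5, 1.0], relab=0.02)
        sub = planted.table.set_index("taxon").loc[names]
        assert list(sub["alpha"]) == [0.0, 0.5, 1.0]
        assert sub["baseline_relab"].to_numpy() == pytest.approx([0.02] * 3)
        assert planted.table["baseline_relab"].sum() == pytest.approx(1.0)


class TestSimulateGradient:
    def grad(self, cfg, truth, treatment="C13", seed=99):
        meta = GradientMeta(f"{treatment}_E_coli_1d", treatment, "E_coli", "1d")
        return simulate_gradient(truth, meta, cfg, np.random.default_rng(seed))

    def test_multinomial_read_conservation(self):
        cfg = small_cfg()
        truth = simulate_community(cfg, preys=("E_coli",))
        for f in self.grad(cfg, truth):
            assert sum(f.counts.values()) == cfg.reads_per_fraction

    def test_identical_seed_identical_counts(self):
        cfg = small_cfg()
        truth = simulate_community(cfg, preys=("E_coli",))
        g1 = self.grad(cfg, truth)
        g2 = self.grad(cfg, truth)
        assert [f.counts for f in g1] == [f.counts for f in g2]
        assert [f.copies for f in g1] == [f.copies for f in g2]

    @staticmethod
    def mass_weighted_mean_density(fracs, taxon=None):
        """Mean density weighted by the taxon's rRNA mass profile: its
        within-fraction read share times the fraction's qPCR copies.
        Sequencing depth is equal per fraction, so the across-gradient
        profile is carried by the copies, not by raw read totals."""
        num = den = 0.0
        for f in fracs:
            tot = sum(f.counts.values())
            share = (f.counts.get(taxon, 0) / tot) if taxon else 1.0
            w = share * f.copies
            num += f.density * w
            den += w
        return num / den

    def test_unlabeled_mass_centers_in_light_window(self):
        """Mass-weighted mean density of an alpha=0 community ~ mu0."""
        cfg = small_cfg(reads_per_fraction=50000)
        truth = simulate_community(cfg, roles={"inactive": 1.0})
        means = []
        for seed in range(20):
            fracs = self.grad(cfg, truth, seed=seed)
            means.append(self.mass_weighted_mean_density(fracs))
        assert np.mean(means) == pytest.approx(cfg.mu0, abs=0.002)

    def test_fully_labeled_mass_shifts_by_atom_pct_delta(self):
        """alpha=1 taxa center near mu0 + 0.97 * 0.045 = 1.8557."""
        cfg = small_cfg(reads_per_fraction=50000)
        table = pd.DataFrame({
            "taxon": ["hot", "cold"],
            "genus": ["g_hot", "g_cold"],
            "baseline_relab": [0.5, 0.5],
            "alpha": [1.0, 0.0],
            "role": ["planted", "inactive"],
            "prey": ["", ""],
        })
        truth = CommunityTruth(table)
        means = []
        for seed in range(20):
            fracs = self.grad(cfg, truth, seed=seed)
            means.append(self.mass_weighted_mean_density(fracs, "hot"))
        assert np.mean(means) == pytest.approx(
            cfg.mu0 + cfg.atom_pct * cfg.delta_max, abs=0.003
        )

    def test_c12_treatment_ignores_alpha(self):
        cfg = small_cfg(reads_per_fraction=50000)
        truth = simulate_community(cfg, preys=("E_coli",))
        fracs = self.grad(cfg, truth, treatment="C12")
        mean = self.mass_weighted_mean_density(fracs, "prey_E_coli")
        assert mean == pytest.approx(cfg.mu0, abs=0.005)

    def test_baseline_recovered_from_pooled_reads(self):
        """Pooling a taxon's reads over all fractions recovers its
        baseline abundance (within sampling noise over seeds)."""
        cfg = small_cfg()
        truth = simulate_community(cfg, roles={"inactive": 1.0})
        taxon = truth.table.nlargest(3, "baseline_relab").iloc[1]
        shares = []
        for seed in range(20):
            fracs = self.grad(cfg, truth, seed=seed)
            tot = sum(sum(f.counts.values()) for f in fracs)
            shares.append(
                sum(f.counts.get(taxon["taxon"], 0) for f in fracs) / tot
            )
        se = np.std(shares, ddof=1) / np.sqrt(len(shares))
        assert abs(np.mean(shares) - taxon["baseline_relab"]) < 3 * se + 1e-3

    def test_copies_track_total_mass_profile(self):
        cfg = small_cfg()
        truth = simulate_community(cfg, roles={"inactive": 1.0})
        fracs = self.grad(cfg, truth)
        by_idx = {f.fraction_index: f.copies for f in fracs}
        # unlabeled community: the light-window fraction carries the most copies
        peak = max(by_idx, key=by_idx.get)
        assert LIGHT_WINDOW.contains(fracs[peak - 1].density)


class TestSimulateExperiment:
    def test_paired_gradients_and_ef_recovery(self):
        cfg = small_cfg(seed=7)
        grads, truth = simulate_experiment(cfg)
        assert {g.meta.treatment for g in grads} == {"C13", "C12"}
        tab = ef_table(grads).set_index("taxon")
        # the planted full incorporator (prey spike, alpha=1) is labeled
        assert bool(tab.loc["prey_E_coli", "labeled"])

    def test_dropped_12c_yields_missing_status(self):
        cfg = small_cfg(seed=7)
        grads, _ = simulate_experiment(cfg, drop=[("C12", "E_coli", "1d")])
        tab = ef_table(grads)
        assert (tab["status"] == "missing_12C").all()

    def test_byte_level_determinism(self):
        cfg = small_cfg(seed=13)
        g1, t1 = simulate_experiment(cfg)
        g2, t2 = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        for a, b in zip(g1, g2):
            assert [f.counts for f in a.fractions] == [f.counts for f in b.fractions]


class TestSimulateSequences:
    def test_zero_rate_identity(self):
        refs, queries, truth = simulate_sequences(2, 2, 150, 0.0, seed=1)
        assert queries[0][1] == refs[0][1]
        assert truth["realized_identity"].tolist() == [100.0, 100.0]

    def test_exact_mutation_count(self):
        _, _, truth = simulate_sequences(1, 3, 2000, 0.055, seed=2, exact=True)
        assert (truth["n_mut"] == 110).all()
        assert truth["realized_identity"].tolist() == [94.5] * 3

    def test_same_seed_identical_output(self):
        out1 = simulate_sequences(3, 5, 200, 0.02, seed=9)
        out2 = simulate_sequences(3, 5, 200, 0.02, seed=9)
        assert out1[0] == out2[0] and out1[1] == out2[1]

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequences(1, 1, 100, 1.5, seed=1)


class TestSimulateMetadata:
    def test_same_seed_identical_tables(self):
        a1, m1, _ = simulate_metadata(50, [("tax_001", "HRT", 1, 0.5)], seed=4, n_variables=8)
        a2, m2, _ = simulate_metadata(50, [("tax_001", "HRT", 1, 0.5)], seed=4, n_variables=8)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_duplicate_planted_pair_rejected(self):
        with pytest.raises(ValueError):
            simulate_metadata(
                20,
                [("tax_001", "HRT", 1, 0.5), ("tax_001", "HRT", -1, 0.5)],
                seed=1,
            )

    def test_planted_strength_calibration(self):
        """A strength-0.9 link yields empirical r_s > 0.6 in >= 95% of
        seeds at n = 200."""
        from sipscreen.ecology import spearman

        hits = 0
        for seed in range(20):
            ab, md, _ = simulate_metadata(
                200, [("tax_001", "HRT", 1, 0.9)], seed=seed, n_variables=8
            )
            r, _ = spearman(ab.loc["tax_001"].to_numpy(), md["HRT"].to_numpy())
            hits += r > 0.6
        assert hits >= 19
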