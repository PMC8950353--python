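import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morelnet import abundance, beta, network, simulate


class TestSimulateCounts:
    def test_column_sums_equal_library(self):
        cfg = simulate.SimulationConfig(n_taxa=15, library_size=10_000, seed=7)
        table, _ = simulate.simulate_counts(cfg)
        assert (table.sum(axis=0) == 10_000).all()
        assert (table.values >= 0).all()

    def test_seed_determinism(self):
        cfg = simulate.SimulationConfig(
            n_taxa=20, correlation_blocks=[({0, 1, 2}, 0.7)],
            differential_taxa=[(4, "A", "B", 1.0)],
            n_samples_per_group={"A": 5, "B": 5}, seed=7,
        )
        t1, tr1 = simulate.simulate_counts(cfg)
        t2, tr2 = simulate.simulate_counts(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert tr1.true_edges == tr2.true_edges
        assert np.array_equal(tr1.latent_correlation, tr2.latent_correlation)

    def test_lognormal_library_varies(self):
        cfg = simulate.SimulationConfig(n_taxa=10, library_size=5000, library_sd=0.4,
                                        n_samples_per_group={"A": 30}, seed=1)
        table, _ = simulate.simulate_counts(cfg)
        sums = table.sum(axis=0)
        assert sums.nunique() > 1
        assert (sums >= 1).all()

    def test_within_block_correlation_exceeds_between(self):
        """Planted block at latent r = 0.9 shows up in sample Spearman rho."""
        within, between = [], []
        for seed in range(20):
            cfg = simulate.SimulationConfig(
                n_taxa=40, n_samples_per_group={"A": 100},
                correlation_blocks=[(set(range(6)), 0.9)], seed=seed,
            )
            table, _ = simulate.simulate_counts(cfg)
            cm = network.spearman_matrix(abundance.tss_normalize(table))
            rho = cm.rho.to_numpy()
            within.extend(rho[i, j] for i, j in itertools.combinations(range(6), 2))
            between.extend(rho[i, j] for i in range(6) for j in range(6, 12))
        assert np.mean(within) > np.mean(between) + 0.5

    def test_null_strong_correlations_rare(self):
        """No planted correlation, n = 200: under 1% of pairs reach |rho| >= 0.6."""
        cfg = simulate.SimulationConfig(n_taxa=40, n_samples_per_group={"A": 200}, seed=3)
        table, _ = simulate.simulate_counts(cfg)
        cm = network.spearman_matrix(abundance.tss_normalize(table))
        iu = np.triu_indices(40, 1)
        frac = np.mean(np.abs(cm.rho.to_numpy()[iu]) >= 0.6)
        assert frac < 0.01

    def test_truth_edges_within_planted_pairs(self):
        cfg = simulate.SimulationConfig(
            n_taxa=20, correlation_blocks=[({0, 1, 2}, 0.8)],
            hub_spec=(5, {6, 7, 8}, 0.7), seed=0,
        )
        _, truth = simulate.simulate_counts(cfg)
        allowed = {frozenset(p) for p in itertools.combinations([0, 1, 2], 2)}
        allowed |= {frozenset((5, s)) for s in (6, 7, 8)}
        assert set(truth.true_edges) == allowed
        assert truth.true_hubs == {5}
        assert not any(len(pair) != 2 for pair in truth.true_edges)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_taxa=0), dict(library_size=0), dict(latent_sd=0),
         dict(correlation_blocks=[({0, 99}, 0.5)], n_taxa=10),
         dict(correlation_blocks=[({0, 1}, 1.5)], n_taxa=10),
         dict(n_samples_per_group={"A": 0})],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate.SimulationConfig(**kwargs)

    def test_overlapping_blocks_repaired_and_reported(self):
        # contradictory overlapping blocks need an eigenvalue repair
        cfg = simulate.SimulationConfig(
            n_taxa=6, correlation_blocks=[({0, 1, 2}, 0.9), ({2, 3}, -0.9), ({1, 3}, 0.9)],
            repair_tolerance=1.0, seed=0,
        )
        corr, perturb = simulate.build_latent_correlation(cfg)
        assert perturb > 0
        assert np.linalg.eigvalsh(corr).min() > 0
        assert np.allclose(np.diag(corr), 1.0)

    def test_unrepairable_blocks_error_names_blocks(self):
        cfg = simulate.SimulationConfig(
            n_taxa=6, correlation_blocks=[({0, 1, 2}, 0.9), ({2, 3}, -0.9), ({1, 3}, 0.9)],
            repair_tolerance=1e-6, seed=0,
        )
        with pytest.raises(ValueError, match=r"\[0, 1, 2\]"):
            simulate.build_latent_correlation(cfg)


class TestStudyDesign:
    def test_defaults_give_92_samples(self):
        table, meta, _ = simulate.emulate_study_design(
            simulate.SimulationConfig(n_taxa=10, seed=0)
        )
        assert table.shape[1] == 92
        assert len(meta) == 92
        assert meta["plot"].nunique() == 23
        assert set(meta["replicate"]) == {1, 2, 3, 4}

    def test_group_membership_counts(self):
        _, meta, _ = simulate.emulate_study_design(simulate.SimulationConfig(n_taxa=5, seed=0))
        ii = meta[meta["analysis_group"] == "II"]
        iii = meta[meta["analysis_group"] == "III"]
        assert ii["plot"].nunique() == 12 and len(ii) == 48
        assert iii["plot"].nunique() == 7 and len(iii) == 28
        assert (ii["yield_class"] == "H").all()
        assert set(iii["yield_class"]) == {"L", "N"}

    def test_custom_small_design(self):
        table, meta, _ = simulate.emulate_study_design(
            simulate.SimulationConfig(n_taxa=8, seed=1), n_plots=2, n_replicates=3
        )
        assert table.shape[1] == 6
        assert meta["plot"].nunique() == 2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate.emulate_study_design(n_replicates=0)

    def test_zero_plot_effect_gives_uniform_permanova_p(self):
        """With plot_sd = 0 the plot factor is pure noise, so PERMANOVA p on
        plot labels should be uniform: checked by KS over repeated simulation."""
        pvals = []
        for seed in range(60):
            cfg = simulate.SimulationConfig(n_taxa=20, library_size=2000, seed=seed)
            table, meta, _ = simulate.emulate_study_design(
                cfg, n_plots=5, n_replicates=4, plot_sd=0.0, seed=seed
            )
            dm = beta.bray_curtis_matrix(abundance.tss_normalize(table))
            pvals.append(
                beta.permanova(dm, meta["plot"], permutations=99, seed=seed).p_value
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
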