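"""Synthetic data generator: baselines, effects, errors, counts, outliers."""

import numpy as np
import pytest
from scipy import stats as sps

from robustdaa import (
    SimConfig,
    build_dataset,
    evaluate_fdr_power,
    inject_outliers,
    metadata_frame,
    subseed,
)
from robustdaa.simulate import (
    SIGNAL_GRID,
    assign_effects,
    sample_baseline,
    sample_design,
    sample_errors,
)


class TestBaseline:
    def test_flat_parameters_give_uniform_composition(self):
        cfg = SimConfig(m=20, n=10, beta_star_sd=0.0, sigma_star_low=0.0,
                        sigma_star_high=0.0, seed=1)
        base = sample_baseline(cfg)
        np.testing.assert_allclose(base.pi_bar, 1 / 20, atol=1e-12)

    def test_mean_proportions_sum_to_one(self):
        base = sample_baseline(SimConfig(m=100, n=30, seed=2))
        assert base.pi_bar.sum() == pytest.approx(1.0, abs=1e-12)

    def test_abundant_taxa_have_larger_share(self):
        base = sample_baseline(SimConfig(m=200, n=50, seed=3))
        rho = sps.spearmanr(base.beta_star, base.pi_bar).statistic
        assert rho > 0.5


class TestAssignEffects:
    def test_abundant_branch_large_n(self):
        _, alpha = assign_effects(np.array([0.01]), mu=2.0, n=200, p_gamma=1.0, seed=0)
        assert alpha[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_abundant_branch_small_n_doubles(self):
        _, alpha = assign_effects(np.array([0.01]), mu=2.0, n=50, p_gamma=1.0, seed=0)
        assert alpha[0] == pytest.approx(np.log(4), abs=1e-12)

    def test_rare_branch_boost(self):
        _, alpha = assign_effects(np.array([5e-4]), mu=2.0, n=200, p_gamma=1.0, seed=0)
        assert alpha[0] == pytest.approx(np.log(2 * 10 ** (1 / 3)), abs=1e-4)

    def test_null_taxa_have_zero_effect(self):
        gamma, alpha = assign_effects(
            np.full(500, 0.01), mu=1.5, n=100, p_gamma=0.3, seed=4
        )
        assert (alpha[gamma == 0] == 0).all() and (alpha[gamma == 1] != 0).all()
        assert abs(gamma.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 500)

    def test_nonpositive_pi_bar_rejected(self):
        with pytest.raises(ValueError):
            assign_effects(np.array([0.0, 0.1]), mu=1.5, n=50, p_gamma=0.1)


class TestDesign:
    def test_unconfounded_balance(self):
        design = sample_design(10_000, confounded=False, seed=5)
        assert design.d == 0
        assert abs(design.u.mean() - 0.5) < 3 * 0.5 / 100  # 3 SE

    def test_confounded_association(self):
        design = sample_design(20_000, confounded=True, seed=6)
        c1 = design.C[:, 0]
        # logistic link: P(u=1|c1=1) > P(u=1|c1=0)
        assert design.u[c1 == 1].mean() > design.u[c1 == 0].mean() + 0.05
        # marginal rates near the logistic predictions at c2 = 0
        assert abs(design.u[c1 == 1].mean() - 0.62) < 0.03

    def test_degenerate_draws_resampled(self):
        design = sample_design(4, confounded=False, seed=0)
        assert np.ptp(design.u) == 1


class TestErrors:
    @pytest.mark.parametrize("family", ["t3", "lognormal", "weibull"])
    def test_heavy_tailed_families_recentered(self, family):
        draws = sample_errors(family, (400, 500), seed=7)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean()) < 4 * se

    def test_normal_uses_taxon_scales(self):
        sigma = np.array([0.5, 3.0])
        draws = sample_errors("normal", (2, 20_000), seed=8, sigma_star=sigma)
        np.testing.assert_allclose(draws.std(axis=1), sigma, rtol=0.05)

    def test_lognormal_centering_constant(self):
        # centering subtracts the theoretical mean exp(0.8^2/2) = 1.3771
        draws = sample_errors("lognormal", (1, 200_000), seed=9)
        raw_mean = (draws + np.exp(0.32)).mean()
        assert raw_mean == pytest.approx(np.exp(0.32), rel=0.02)

    def test_weibull_centering_constant(self):
        # scale * Gamma(1 + 1/shape) = 0.3 * Gamma(3) = 0.6
        draws = sample_errors("weibull", (1, 200_000), seed=10)
        raw_mean = (draws + 0.6).mean()
        assert raw_mean == pytest.approx(0.6, rel=0.05)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            sample_errors("cauchy", (2, 2), seed=0)


class TestBuildDataset:
    def test_counts_respect_multinomial_totals(self):
        ds = build_dataset(SimConfig(m=50, n=20, seed=11))
        np.testing.assert_allclose(ds.proportions.sum(axis=0), 1.0, atol=1e-12)
        sums = ds.counts.counts.sum(axis=0).to_numpy()
        assert (sums == np.round(sums)).all() and (sums > 0).all()

    def test_truth_alignment(self):
        ds = build_dataset(SimConfig(m=50, n=20, p_gamma=0.2, seed=12))
        assert list(ds.truth.index) == ds.counts.taxon_ids
        assert (ds.truth.loc[ds.truth["gamma"] == 0, "alpha"] == 0).all()

    def test_confounded_design_carries_covariates(self):
        ds = build_dataset(SimConfig(m=30, n=40, confounded=True, seed=13))
        meta = metadata_frame(ds)
        assert list(meta.columns) == ["group", "c1", "c2"]
        assert {"beta1", "beta2"} <= set(ds.truth.columns)

    def test_default_scale_smoke(self):
        ds = build_dataset(SimConfig(m=500, n=100, seed=14))
        assert ds.counts.counts.shape == (500, 100)

    def test_multinomial_error_vanishes_with_depth(self):
        """Observed proportions converge to the true composition as reads grow."""
        devs = []
        for log_depth in (3, 6):
            cfg = SimConfig(m=50, n=10, depth_meanlog=np.log(10**log_depth),
                            depth_sdlog=0.0, seed=15)
            ds = build_dataset(cfg)
            obs = ds.counts.counts.to_numpy() / ds.counts.library_sizes.to_numpy()
            devs.append(np.max(np.abs(obs - ds.proportions)))
        assert devs[1] < devs[0] / 5

    def test_null_dataset_exchangeable_between_groups(self):
        """With no signal, per-taxon proportions should look the same in the
        two u groups (two-sample KS at 1% for >= 95% of taxa)."""
        cfg = SimConfig(m=100, n=60, p_gamma=0.0, seed=16)
        ds = build_dataset(cfg)
        props = ds.counts.counts.to_numpy() / ds.counts.library_sizes.to_numpy()
        u = ds.design.u
        rejected = 0
        for i in range(cfg.m):
            p = sps.ks_2samp(props[i, u == 0], props[i, u == 1]).pvalue
            rejected += p < 0.01
        assert rejected / cfg.m <= 0.05


class TestInjectOutliers:
    def test_zero_rho_is_identity(self):
        ds = build_dataset(SimConfig(m=30, n=15, seed=17))
        out, mask = inject_outliers(ds.counts, rho=0.0, seed=1)
        assert not mask.any()
        np.testing.assert_array_equal(out.counts, ds.counts.counts)

    def test_exact_cell_count_at_standard_scale(self):
        ds = build_dataset(SimConfig(m=500, n=100, seed=18))
        _, mask = inject_outliers(ds.counts, rho=0.5, seed=2)
        assert mask.sum() == 250

    def test_masked_cells_scaled_by_fold(self):
        ds = build_dataset(SimConfig(m=40, n=20, seed=19))
        out, mask = inject_outliers(ds.counts, rho=1.0, fold=20.0, seed=3)
        before = ds.counts.counts.to_numpy()
        after = out.counts.to_numpy()
        np.testing.assert_allclose(after[mask], 20.0 * before[mask])
        np.testing.assert_allclose(after[~mask], before[~mask])

    def test_requesting_too_many_cells_raises(self, rng):
        import pandas as pd

        from robustdaa import CountTable

        table = CountTable(pd.DataFrame(np.eye(4)))
        with pytest.raises(ValueError, match="nonzero"):
            inject_outliers(table, rho=10.0, seed=4)


class TestEvaluate:
    def test_no_discoveries_gives_zero_fdr(self):
        fdr, power = evaluate_fdr_power(np.ones(10), [0, 1, 0, 0, 0, 0, 0, 0, 0, 1], 0.05)
        assert fdr == 0.0 and power == 0.0

    def test_perfect_recovery(self):
        padj = np.array([0.01, 0.9, 0.01, 0.9])
        fdr, power = evaluate_fdr_power(padj, [1, 0, 1, 0], 0.05)
        assert fdr == 0.0 and power == 1.0

    def test_mixed_counting(self):
        gamma = np.array([1] * 10 + [0] * 10)
        padj = np.ones(20)
        padj[[0, 1, 2, 10]] = 0.01  # 3 true + 1 false discovery
        fdr, power = evaluate_fdr_power(padj, gamma, 0.05)
        assert fdr == pytest.approx(0.25) and power == pytest.approx(0.3)

    def test_no_signals_reports_nan_power(self):
        fdr, power = evaluate_fdr_power(np.ones(5), np.zeros(5), 0.05)
        assert np.isnan(power)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_fdr_power(np.ones(3), [0, 1], 0.05)


class TestSeeds:
    def test_subseed_deterministic_and_bounded(self):
        a = subseed(1, 2, 3)
        assert a == subseed(1, 2, 3)
        assert a != subseed(1, 2, 4)
        assert 0 <= a < 2**31

    def test_signal_grid(self):
        assert len(SIGNAL_GRID) == 6
        assert SIGNAL_GRID[0] == pytest.approx(1.05)
        assert SIGNAL_GRID[-1] == pytest.approx(2.0)

    def test_build_dataset_reproducible(self):
        a = build_dataset(SimConfig(m=20, n=10, seed=42))
        b = build_dataset(SimConfig(m=20, n=10, seed=42))
        np.testing.assert_array_equal(a.counts.counts, b.counts.counts)


class TestParameterRecovery:
    def test_l2_pipeline_unbiased_on_normal_errors(self):
        """Averaged over replicates at n = 200, the bias-corrected effects
        track the true alpha for abundant signal taxa and stay near zero for
        null taxa."""
        from robustdaa import DAAConfig, LossSpec, run_robust_daa

        reps = 20
        errs_signal, errs_null = [], []
        for rep in range(reps):
            cfg = SimConfig(m=100, n=200, p_gamma=0.05, mu=1.8,
                            seed=subseed(99, rep))
            ds = build_dataset(cfg)
            res = run_robust_daa(
                ds.counts, metadata_frame(ds),
                DAAConfig(variable="group", loss=LossSpec("l2"), min_depth=1),
            )
            truth = ds.truth.loc[res.table["taxon"]]
            pi_bar = ds.baseline.pi_bar[
                [ds.counts.taxon_ids.index(t) for t in res.table["taxon"]]
            ]
            alpha_hat = res.table["alpha_hat"].to_numpy()
            abundant_signal = (truth["gamma"].to_numpy() == 1) & (pi_bar > 5e-3)
            null = truth["gamma"].to_numpy() == 0
            if abundant_signal.any():
                errs_signal.append(
                    np.mean(alpha_hat[abundant_signal] - truth["alpha"].to_numpy()[abundant_signal])
                )
            errs_null.append(np.mean(alpha_hat[null]))
        assert abs(np.mean(errs_signal)) < 0.1
        assert abs(np.mean(errs_null)) < 0.05
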