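"""Univariate statistics and grouped PLSC with independent oracles."""

import numpy as np
import pytest

from capdyn.stats import (
    paired_ttest,
    pearson_corr,
    plsc_analyze,
    plsc_bootstrap,
    plsc_fit,
    plsc_permutation,
)


class TestPairedTTest:
    def test_hand_computation(self):
        t, df, p = paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        # d = [1, 1, 2]: mean 4/3, sd 1/sqrt(3), t = (4/3)/(1/3) = 4
        assert t == pytest.approx(4.0)
        assert df == 2

    def test_zero_variance_differences_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        x = rng.standard_normal(22)
        y = x + rng.standard_normal(22)
        t, df, p = paired_ttest(x, y)
        ref = ttest_rel(y, x)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_calibration(self, rng):
        """Rejection rate at alpha=0.05 under the null, n=22."""
        n_rep = 5000
        d = rng.standard_normal((n_rep, 22))
        rej = 0
        for row in d:
            _, _, p = paired_ttest(np.zeros(22), row)
            rej += p < 0.05
        assert 0.04 <= rej / n_rep <= 0.06


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        r, _ = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        r, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_planted_negative_association_power(self):
        """Score change vs state-duration change: negative r detected reliably."""
        from capdyn.dynamics import longitudinal_delta
        from capdyn.neuro import delta_scores
        from capdyn.synthetic import CohortSpec, generate_cohort

        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            cohort = generate_cohort(
                CohortSpec(n_subjects=22, n_frames=180, n_parcels=30, seed=100 + seed)
            )
            dm = longitudinal_delta(cohort.metrics)
            dd = dm[dm["state"] == cohort.spec.fpn_state].set_index("subject")["occurrence"]
            db = delta_scores(cohort.behavior)["TMTB"]
            common = dd.index.intersection(db.index)
            r, p = pearson_corr(dd.loc[common].to_numpy(), db.loc[common].to_numpy())
            hits += (r < 0) and (p < 0.05)
        assert hits / n_rep >= 0.8


class TestPLSCFit:
    def test_self_covariance_single_group(self, rng):
        x = rng.standard_normal((12, 3))
        fit = plsc_fit(x, x.copy(), ["g"] * 12)
        # identical blocks: latent brain/behavior scores correlate perfectly on LC1
        r = np.corrcoef(fit.latent_brain_scores[:, 0], fit.latent_behavior_scores[:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_no_dominant_axis(self, rng):
        x = rng.standard_normal((200, 4))
        y = rng.standard_normal((200, 4))
        fit = plsc_fit(x, y, ["g"] * 200)
        share = fit.singular_values[0] ** 2 / np.sum(fit.singular_values**2)
        # planted rank-1 structure concentrates nearly all energy on LC1;
        # independent noise spreads it across components
        latent = rng.standard_normal(200)
        xs = np.outer(latent, [1.0, -1.0, 0.5, 0.2]) + 0.2 * rng.standard_normal((200, 4))
        ys = np.outer(latent, [1.0, 0.7, -0.3, 0.1]) + 0.2 * rng.standard_normal((200, 4))
        structured = plsc_fit(xs, ys, ["g"] * 200)
        share_structured = structured.singular_values[0] ** 2 / np.sum(
            structured.singular_values**2
        )
        assert share < 0.75 < 0.95 < share_structured

    def test_matches_direct_svd_oracle(self):
        """Hand-sized single-group example equals SVD of the printed R."""
        rng = np.random.default_rng(42)
        x = rng.standard_normal((6, 2))
        y = rng.standard_normal((6, 2))
        groups = ["g"] * 6
        fit = plsc_fit(x, y, groups)
        xz = (x - x.mean(0)) / x.std(0, ddof=1)
        yz = (y - y.mean(0)) / y.std(0, ddof=1)
        r = yz.T @ xz / 5
        u, s, vt = np.linalg.svd(r, full_matrices=False)
        assert np.allclose(np.sort(fit.singular_values), np.sort(s), atol=1e-10)
        assert np.allclose(fit.cross_correlation, r, atol=1e-12)
        for ell in range(2):
            v_ref = vt[ell]
            v_got = fit.brain_saliences[:, ell]
            assert np.allclose(np.abs(v_ref @ v_got), 1.0, atol=1e-10)

    def test_energy_conservation(self, rng):
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal((20, 3))
        groups = ["a"] * 10 + ["b"] * 10
        fit = plsc_fit(x, y, groups)
        assert np.sum(fit.singular_values**2) == pytest.approx(
            np.linalg.norm(fit.cross_correlation) ** 2, rel=1e-12
        )

    def test_reconstruction_full_rank(self, rng):
        x = rng.standard_normal((15, 3))
        y = rng.standard_normal((15, 3))
        fit = plsc_fit(x, y, ["g"] * 15)
        rec = fit.behavior_saliences @ np.diag(fit.singular_values) @ fit.brain_saliences.T
        assert np.allclose(rec, fit.cross_correlation, atol=1e-10)

    def test_invariant_to_per_group_affine_shift(self, rng):
        x = rng.standard_normal((20, 4))
        y = rng.standard_normal((20, 2))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        fit1 = plsc_fit(x, y, groups)
        x2 = x.copy()
        x2[groups == "a"] += 55.0  # group-level shift is removed by design
        x2[groups == "b"] *= 3.0
        fit2 = plsc_fit(x2, y, groups)
        assert np.allclose(fit1.singular_values, fit2.singular_values, atol=1e-10)
        assert np.allclose(fit1.brain_saliences, fit2.brain_saliences, atol=1e-10)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 3"):
            plsc_fit(rng.standard_normal((5, 2)), rng.standard_normal((5, 2)),
                     ["a", "a", "a", "b", "b"])


class TestPLSCPermutation:
    def test_zero_perms_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            plsc_permutation(rng.standard_normal((9, 2)), rng.standard_normal((9, 2)),
                             ["g"] * 9, n_perm=0)

    def test_planted_axis_detected(self, rng):
        latent = rng.standard_normal(22)
        x = np.outer(latent, [1.0, 0.5, -0.5]) + 0.3 * rng.standard_normal((22, 3))
        y = np.outer(latent, [1.0, -1.0]) + 0.3 * rng.standard_normal((22, 2))
        groups = ["a"] * 11 + ["b"] * 11
        p = plsc_permutation(x, y, groups, n_perm=500, rng_seed=0)
        assert p[0] < 0.05
        assert np.all(p[1:] > 0.05)

    def test_determinism(self, rng):
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((12, 2))
        p1 = plsc_permutation(x, y, ["g"] * 12, n_perm=100, rng_seed=5)
        p2 = plsc_permutation(x, y, ["g"] * 12, n_perm=100, rng_seed=5)
        assert np.array_equal(p1, p2)

    def test_type_one_error_calibrated(self):
        """P(p1 < 0.05) under independent blocks stays near nominal."""
        rng = np.random.default_rng(2024)
        n_rep, hits = 200, 0
        for _ in range(n_rep):
            x = rng.standard_normal((22, 5))
            y = rng.standard_normal((22, 4))
            groups = ["a"] * 11 + ["b"] * 11
            p = plsc_permutation(x, y, groups, n_perm=199,
                                 rng_seed=int(rng.integers(2**31)))
            hits += p[0] < 0.05
        assert 0.02 <= hits / n_rep <= 0.08


class TestPLSCBootstrap:
    def test_noiseless_intervals_collapse(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 1))
        fit = plsc_fit(x, x.copy(), ["g"] * 10)
        boot = plsc_bootstrap(x, x.copy(), ["g"] * 10, n_boot=50, rng_seed=0, fit=fit)
        assert np.allclose(boot["boot_low_brain"], fit.brain_saliences, atol=1e-9)
        assert np.allclose(boot["boot_high_brain"], fit.brain_saliences, atol=1e-9)

    def test_determinism(self, rng):
        x = rng.standard_normal((14, 3))
        y = rng.standard_normal((14, 2))
        a = plsc_bootstrap(x, y, ["g"] * 14, n_boot=60, rng_seed=9)
        b = plsc_bootstrap(x, y, ["g"] * 14, n_boot=60, rng_seed=9)
        for key in a:
            assert np.array_equal(a[key], b[key])

    def test_planted_loadings_flagged_robust(self, rng):
        hits_pos, hits_null = 0, 0
        n_rep = 20
        for i in range(n_rep):
            latent = rng.standard_normal(22)
            x = np.column_stack([
                latent + 0.3 * rng.standard_normal(22),
                0.8 * latent + 0.3 * rng.standard_normal(22),
                rng.standard_normal(22),  # zero-loading brain column
            ])
            y = np.column_stack([latent + 0.3 * rng.standard_normal(22)])
            res = plsc_analyze(x, y, ["g"] * 22, n_perm=50, n_boot=200, rng_seed=i)
            hits_pos += bool(res.robust_brain[0, 0] and res.robust_brain[1, 0])
            hits_null += bool(res.robust_brain[2, 0])
        assert hits_pos / n_rep >= 0.8
        assert hits_null / n_rep <= 0.2
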