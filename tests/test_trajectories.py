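"""Penalized-spline mixed models and thinning profiles."""

import numpy as np
import pandas as pd
import pytest

import vhlifespan as vh
from vhlifespan.trajectories import (CubicRegressionSpline, FitError, GridError,
                                     ThinningProfileSet, _wiggly_transform)


@pytest.fixture(scope="module")
def basis():
    return CubicRegressionSpline(np.array([4.0, 12.0, 25.0, 45.0, 65.0, 90.0]))


class TestSplineBasis:
    def test_partition_of_unity(self, basis):
        x = np.linspace(4.0, 90.0, 60)
        np.testing.assert_allclose(basis.design(x).sum(axis=1), 1.0, atol=1e-12)

    def test_dimension(self, basis):
        assert basis.dim == 8  # k distinct knots -> k + 2 cubic B-splines

    def test_penalty_is_symmetric_psd(self, basis):
        S = basis.penalty
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        vals = np.linalg.eigvalsh(S)
        assert vals.min() > -1e-10

    def test_penalty_null_space_is_linear(self, basis):
        # coefficients reproducing a straight line must have zero penalty
        x = np.linspace(4.0, 90.0, 200)
        Phi = basis.design(x)
        for target in (np.ones_like(x), x):
            c, *_ = np.linalg.lstsq(Phi, target, rcond=None)
            np.testing.assert_allclose(Phi @ c, target, atol=1e-8)
            assert abs(c @ basis.penalty @ c) < 1e-8

    def test_penalty_matches_dense_quadrature(self, basis):
        # compare the 2-point Gauss rule with brute-force trapezoid
        x = np.linspace(4.0, 90.0, 200_001)
        d2 = basis._d2(x)
        dense = np.trapezoid(d2[:, :, None] * d2[:, None, :], x, axis=0)
        np.testing.assert_allclose(basis.penalty, dense, rtol=1e-5, atol=1e-8)

    def test_knot_validation(self):
        with pytest.raises(ValueError):
            CubicRegressionSpline(np.array([1.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            CubicRegressionSpline(np.array([1.0, 2.0]))

    def test_wiggly_transform_whitens_penalty(self, basis):
        W = _wiggly_transform(basis.penalty)
        assert W.shape == (basis.dim, basis.dim - 2)  # null space dim 2
        np.testing.assert_allclose(W.T @ basis.penalty @ W,
                                   np.eye(W.shape[1]), atol=1e-8)


class TestFitRegion:
    def test_fit_converges_and_reports(self, small_fit):
        region, fit = small_fit
        assert fit.converged
        assert fit.n_obs > 0
        assert fit.sigma2 > 0
        assert fit.region == region

    def test_variance_components_recovered(self, small_fit, small_cohort):
        _, fit = small_fit
        _, truth = small_cohort
        # generous brackets: n=150 subjects
        assert 0.5 * truth.spec.noise_sd**2 < fit.sigma2 < 2.0 * truth.spec.noise_sd**2
        ri = fit.random_intercept_var
        assert 0.4 * truth.spec.subject_sd**2 < ri < 2.5 * truth.spec.subject_sd**2

    def test_predict_residuals_are_small(self, small_fit, small_cohort):
        cohort, _ = small_cohort
        region, fit = small_fit
        sub = cohort.data[cohort.data["region"] == region]
        resid = sub["thickness_mm"].to_numpy() - fit.predict(sub)
        assert np.abs(resid).mean() < 3 * np.sqrt(fit.sigma2)

    def test_too_few_observations(self, small_cohort, small_cfg, atlas):
        cohort, _ = small_cohort
        region = atlas.regions[0]
        tiny = vh.LongitudinalCohort(
            cohort.data[cohort.data["region"] == region].head(5))
        with pytest.raises(FitError):
            vh.fit_region(tiny, region, small_cfg)

    def test_fit_is_deterministic(self, small_cohort, small_cfg, atlas):
        cohort, _ = small_cohort
        region = atlas.regions[1]
        a = vh.fit_region(cohort, region, small_cfg)
        b = vh.fit_region(cohort, region, small_cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.u_wiggly, b.u_wiggly)


class TestOutlierPass:
    def test_clean_data_has_no_exclusions(self, small_cohort, small_cfg, atlas):
        cohort, _ = small_cohort
        region = atlas.regions[2]
        fit = vh.fit_region(cohort, region, small_cfg)
        _, excluded = vh.remove_outliers_refit(cohort, region, fit, small_cfg)
        assert len(excluded) == 0

    def test_gross_outlier_is_excluded(self, small_cohort, small_cfg, atlas):
        cohort, _ = small_cohort
        region = atlas.regions[2]
        df = cohort.data.copy()
        sub = df[df["region"] == region]
        # spike a subject with several visits, so the subject random
        # intercept cannot absorb the aberrant scan
        counts = sub.groupby("subject_id").size()
        sid = counts.idxmax()
        idx = sub.index[sub["subject_id"] == sid][0]
        df.loc[idx, "thickness_mm"] = 5.9  # within bounds, far off the curve
        spiked = vh.LongitudinalCohort(df)
        fit = vh.fit_region(spiked, region, small_cfg)
        refit, excluded = vh.remove_outliers_refit(spiked, region, fit, small_cfg)
        assert idx in excluded
        assert refit.n_obs == fit.n_obs - len(excluded)


@pytest.fixture(scope="module")
def profiles(small_cohort, small_cfg, atlas):
    cohort, _ = small_cohort
    regions = list(atlas.regions[:3])
    fits, excluded = vh.fit_all_regions(cohort, small_cfg, regions=regions)
    return vh.thinning_profiles(fits, small_cfg, excluded)


class TestThinningProfiles:
    def test_shape_and_finiteness(self, profiles, small_cfg):
        assert profiles.derivative.shape == (len(small_cfg.age_grid), 3)
        assert np.isfinite(profiles.derivative.to_numpy()).all()
        assert (profiles.ci_halfwidth.to_numpy() >= 0).all()

    def test_derivative_is_negative_through_midlife(self, profiles):
        # the generated world thins everywhere before the late-life terms
        mid = profiles.derivative.loc[20.0:60.0]
        assert (mid.to_numpy() < 0).all()

    def test_tsv_roundtrip(self, profiles, tmp_path):
        p = tmp_path / "prof.tsv"
        profiles.to_tsv(p)
        back = ThinningProfileSet.from_tsv(p)
        np.testing.assert_allclose(back.derivative.to_numpy(),
                                   profiles.derivative.to_numpy(), atol=1e-9)
        assert back.regions == profiles.regions

    def test_grid_outside_support_raises(self, small_cohort, small_cfg, atlas):
        cohort, _ = small_cohort
        region = atlas.regions[0]
        fit = vh.fit_region(cohort, region, small_cfg)
        wide = vh.VHConfig(rng_seed=5, age_max=120.0)
        with pytest.raises(GridError):
            vh.thinning_profiles({region: fit}, wide)

    def test_nonfinite_derivative_rejected(self, small_cfg):
        ages = small_cfg.age_grid
        bad = pd.DataFrame(np.nan, index=ages, columns=["lh.x"])
        with pytest.raises(ValueError):
            ThinningProfileSet(ages=ages, regions=("lh.x",), derivative=bad,
                               ci_halfwidth=bad, excluded_count={"lh.x": 0})


class TestNoisyRecovery:
    def test_interior_recovery_at_moderate_n(self, atlas, expr_world,
                                             coupled_panel, small_cfg):
        """At n=800 with observation noise, the fitted derivative tracks the
        truth closely in the grid interior; the first grid age sits at the
        edge of the age support where penalized splines carry extra
        smoothing bias, so it gets a wider (characterized) bound."""
        spec = vh.GeneratorSpec(rng_seed=3, n_subjects=800)
        cohort, truth = vh.generate_cohort(spec, atlas, expr_world["pool"].median,
                                           coupled_panel.genes, rng_seed=7)
        region = atlas.regions[0]
        fit = vh.fit_region(cohort, region, small_cfg)
        prof = vh.thinning_profiles({region: fit}, small_cfg)
        est = prof.derivative[region].to_numpy()
        tru = truth.true_derivative(small_cfg.age_grid)[region].to_numpy()
        err = np.abs(est - tru)
        assert err[0] < 0.02          # boundary age
        assert err[1:].max() < 0.01   # interior of the grid
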