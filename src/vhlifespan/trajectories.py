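"""Lifespan thickness trajectories: penalized-spline mixed models per region.

Each region's thickness is modelled as

    thickness ~ s(age) + sex + scanner + (1 | subject)

where ``s`` is a penalized cubic regression spline (B-spline form, ``knots_k``
knots placed at empirical age quantiles — quintiles for the default k = 6 —
boundary knots at the observed age min/max) with an exact curvature
penalty, estimated jointly with the subject random intercept by restricted
maximum likelihood. The spline is handled through its mixed-model
representation: the penalty's null space (linear trend) enters as fixed
effects and the wiggly part as i.i.d. random coefficients whose variance is
the inverse smoothing parameter, so a single 2-parameter REML search selects
both the amount of smoothing and the between-subject variance.

Outliers are removed in a single pass (|residual| strictly greater than
``outlier_sd`` times the working-residual SD, residuals taken against the
fitted trajectory including the random intercept) and the model is refitted
once. Thinning profiles are the forward finite-difference derivative of the
fitted smooth on the age grid, with pointwise delta-method confidence
intervals; covariates enter additively, so the derivative does not depend on
the sex/scanner level used for prediction.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .atlas_io import LongitudinalCohort, VHConfig

logger = logging.getLogger("vhlifespan")


class FitError(RuntimeError):
    """A regional trajectory fit could not be completed."""


class GridError(ValueError):
    """A requested evaluation age lies outside the fitted age support."""


# ---------------------------------------------------------------------------
# Penalized cubic spline basis on quantile knots
# ---------------------------------------------------------------------------

class CubicRegressionSpline:
    """Cubic B-spline basis on a given set of distinct knots with the exact
    curvature penalty ``int f''(x)^2 dx``.

    The ``knots_k`` distinct knots (boundary knots at the observed age
    min/max, interior knots at the quantiles between them) give a basis of
    dimension ``knots_k + 2``; no natural boundary constraint is imposed, so
    the fit keeps full cubic flexibility at the edges of the age range, where
    childhood curvature matters for the derivative. The penalty is computed
    exactly with two-point Gauss-Legendre quadrature per inter-knot segment
    (the integrand is piecewise quadratic in each segment's parameterization,
    as B'' of a cubic is piecewise linear). Its null space is the linear
    functions. Evaluation outside the knot range extends the boundary
    polynomial.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 3:
            raise ValueError("need at least 3 distinct knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        from scipy.interpolate import BSpline

        self.knots = knots
        t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
        m = t.size - 4
        self._spl = BSpline(t, np.eye(m), 3, extrapolate=True)
        self._d2 = self._spl.derivative(2)
        # exact curvature penalty: 2-point Gauss per segment
        g = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        S = np.zeros((m, m))
        for a, b in zip(knots[:-1], knots[1:]):
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            for gp in g:
                row = self._d2(mid + half * gp)
                S += half * np.outer(row, row)
        self.penalty = S

    @property
    def dim(self) -> int:
        return self._spl.c.shape[0]

    def design(self, x) -> np.ndarray:
        """Basis function values at ``x`` (rows: points, cols: basis)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self._spl(x)


def _wiggly_transform(S: np.ndarray) -> np.ndarray:
    """Columns mapping i.i.d. wiggly coefficients to the cr coefficient space.

    Eigendecompose the penalty; the positive-eigenvalue subspace scaled by
    1/sqrt(eigenvalue) gives random-effect columns with identity penalty. The
    null space (linear functions) is represented by explicit intercept and
    linear-age fixed-effect columns instead.
    """
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    tol = vals[-1] * 1e-9
    keep = vals > tol
    return vecs[:, keep] / np.sqrt(vals[keep])[None, :]


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrajectoryFit:
    """A fitted regional trajectory model and everything needed downstream."""

    region: str
    basis: CubicRegressionSpline
    wiggly_map: np.ndarray                  # cr-coef space <- iid wiggly coefs
    age_center: float
    fixed_names: list[str]
    beta: np.ndarray                        # fixed effects (incl. intercept, linear age)
    u_wiggly: np.ndarray                    # working wiggly coefs (unscaled by sqrt(gamma1))
    gamma1: float                           # var ratio, wiggly / residual
    gamma2: float                           # var ratio, subject / residual
    sigma2: float                           # residual variance
    subject_effects: pd.Series              # BLUPs of subject intercepts
    smooth_cov: np.ndarray                  # cov of (linear-age beta, u_wiggly)
    fixed_cov: np.ndarray                   # cov of all fixed effects
    residual_sd: float                      # SD of working residuals (outlier rule)
    n_obs: int
    reml: float
    converged: bool
    age_support: tuple[float, float]

    @property
    def random_intercept_var(self) -> float:
        return self.gamma2 * self.sigma2

    def smooth(self, ages) -> np.ndarray:
        """The fitted smooth s(age) including intercept and linear trend,
        at reference covariate levels (first levels; immaterial for
        differences because covariates are additive)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        Phi = self.basis.design(ages)
        lin = ages - self.age_center
        return (self.beta[0] + self.beta[1] * lin
                + Phi @ self.wiggly_map @ (np.sqrt(self.gamma1) * self.u_wiggly))

    def smooth_design(self, ages) -> np.ndarray:
        """Rows mapping (linear beta, u_wiggly) to s(age) minus intercept."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        Phi = self.basis.design(ages)
        return np.column_stack([ages - self.age_center,
                                np.sqrt(self.gamma1) * (Phi @ self.wiggly_map)])

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Fitted values for observation rows, including subject intercepts."""
        X, Z1, subj = self._row_design(rows)
        mu = X @ self.beta + Z1 @ (np.sqrt(self.gamma1) * self.u_wiggly)
        mu += self.subject_effects.reindex(subj).fillna(0.0).to_numpy()
        return mu

    def _row_design(self, rows: pd.DataFrame):
        ages = rows["visit_age"].to_numpy(dtype=float)
        Phi = self.basis.design(ages)
        cols = [np.ones(len(rows)), ages - self.age_center]
        for name in self.fixed_names[2:]:
            kind, _, level = name.partition(":")
            col = rows["sex" if kind == "sex" else "scanner_id"].astype(str) == level
            cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols), Phi @ self.wiggly_map, rows["subject_id"].to_numpy()


def _design_for_region(sub: pd.DataFrame, cfg: VHConfig):
    ages = sub["visit_age"].to_numpy(dtype=float)
    qs = np.linspace(0.0, 1.0, cfg.knots_k)
    knots = np.unique(np.quantile(ages, qs))
    if knots.size < cfg.knots_k:
        raise FitError("too few distinct ages to place knots by quantiles")
    basis = CubicRegressionSpline(knots)
    W = _wiggly_transform(basis.penalty)
    center = float(ages.mean())

    cols = [np.ones(len(sub)), ages - center]
    names = ["intercept", "age"]
    for var, label in (("sex", "sex"), ("scanner_id", "scanner")):
        levels = sorted(sub[var].astype(str).unique())
        if len(levels) == 1:
            logger.info("region %s: single %s level '%s', dummy dropped",
                        sub["region"].iloc[0], label, levels[0])
            continue
        for lev in levels[1:]:
            cols.append((sub[var].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{label}:{lev}")
    X = np.column_stack(cols)
    Z1 = basis.design(ages) @ W

    subj, subj_idx = np.unique(sub["subject_id"].to_numpy(), return_inverse=True)
    Z2 = np.zeros((len(sub), subj.size))
    Z2[np.arange(len(sub)), subj_idx] = 1.0
    return basis, W, center, names, X, Z1, Z2, subj


def _reml_objective(theta, GXX, GXZ, GZZ, cX, cZ, yty, n, p, q1):
    g1, g2 = np.exp(np.clip(theta, -30.0, 30.0))
    q = GZZ.shape[0]
    s = np.concatenate([np.full(q1, np.sqrt(g1)), np.full(q - q1, np.sqrt(g2))])
    A = np.outer(s, s) * GZZ
    A[np.diag_indices(q)] += 1.0
    try:
        cf = cho_factor(A, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, None
    ZX = s[:, None] * GXZ.T                     # q x p
    Zy = s * cZ
    W1 = cho_solve(cf, ZX, check_finite=False)
    W2 = cho_solve(cf, Zy, check_finite=False)
    XtVX = GXX - ZX.T @ W1
    XtVy = cX - ZX.T @ W2
    ytVy = yty - Zy @ W2
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None
    yPy = max(ytVy - XtVy @ beta, 1e-300)
    logdetA = 2.0 * np.sum(np.log(np.diag(cf[0])))
    sign, logdetX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf, None
    reml = (n - p) * np.log(yPy) + logdetA + logdetX
    return reml, (beta, cf, s, ZX, Zy, yPy)


def fit_region(cohort: LongitudinalCohort, region: str, cfg: VHConfig) -> TrajectoryFit:
    """Fit the penalized-spline mixed model for one region by REML."""
    sub = cohort.data[cohort.data["region"] == region]
    if len(sub) < 3 * cfg.knots_k:
        raise FitError(f"region {region}: only {len(sub)} observations")
    basis, W, center, names, X, Z1, Z2, subjects = _design_for_region(sub, cfg)
    y = sub["thickness_mm"].to_numpy(dtype=float)
    n, p = X.shape
    q1 = Z1.shape[1]
    Z = np.hstack([Z1, Z2])

    GXX = X.T @ X
    GXZ = X.T @ Z
    GZZ = Z.T @ Z
    cX = X.T @ y
    cZ = Z.T @ y
    yty = float(y @ y)

    def f(theta):
        val, _ = _reml_objective(theta, GXX, GXZ, GZZ, cX, cZ, yty, n, p, q1)
        return val

    res = optimize.minimize(f, x0=np.array([0.0, 0.0]), method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
    val, parts = _reml_objective(res.x, GXX, GXZ, GZZ, cX, cZ, yty, n, p, q1)
    if parts is None:
        raise FitError(f"region {region}: REML evaluation failed at the optimum")
    if not np.isfinite(val):
        raise FitError(f"region {region}: REML did not converge")
    beta, cf, s, ZX, Zy, yPy = parts
    g1, g2 = np.exp(np.clip(res.x, -30.0, 30.0))
    sigma2 = yPy / (n - p)

    u = cho_solve(cf, Zy - ZX @ beta, check_finite=False)
    u1 = u[:q1]
    b2 = np.sqrt(g2) * u[q1:]

    # Bayesian covariance of (beta, u) via the full penalized normal matrix
    q = GZZ.shape[0]
    Afull = np.zeros((p + q, p + q))
    Afull[:p, :p] = GXX
    Afull[:p, p:] = (s[:, None] * GXZ.T).T
    Afull[p:, :p] = Afull[:p, p:].T
    Afull[p:, p:] = np.outer(s, s) * GZZ
    Afull[p + np.arange(q), p + np.arange(q)] += 1.0
    want = np.concatenate([np.arange(p), p + np.arange(q1)])
    E = np.zeros((p + q, want.size))
    E[want, np.arange(want.size)] = 1.0
    cov_cols = sigma2 * np.linalg.solve(Afull, E)
    cov_sub = cov_cols[want]                      # (p+q1) x (p+q1)
    # cov of (linear-age beta, u_wiggly): index 1 is the linear-age column
    smooth_sel = np.concatenate([[1], np.arange(p, p + q1)]).astype(int)
    smooth_cov = cov_sub[np.ix_(smooth_sel, smooth_sel)]
    fixed_cov = cov_sub[:p, :p]

    fitted = X @ beta + Z1 @ (np.sqrt(g1) * u1) + Z2 @ b2
    resid = y - fitted
    residual_sd = float(np.std(resid, ddof=0))
    if residual_sd <= 0:
        residual_sd = float(np.sqrt(max(sigma2, 1e-30)))

    return TrajectoryFit(
        region=region, basis=basis, wiggly_map=W, age_center=center,
        fixed_names=names, beta=beta, u_wiggly=u1, gamma1=float(g1),
        gamma2=float(g2), sigma2=float(sigma2),
        subject_effects=pd.Series(b2, index=subjects),
        smooth_cov=smooth_cov, fixed_cov=fixed_cov, residual_sd=residual_sd,
        n_obs=n, reml=float(val), converged=bool(np.isfinite(val)),
        age_support=(float(sub["visit_age"].min()), float(sub["visit_age"].max())),
    )


def remove_outliers_refit(cohort: LongitudinalCohort, region: str,
                          fit: TrajectoryFit, cfg: VHConfig,
                          ) -> tuple[TrajectoryFit, pd.Index]:
    """One outlier pass against the fitted trajectory, then a single refit.

    Rows with |residual| strictly greater than ``outlier_sd`` times the
    working-residual SD are removed; residuals include the subject random
    intercept. A row sitting exactly on the threshold is retained.
    """
    sub = cohort.data[cohort.data["region"] == region]
    resid = sub["thickness_mm"].to_numpy(dtype=float) - fit.predict(sub)
    mask = np.abs(resid) > cfg.outlier_sd * fit.residual_sd
    excluded = sub.index[mask]
    if mask.all():
        raise FitError(f"region {region}: outlier rule excluded every observation")
    if not mask.any():
        return fit, excluded
    kept = LongitudinalCohort(cohort.data.drop(index=excluded))
    logger.info("region %s: excluded %d outlier observation(s)", region, len(excluded))
    return fit_region(kept, region, cfg), excluded


def fit_all_regions(cohort: LongitudinalCohort, cfg: VHConfig,
                    regions: Sequence[str] | None = None,
                    outlier_pass: bool = True,
                    ) -> tuple[dict[str, TrajectoryFit], dict[str, int]]:
    """Fit every region, optionally with the outlier pass + refit."""
    regions = cohort.regions if regions is None else list(regions)
    fits: dict[str, TrajectoryFit] = {}
    excluded: dict[str, int] = {}
    for region in regions:
        fit = fit_region(cohort, region, cfg)
        if outlier_pass:
            fit, dropped = remove_outliers_refit(cohort, region, fit, cfg)
            excluded[region] = int(len(dropped))
        else:
            excluded[region] = 0
        fits[region] = fit
    return fits, excluded


# ---------------------------------------------------------------------------
# Thinning profiles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ThinningProfileSet:
    """Thickness derivatives (mm/yr) on the age grid, one column per region.

    Negative values denote thinning, positive values thickening.
    """

    ages: np.ndarray
    regions: tuple[str, ...]
    derivative: pd.DataFrame       # ages x regions
    ci_halfwidth: pd.DataFrame     # same shape
    excluded_count: Mapping[str, int]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.derivative.to_numpy())):
            raise ValueError("derivative contains non-finite values")

    def to_tsv(self, path) -> None:
        out = self.derivative.copy()
        out.insert(0, "age", self.ages)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ThinningProfileSet":
        df = pd.read_csv(path, sep="\t")
        ages = df.pop("age").to_numpy(dtype=float)
        df.index = ages
        return cls(ages=ages, regions=tuple(df.columns),
                   derivative=df,
                   ci_halfwidth=pd.DataFrame(np.nan, index=ages, columns=df.columns),
                   excluded_count={r: 0 for r in df.columns})


def thinning_profiles(fits: Mapping[str, TrajectoryFit], cfg: VHConfig,
                      excluded: Mapping[str, int] | None = None,
                      ) -> ThinningProfileSet:
    """Forward finite-difference derivative of each fitted smooth on the grid,
    with pointwise delta-method confidence half-widths (1.96 SE)."""
    ages = cfg.age_grid
    deriv = {}
    ci = {}
    for region, fit in fits.items():
        lo, hi = fit.age_support
        if ages[0] < lo or ages[-1] + cfg.fd_eps > hi:
            raise GridError(
                f"region {region}: grid [{ages[0]}, {ages[-1] + cfg.fd_eps}] outside "
                f"fitted age support [{lo}, {hi}]")
        d = (fit.smooth(ages + cfg.fd_eps) - fit.smooth(ages)) / cfg.fd_eps
        Dmat = (fit.smooth_design(ages + cfg.fd_eps) - fit.smooth_design(ages)) / cfg.fd_eps
        var = np.einsum("ij,jk,ik->i", Dmat, fit.smooth_cov, Dmat)
        deriv[region] = d
        ci[region] = 1.96 * np.sqrt(np.maximum(var, 0.0))
    regions = tuple(fits.keys())
    return ThinningProfileSet(
        ages=ages, regions=regions,
        derivative=pd.DataFrame(deriv, index=ages)[list(regions)],
        ci_halfwidth=pd.DataFrame(ci, index=ages)[list(regions)],
        excluded_count=dict(excluded or {r: 0 for r in regions}),
    )
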