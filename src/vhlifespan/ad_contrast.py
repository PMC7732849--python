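"""Diagnosis-related regional thinning profiles and their virtual histology.

Per region, cortical thickness in an elderly clinical cohort is modelled
with a linear mixed model: fixed effects for diagnosis (HC reference, MCI
and AD dummies), age, sex and site/field-strength, and a subject random
intercept (REML). The inter-regional contrast profiles are differences of
diagnosis coefficients (AD - HC is the AD dummy itself since HC is the
reference), so AD_vs_HC = AD_vs_MCI + MCI_vs_HC holds identically. Each
contrast profile is then tested against cell-type expression with the same
gene-resampling machinery as the lifespan analysis, with a single "age"
(the max-statistic step degenerates to the identity). A negative mean
correlation means higher expression where the diagnosis-related thinning is
more pronounced.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf

from .atlas_io import ClinicalCohort, VHConfig
from .expression import CellTypePanel, RegionalExpressionMatrix
from .trajectories import ThinningProfileSet
from .virtual_histology import VHResult, run_virtual_histology

logger = logging.getLogger("vhlifespan")


class ContrastFitError(RuntimeError):
    """A per-region diagnosis model could not be estimated."""


@dataclasses.dataclass
class DiagnosisFit:
    """Fixed-effect estimates for one region's diagnosis model."""

    region: str
    coef: pd.Series            # includes MCI and AD effects vs HC
    se: pd.Series
    cov: pd.DataFrame
    used_random_intercept: bool


@dataclasses.dataclass
class ContrastProfile:
    """One diagnosis contrast across all regions (mm; negative = thinner)."""

    name: str
    values: pd.Series          # region -> thickness difference
    se: pd.Series

    def as_profile_set(self) -> ThinningProfileSet:
        """Wrap as a single-row profile set so the resampling machinery can
        consume it (the 'age' axis has one entry)."""
        regions = tuple(self.values.index)
        df = pd.DataFrame([self.values.to_numpy()], index=[0.0], columns=list(regions))
        return ThinningProfileSet(
            ages=np.array([0.0]), regions=regions, derivative=df,
            ci_halfwidth=pd.DataFrame([1.96 * self.se.to_numpy()], index=[0.0],
                                      columns=list(regions)),
            excluded_count={r: 0 for r in regions},
        )


_MCI = "C(diagnosis, Treatment('HC'))[T.MCI]"
_AD = "C(diagnosis, Treatment('HC'))[T.AD]"


def fit_diagnosis_lmm(cohort: ClinicalCohort, region: str, cfg: VHConfig) -> DiagnosisFit:
    """REML linear mixed model of thickness on diagnosis + age + sex + site
    with a subject random intercept, for one region."""
    sub = cohort.data[cohort.data["region"] == region].copy()
    counts = sub.groupby("diagnosis")["subject_id"].nunique()
    low = [d for d in ("HC", "MCI", "AD") if counts.get(d, 0) < 10]
    if low:
        raise ContrastFitError(f"region {region}: fewer than 10 subjects for {low}")

    terms = ["C(diagnosis, Treatment('HC'))", "visit_age"]
    for var in ("sex", "site"):
        if sub[var].nunique() > 1:
            terms.append(f"C({var})")
        else:
            logger.info("region %s: single %s level, dummy dropped", region, var)
    formula = "thickness_mm ~ " + " + ".join(terms)

    X = patsy.dmatrix(" + ".join(terms), sub, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        dep = [X.columns[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ContrastFitError(f"region {region}: rank-deficient design, collinear columns {dep}")

    multi_visit = (sub.groupby("subject_id")["visit_age"].nunique() > 1).any()
    if multi_visit:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, sub, groups=sub["subject_id"])
            fit = model.fit(reml=True, method="lbfgs")
        params, cov = fit.fe_params, fit.cov_params().iloc[:len(fit.fe_params), :len(fit.fe_params)]
        used_ri = True
    else:
        logger.warning("region %s: no multi-visit subjects; falling back to OLS", region)
        fit = smf.ols(formula, sub).fit()
        params, cov = fit.params, fit.cov_params()
        used_ri = False
    se = pd.Series(np.sqrt(np.diag(cov)), index=params.index)
    return DiagnosisFit(region=region, coef=params, se=se,
                        cov=pd.DataFrame(cov, index=params.index, columns=params.index),
                        used_random_intercept=used_ri)


def fit_all_diagnosis(cohort: ClinicalCohort, cfg: VHConfig,
                      regions: Sequence[str] | None = None) -> dict[str, DiagnosisFit]:
    regions = cohort.regions if regions is None else list(regions)
    return {r: fit_diagnosis_lmm(cohort, r, cfg) for r in regions}


def contrast_profiles(fits: Mapping[str, DiagnosisFit]) -> list[ContrastProfile]:
    """The three pairwise diagnosis contrasts per region, from one fit each
    (no per-pair refitting): AD-HC and MCI-HC are the dummy coefficients,
    AD-MCI their difference."""
    regions = list(fits)
    ad = pd.Series({r: fits[r].coef[_AD] for r in regions})
    mci = pd.Series({r: fits[r].coef[_MCI] for r in regions})
    se_ad = pd.Series({r: fits[r].se[_AD] for r in regions})
    se_mci = pd.Series({r: fits[r].se[_MCI] for r in regions})
    se_diff = pd.Series({
        r: float(np.sqrt(max(fits[r].cov.loc[_AD, _AD] + fits[r].cov.loc[_MCI, _MCI]
                             - 2 * fits[r].cov.loc[_AD, _MCI], 0.0)))
        for r in regions})
    return [
        ContrastProfile("AD_vs_HC", ad, se_ad),
        ContrastProfile("MCI_vs_HC", mci, se_mci),
        ContrastProfile("AD_vs_MCI", ad - mci, se_diff),
    ]


def vh_on_contrast(profile: ContrastProfile, expr: RegionalExpressionMatrix,
                   panels: Sequence[CellTypePanel], cfg: VHConfig) -> VHResult:
    """Virtual histology of one diagnosis-contrast profile (single-age grid)."""
    return run_virtual_histology(profile.as_profile_set(), expr, panels, cfg)
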