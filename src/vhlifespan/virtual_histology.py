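"""Expression-thinning correlations and the gene-resampling null.

For every consistent gene and every sampled age, the Pearson correlation
between the gene's regional expression profile and the age's regional
thinning profile is computed (positive r: higher expression where thinning
is shallower, because the derivative is signed with negative = thinning).
A cell-type panel's statistic at an age is the unweighted mean of its member
genes' correlations.

Significance uses a gene-resampling null with a max-statistic family
correction over the age grid: each of B iterations (1) draws, without
replacement from the full consistent pool, as many genes as the panel has,
(2) averages their correlations at every age, and (3) keeps the signed mean
with the largest absolute value across ages. The observed per-age mean is
compared two-sidedly to that null, p = (1 + #{|null| >= |observed|}) / (B+1),
which controls the family-wise rate over ages within a panel. Across panels,
p-values are Benjamini-Hochberg adjusted at each age. In replication mode
only a stated subset of panels is tested and adjusted.

Variance explained is the R-squared of an OLS regression of the 34-region
thinning profile at one age on the panel-average expression profiles of the
panels significant at that age.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas_io import VHConfig
from .expression import CellTypePanel, RegionalExpressionMatrix
from .trajectories import ThinningProfileSet


class VHInputError(ValueError):
    """Inconsistent inputs to the virtual-histology statistics."""


# ---------------------------------------------------------------------------
# Gene-level correlations
# ---------------------------------------------------------------------------

def gene_correlations(expr: RegionalExpressionMatrix,
                      profiles: ThinningProfileSet) -> pd.DataFrame:
    """Pearson r between each gene's regional profile and each age's thinning
    profile; genes x ages."""
    if list(expr.regions) != list(profiles.regions):
        common = [r for r in profiles.regions if r in expr.regions]
        if len(common) != len(profiles.regions):
            raise VHInputError("expression and thinning profiles cover different regions")
        expr_mat = expr.median[list(profiles.regions)].to_numpy()
    else:
        expr_mat = expr.median.to_numpy()
    D = profiles.derivative.to_numpy()                     # ages x regions
    sd = D.std(axis=1, ddof=0)
    # numerically-zero variance counts too (a constant row can acquire an
    # O(1e-18) sd purely from floating-point mean subtraction)
    tol = 1e-12 * np.maximum(np.abs(D).max(axis=1), np.finfo(float).tiny)
    zero = np.flatnonzero(sd <= tol)
    if zero.size:
        raise VHInputError(
            f"thinning profile has zero variance across regions at age "
            f"{profiles.ages[zero[0]]}")
    R = expr_mat.shape[1]
    Zg = (expr_mat - expr_mat.mean(axis=1, keepdims=True))
    gsd = Zg.std(axis=1, ddof=0)
    gtol = 1e-12 * np.maximum(np.abs(expr_mat).max(axis=1), np.finfo(float).tiny)
    if (gsd <= gtol).any():
        raise VHInputError("gene profile with zero variance across regions")
    Zg /= gsd[:, None]
    Zd = (D - D.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = Zg @ Zd.T / R
    return pd.DataFrame(corr, index=expr.genes, columns=profiles.ages)


def panel_statistic(corr: pd.DataFrame, panel: CellTypePanel) -> pd.Series:
    """Unweighted mean correlation over the panel's genes, per age."""
    if not panel.genes:
        raise VHInputError(f"panel {panel.name} is empty")
    missing = [g for g in panel.genes if g not in corr.index]
    if missing:
        raise VHInputError(f"panel {panel.name}: genes not in correlation matrix: {missing[:5]}")
    return corr.loc[list(panel.genes)].mean(axis=0)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def panel_rng(master_seed: int, panel_name: str) -> np.random.Generator:
    """Per-panel RNG stream derived from the master seed and a stable hash of
    the panel name, so adding panels never perturbs other panels' draws."""
    digest = hashlib.sha256(panel_name.encode("utf-8")).digest()
    word = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, word]))


def null_max_draws(corr_values: np.ndarray, panel_size: int, B: int,
                   rng: np.random.Generator) -> np.ndarray:
    """B signed mean correlations taken at the age of maximum absolute value,
    for random without-replacement gene subsets of the pool."""
    n_pool, n_ages = corr_values.shape
    if panel_size > n_pool:
        raise VHInputError(f"panel size {panel_size} exceeds pool size {n_pool}")
    draws = np.empty(B)
    for b in range(B):
        idx = rng.choice(n_pool, size=panel_size, replace=False)
        means = corr_values[idx].mean(axis=0)
        draws[b] = means[np.argmax(np.abs(means))]
    return draws


def permutation_test(corr: pd.DataFrame, panel: CellTypePanel, cfg: VHConfig,
                     ) -> tuple[pd.Series, dict]:
    """Per-age two-sided permutation p-values against the max-over-ages null.

    The pool is sorted by gene symbol before drawing, so the null draws do not
    depend on the row order of the supplied correlation matrix.
    """
    observed = panel_statistic(corr, panel)
    rng = panel_rng(cfg.rng_seed, panel.name)
    B = cfg.n_permutations
    draws = null_max_draws(corr.sort_index().to_numpy(), len(panel.genes), B, rng)
    abs_null = np.abs(draws)
    p = (1.0 + (abs_null[None, :] >= np.abs(observed.to_numpy())[:, None]).sum(axis=1)) / (B + 1.0)
    summary = {
        "panel": panel.name, "panel_size": len(panel.genes), "B": B,
        "seed": cfg.rng_seed,
        "null_mean": float(draws.mean()), "null_sd": float(draws.std(ddof=0)),
        "null_abs_q95": float(np.quantile(abs_null, 0.95)),
    }
    return pd.Series(p, index=observed.index), summary


def fdr_across_panels(p_perm: pd.DataFrame, cfg: VHConfig) -> pd.DataFrame:
    """Benjamini-Hochberg over the panel dimension at each age independently.

    With ``cfg.restrict_panels`` set (replication mode), only those panels are
    adjusted; the rest get NaN.
    """
    if p_perm.empty:
        raise VHInputError("no panels to adjust")
    panels = list(p_perm.index)
    if cfg.restrict_panels is not None:
        panels = [p for p in panels if p in set(cfg.restrict_panels)]
    out = pd.DataFrame(np.nan, index=p_perm.index, columns=p_perm.columns)
    for age in p_perm.columns:
        pv = p_perm.loc[panels, age].to_numpy()
        out.loc[panels, age] = multipletests(pv, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Variance explained
# ---------------------------------------------------------------------------

def variance_explained(profiles: ThinningProfileSet, expr: RegionalExpressionMatrix,
                       significant_panels: Mapping[float, Sequence[CellTypePanel]],
                       ) -> pd.Series:
    """Per-age R-squared of OLS of the thinning profile on the significant
    panels' mean expression profiles (plus intercept). Ages with no
    significant panel get NaN."""
    regions = list(profiles.regions)
    out = {}
    for age, panels in significant_panels.items():
        if not panels:
            out[age] = np.nan
            continue
        if len(panels) > len(regions) - 1:
            raise VHInputError("more predictors than regions minus one")
        X = np.column_stack([np.ones(len(regions))] + [
            expr.median.loc[list(p.genes), regions].mean(axis=0).to_numpy() for p in panels])
        y = profiles.derivative.loc[age, regions].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        out[age] = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return pd.Series(out).sort_index()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VHResult:
    """Tidy per (panel, age) results plus null summaries and R-squared."""

    table: pd.DataFrame                    # panel, age, mean_r, p_perm, p_fdr
    null_summaries: dict[str, dict]
    r_squared: pd.Series
    config: VHConfig

    def significant(self, panel: str) -> pd.DataFrame:
        t = self.table
        return t[(t["panel"] == panel) & (t["p_fdr"] < self.config.alpha)]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_virtual_histology(profiles: ThinningProfileSet,
                          expr: RegionalExpressionMatrix,
                          panels: Sequence[CellTypePanel],
                          cfg: VHConfig) -> VHResult:
    """Full analysis: correlations, panel statistics, resampling null, FDR,
    and variance explained by the significant panels."""
    corr = gene_correlations(expr, profiles)
    pool = set(corr.index)
    for panel in panels:
        if not set(panel.genes) <= pool:
            raise VHInputError(f"panel {panel.name} is not a subset of the consistent pool")

    mean_r = pd.DataFrame({p.name: panel_statistic(corr, p) for p in panels}).T
    p_perm = {}
    summaries = {}
    for panel in panels:
        p, s = permutation_test(corr, panel, cfg)
        p_perm[panel.name] = p
        summaries[panel.name] = s
    p_perm = pd.DataFrame(p_perm).T.loc[mean_r.index]
    p_fdr = fdr_across_panels(p_perm, cfg)

    sig: dict[float, list[CellTypePanel]] = {}
    by_name = {p.name: p for p in panels}
    for age in mean_r.columns:
        names = p_fdr.index[(p_fdr[age] < cfg.alpha).fillna(False)]
        sig[age] = [by_name[n] for n in names]
    r2 = variance_explained(profiles, expr, sig)

    long = (mean_r.rename_axis("panel").reset_index()
            .melt(id_vars="panel", var_name="age", value_name="mean_r"))
    long["p_perm"] = [p_perm.loc[r.panel, r.age] for r in long.itertuples()]
    long["p_fdr"] = [p_fdr.loc[r.panel, r.age] for r in long.itertuples()]
    long["age"] = long["age"].astype(float)
    long = long.sort_values(["panel", "age"]).reset_index(drop=True)
    return VHResult(table=long, null_summaries=summaries, r_squared=r2, config=cfg)
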