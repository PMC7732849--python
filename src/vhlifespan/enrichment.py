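"""Co-expression partners of high-fidelity marker genes and disease-gene
over-representation.

This is a deliberately desk-scale version of the post-hoc enrichment step:
(1) select the panel genes whose regional profile tracks a target profile
with |r| at or above a fidelity threshold, (2) collect background genes
co-expressed with the mean profile of that seed set, and (3) test whether a
curated disease gene set is over-represented among the partners with a
one-sided hypergeometric tail, BH-adjusted across the seed sets tested in
one run. Co-expression is computed on the single supplied regional matrix
rather than a multi-resource brain-bank compendium; the statistical shape
(seed genes -> partners -> over-representation) is preserved.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import CellTypePanel, RegionalExpressionMatrix

logger = logging.getLogger("vhlifespan")


class EnrichmentError(ValueError):
    """Invalid gene-set inputs."""


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named set of human gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        # may be empty (a fidelity screen can return nothing); never duplicated
        if len(set(self.genes)) != len(self.genes):
            raise EnrichmentError(f"gene set {self.name}: duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One symbol per line; ``#`` starts a comment."""
    symbols = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            symbols.append(sym)
    if not symbols:
        raise EnrichmentError(f"gene set file {path} is empty")
    return GeneSet(name or Path(path).stem, tuple(dict.fromkeys(symbols)))


def _profile_corr(profiles: np.ndarray, target: np.ndarray) -> np.ndarray:
    t = target - target.mean()
    tsd = t.std()
    if tsd == 0:
        raise EnrichmentError("target profile has zero variance across regions")
    P = profiles - profiles.mean(axis=1, keepdims=True)
    sd = P.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (P @ t) / (profiles.shape[1] * sd * tsd)
    return r


def high_fidelity_genes(panel: CellTypePanel, target_profile: pd.Series,
                        expr: RegionalExpressionMatrix, threshold: float = 0.5) -> GeneSet:
    """Panel genes whose regional profile correlates with the target profile
    at |r| >= threshold."""
    genes = [g for g in panel.genes if g in expr.genes]
    if len(genes) < len(panel.genes):
        raise EnrichmentError(f"panel {panel.name} not fully contained in expression matrix")
    regions = expr.regions
    r = _profile_corr(expr.median.loc[genes, regions].to_numpy(),
                      target_profile.reindex(regions).to_numpy())
    kept = tuple(g for g, ri in zip(genes, r) if np.isfinite(ri) and abs(ri) >= threshold)
    if not kept:
        logger.warning("panel %s: no gene reaches fidelity |r| >= %.2f", panel.name, threshold)
    return GeneSet(f"{panel.name}_high_fidelity", kept)


def coexpression_partners(seed_set: GeneSet, expr: RegionalExpressionMatrix,
                          background: GeneSet, r_threshold: float = 0.5) -> GeneSet:
    """Background genes co-expressed (r >= threshold) with the seed-set mean
    regional profile."""
    if not seed_set.genes:
        raise EnrichmentError("seed set is empty")
    regions = expr.regions
    mean_profile = expr.median.loc[list(seed_set.genes), regions].mean(axis=0)
    if mean_profile.std(ddof=0) == 0:
        raise EnrichmentError("seed mean profile has zero variance")
    bg = [g for g in background.genes if g in expr.genes]
    r = _profile_corr(expr.median.loc[bg, regions].to_numpy(), mean_profile.to_numpy())
    kept = tuple(g for g, ri in zip(bg, r) if np.isfinite(ri) and ri >= r_threshold)
    return GeneSet(f"{seed_set.name}_partners", kept)


def hypergeometric_test(partners: GeneSet, disease: GeneSet, universe: GeneSet) -> dict:
    """One-sided over-representation: P(X >= k) with k = |partners & disease|,
    drawing |partners| from a universe containing |disease| successes."""
    if not universe.genes:
        raise EnrichmentError("universe is empty")
    uni = set(universe.genes)
    part = set(partners.genes) & uni
    dis = set(disease.genes) & uni
    if set(partners.genes) - uni or set(disease.genes) - uni:
        raise EnrichmentError("partners and disease set must be subsets of the universe")
    k = len(part & dis)
    N, K, n = len(uni), len(dis), len(part)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return {"k": k, "N": N, "K": K, "n": n, "p": p}


def enrichment_analysis(seed_sets: Sequence[GeneSet], expr: RegionalExpressionMatrix,
                        background: GeneSet, disease: GeneSet, universe: GeneSet,
                        r_threshold: float = 0.5) -> pd.DataFrame:
    """Partners + hypergeometric test for each seed set, with BH across the
    seed sets tested in this run."""
    rows = []
    for seed in seed_sets:
        partners = coexpression_partners(seed, expr, background, r_threshold)
        res = hypergeometric_test(partners, disease, universe)
        rows.append({"seed_set": seed.name, "n_partners": len(partners), **res})
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
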