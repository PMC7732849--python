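"""Regional gene-expression profiles and cell-type marker panels.

Sample-level microarray-style tables (donor, sample, region, probe, gene,
intensity) are reduced to one value per gene per region: probe values are
mean-averaged within a sample, samples are median-summarized within each
(donor, region), and the cross-donor median of those donor medians is the
regional profile. Genes whose profiles are not reproducible across donors
(mean pairwise inter-donor Pearson r below a threshold), or across a second
dataset when one is supplied, are filtered out; the retained genes form the
"consistent" pool that both anchors the cell-type panels and serves as the
resampling universe for the permutation null.

Mouse marker panels are converted to human symbols through a two-column
homolog table (many-to-many allowed), deduplicated, and intersected with the
consistent pool.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas_io import RegionAtlas, SchemaError, VHConfig

logger = logging.getLogger("vhlifespan")

EXPRESSION_COLUMNS = ["donor_id", "sample_id", "region", "probe_id", "gene_symbol", "expression"]


class ExpressionInputError(ValueError):
    """Malformed expression, panel, or homolog inputs."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegionalExpressionMatrix:
    """Cross-donor median regional profiles plus the per-donor matrices."""

    median: pd.DataFrame                     # genes x regions
    per_donor: dict[str, pd.DataFrame]       # donor -> genes x regions
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.median.index

    @property
    def regions(self) -> list[str]:
        return list(self.median.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.median.rename_axis("gene_symbol").to_csv(path, sep="\t", float_format="%.10g")


@dataclasses.dataclass(frozen=True)
class CellTypePanel:
    """Human marker-gene symbols for one cell class."""

    name: str
    genes: tuple[str, ...]
    source_mouse: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ExpressionInputError(f"panel {self.name}: duplicate gene symbols")
        if not self.genes:
            raise ExpressionInputError(f"panel {self.name}: empty after filtering")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def load_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"expression table missing columns: {missing}")
    return df


def aggregate_probes(samples: pd.DataFrame) -> pd.DataFrame:
    """Mean over microarray probes: one expression value per (donor, sample,
    region, gene)."""
    missing = [c for c in EXPRESSION_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"expression table missing columns: {missing}")
    g = samples.groupby(["donor_id", "sample_id", "region", "gene_symbol"],
                        observed=True, sort=False)
    return g["expression"].mean().reset_index()


def summarize_regions(values: pd.DataFrame, atlas: RegionAtlas) -> RegionalExpressionMatrix:
    """Median within (donor, region), then the median across donors.

    Even-count medians use the midpoint convention. A gene missing a region in
    every donor is dropped with a log entry.
    """
    donor_med = (values.groupby(["donor_id", "gene_symbol", "region"], observed=True, sort=False)
                 ["expression"].median())
    per_donor = {}
    for donor, block in donor_med.groupby(level="donor_id", observed=True):
        mat = block.droplevel("donor_id").unstack("region")
        per_donor[str(donor)] = mat.reindex(columns=list(atlas.regions))
    aligned = _aligned(per_donor)
    stacked = np.stack([m.to_numpy() for m in aligned], axis=0)
    genes = aligned[0].index
    with warnings.catch_warnings():
        # an all-NaN (gene, region) slice is handled below, not a problem here
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        med = np.nanmedian(stacked, axis=0)
    median = pd.DataFrame(med, index=genes, columns=list(atlas.regions))
    incomplete = median.isna().any(axis=1)
    if incomplete.any():
        dropped = list(median.index[incomplete])
        logger.info("summarize_regions: dropped %d gene(s) missing a region in "
                    "all donors: %s%s", len(dropped), dropped[:5],
                    "..." if len(dropped) > 5 else "")
        median = median[~incomplete]
        per_donor = {d: m.loc[median.index] for d, m in per_donor.items()}
    else:
        per_donor = {d: m.loc[median.index] for d, m in per_donor.items()}
    return RegionalExpressionMatrix(
        median=median, per_donor=per_donor,
        provenance={"n_donors": len(per_donor), "n_genes": int(len(median))},
    )


def _aligned(per_donor: dict[str, pd.DataFrame]) -> list[pd.DataFrame]:
    genes = None
    for m in per_donor.values():
        genes = m.index if genes is None else genes.union(m.index)
    return [m.reindex(index=genes) for m in per_donor.values()]


# ---------------------------------------------------------------------------
# Consistency filtering
# ---------------------------------------------------------------------------

def _profile_zscores(mat: np.ndarray) -> np.ndarray:
    """Row-standardize (population SD); rows with zero variance become NaN."""
    mu = np.nanmean(mat, axis=1, keepdims=True)
    sd = np.nanstd(mat, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mat - mu) / sd


def mean_interdonor_correlation(mat: RegionalExpressionMatrix) -> pd.Series:
    """Mean pairwise Pearson correlation of each gene's regional profile
    across donors. NaN where any donor profile has zero variance or gaps."""
    donors = list(mat.per_donor)
    R = len(mat.regions)
    Z = np.stack([_profile_zscores(mat.per_donor[d].to_numpy()) for d in donors])  # D,G,R
    D = Z.shape[0]
    pair_sum = np.zeros(Z.shape[1])
    n_pairs = D * (D - 1) / 2
    for i in range(D):
        for j in range(i + 1, D):
            pair_sum += np.einsum("gr,gr->g", Z[i], Z[j]) / R
    return pd.Series(pair_sum / n_pairs, index=mat.genes)


def consistency_filter(mat: RegionalExpressionMatrix,
                       second: RegionalExpressionMatrix | None,
                       cfg: VHConfig) -> RegionalExpressionMatrix:
    """Keep genes reproducible across donors (and across datasets if a second
    matrix is given). The retained set is the consistent-gene pool."""
    if len(mat.per_donor) < 2:
        raise ExpressionInputError("consistency filter needs >= 2 donors")
    thr = cfg.consistency_threshold
    r_donor = mean_interdonor_correlation(mat)
    undefined = r_donor.isna()
    if undefined.any():
        logger.warning("consistency_filter: %d gene(s) with undefined inter-donor "
                       "correlation dropped", int(undefined.sum()))
    keep = r_donor >= thr

    if second is not None:
        common = mat.genes.intersection(second.genes)
        A = _profile_zscores(mat.median.loc[common].to_numpy())
        B = _profile_zscores(second.median.loc[common, mat.regions].to_numpy())
        r_ds = pd.Series(np.einsum("gr,gr->g", A, B) / len(mat.regions), index=common)
        keep &= mat.genes.isin(r_ds.index[r_ds >= thr])

    kept = mat.genes[keep.fillna(False)]
    logger.info("consistency_filter: kept %d / %d genes at threshold %.2f",
                len(kept), len(mat.genes), thr)
    return RegionalExpressionMatrix(
        median=mat.median.loc[kept],
        per_donor={d: m.loc[kept] for d, m in mat.per_donor.items()},
        provenance={**mat.provenance, "consistency_threshold": thr,
                    "cross_dataset": second is not None, "n_consistent": int(len(kept))},
    )


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def load_panel_file(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (panel_name, mouse_symbol) -> ordered symbol lists."""
    df = pd.read_csv(path, sep="\t")
    if not {"panel_name", "mouse_symbol"}.issubset(df.columns):
        raise SchemaError("panel file needs columns panel_name, mouse_symbol")
    return {str(name): block["mouse_symbol"].astype(str).tolist()
            for name, block in df.groupby("panel_name", sort=False)}


def load_homolog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"mouse_symbol", "human_symbol"}.issubset(df.columns):
        raise SchemaError("homolog table needs columns mouse_symbol, human_symbol")
    return df[["mouse_symbol", "human_symbol"]].astype(str)


def default_panel_fixture() -> tuple[dict[str, list[str]], pd.DataFrame]:
    """The packaged synthetic stand-in for the nine mouse cell-class marker
    panels and their mouse-to-human homolog table."""
    data = importlib.resources.files("vhlifespan.data")
    with importlib.resources.as_file(data / "panels_synthetic.tsv") as p:
        panels = load_panel_file(p)
    with importlib.resources.as_file(data / "homologs_synthetic.tsv") as p:
        homologs = load_homolog_table(p)
    return panels, homologs


def map_panels_to_human(mouse_panels: Mapping[str, Sequence[str]],
                        homologs: pd.DataFrame) -> dict[str, list[str]]:
    """Mouse panels -> deduplicated human symbol lists (no pool filtering);
    used e.g. to decide which human genes a simulated dataset must measure."""
    lookup: dict[str, list[str]] = {}
    for m, h in homologs.itertuples(index=False):
        lookup.setdefault(m, []).append(h)
    out = {}
    for name, mouse_genes in mouse_panels.items():
        mapped = [h for m in mouse_genes for h in lookup.get(m, [])]
        if not mapped:
            raise ExpressionInputError(f"panel {name}: no mouse symbol found in homolog table")
        out[name] = list(dict.fromkeys(mapped))
    return out


def build_panels(mouse_panels: Mapping[str, Sequence[str]], homologs: pd.DataFrame,
                 consistent: RegionalExpressionMatrix) -> list[CellTypePanel]:
    """Map mouse symbols to human homologs, deduplicate, and intersect each
    panel with the consistent-gene pool. Panels emptied by filtering are
    excluded with a log entry."""
    lookup: dict[str, list[str]] = {}
    for m, h in homologs.itertuples(index=False):
        lookup.setdefault(m, []).append(h)
    pool = set(consistent.genes)
    panels: list[CellTypePanel] = []
    for name, mouse_genes in mouse_panels.items():
        mapped: list[str] = []
        unmapped = 0
        for m in mouse_genes:
            if m in lookup:
                mapped.extend(lookup[m])
            else:
                unmapped += 1
        if not mapped:
            raise ExpressionInputError(f"panel {name}: no mouse symbol found in homolog table")
        if unmapped:
            logger.info("panel %s: %d mouse symbol(s) without homolog dropped", name, unmapped)
        human = list(dict.fromkeys(mapped))          # dedupe, preserve order
        kept = tuple(g for g in human if g in pool)
        if not kept:
            logger.warning("panel %s emptied by the consistency filter; excluded", name)
            continue
        panels.append(CellTypePanel(name=name, genes=kept, source_mouse=tuple(mouse_genes)))
    return panels
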