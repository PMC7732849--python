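"""Region atlas, run configuration, and delimited-table I/O shared by all stages.

The parcellation fixture is the 34-parcel left-hemisphere Desikan-Killiany
gyral atlas (FreeSurfer label names prefixed ``lh.``), which is the unit of
analysis throughout: thickness tables, expression profiles and thinning
profiles are all indexed by these 34 labels.

Thickness tables are long-format TSV (UTF-8, header row, ``.`` decimal) with
columns ``subject_id, visit_age, sex, scanner_id, region, thickness_mm``;
clinical tables add ``diagnosis`` (HC/MCI/AD) and ``site``.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("vhlifespan")

THICKNESS_BOUNDS = (0.5, 6.0)  # plausible cortical thickness in mm

COHORT_COLUMNS = ["subject_id", "visit_age", "sex", "scanner_id", "region", "thickness_mm"]
CLINICAL_COLUMNS = COHORT_COLUMNS + ["diagnosis", "site"]
DIAGNOSIS_LEVELS = ("HC", "MCI", "AD")


class SchemaError(ValueError):
    """A table is missing required columns or references unknown labels."""


class VHParseError(ValueError):
    """A table cell could not be parsed as the required type."""


class VHValidationError(ValueError):
    """Parsed values violate a domain invariant (e.g. thickness bounds)."""


class ConfigurationError(ValueError):
    """An operation was invoked without the configuration it requires."""


# ---------------------------------------------------------------------------
# Region atlas
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of cortical parcels with optional per-region area weights."""

    regions: tuple[str, ...]
    area_weight: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise VHValidationError("atlas region labels must be unique")
        if self.area_weight is not None:
            missing = [r for r in self.regions if r not in self.area_weight]
            if missing:
                raise VHValidationError(f"area weights missing for regions: {missing}")
            bad = [r for r in self.regions if not self.area_weight[r] > 0]
            if bad:
                raise VHValidationError(f"area weights must be strictly positive: {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def with_uniform_weights(self, value: float = 1.0) -> "RegionAtlas":
        return RegionAtlas(self.regions, {r: value for r in self.regions})

    @classmethod
    def default(cls) -> "RegionAtlas":
        """The packaged 34-parcel left-hemisphere Desikan-Killiany fixture."""
        ref = importlib.resources.files("vhlifespan.data") / "dk_left_regions.tsv"
        with importlib.resources.as_file(ref) as path:
            labels = pd.read_csv(path, sep="\t")["region"].tolist()
        return cls(tuple(labels))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VHConfig:
    """Resolved parameters of one virtual-histology run.

    Defaults follow the reference analysis: derivative grid 5-89 years in
    2-year steps (43 ages), spline basis dimension 6 with knots at age
    quintiles, a +/-7 SD outlier pass, 10,000 resampling iterations and
    alpha = 0.05 after FDR adjustment across cell types.
    """

    age_min: float = 5.0
    age_max: float = 89.0
    age_step: float = 2.0
    knots_k: int = 6
    outlier_sd: float = 7.0
    n_permutations: int = 10_000
    alpha: float = 0.05
    fd_eps: float = 0.01
    rng_seed: int = 0
    consistency_threshold: float = 0.45
    restrict_panels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise VHValidationError("age_min must be < age_max")
        if not self.age_step > 0:
            raise VHValidationError("age_step must be > 0")
        if self.knots_k < 4:
            raise VHValidationError("knots_k must be >= 4")
        if self.n_permutations < 1:
            raise VHValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise VHValidationError("alpha must lie in (0, 1)")
        if self.restrict_panels is not None:
            self.restrict_panels = tuple(self.restrict_panels)

    @property
    def age_grid(self) -> np.ndarray:
        """Ages at which the thickness derivative is sampled."""
        n = int(np.floor((self.age_max - self.age_min) / self.age_step + 1e-9)) + 1
        return self.age_min + self.age_step * np.arange(n)

    @classmethod
    def from_dict(cls, d: Mapping) -> "VHConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VHConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["restrict_panels"] is not None:
            d["restrict_panels"] = list(d["restrict_panels"])
        return d

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", self.to_dict())


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LongitudinalCohort:
    """Long-format longitudinal thickness observations (one row per
    subject-visit-region)."""

    data: pd.DataFrame

    REQUIRED = tuple(COHORT_COLUMNS)

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def regions(self) -> list[str]:
        return sorted(self.data["region"].unique())


@dataclasses.dataclass
class ClinicalCohort(LongitudinalCohort):
    """Longitudinal cohort with a clinical diagnosis (HC/MCI/AD) and site."""

    REQUIRED = tuple(CLINICAL_COLUMNS)

    def __post_init__(self) -> None:
        super().__post_init__()
        bad = set(self.data["diagnosis"].unique()) - set(DIAGNOSIS_LEVELS)
        if bad:
            raise VHValidationError(f"unknown diagnosis levels: {sorted(bad)}")
        per_visit = self.data.groupby(["subject_id", "visit_age"], sort=False)["diagnosis"].nunique()
        if (per_visit > 1).any():
            raise VHValidationError("diagnosis must be constant within a visit")


def _validate_cohort_frame(df: pd.DataFrame, atlas: RegionAtlas, columns: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df[list(columns)].copy()
    for col in ("visit_age", "thickness_mm"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise VHParseError(f"non-numeric value in column '{col}' at row {idx}: {df[col].iloc[idx]!r}")
        if converted.isna().any():
            idx = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise VHParseError(f"missing value in column '{col}' at row {idx}")
        # re-parse with the correctly-rounded parser so written tables
        # round-trip bit-exactly (pd.to_numeric's fast path does not)
        df[col] = np.array([float(x) for x in df[col]], dtype=float)
    unknown = set(df["region"].unique()) - set(atlas.regions)
    if unknown:
        raise SchemaError(f"unknown region label(s): {sorted(unknown)}")
    lo, hi = THICKNESS_BOUNDS
    t = df["thickness_mm"].to_numpy()
    out = ~((t > lo) & (t < hi) & np.isfinite(t))
    if out.any():
        idx = int(np.flatnonzero(out)[0])
        raise VHValidationError(
            f"thickness_mm out of ({lo}, {hi}) at row {idx}: {t[idx]!r}"
        )
    return df


def load_cohort(path: str | Path, atlas: RegionAtlas) -> LongitudinalCohort:
    """Read and validate a long-format thickness TSV against the atlas."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _validate_cohort_frame(df, atlas, COHORT_COLUMNS)
    logger.info("loaded cohort %s: %d rows", path, len(df))
    return LongitudinalCohort(df)


def load_clinical_cohort(path: str | Path, atlas: RegionAtlas) -> ClinicalCohort:
    """Read and validate a clinical thickness TSV (adds diagnosis and site)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _validate_cohort_frame(df, atlas, CLINICAL_COLUMNS)
    logger.info("loaded clinical cohort %s: %d rows", path, len(df))
    return ClinicalCohort(df)


def write_cohort(cohort: LongitudinalCohort, path: str | Path) -> None:
    """Write a cohort back to TSV with full float precision (round-trip safe)."""
    cohort.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def weighted_mean_thickness(cohort: LongitudinalCohort, atlas: RegionAtlas) -> pd.DataFrame:
    """Area-weighted mean thickness per scan.

    For every (subject, visit age, scanner) the weighted average
    ``sum_r w_r t_r / sum_r w_r`` is taken over the regions present in that
    scan. Scanner is part of the scan key so that same-day duplicate scans on
    a second scanner remain separate observations.
    """
    if atlas.area_weight is None:
        raise ConfigurationError("weighted_mean_thickness requires an atlas with area weights")
    df = cohort.data.copy()
    df["_w"] = df["region"].map(atlas.area_weight).astype(float)
    df["_wt"] = df["_w"] * df["thickness_mm"]
    g = df.groupby(["subject_id", "visit_age", "scanner_id"], sort=True)
    out = (g["_wt"].sum() / g["_w"].sum()).rename("mean_thickness_mm").reset_index()
    return out
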