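"""Synthetic cohorts, expression tables and clinical data with known ground truth.

The generators emulate the statistical structure the analysis assumes:

* a lifespan thickness curve with a steep childhood decline, mild monotonic
  adult thinning and late-life acceleration,
  ``T(age) = a - b*ln(1 + age/tau) - c*max(0, age-60)**2``;
* inter-regional coupling acting on the *derivative*: each region's thinning
  rate is offset by ``g(age) * z_r`` where ``z_r`` is the standardized
  regional mean expression of one chosen cell-type panel and ``g`` is a
  difference of Gaussian bumps centred in development (8 +/- 4 y) and in
  aging (70 +/- 6 y). Because the coupling is affine in ``z_r`` the true
  expression-thinning correlation is exactly +/-1 at the bump centres, which
  makes recovery checkable;
* donor/sample/probe structure of a six-donor microarray atlas, with each
  panel's member genes sharing a latent regional profile;
* an elderly clinical cohort where MCI and AD shift thickness down by a
  regionally-varying amount affine in the same ``z_r``.

All generators are pure functions of (spec, seed): identical inputs give
byte-identical outputs. Thickness integrates the coupled derivative in
closed form (Gaussian integrals via ``erf``), so ground truth is exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .atlas_io import ClinicalCohort, LongitudinalCohort, RegionAtlas
from .trajectories import ThinningProfileSet


class GeneratorInputError(ValueError):
    """Inputs to a generator are inconsistent (e.g. panel absent from matrix)."""


@dataclasses.dataclass
class GeneratorSpec:
    """All knobs of the synthetic world. Defaults are the study conditions.

    Sampling is bimodal in age (dense in childhood/adolescence and in the
    7th-8th decades, thin in mid-adulthood), subjects carry 1-6 visits with a
    follow-up window of up to 11 years, four scanners with fixed additive
    offsets are used and a fraction of subjects receives a same-day duplicate
    scan on a second scanner.
    """

    n_subjects: int = 800
    visit_probs: tuple[float, ...] = (0.35, 0.35, 0.15, 0.08, 0.05, 0.02)
    followup_max: float = 11.0
    # lifespan curve T(age) = a - b*ln(1+age/tau) - c*max(0, age-60)^2
    curve_a: float = 3.7
    curve_b: float = 0.35
    curve_tau: float = 5.0
    curve_c: float = 0.0002
    anchor_age: float = 5.0
    # derivative coupling g(age) = g0 * (bump(dev) - bump(aging))
    g0: float = 0.01
    dev_center: float = 8.0
    dev_width: float = 4.0
    aging_center: float = 70.0
    aging_width: float = 6.0
    # observation model
    subject_sd: float = 0.10
    noise_sd: float = 0.05
    scanner_offsets: tuple[float, ...] = (0.0, 0.03, -0.02, 0.05)
    dual_scan_frac: float = 0.15
    sex_offset: float = 0.02
    region_offset_sd: float = 0.10
    # expression model
    n_background_genes: int = 1500
    panel_latent_sd: float = 1.0
    within_panel_sd: float = 12.0
    donor_sd: float = 0.3
    probe_sd: float = 0.2
    extra_samples_mean: float = 0.7
    # clinical model: delta_dx(r) = base + coupled * z_r (mm, subtracted)
    mci_base: float = 0.05
    mci_coupled: float = 0.02
    ad_base: float = 0.12
    ad_coupled: float = 0.05
    n_per_group: int = 200
    site_offsets: tuple[float, ...] = (0.0, 0.02)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "noise_sd", "region_offset_sd", "within_panel_sd",
                     "panel_latent_sd", "donor_sd", "probe_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= len(self.visit_probs) <= 6:
            raise ValueError("visit_probs must cover 1..6 visits")
        if abs(sum(self.visit_probs) - 1.0) > 1e-9:
            raise ValueError("visit_probs must sum to 1")


# ---------------------------------------------------------------------------
# Closed-form lifespan curve and coupling
# ---------------------------------------------------------------------------

def lifespan_thickness(age, spec: GeneratorSpec):
    """Base thickness curve T(age) in mm."""
    age = np.asarray(age, dtype=float)
    late = np.maximum(0.0, age - 60.0)
    return spec.curve_a - spec.curve_b * np.log1p(age / spec.curve_tau) - spec.curve_c * late**2


def lifespan_derivative(age, spec: GeneratorSpec):
    """dT/dage in mm/yr for the base curve."""
    age = np.asarray(age, dtype=float)
    late = np.maximum(0.0, age - 60.0)
    return -spec.curve_b / (spec.curve_tau + age) - 2.0 * spec.curve_c * late


def coupling_g(age, spec: GeneratorSpec):
    """Age-varying coupling amplitude g(age) in mm/yr per expression SD."""
    age = np.asarray(age, dtype=float)
    dev = np.exp(-((age - spec.dev_center) ** 2) / (2.0 * spec.dev_width**2))
    aging = np.exp(-((age - spec.aging_center) ** 2) / (2.0 * spec.aging_width**2))
    return spec.g0 * (dev - aging)


def _gauss_integral(a, c, s):
    # int_{-inf}^{a} exp(-(x-c)^2/(2 s^2)) dx
    return s * np.sqrt(np.pi / 2.0) * (1.0 + erf((np.asarray(a, float) - c) / (s * np.sqrt(2.0))))


def coupling_G(age, spec: GeneratorSpec):
    """Exact integral of g from the anchor age to ``age`` (mm per SD)."""
    def F(x):
        return (_gauss_integral(x, spec.dev_center, spec.dev_width)
                - _gauss_integral(x, spec.aging_center, spec.aging_width))
    return spec.g0 * (F(age) - F(spec.anchor_age))


def panel_zscores(expr_median: pd.DataFrame, panel_genes: Sequence[str]) -> pd.Series:
    """Standardized panel-mean regional expression profile z_r.

    ``expr_median`` is genes x regions; the result has mean 0 and SD 1
    (population convention) across regions.
    """
    genes = [g for g in panel_genes if g in expr_median.index]
    if not genes:
        raise GeneratorInputError("coupled panel has no genes in the expression matrix")
    prof = expr_median.loc[genes].mean(axis=0)
    sd = prof.std(ddof=0)
    if sd == 0:
        raise GeneratorInputError("panel mean profile has zero variance across regions")
    return (prof - prof.mean()) / sd


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CohortTruth:
    """Exact generative quantities for a simulated cohort."""

    spec: GeneratorSpec
    z: pd.Series              # region -> coupled-panel z-score
    region_offset: pd.Series  # region -> baseline offset delta_r (mm)

    def true_derivative(self, ages) -> pd.DataFrame:
        """Ages x regions matrix of the true thickness derivative (mm/yr)."""
        ages = np.asarray(ages, dtype=float)
        base = lifespan_derivative(ages, self.spec)[:, None]
        g = coupling_g(ages, self.spec)[:, None]
        out = base + g * self.z.to_numpy()[None, :]
        return pd.DataFrame(out, index=ages, columns=self.z.index)

    def true_thickness(self, ages) -> pd.DataFrame:
        ages = np.asarray(ages, dtype=float)
        base = lifespan_thickness(ages, self.spec)[:, None]
        G = coupling_G(ages, self.spec)[:, None]
        out = base + G * self.z.to_numpy()[None, :] + self.region_offset.to_numpy()[None, :]
        return pd.DataFrame(out, index=ages, columns=self.z.index)

    def to_json(self, path: str | Path, ages=None) -> None:
        """Sidecar JSON with z_r, g(age) and true derivatives on a grid."""
        ages = np.arange(5.0, 90.0, 2.0) if ages is None else np.asarray(ages, float)
        doc = {
            "z": {r: float(v) for r, v in self.z.items()},
            "region_offset": {r: float(v) for r, v in self.region_offset.items()},
            "ages": ages.tolist(),
            "g": coupling_g(ages, self.spec).tolist(),
            "true_derivative": {
                r: col.tolist() for r, col in self.true_derivative(ages).items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionTruth:
    """Latent (noise-free) regional profiles underlying a sample table."""

    latent: pd.DataFrame            # genes x regions
    panel_latent: pd.DataFrame      # panels x regions


def latent_gene_profiles(spec: GeneratorSpec, atlas: RegionAtlas,
                         panels: Mapping[str, Sequence[str]],
                         rng: np.random.Generator) -> ExpressionTruth:
    """Draw latent regional profiles for panel members and background genes.

    Each panel has a shared latent profile of amplitude ``panel_latent_sd``;
    a member gene adds independent N(0, within_panel_sd^2) per region.
    Background genes (named BG#####) are independent N(0, 1) profiles.
    """
    R = atlas.n_regions
    rows, names = [], []
    panel_rows = {}
    for pname, genes in panels.items():
        p = spec.panel_latent_sd * rng.normal(size=R)
        panel_rows[pname] = p
        member = p[None, :] + spec.within_panel_sd * rng.normal(size=(len(genes), R))
        rows.append(member)
        names.extend(genes)
    if spec.n_background_genes:
        bg = rng.normal(size=(spec.n_background_genes, R))
        rows.append(bg)
        names.extend(f"BG{i:05d}" for i in range(1, spec.n_background_genes + 1))
    if len(set(names)) != len(names):
        raise GeneratorInputError("duplicate gene symbols across panels/background")
    latent = pd.DataFrame(np.vstack(rows), index=names, columns=list(atlas.regions))
    plat = pd.DataFrame(panel_rows, index=list(atlas.regions)).T
    return ExpressionTruth(latent=latent, panel_latent=plat)


def generate_expression(spec: GeneratorSpec, atlas: RegionAtlas,
                        panels: Mapping[str, Sequence[str]], n_donors: int = 6,
                        rng_seed: int | None = None,
                        truth: ExpressionTruth | None = None,
                        ) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Simulate a donor/sample/probe expression table.

    Returns a long-format sample table (donor_id, sample_id, region, probe_id,
    gene_symbol, expression) plus the latent truth. Pass a previously drawn
    ``truth`` to simulate a second dataset measuring the same genes (the
    cross-dataset consistency scenario).
    """
    if n_donors < 2:
        raise GeneratorInputError("n_donors must be >= 2")
    rng = np.random.default_rng(spec.rng_seed if rng_seed is None else rng_seed)
    if truth is None:
        truth = latent_gene_profiles(spec, atlas, panels, rng)
    latent = truth.latent
    G, R = latent.shape

    # samples per (donor, region), >= 1 each
    n_samp = 1 + rng.poisson(spec.extra_samples_mean, size=(n_donors, R))
    donor_of = np.repeat(np.arange(n_donors), n_samp.sum(axis=1))
    region_of = np.concatenate([np.repeat(np.arange(R), n_samp[d]) for d in range(n_donors)])
    S = donor_of.size
    sample_ids = np.arange(S)

    # per-sample gene values: latent + N(0, donor_sd^2)
    vals = latent.to_numpy()[:, region_of] + spec.donor_sd * rng.normal(size=(G, S))

    # probes: 1-4 per gene, probe value = sample value + N(0, probe_sd^2)
    n_probes = rng.integers(1, 5, size=G)
    gene_rep = np.repeat(np.arange(G), n_probes)          # (P,)
    probe_within = np.concatenate([np.arange(k) for k in n_probes])
    pvals = vals[gene_rep] + spec.probe_sd * rng.normal(size=(gene_rep.size, S))

    P = gene_rep.size
    genes_idx = np.tile(gene_rep, S)
    probe_idx = np.tile(probe_within, S)
    sample_idx = np.repeat(sample_ids, P)

    gene_names = latent.index.to_numpy()
    probe_names = pd.Categorical.from_codes(
        codes=genes_idx * 4 + probe_idx,
        categories=[f"{g}_p{j + 1}" for g in gene_names for j in range(4)],
    )
    df = pd.DataFrame({
        "donor_id": pd.Categorical.from_codes(donor_of[sample_idx],
                                              [f"donor{d + 1}" for d in range(n_donors)]),
        "sample_id": sample_idx,
        "region": pd.Categorical.from_codes(region_of[sample_idx], list(atlas.regions)),
        "probe_id": probe_names,
        "gene_symbol": pd.Categorical.from_codes(genes_idx, list(gene_names)),
        "expression": pvals.T.reshape(-1),
    })
    df["sample_id"] = "s" + df["sample_id"].astype(str)
    return df, truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def _draw_visit_ages(rng: np.random.Generator, spec: GeneratorSpec, n: int,
                     elderly_only: bool = False) -> list[np.ndarray]:
    """Baseline ages (bimodal over the lifespan, or uniform 55-90 for the
    clinical cohort) plus follow-up visits within the follow-up window."""
    if elderly_only:
        base = rng.uniform(55.0, 88.0, size=n)
    else:
        comp = rng.choice(3, size=n, p=[0.45, 0.15, 0.40])
        base = np.where(comp == 0, rng.uniform(4.0, 20.0, size=n),
                        np.where(comp == 1, rng.uniform(20.0, 55.0, size=n),
                                 rng.uniform(55.0, 88.0, size=n)))
    k = len(spec.visit_probs)
    n_visits = 1 + rng.choice(k, size=n, p=np.asarray(spec.visit_probs))
    out = []
    for i in range(n):
        gaps = rng.uniform(0.8, 3.5, size=n_visits[i] - 1)
        offs = np.concatenate([[0.0], np.cumsum(gaps)])
        offs = offs[offs <= spec.followup_max]
        ages = np.clip(base[i] + offs, 4.0, 90.0)
        out.append(np.unique(ages))
    return out


def _observe(rng, spec, ages, z, delta, u_i, sex_is_f, scan_off, extra=0.0):
    """Noisy thickness observations for one subject-scan across all regions."""
    base = lifespan_thickness(ages, spec)[:, None]
    G = coupling_G(ages, spec)[:, None]
    mean = base + G * z[None, :] + delta[None, :] + u_i \
        + spec.sex_offset * sex_is_f + scan_off + extra
    return mean + spec.noise_sd * rng.normal(size=mean.shape)


def generate_cohort(spec: GeneratorSpec, atlas: RegionAtlas,
                    expr_median: pd.DataFrame, coupled_panel: Sequence[str],
                    rng_seed: int | None = None,
                    ) -> tuple[LongitudinalCohort, CohortTruth]:
    """Simulate a lifespan cohort whose regional thinning rates are coupled to
    the given panel's expression profile. Returns the cohort and exact truth."""
    missing = [r for r in atlas.regions if r not in expr_median.columns]
    if missing:
        raise GeneratorInputError(f"expression matrix missing regions: {missing}")
    rng = np.random.default_rng(spec.rng_seed if rng_seed is None else rng_seed)
    z = panel_zscores(expr_median, coupled_panel).reindex(list(atlas.regions))
    delta = pd.Series(spec.region_offset_sd * rng.normal(size=atlas.n_regions),
                      index=list(atlas.regions))
    truth = CohortTruth(spec=spec, z=z, region_offset=delta)

    zv, dv = z.to_numpy(), delta.to_numpy()
    visit_ages = _draw_visit_ages(rng, spec, spec.n_subjects)
    sex = rng.random(spec.n_subjects) < 0.5
    scanner = rng.integers(0, len(spec.scanner_offsets), size=spec.n_subjects)
    u = spec.subject_sd * rng.normal(size=spec.n_subjects)
    dual = rng.random(spec.n_subjects) < spec.dual_scan_frac

    frames = []
    regions = list(atlas.regions)
    for i in range(spec.n_subjects):
        ages = visit_ages[i]
        off = spec.scanner_offsets[scanner[i]]
        t = _observe(rng, spec, ages, zv, dv, u[i], sex[i], off)
        frames.append(_cohort_rows(f"sub{i + 1:05d}", ages, sex[i],
                                   f"scanner{scanner[i] + 1}", regions, t))
        if dual[i]:
            alt = (scanner[i] + 1) % len(spec.scanner_offsets)
            t2 = _observe(rng, spec, ages[:1], zv, dv, u[i], sex[i],
                          spec.scanner_offsets[alt])
            frames.append(_cohort_rows(f"sub{i + 1:05d}", ages[:1], sex[i],
                                       f"scanner{alt + 1}", regions, t2))
    df = pd.concat(frames, ignore_index=True)
    return LongitudinalCohort(df), truth


def _cohort_rows(sid, ages, sex_is_f, scanner, regions, thickness):
    A, R = thickness.shape
    return pd.DataFrame({
        "subject_id": sid,
        "visit_age": np.repeat(np.asarray(ages, float), R),
        "sex": "F" if sex_is_f else "M",
        "scanner_id": scanner,
        "region": np.tile(np.asarray(regions, object), A),
        "thickness_mm": thickness.reshape(-1),
    })


# ---------------------------------------------------------------------------
# Clinical cohort generator
# ---------------------------------------------------------------------------

def generate_clinical(spec: GeneratorSpec, atlas: RegionAtlas,
                      expr_median: pd.DataFrame, coupled_panel: Sequence[str],
                      rng_seed: int | None = None,
                      ) -> tuple[ClinicalCohort, CohortTruth]:
    """Simulate an elderly HC/MCI/AD cohort.

    MCI and AD scans are the healthy-model value minus a regional deficit
    ``delta_dx(r) = base + coupled * z_r`` (mm), so the true AD-vs-HC contrast
    profile is exactly ``-(ad_base + ad_coupled * z_r)``.
    """
    missing = [r for r in atlas.regions if r not in expr_median.columns]
    if missing:
        raise GeneratorInputError(f"expression matrix missing regions: {missing}")
    rng = np.random.default_rng(spec.rng_seed if rng_seed is None else rng_seed)
    z = panel_zscores(expr_median, coupled_panel).reindex(list(atlas.regions))
    delta = pd.Series(spec.region_offset_sd * rng.normal(size=atlas.n_regions),
                      index=list(atlas.regions))
    truth = CohortTruth(spec=spec, z=z, region_offset=delta)
    zv, dv = z.to_numpy(), delta.to_numpy()

    deficits = {"HC": np.zeros_like(zv),
                "MCI": spec.mci_base + spec.mci_coupled * zv,
                "AD": spec.ad_base + spec.ad_coupled * zv}
    frames = []
    regions = list(atlas.regions)
    sid = 0
    for dx in ("HC", "MCI", "AD"):
        visit_ages = _draw_visit_ages(rng, spec, spec.n_per_group, elderly_only=True)
        sex = rng.random(spec.n_per_group) < 0.5
        site = rng.integers(0, len(spec.site_offsets), size=spec.n_per_group)
        u = spec.subject_sd * rng.normal(size=spec.n_per_group)
        for i in range(spec.n_per_group):
            sid += 1
            ages = visit_ages[i]
            t = _observe(rng, spec, ages, zv, dv, u[i], sex[i],
                         spec.site_offsets[site[i]], extra=-deficits[dx][None, :])
            rows = _cohort_rows(f"c{sid:05d}", ages, sex[i],
                                f"scanner{site[i] + 1}", regions, t)
            rows["diagnosis"] = dx
            rows["site"] = f"site{site[i] + 1}"
            frames.append(rows)
    df = pd.concat(frames, ignore_index=True)
    return ClinicalCohort(df), truth


def true_contrast_profiles(spec: GeneratorSpec, z: pd.Series) -> dict[str, pd.Series]:
    """Exact diagnosis-contrast profiles implied by the clinical generator."""
    zv = z
    return {
        "AD_vs_HC": -(spec.ad_base + spec.ad_coupled * zv),
        "MCI_vs_HC": -(spec.mci_base + spec.mci_coupled * zv),
        "AD_vs_MCI": -((spec.ad_base - spec.mci_base) + (spec.ad_coupled - spec.mci_coupled) * zv),
    }


# ---------------------------------------------------------------------------
# Null thinning profiles (no expression coupling)
# ---------------------------------------------------------------------------

def null_thinning_profiles(spec: GeneratorSpec, atlas: RegionAtlas, ages,
                           rng: np.random.Generator, wiggle_sd: float = 0.002,
                           ) -> ThinningProfileSet:
    """Thinning profiles with no expression coupling, for calibration studies.

    With g0 = 0 the *true* derivative is identical in every region, so the
    inter-regional Pearson statistic is undefined on exact truth; what the
    analysis would see is the base curve plus estimation error. This helper
    emulates that error with smooth, region-independent random perturbations
    (Gaussian bumps across the age axis with coefficient SD ``wiggle_sd``
    mm/yr), giving profiles that vary across regions but are independent of
    any expression profile by construction.
    """
    ages = np.asarray(ages, dtype=float)
    centers = np.linspace(10.0, 85.0, 5)
    basis = np.exp(-((ages[:, None] - centers[None, :]) ** 2) / (2.0 * 18.0**2))
    eps = wiggle_sd * rng.normal(size=(centers.size, atlas.n_regions))
    deriv = lifespan_derivative(ages, spec)[:, None] + basis @ eps
    return ThinningProfileSet(
        ages=ages,
        regions=tuple(atlas.regions),
        derivative=pd.DataFrame(deriv, index=ages, columns=list(atlas.regions)),
        ci_halfwidth=pd.DataFrame(0.0, index=ages, columns=list(atlas.regions)),
        excluded_count={r: 0 for r in atlas.regions},
    )
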