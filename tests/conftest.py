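"""Shared fixtures: one small synthetic world reused across the unit tests.

Everything here is deliberately smaller than the defaults (fewer background
genes, fewer subjects) so the unit tests stay fast; the acceptance tests
build their own full-size worlds.
"""

import numpy as np
import pytest

import vhlifespan as vh


@pytest.fixture(scope="session")
def atlas():
    return vh.RegionAtlas.default()


@pytest.fixture(scope="session")
def panel_fixture():
    """(mouse panels, homolog table, mapped human panels)."""
    mouse, hom = vh.default_panel_fixture()
    human = vh.map_panels_to_human(mouse, hom)
    return mouse, hom, human


@pytest.fixture(scope="session")
def small_cfg():
    return vh.VHConfig(rng_seed=5, n_permutations=200)


@pytest.fixture(scope="session")
def expr_world(atlas, panel_fixture, small_cfg):
    """Small expression dataset -> aggregated matrix, consistent pool, panels."""
    mouse, hom, human = panel_fixture
    spec = vh.GeneratorSpec(rng_seed=11, n_background_genes=300)
    table, truth = vh.generate_expression(spec, atlas, human, n_donors=6, rng_seed=11)
    mat = vh.summarize_regions(vh.aggregate_probes(table), atlas)
    pool = vh.consistency_filter(mat, None, small_cfg)
    panels = vh.build_panels(mouse, hom, pool)
    return {"spec": spec, "table": table, "truth": truth, "mat": mat,
            "pool": pool, "panels": panels}


@pytest.fixture(scope="session")
def coupled_panel(expr_world):
    return next(p for p in expr_world["panels"] if p.name == "astrocytes")


@pytest.fixture(scope="session")
def small_cohort(atlas, expr_world, coupled_panel):
    """150-subject lifespan cohort coupled to the astrocyte panel."""
    spec = vh.GeneratorSpec(rng_seed=21, n_subjects=150)
    cohort, truth = vh.generate_cohort(spec, atlas, expr_world["pool"].median,
                                       coupled_panel.genes, rng_seed=21)
    return cohort, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort, atlas, small_cfg):
    """One fitted region of the small cohort."""
    cohort, _ = small_cohort
    region = atlas.regions[0]
    return region, vh.fit_region(cohort, region, small_cfg)


@pytest.fixture(scope="session")
def small_clinical(atlas, expr_world, coupled_panel):
    """Small HC/MCI/AD cohort (30 subjects per group)."""
    spec = vh.GeneratorSpec(rng_seed=31, n_per_group=30)
    cohort, truth = vh.generate_clinical(spec, atlas, expr_world["pool"].median,
                                         coupled_panel.genes, rng_seed=31)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
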