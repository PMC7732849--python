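"""Probe aggregation, regional summarization, consistency filter, panels."""

import numpy as np
import pandas as pd
import pytest

import vhlifespan as vh
from vhlifespan.atlas_io import SchemaError
from vhlifespan.expression import (ExpressionInputError, CellTypePanel,
                                   load_homolog_table, load_panel_file,
                                   mean_interdonor_correlation)


def _sample_rows(donor, sample, region, gene, values):
    return [{"donor_id": donor, "sample_id": sample, "region": region,
             "probe_id": f"{gene}_p{i+1}", "gene_symbol": gene,
             "expression": v} for i, v in enumerate(values)]


class TestAggregateProbes:
    def test_probe_mean(self):
        df = pd.DataFrame(_sample_rows("d1", "s1", "lh.bankssts", "G1",
                                       [1.0, 3.0]))
        out = vh.aggregate_probes(df)
        assert len(out) == 1
        assert out["expression"].iloc[0] == 2.0

    def test_missing_column_rejected(self):
        with pytest.raises(SchemaError):
            vh.aggregate_probes(pd.DataFrame({"gene_symbol": ["G1"]}))


class TestSummarizeRegions:
    def test_median_of_donor_medians_midpoint(self, atlas):
        r = atlas.regions[0]
        rows = []
        # donor 1: two samples 1.0 and 3.0 -> median 2.0; donor 2: 6.0
        rows += _sample_rows("d1", "s1", r, "G1", [1.0])
        rows += _sample_rows("d1", "s2", r, "G1", [3.0])
        rows += _sample_rows("d2", "s3", r, "G1", [6.0])
        # fill remaining regions so the gene survives
        for other in atlas.regions[1:]:
            rows += _sample_rows("d1", f"sa_{other}", other, "G1", [0.0])
            rows += _sample_rows("d2", f"sb_{other}", other, "G1", [0.0])
        out = vh.summarize_regions(vh.aggregate_probes(pd.DataFrame(rows)), atlas)
        assert out.median.loc["G1", r] == (2.0 + 6.0) / 2.0

    def test_gene_missing_a_region_everywhere_dropped(self, atlas):
        rows = []
        for d in ("d1", "d2"):
            for other in atlas.regions[1:]:  # region 0 never sampled
                rows += _sample_rows(d, f"{d}_{other}", other, "G1", [1.0])
        out = vh.summarize_regions(vh.aggregate_probes(pd.DataFrame(rows)), atlas)
        assert "G1" not in out.median.index


class TestConsistencyFilter:
    def _matrix(self, atlas, donor_profiles):
        per_donor = {
            d: pd.DataFrame(p, index=[f"G{i}" for i in range(p.shape[0])],
                            columns=list(atlas.regions))
            for d, p in donor_profiles.items()}
        median = pd.concat(per_donor.values()).groupby(level=0).median()
        return vh.RegionalExpressionMatrix(median=median, per_donor=per_donor)

    def test_reproducible_gene_kept_noise_gene_dropped(self, atlas, small_cfg, rng):
        R = atlas.n_regions
        shared = rng.normal(size=R)
        profiles = {}
        for d in ("d1", "d2", "d3"):
            consistent = shared + 0.05 * rng.normal(size=R)
            noise = rng.normal(size=R)
            profiles[d] = np.vstack([consistent, noise])
        mat = self._matrix(atlas, profiles)
        kept = vh.consistency_filter(mat, None, small_cfg)
        assert "G0" in kept.genes and "G1" not in kept.genes

    def test_needs_two_donors(self, atlas, small_cfg, rng):
        mat = self._matrix(atlas, {"d1": rng.normal(size=(2, atlas.n_regions))})
        with pytest.raises(ExpressionInputError):
            vh.consistency_filter(mat, None, small_cfg)

    def test_cross_dataset_filter(self, atlas, small_cfg, rng):
        R = atlas.n_regions
        shared = rng.normal(size=R)
        profiles = {d: np.vstack([shared + 0.05 * rng.normal(size=R),
                                  shared + 0.05 * rng.normal(size=R)])
                    for d in ("d1", "d2")}
        mat = self._matrix(atlas, profiles)
        # second dataset replicates G0 but scrambles G1
        second = self._matrix(atlas, {
            d: np.vstack([shared + 0.05 * rng.normal(size=R),
                          rng.normal(size=R)]) for d in ("d1", "d2")})
        kept = vh.consistency_filter(mat, second, small_cfg)
        assert "G0" in kept.genes and "G1" not in kept.genes

    def test_mean_interdonor_correlation_matches_manual(self, atlas, rng):
        R = atlas.n_regions
        profiles = {d: rng.normal(size=(1, R)) for d in ("d1", "d2", "d3")}
        mat = self._matrix(atlas, profiles)
        got = mean_interdonor_correlation(mat)["G0"]
        rs = []
        donors = list(profiles)
        for i in range(3):
            for j in range(i + 1, 3):
                rs.append(np.corrcoef(profiles[donors[i]][0],
                                      profiles[donors[j]][0])[0, 1])
        assert abs(got - np.mean(rs)) < 1e-12


class TestPanels:
    def test_fixture_panel_sizes(self, expr_world):
        sizes = {p.name: len(p.genes) for p in expr_world["panels"]}
        assert len(sizes) == 9
        assert all(n > 0 for n in sizes.values())

    def test_build_panels_deduplicates_and_intersects(self, atlas, rng):
        homologs = pd.DataFrame({"mouse_symbol": ["Ma", "Mb", "Mb"],
                                 "human_symbol": ["HA", "HB", "HA"]})
        median = pd.DataFrame(rng.normal(size=(2, atlas.n_regions)),
                              index=["HA", "HB"], columns=list(atlas.regions))
        pool = vh.RegionalExpressionMatrix(median=median, per_donor={})
        panels = vh.build_panels({"p": ["Ma", "Mb"]}, homologs, pool)
        assert panels[0].genes == ("HA", "HB")  # HA mapped twice, kept once

    def test_fully_unmapped_panel_raises(self, atlas, rng):
        homologs = pd.DataFrame({"mouse_symbol": ["Ma"], "human_symbol": ["HA"]})
        median = pd.DataFrame(rng.normal(size=(1, atlas.n_regions)),
                              index=["HA"], columns=list(atlas.regions))
        pool = vh.RegionalExpressionMatrix(median=median, per_donor={})
        with pytest.raises(ExpressionInputError):
            vh.build_panels({"p": ["Mzz"]}, homologs, pool)

    def test_emptied_panel_excluded(self, atlas, rng):
        homologs = pd.DataFrame({"mouse_symbol": ["Ma", "Mb"],
                                 "human_symbol": ["HA", "HB"]})
        median = pd.DataFrame(rng.normal(size=(1, atlas.n_regions)),
                              index=["HA"], columns=list(atlas.regions))
        pool = vh.RegionalExpressionMatrix(median=median, per_donor={})
        panels = vh.build_panels({"kept": ["Ma"], "emptied": ["Mb"]},
                                 homologs, pool)
        assert [p.name for p in panels] == ["kept"]

    def test_duplicate_genes_in_panel_rejected(self):
        with pytest.raises(ExpressionInputError):
            CellTypePanel("p", ("A", "A"))

    def test_panel_and_homolog_file_schemas(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("x\ty\n1\t2\n")
        with pytest.raises(SchemaError):
            load_panel_file(bad)
        with pytest.raises(SchemaError):
            load_homolog_table(bad)

    def test_panels_are_subset_of_pool(self, expr_world):
        pool = set(expr_world["pool"].genes)
        for p in expr_world["panels"]:
            assert set(p.genes) <= pool
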