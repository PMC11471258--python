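"""Unit tests for table I/O, validation and the structure roll-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import atlasxref as ax
from atlasxref.atlas_model import conservation_check


def write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadTaxonomy:
    def test_reads_valid_table(self, tmp_path):
        p = write_tsv(
            tmp_path / "t.tsv",
            "cluster_id\tcluster_label\tnt_class\n"
            "K1\ta\tglutamatergic\nK2\tb\tGABAergic\nK3\tc\tdopaminergic\n",
        )
        tax = ax.read_taxonomy(p)
        assert len(tax) == 3
        assert list(tax["nt_class"]) == ["glutamatergic", "GABAergic", "dopaminergic"]

    def test_unknown_class_maps_to_unassigned_with_warning(self, tmp_path, caplog):
        p = write_tsv(
            tmp_path / "t.tsv",
            "cluster_id\tcluster_label\tnt_class\nK1\ta\tGlut-unknown\n",
        )
        with caplog.at_level("WARNING", logger="atlasxref"):
            tax = ax.read_taxonomy(p)
        assert tax.loc[0, "nt_class"] == "unassigned"
        assert any("unassigned" in r.message for r in caplog.records)

    def test_duplicate_cluster_id_is_error(self, tmp_path):
        p = write_tsv(
            tmp_path / "t.tsv",
            "cluster_id\tcluster_label\tnt_class\nK1\ta\tGABAergic\nK1\tb\tGABAergic\n",
        )
        with pytest.raises(ax.ValidationError, match="duplicate"):
            ax.read_taxonomy(p)

    def test_missing_column_names_the_column(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "cluster_id\tcluster_label\nK1\ta\n")
        with pytest.raises(ax.SchemaError, match="nt_class"):
            ax.read_taxonomy(p)


class TestReadScCells:
    def taxonomy(self):
        return pd.DataFrame(
            {
                "cluster_id": ["K1", "K2"],
                "cluster_label": ["a", "b"],
                "nt_class": ["glutamatergic", "GABAergic"],
            }
        )

    def test_region_filter(self, tmp_path, config):
        body = "".join(
            f"c{i}\t{r}\tK1\t{i}\n"
            for i, r in enumerate(["OLF", "OLF", "CTX", "OLF", "CTX", "OLF"])
        )
        p = write_tsv(tmp_path / "sc.tsv", "cell_id\tregion\tcluster_id\tmarker_count\n" + body)
        sc = ax.read_sc_cells(p, self.taxonomy(), config)
        assert len(sc) == 4
        assert sc.attrs["n_input"] == 6
        conservation_check(len(sc), [6 - len(sc)], sc.attrs["n_input"])

    def test_negative_count_is_error(self, tmp_path, config):
        p = write_tsv(
            tmp_path / "sc.tsv",
            "cell_id\tregion\tcluster_id\tmarker_count\nc1\tOLF\tK1\t-1\n",
        )
        with pytest.raises(ax.ValidationError, match="non-negative"):
            ax.read_sc_cells(p, self.taxonomy(), config)

    def test_non_integral_count_is_error(self, tmp_path, config):
        p = write_tsv(
            tmp_path / "sc.tsv",
            "cell_id\tregion\tcluster_id\tmarker_count\nc1\tOLF\tK1\t1.5\n",
        )
        with pytest.raises(ax.ValidationError, match="integral"):
            ax.read_sc_cells(p, self.taxonomy(), config)

    def test_empty_region_is_empty_result_error(self, tmp_path, config):
        p = write_tsv(
            tmp_path / "sc.tsv",
            "cell_id\tregion\tcluster_id\tmarker_count\nc1\tCTX\tK1\t1\n",
        )
        with pytest.raises(ax.EmptyResultError, match="no cells in region"):
            ax.read_sc_cells(p, self.taxonomy(), config)

    def test_unknown_cluster_strict_vs_lenient(self, tmp_path, caplog):
        p = write_tsv(
            tmp_path / "sc.tsv",
            "cell_id\tregion\tcluster_id\tmarker_count\nc1\tOLF\tK9\t1\n",
        )
        with pytest.raises(ax.ValidationError, match="K9"):
            ax.read_sc_cells(p, self.taxonomy(), ax.AnalysisConfig(strict=True))
        with caplog.at_level("WARNING", logger="atlasxref"):
            sc = ax.read_sc_cells(p, self.taxonomy(), ax.AnalysisConfig(strict=False))
        assert len(sc) == 1  # row kept; class resolves to unassigned at join


class TestStructureMap:
    def test_explicit_mapping_and_prefix(self):
        smap = ax.StructureMap(("MOB", "AOB"), {"MOB-gl": "MOB"})
        assert smap.apply("MOB-gl") == "MOB"
        assert smap.apply("AOBgr") == "AOB"  # prefix rule
        assert smap.apply("CTX") is None

    def test_mapping_onto_non_target_rejected(self):
        with pytest.raises(ax.ValidationError):
            ax.StructureMap(("MOB",), {"X": "CTX"})

    @given(st_.sampled_from(["MOB", "MOB-gl", "AOB", "AOBgr", "AONd", "CTX", "HIP"]))
    @settings(deadline=None, max_examples=30)
    def test_rollup_idempotent(self, raw):
        smap = ax.StructureMap.from_prefix(("MOB", "AOB", "AON"))
        once = smap.apply(raw)
        if once is not None:
            assert smap.apply(once) == once


class TestReadSpatialCells:
    HEADER = "cell_id\tsection_id\tcluster_id\tstructure\n"

    def test_rollup_and_exclusion_counts(self, tmp_path, config):
        p = write_tsv(
            tmp_path / "st.tsv",
            self.HEADER + "s1\t60\tK1\tMOB-gl\ns2\t60\tK1\tCTX\ns3\t62\tK1\tAOB\n",
        )
        smap = ax.StructureMap(("MOB", "AOB", "AON"), {"MOB-gl": "MOB"})
        st = ax.read_spatial_cells(p, smap, config)
        assert list(st["structure"]) == ["MOB", "AOB"]
        assert st.attrs["n_excluded_structure"] == 1
        conservation_check(
            len(st),
            [st.attrs["n_excluded_structure"], st.attrs["n_excluded_section"]],
            st.attrs["n_input"],
        )

    def test_section_filter(self, tmp_path):
        cfg = ax.AnalysisConfig(sections=("60", "62"))
        p = write_tsv(
            tmp_path / "st.tsv",
            self.HEADER + "s1\t60\tK1\tMOB\ns2\t64\tK1\tMOB\ns3\t62\tK1\tAOB\n",
        )
        st = ax.read_spatial_cells(p, ax.StructureMap.from_prefix(cfg.structures), cfg)
        assert len(st) == 2
        assert st.attrs["n_excluded_section"] == 1

    def test_all_rows_excluded_is_error(self, tmp_path, config):
        p = write_tsv(tmp_path / "st.tsv", self.HEADER + "s1\t60\tK1\tCTX\n")
        with pytest.raises(ax.EmptyResultError, match="no spatial cells"):
            ax.read_spatial_cells(
                p, ax.StructureMap.from_prefix(config.structures), config
            )


class TestWriteTable:
    def test_taxonomy_roundtrip(self, toy, tmp_path):
        _, _, tax = toy
        path = tmp_path / "tax.tsv"
        ax.write_table(tax, path)
        back = ax.read_taxonomy(path)
        pd.testing.assert_frame_equal(back, tax)

    def test_sc_roundtrip(self, toy, tmp_path, config):
        sc, _, tax = toy
        path = tmp_path / "sc.tsv"
        ax.write_table(sc, path)
        back = ax.read_sc_cells(path, tax, config)
        pd.testing.assert_frame_equal(back, sc)

    def test_prevalence_schema_and_float_precision(self, toy, tmp_path):
        sc, _, tax = toy
        pos = ax.filter_marker_positive(sc, ax.AnalysisConfig())
        prev = ax.cluster_prevalence(sc, pos, tax)
        path = tmp_path / "prev.tsv"
        ax.write_table(prev, path)
        header = path.read_text().splitlines()[0]
        assert header.split("\t") == [
            "cluster_id", "nt_class", "n_total", "n_pos", "fraction", "ci_low", "ci_high",
        ]
        back = ax.read_prevalence(path)
        np.testing.assert_allclose(back["ci_low"], prev["ci_low"], rtol=1e-11)
        assert list(back["n_pos"]) == list(prev["n_pos"])

    def test_empty_table_writes_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["cluster_id", "cluster_label", "nt_class"])
        path = tmp_path / "empty.tsv"
        ax.write_table(df, path)
        assert path.read_text() == "cluster_id\tcluster_label\tnt_class\n"


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = ax.AnalysisConfig(marker_name="Ghsr", sections=("60", "62"), seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert ax.AnalysisConfig.from_yaml(path) == cfg

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ax.ValidationError):
            ax.AnalysisConfig(positivity_threshold=0)

    def test_empty_structures_rejected(self):
        with pytest.raises(ax.ValidationError):
            ax.AnalysisConfig(structures=())

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("markr_name: Ghsr\n")
        with pytest.raises(ax.SchemaError, match="markr_name"):
            ax.AnalysisConfig.from_yaml(path)


class TestH5adAdapter:
    def make_h5ad(self, tmp_path):
        """Small synthetic stand-in for an atlas-style h5ad file."""
        import anndata as ad

        X = np.array([[0, 2], [3, 0], [1, 1], [0, 0]], dtype=np.float32)
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(
                {
                    "region_of_interest_acronym": ["OLF", "OLF", "CTX", "OLF"],
                    "cluster_alias": ["K1", "K2", "K1", "K2"],
                },
                index=[f"cell{i}" for i in range(4)],
            ),
            var=pd.DataFrame(index=["Gad1", "Ghsr"]),
        )
        path = tmp_path / "synthetic_atlas.h5ad"
        adata.write_h5ad(path)
        return path

    def test_emits_sc_schema(self, tmp_path):
        path = self.make_h5ad(tmp_path)
        sc = ax.sc_cells_from_h5ad(path, "Ghsr")
        assert list(sc.columns) == ["cell_id", "region", "cluster_id", "marker_count"]
        assert list(sc["marker_count"]) == [2, 0, 1, 0]

    def test_missing_marker_is_schema_error(self, tmp_path):
        path = self.make_h5ad(tmp_path)
        with pytest.raises(ax.SchemaError, match="Npy"):
            ax.sc_cells_from_h5ad(path, "Npy")

    def test_spatial_frame_rename(self):
        df = pd.DataFrame(
            {
                "cell_label": ["a"],
                "brain_section_label": ["62"],
                "cluster_alias": ["K1"],
                "parcellation_substructure": ["MOB-gl"],
            }
        )
        out = ax.spatial_cells_from_frame(
            df,
            {
                "cell_id": "cell_label",
                "section_id": "brain_section_label",
                "cluster_id": "cluster_alias",
                "structure": "parcellation_substructure",
            },
        )
        assert list(out.columns) == ["cell_id", "section_id", "cluster_id", "structure"]
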