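"""Perturb-seq preprocessing: assignment, QC, normalization, knockout check."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from dualscreen import (
    assign_guides,
    knockout_efficiency,
    normalize_expression,
    qc_filter,
    read_cell_dataset,
    select_variable_features,
    simulate_perturb_seq,
    write_cell_dataset,
)


def make_dataset(guide_umis: dict[str, dict[str, int]], mito=None, totals=None):
    """Minimal AnnData from a per-cell guide-UMI mapping."""
    cells = list(guide_umis)
    guides = sorted({g for m in guide_umis.values() for g in m})
    gu = pd.DataFrame(0, index=pd.Index(cells, name="cell_id"), columns=guides)
    for c, m in guide_umis.items():
        for g, v in m.items():
            gu.loc[c, g] = v
    n = len(cells)
    X = np.ones((n, 3), dtype=np.int32) * 100
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {
                "total_counts": totals if totals is not None else X.sum(axis=1),
                "mito_fraction": mito if mito is not None else np.zeros(n),
            },
            index=gu.index,
        ),
        var=pd.DataFrame(index=pd.Index(["a", "b", "c"], name="gene_id")),
    )
    adata.obsm["guide_umis"] = gu
    return adata


class TestAssignGuides:
    def test_status_by_detected_guide_count(self):
        adata = make_dataset(
            {
                "c1": {"g1": 10},
                "c2": {"g1": 10, "g2": 8},
                "c3": {"g1": 2},  # below threshold
            }
        )
        out = assign_guides(adata, min_umis=3)
        assert out.loc["c1", "status"] == "single"
        assert out.loc["c1", "guide_id"] == "g1"
        assert out.loc["c2", "status"] == "multiple"
        assert out.loc["c3", "status"] == "none"

    def test_threshold_is_inclusive(self):
        adata = make_dataset({"c1": {"g1": 3}})
        assert assign_guides(adata, min_umis=3).loc["c1", "status"] == "single"

    def test_target_gene_mapping(self):
        adata = make_dataset({"c1": {"g1": 10}, "c2": {"nt": 8}})
        out = assign_guides(adata, guide_to_gene={"g1": "GENEX", "nt": ""})
        assert out.loc["c1", "target_gene"] == "GENEX"
        assert out.loc["c2", "target_gene"] == ""


class TestQcFilter:
    def test_boundary_semantics(self):
        # mito strictly <5%, totals >= 200
        adata = make_dataset(
            {"c1": {"g1": 9}, "c2": {"g1": 9}, "c3": {"g1": 9}},
            mito=[0.02, 0.05, 0.02],
            totals=[500, 500, 200],
        )
        out, report = qc_filter(adata, assign_guides(adata), max_mito=0.05, min_rnas=200)
        assert list(out.obs_names) == ["c1", "c3"]
        assert report["removed_high_mito"] == 1

    def test_hand_enumerated_fixture(self):
        adata = make_dataset(
            {
                "c1": {"g1": 9},            # single, 2%, 500 -> kept
                "c2": {"g1": 9, "g2": 9},   # multiple
                "c3": {"g1": 9},            # 7% mito
                "c4": {"g1": 9},            # 150 counts
                "c5": {},                   # no guide
            },
            mito=[0.02, 0.01, 0.07, 0.02, 0.0],
            totals=[500, 500, 500, 150, 500],
        )
        out, report = qc_filter(adata, assign_guides(adata))
        assert list(out.obs_names) == ["c1"]
        assert report["n_kept"] == 1

    def test_empty_dataset(self):
        adata = make_dataset({})
        out, report = qc_filter(adata, assign_guides(adata))
        assert out.n_obs == 0
        assert report["n_kept"] == 0

    def test_matches_brute_force_predicate_and_idempotent(self, small_config, small_library):
        adata, _ = simulate_perturb_seq(small_config, small_library)
        asn = assign_guides(adata)
        out, _ = qc_filter(adata, asn)
        expected = [
            c
            for c in adata.obs_names
            if asn.loc[c, "status"] == "single"
            and adata.obs.loc[c, "mito_fraction"] < 0.05
            and adata.obs.loc[c, "total_counts"] >= 200
        ]
        assert list(out.obs_names) == expected
        again, report2 = qc_filter(out, asn.loc[out.obs_names])
        assert list(again.obs_names) == expected
        assert report2["n_kept"] == report2["n_input"]


class TestNormalize:
    def test_zero_gene_stays_zero(self):
        adata = make_dataset({"c1": {"g1": 9}, "c2": {"g1": 9}})
        adata.X = np.array([[5, 0, 1], [7, 0, 3]], dtype=np.int32)
        normalize_expression(adata)
        assert (adata.layers["lognorm"][:, 1] == 0).all()

    def test_depth_invariance_for_proportional_cells(self):
        adata = make_dataset({"c1": {"g1": 9}, "c2": {"g1": 9}})
        adata.X = np.array([[10, 20, 30], [20, 40, 60]], dtype=np.int32)
        normalize_expression(adata)
        np.testing.assert_allclose(adata.layers["lognorm"][0], adata.layers["lognorm"][1])

    def test_single_cell_formula(self):
        adata = make_dataset({"c1": {"g1": 9}})
        adata.X = np.array([[1, 3, 0]], dtype=np.int32)
        normalize_expression(adata)
        np.testing.assert_allclose(
            adata.layers["lognorm"][0], np.log1p([1.0, 3.0, 0.0])
        )


class TestVariableFeatures:
    def test_returns_all_when_n_exceeds_genes(self, small_config, small_library):
        adata, _ = simulate_perturb_seq(small_config, small_library)
        normalize_expression(adata)
        feats = select_variable_features(adata, n=10_000)
        assert feats == list(adata.var_names)

    def test_trajectory_markers_rank_highly(self, small_config, small_library):
        adata, _ = simulate_perturb_seq(small_config, small_library)
        asn = assign_guides(adata)
        filt, _ = qc_filter(adata, asn)
        normalize_expression(filt)
        feats = set(select_variable_features(filt, n=40))
        markers = set(
            filt.var_names[filt.var["gene_class"].isin(
                ["progenitor_marker", "differentiation_marker"]
            )]
        )
        assert len(feats & markers) >= 0.8 * len(markers)


class TestKnockoutEfficiency:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        adata = make_dataset({f"c{i}": {"g1" if i % 2 else "nt": 9} for i in range(40)})
        adata.X = rng.poisson(20, size=(40, 3)).astype(np.int32)
        normalize_expression(adata)
        asn = assign_guides(adata, guide_to_gene={"g1": "a", "nt": ""})
        _, p = knockout_efficiency(adata, asn, "a")
        assert p >= 0.3

    def test_simulated_knockdown_detected(self, small_config, small_library):
        adata, _ = simulate_perturb_seq(small_config, small_library)
        asn = assign_guides(adata, guide_to_gene=small_library.guide_to_gene)
        filt, _ = qc_filter(adata, asn)
        normalize_expression(filt)
        _, p = knockout_efficiency(filt, asn.loc[filt.obs_names], "GENE001")
        assert p < 0.01

    def test_empty_target_group_errors(self):
        adata = make_dataset({"c1": {"nt": 9}})
        normalize_expression(adata)
        asn = assign_guides(adata, guide_to_gene={"nt": ""})
        with pytest.raises(ValueError, match="empty"):
            knockout_efficiency(adata, asn, "a")


class TestDatasetIO:
    def test_matrixmarket_round_trip(self, small_config, small_library, tmp_path):
        adata, _ = simulate_perturb_seq(small_config, small_library)
        write_cell_dataset(adata, tmp_path / "ds")
        back = read_cell_dataset(tmp_path / "ds", guide_ids=list(small_library.guide_ids))
        np.testing.assert_array_equal(
            np.asarray(back.X.todense()), np.asarray(adata.X)
        )
        assert list(back.obs_names) == list(adata.obs_names)
        assert list(back.var_names) == list(adata.var_names)
        pd.testing.assert_frame_equal(
            back.obsm["guide_umis"],
            adata.obsm["guide_umis"].astype(np.int32),
            check_names=False,
        )
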