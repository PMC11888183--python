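"""Perturb-seq preprocessing.

Cells are assigned guides from capture UMIs, filtered to single-guide
cells with low mitochondrial content and adequate depth, depth-normalized,
and reduced to the most variable features.  A knockout-efficiency check
confirms that cells perturbing a gene express it less than non-targeting
control cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats

SINGLE, MULTIPLE, UNASSIGNED = "single", "multiple", "none"


def _guide_umi_frame(dataset: ad.AnnData) -> pd.DataFrame:
    if "guide_umis" not in dataset.obsm:
        raise ValueError("dataset lacks obsm['guide_umis']")
    gu = dataset.obsm["guide_umis"]
    if not isinstance(gu, pd.DataFrame):
        raise ValueError("obsm['guide_umis'] must be a DataFrame (cells x guides)")
    return gu


def assign_guides(
    dataset: ad.AnnData,
    min_umis: int = 3,
    guide_to_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cell guide assignment by a UMI threshold.

    A guide is detected in a cell when its capture UMIs reach ``min_umis``;
    status is single / multiple / none by the number detected.  When a
    guide -> target-gene map is given, single-guide cells also get their
    target_gene (empty for control guides).
    """
    gu = _guide_umi_frame(dataset)
    detected = gu.to_numpy() >= min_umis
    n_det = detected.sum(axis=1)
    status = np.where(n_det == 1, SINGLE, np.where(n_det > 1, MULTIPLE, UNASSIGNED))
    guide_cols = gu.columns.to_numpy()
    assigned = [",".join(guide_cols[row]) for row in detected]
    out = pd.DataFrame(
        {"status": status, "assigned_guides": assigned},
        index=gu.index.rename("cell_id"),
    )
    single_guide = np.where(n_det == 1, [guide_cols[row][0] if row.any() else "" for row in detected], "")
    out["guide_id"] = single_guide
    if guide_to_gene is not None:
        out["target_gene"] = [
            guide_to_gene.get(g, "") if s == SINGLE else ""
            for g, s in zip(out["guide_id"], out["status"])
        ]
    return out


def qc_filter(
    dataset: ad.AnnData,
    assignments: pd.DataFrame,
    max_mito: float = 0.05,
    min_rnas: int = 200,
) -> tuple[ad.AnnData, dict]:
    """Keep single-guide cells with mito_fraction < max_mito and
    total_counts >= min_rnas (strict / inclusive boundaries respectively).

    Returns the filtered dataset and per-criterion removal tallies.  The
    tallies count each failed criterion independently, so a cell failing
    two criteria appears in both.
    """
    if not dataset.obs_names.equals(assignments.index):
        assignments = assignments.reindex(dataset.obs_names)
    single = (assignments["status"] == SINGLE).to_numpy()
    mito_ok = (dataset.obs["mito_fraction"] < max_mito).to_numpy()
    depth_ok = (dataset.obs["total_counts"] >= min_rnas).to_numpy()
    keep = single & mito_ok & depth_ok
    report = {
        "n_input": int(dataset.n_obs),
        "n_kept": int(keep.sum()),
        "removed_not_single_guide": int((~single).sum()),
        "removed_high_mito": int((~mito_ok).sum()),
        "removed_low_counts": int((~depth_ok).sum()),
    }
    filtered = dataset[keep].copy()
    cols = ["guide_id", "status"] + (
        ["target_gene"] if "target_gene" in assignments.columns else []
    )
    for col in cols:
        filtered.obs[col] = assignments.loc[keep, col]
    return filtered, report


def normalize_expression(dataset: ad.AnnData, layer_out: str = "lognorm") -> ad.AnnData:
    """log1p of counts scaled per cell to the median total count.

    A deliberately simple, monotone normalization: the downstream
    trajectory uses correlation distances, which are insensitive to the
    particular variance-stabilizing choice.  Stored in
    ``dataset.layers[layer_out]``; returns the same object.
    """
    X = dataset.X
    x = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts; run qc_filter first")
    median_depth = float(np.median(totals))
    dataset.layers[layer_out] = np.log1p(x * (median_depth / totals)[:, None])
    return dataset


def select_variable_features(
    dataset: ad.AnnData, n: int = 2000, layer: str = "lognorm", n_bins: int = 20
) -> list[str]:
    """Top-n genes by standardized dispersion.

    Dispersion = variance / mean of the normalized expression; z-scored
    within ``n_bins`` equal-frequency mean bins so highly expressed genes
    do not dominate.  Ties break by gene id for determinism.  All genes
    are returned when fewer than n are present.
    """
    if layer not in dataset.layers:
        raise ValueError(f"layer {layer!r} missing; run normalize_expression")
    x = np.asarray(dataset.layers[layer], dtype=float)
    gene_ids = dataset.var_names.to_numpy()
    if len(gene_ids) <= n:
        return list(gene_ids)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.arange(len(mean)) * n_bins // len(mean)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        m = bins == b
        if m.sum() == 0:
            continue
        mu, sd = disp[m].mean(), disp[m].std(ddof=0)
        z[m] = (disp[m] - mu) / sd if sd > 0 else 0.0
    ranking = pd.DataFrame({"gene_id": gene_ids, "z": z}).sort_values(
        ["z", "gene_id"], ascending=[False, True], kind="stable"
    )
    return ranking["gene_id"].head(n).tolist()


def knockout_efficiency(
    dataset: ad.AnnData,
    assignments: pd.DataFrame,
    gene: str,
    layer: str = "lognorm",
    control_category_guides: list[str] | None = None,
) -> tuple[float, float]:
    """One-sided Mann-Whitney test that cells perturbing ``gene`` express
    it less than non-targeting control cells.

    Target cells: single-guide cells whose assignment's target_gene equals
    ``gene``.  Control cells: single-guide cells carrying one of
    ``control_category_guides`` (or any empty-target guide when None).
    Returns (U statistic, one-sided p).
    """
    if gene not in dataset.var_names:
        raise ValueError(f"gene {gene} not in dataset")
    if "target_gene" not in assignments.columns:
        raise ValueError("assignments lack target_gene; pass guide_to_gene to assign_guides")
    assignments = assignments.reindex(dataset.obs_names)
    single = assignments["status"] == SINGLE
    target_cells = (single & (assignments["target_gene"] == gene)).to_numpy()
    if control_category_guides is not None:
        control_cells = (
            single & assignments["guide_id"].isin(control_category_guides)
        ).to_numpy()
    else:
        control_cells = (single & (assignments["target_gene"] == "")).to_numpy()
    if target_cells.sum() == 0 or control_cells.sum() == 0:
        raise ValueError("empty target or control group")
    expr = np.asarray(dataset[:, gene].layers[layer]).ravel()
    res = stats.mannwhitneyu(
        expr[target_cells], expr[control_cells], alternative="less", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# dataset I/O: MatrixMarket matrix + TSV sidecars (plain-text exchange format)

def write_cell_dataset(dataset: ad.AnnData, outdir: str | Path) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = dataset.X
    mat = sparse.csr_matrix(X) if not sparse.issparse(X) else X.tocsr()
    spio.mmwrite(str(outdir / "matrix.mtx"), mat.T.astype(np.int64))  # genes x cells
    dataset.var.reset_index().to_csv(outdir / "features.tsv", sep="\t", index=False)
    dataset.obs.reset_index().to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    gu = _guide_umi_frame(dataset)
    long = gu.stack()
    long = long[long > 0].rename("umis").reset_index()
    long.columns = ["cell_id", "guide_id", "umis"]
    long.to_csv(outdir / "guide_umis.tsv", sep="\t", index=False)
    return {
        "matrix": str(outdir / "matrix.mtx"),
        "features": str(outdir / "features.tsv"),
        "barcodes": str(outdir / "barcodes.tsv"),
        "guide_umis": str(outdir / "guide_umis.tsv"),
    }


def read_cell_dataset(indir: str | Path, guide_ids: list[str] | None = None) -> ad.AnnData:
    indir = Path(indir)
    mat = sparse.csr_matrix(spio.mmread(str(indir / "matrix.mtx")).T)
    var = pd.read_csv(indir / "features.tsv", sep="\t").set_index("gene_id")
    obs = pd.read_csv(indir / "barcodes.tsv", sep="\t").set_index("cell_id")
    if "is_mito" in var.columns:
        var["is_mito"] = var["is_mito"].astype(bool)
    adata = ad.AnnData(X=mat, obs=obs, var=var)
    long = pd.read_csv(indir / "guide_umis.tsv", sep="\t")
    wide = long.pivot_table(
        index="cell_id", columns="guide_id", values="umis", fill_value=0, aggfunc="sum"
    )
    if guide_ids is not None:
        wide = wide.reindex(columns=guide_ids, fill_value=0)
    wide = wide.reindex(adata.obs_names, fill_value=0).astype(np.int32)
    wide.columns.name = None
    adata.obsm["guide_umis"] = wide
    return adata


def write_qc_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
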