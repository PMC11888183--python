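"""Pseudotime inference by principal-curve fitting.

The pipeline mirrors the classic single-trajectory recipe: Pearson
correlation distances between cells over the variable features, classical
(Torgerson) multidimensional scaling to a small number of dimensions
(default 10), then an iterated principal curve — order cells by their
projection, smooth each embedding coordinate against that order, project
cells back onto the smoothed piecewise-linear curve — whose arc-length
positions, min-max rescaled to [0,1], are the pseudotime.  Orientation is
fixed by marker genes so progenitor-high cells sit at t ~ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class Embedding:
    coordinates: np.ndarray  # cells x k
    eigenvalues: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series  # per cell, in [0, 1]
    curve_nodes: np.ndarray  # ordered node coordinates along the curve
    converged: bool
    n_iterations: int
    oriented: bool = False
    flipped: bool = False

    def flip(self) -> "PseudotimeResult":
        return PseudotimeResult(
            pseudotime=1.0 - self.pseudotime,
            curve_nodes=self.curve_nodes[::-1].copy(),
            converged=self.converged,
            n_iterations=self.n_iterations,
            oriented=self.oriented,
            flipped=not self.flipped,
        )


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson(x_i, x_j) between rows (cells).

    Symmetric with a zero diagonal, values in [0, 2].  Rows must have
    nonzero variance across features.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a cells x features matrix with >= 2 features")
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError(f"{int((sd == 0).sum())} cells have zero variance across features")
    corr = np.corrcoef(x)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def reduce_dims(distance: np.ndarray, k: int = 10) -> Embedding:
    """Classical MDS: double-centered Gram matrix eigendecomposition.

    Keeps the top-k eigenpairs with positive eigenvalues (trailing
    coordinates are zero when the distance matrix has lower rank).  The
    sign of each coordinate axis is fixed so its largest-magnitude loading
    is positive, making the embedding deterministic.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n - 1) if n > 1 else 1
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:k]
    vals = eigvals[order]
    vecs = eigvecs[:, order]
    pos = np.clip(vals, 0.0, None)
    # numerical-noise floor: eigenvalues ~0 relative to the leading one are rank deficit
    if pos.max() > 0:
        pos[pos < pos.max() * 1e-12] = 0.0
    coords = vecs * np.sqrt(pos)[None, :]
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return Embedding(coordinates=coords, eigenvalues=vals)


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the ends."""
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _project_to_polyline(points: np.ndarray, nodes: np.ndarray):
    """Project points onto a piecewise-linear curve.

    Returns (arclength position, foot coordinates, squared distance) per
    point, each taken at the nearest segment.
    """
    seg_start = nodes[:-1]
    seg_vec = nodes[1:] - seg_start
    seg_len2 = np.maximum((seg_vec**2).sum(axis=1), 1e-300)
    seg_len = np.sqrt((seg_vec**2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # (cells, segments) projection parameter, clipped into each segment
    diff = points[:, None, :] - seg_start[None, :, :]
    tpar = np.clip((diff * seg_vec[None, :, :]).sum(axis=2) / seg_len2, 0.0, 1.0)
    feet = seg_start[None, :, :] + tpar[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - feet) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(points))
    arclen = cum[best] + tpar[idx, best] * seg_len[best]
    return arclen, feet[idx, best], d2[idx, best]


def fit_principal_curve(
    embedding: Embedding,
    max_iter: int = 100,
    tol: float = 1e-4,
    smooth_frac: float = 0.1,
    n_nodes: int = 100,
    seed: int = 0,
) -> PseudotimeResult:
    """Iterated projection / smoothing principal curve.

    Starts from the ordering along the first embedding coordinate; each
    iteration smooths every coordinate against the current cell order with
    a centered rolling mean over ``smooth_frac`` of the cells, thins the
    smoothed path to ``n_nodes`` nodes, and re-projects cells onto it.
    Stops when the mean displacement of projection feet falls below
    ``tol`` (relative to the curve length) or at ``max_iter`` (returned
    with ``converged=False``).  Pseudotime is the arc-length position,
    min-max rescaled to [0, 1].
    """
    x = embedding.coordinates
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >= 3 cells to fit a curve")
    window = max(3, int(round(smooth_frac * n)))
    n_nodes = min(n_nodes, n)
    order = np.argsort(x[:, 0], kind="stable")
    prev_feet = None
    arclen = np.zeros(n)
    nodes = x[order]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        smoothed = np.column_stack(
            [_rolling_mean(x[order, c], window) for c in range(x.shape[1])]
        )
        node_idx = np.unique(np.linspace(0, n - 1, n_nodes).round().astype(int))
        nodes = smoothed[node_idx]
        arclen, feet, _ = _project_to_polyline(x, nodes)
        order = np.argsort(arclen, kind="stable")
        if prev_feet is not None:
            scale = max(float(np.ptp(arclen)), 1e-12)
            disp = float(np.mean(np.linalg.norm(feet - prev_feet, axis=1))) / scale
            if disp < tol:
                converged = True
                break
        prev_feet = feet
    span = arclen.max() - arclen.min()
    pt = (arclen - arclen.min()) / span if span > 0 else np.zeros(n)
    return PseudotimeResult(
        pseudotime=pd.Series(pt, name="pseudotime"),
        curve_nodes=nodes,
        converged=converged,
        n_iterations=iterations,
    )


def infer_pseudotime(
    matrix: np.ndarray,
    k: int = 10,
    cell_ids: pd.Index | None = None,
    **curve_kwargs,
) -> PseudotimeResult:
    """Convenience wrapper: distance -> MDS -> principal curve."""
    emb = reduce_dims(correlation_distance(matrix), k=k)
    result = fit_principal_curve(emb, **curve_kwargs)
    if cell_ids is not None:
        result.pseudotime.index = cell_ids
    return result


def orient_pseudotime(
    result: PseudotimeResult,
    dataset: ad.AnnData,
    progenitor_markers: list[str],
    differentiation_markers: list[str],
    layer: str = "lognorm",
) -> PseudotimeResult:
    """Flip pseudotime so progenitor markers are high at t ~ 0.

    The curve is flipped iff mean progenitor-marker expression correlates
    positively with pseudotime.  Raises with the missing gene names if
    any marker is absent.
    """
    missing = [g for g in progenitor_markers + differentiation_markers
               if g not in dataset.var_names]
    if missing:
        raise ValueError(f"marker genes missing from dataset: {missing}")
    x = dataset.layers[layer] if layer in dataset.layers else dataset.X
    x = x.toarray() if sparse.issparse(x) else np.asarray(x, dtype=float)
    cols = dataset.var_names.get_indexer(progenitor_markers)
    prog_mean = x[:, cols].mean(axis=1)
    t = result.pseudotime.to_numpy()
    corr = np.corrcoef(prog_mean, t)[0, 1]
    oriented = result.flip() if corr > 0 else result
    oriented.oriented = True
    return oriented


def write_pseudotime(result: PseudotimeResult, path) -> None:
    df = result.pseudotime.rename("pseudotime").rename_axis("cell_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_pseudotime(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("cell_id")["pseudotime"]
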