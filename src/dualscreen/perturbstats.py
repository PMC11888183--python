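"""Per-target pseudotime phenotyping.

Three statistics per perturbed gene, computed on single-guide cells:

* a one-sided Mann-Whitney shift test of the target cells' pseudotimes
  against all other single-guide cells, reported as a signed Z score
  (negative = target cells sit earlier in pseudotime) and its p-value;
* Gaussian KDE density profiles of target and reference pseudotimes on a
  40-point grid over [0, 1];
* a window of length 10 rolled along the grid, comparing the 10 target
  density values against the 10 reference values by one-sided
  Mann-Whitney in both directions (31 windows at stride 1).

A gene is called pro-differentiation when its cells are enriched at low
pseudotime — some early window significant AND a negative shift Z — and
pro-progenitor under the mirrored condition at high pseudotime.  The
conjunction keeps the 31-window multiplicity in check without an
explicit correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PRO_DIFFERENTIATION = "pro_differentiation"
PRO_PROGENITOR = "pro_progenitor"
NONE = "none"

N_GRID_POINTS = 40
WINDOW_LENGTH = 10
EXACT_LIMIT = 20  # exact MW enumeration up to this combined sample size


def mann_whitney_one_sided(
    x: np.ndarray, y: np.ndarray, alternative: str = "less"
) -> tuple[float, float, float]:
    """One-sided Mann-Whitney U of x vs y; returns (U_x, z, p).

    Uses the exact distribution when n1 + n2 <= 20 with no ties, else the
    normal approximation with tie correction and continuity correction.
    z is the signed standardized U (tie-corrected, continuity-corrected):
    negative when x tends to be smaller than y, regardless of the tested
    alternative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 + n2 <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    u_x = float(res.statistic)  # number of (x > y) pairs, ties half-weighted

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    sigma = np.sqrt(sigma2)
    if sigma == 0:
        z = 0.0
    else:
        # continuity correction toward the null
        cc = 0.5 if u_x != mu else 0.0
        z = (u_x - mu - np.sign(u_x - mu) * cc) / sigma
    return u_x, float(z), float(res.pvalue)


def pseudotime_shift_test(
    pseudotimes: pd.Series,
    target_cells: np.ndarray | list,
    background_cells: np.ndarray | list,
) -> tuple[float, float]:
    """Signed Z and one-sided p (target earlier) for a target's cells
    against the background single-guide cells."""
    t = pseudotimes.loc[list(target_cells)].to_numpy()
    b = pseudotimes.loc[list(background_cells)].to_numpy()
    _, z, p = mann_whitney_one_sided(t, b, alternative="less")
    return z, p


@dataclass
class DensityProfile:
    grid: np.ndarray
    densities: np.ndarray
    bandwidth: float
    n_cells: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.grid.shape != self.densities.shape:
            raise ValueError("grid/density length mismatch")
        if (self.densities < 0).any():
            raise ValueError("densities must be non-negative")


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's rule for a univariate Gaussian KDE: n^(-1/5) * std."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("Scott bandwidth undefined for constant samples")
    return float(values.size ** (-1.0 / 5.0) * sd)


def kde_density_profile(
    pseudotimes: np.ndarray | pd.Series,
    n_points: int = N_GRID_POINTS,
    bandwidth: float | None = None,
) -> DensityProfile:
    """Gaussian KDE of pseudotimes at evenly spaced grid points on [0, 1].

    bandwidth is the absolute kernel standard deviation; None uses
    Scott's rule (which needs >= 2 distinct values).
    """
    v = np.asarray(pseudotimes, dtype=float)
    if v.size == 0:
        raise ValueError("no pseudotimes")
    if bandwidth is None:
        if np.unique(v).size < 2:
            raise ValueError(
                "automatic bandwidth needs >= 2 distinct pseudotimes; "
                "pass an explicit bandwidth"
            )
        bandwidth = scott_bandwidth(v)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, 1.0, n_points)
    z = (grid[:, None] - v[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * bandwidth * np.sqrt(2 * np.pi))
    return DensityProfile(grid=grid, densities=dens, bandwidth=float(bandwidth), n_cells=v.size)


def windowed_enrichment(
    target_profile: DensityProfile,
    reference_profile: DensityProfile,
    window: int = WINDOW_LENGTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling one-sided Mann-Whitney tests between the two density
    profiles.

    For each stride-1 window of ``window`` grid points, the window's
    target densities are compared against its reference densities.
    Returns (p_enriched, p_depleted): target > reference and
    target < reference respectively, one p per window
    (len(grid) - window + 1 windows).
    """
    if not np.array_equal(target_profile.grid, reference_profile.grid):
        raise ValueError("profiles must share a grid")
    t = target_profile.densities
    r = reference_profile.densities
    n_windows = t.size - window + 1
    if n_windows < 1:
        raise ValueError("window longer than grid")
    p_enr = np.empty(n_windows)
    p_dep = np.empty(n_windows)
    for i in range(n_windows):
        tw, rw = t[i : i + window], r[i : i + window]
        _, _, p_enr[i] = mann_whitney_one_sided(tw, rw, alternative="greater")
        _, _, p_dep[i] = mann_whitney_one_sided(tw, rw, alternative="less")
    return p_enr, p_dep


def windowed_enrichment_cells(
    target_pseudotimes: np.ndarray,
    reference_pseudotimes: np.ndarray,
    n_points: int = N_GRID_POINTS,
    window: int = WINDOW_LENGTH,
) -> np.ndarray:
    """Alternative window statistic pooling cells rather than densities.

    For each rolling window's pseudotime interval, a one-sided binomial-style
    comparison of how many target vs reference cells fall inside it: the
    reported p is a one-sided hypergeometric (Fisher) enrichment p for the
    target's cell count in the interval.  Provided as the other defensible
    reading of a rolling-window enrichment; the density-value reading
    (:func:`windowed_enrichment`) is the default used by the pipeline.
    """
    t = np.asarray(target_pseudotimes, dtype=float)
    r = np.asarray(reference_pseudotimes, dtype=float)
    grid = np.linspace(0.0, 1.0, n_points)
    n_windows = n_points - window + 1
    p = np.empty(n_windows)
    for i in range(n_windows):
        lo, hi = grid[i], grid[i + window - 1]
        k = int(((t >= lo) & (t <= hi)).sum())
        m = int(((r >= lo) & (r <= hi)).sum())
        # enrichment of target draws among the pooled window population
        p[i] = stats.hypergeom.sf(k - 1, t.size + r.size, k + m, t.size)
    return p


@dataclass
class TargetPhenotype:
    gene: str
    n_cells: int
    z_shift: float
    p_shift: float  # one-sided (target earlier)
    window_p_enriched: np.ndarray  # target density > reference, per window
    window_p_depleted: np.ndarray
    target_profile: DensityProfile
    classification: str = NONE
    p_shift_adj: float = np.nan  # BH across genes
    p_shift_two: float = np.nan  # two-sided shift p
    p_shift_two_adj: float = np.nan


def _two_sided(p_one_sided: float) -> float:
    return float(min(1.0, 2.0 * min(p_one_sided, 1.0 - p_one_sided)))


def classify_target(
    phenotype: TargetPhenotype,
    alpha: float = 0.05,
    region_windows: int = WINDOW_LENGTH,
) -> str:
    """Direction call: windowed enrichment plus a significant shift.

    pro_differentiation: some window in the low-pseudotime region (the
    first ``region_windows`` windows) has target-over-reference density
    enrichment at ``alpha`` AND the pseudotime shift is negative and
    significant (BH-adjusted two-sided p < alpha).  pro_progenitor is
    the mirrored condition in the last ``region_windows`` windows with a
    positive shift.  Otherwise none.

    The window p-values are Mann-Whitney tests on 10 autocorrelated KDE
    grid values and are badly anticalibrated under the null, so the
    window criterion alone (even with the Z sign) flags a large fraction
    of null genes; conjoining it with the calibrated, multiplicity-
    corrected shift test restores error control while the windows retain
    their role of localizing WHERE along pseudotime the target's cells
    concentrate.
    """
    shift_p = phenotype.p_shift_two_adj
    if np.isnan(shift_p):
        shift_p = phenotype.p_shift_two
    if np.isnan(shift_p):
        shift_p = _two_sided(phenotype.p_shift)
    p = phenotype.window_p_enriched
    low = p[:region_windows]
    high = p[-region_windows:]
    if (low < alpha).any() and phenotype.z_shift < 0 and shift_p < alpha:
        return PRO_DIFFERENTIATION
    if (high < alpha).any() and phenotype.z_shift > 0 and shift_p < alpha:
        return PRO_PROGENITOR
    return NONE


def phenotype_targets(
    pseudotimes: pd.Series,
    cell_targets: pd.Series,
    genes: list[str] | None = None,
    n_points: int = N_GRID_POINTS,
    window: int = WINDOW_LENGTH,
    alpha: float = 0.05,
    min_cells: int = 2,
) -> tuple[pd.DataFrame, dict[str, TargetPhenotype]]:
    """Run the full phenotyping battery for every target gene.

    pseudotimes: per single-guide cell.  cell_targets: the target gene of
    each cell's guide ('' for control guides).  The reference profile uses
    all cells (including each target's own, as the screen's reference set
    is the whole single-guide population).  Gene-level shift p-values are
    BH-adjusted across genes.

    Returns a tidy per-gene table and the full phenotype objects.
    """
    cell_targets = cell_targets.reindex(pseudotimes.index)
    if genes is None:
        genes = sorted(g for g in cell_targets.unique() if g)
    reference = kde_density_profile(pseudotimes.to_numpy(), n_points=n_points)
    results: dict[str, TargetPhenotype] = {}
    for gene in genes:
        cells = cell_targets.index[cell_targets == gene]
        if len(cells) < min_cells:
            continue
        background = cell_targets.index[cell_targets != gene]
        z, p = pseudotime_shift_test(pseudotimes, cells, background)
        profile = kde_density_profile(pseudotimes.loc[cells].to_numpy(), n_points=n_points)
        p_enr, p_dep = windowed_enrichment(profile, reference, window=window)
        ph = TargetPhenotype(
            gene=gene,
            n_cells=len(cells),
            z_shift=z,
            p_shift=p,
            p_shift_two=_two_sided(p),
            window_p_enriched=p_enr,
            window_p_depleted=p_dep,
            target_profile=profile,
        )
        results[gene] = ph
    if not results:
        raise ValueError("no target gene had enough cells to phenotype")
    order = list(results)
    adj = stats.false_discovery_control([results[g].p_shift for g in order], method="bh")
    adj_two = stats.false_discovery_control(
        [results[g].p_shift_two for g in order], method="bh"
    )
    for g, a, a2 in zip(order, adj, adj_two):
        results[g].p_shift_adj = float(a)
        results[g].p_shift_two_adj = float(a2)
        results[g].classification = classify_target(results[g], alpha=alpha)
    rows = []
    for g in order:
        ph = results[g]
        row = {
            "gene": g,
            "n_cells": ph.n_cells,
            "z_shift": ph.z_shift,
            "p_shift": ph.p_shift,
            "p_shift_adj": ph.p_shift_adj,
            "p_shift_two": ph.p_shift_two,
            "p_shift_two_adj": ph.p_shift_two_adj,
            "classification": ph.classification,
        }
        row.update({f"window_p_enriched_{i + 1:02d}": v for i, v in enumerate(ph.window_p_enriched)})
        row.update({f"window_p_depleted_{i + 1:02d}": v for i, v in enumerate(ph.window_p_depleted)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene"), results
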