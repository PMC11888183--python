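"""Synthetic dual-screen data with planted knockout effects.

Emulates the data-generating process the analysis assumes:

* a guide library targeting ~100 genes with four guides each plus
  safe-targeting / non-targeting controls;
* a FACS-sorted reporter screen: cells carry guides at low MOI, their
  KRT10-like reporter level follows a logistic function of a latent
  differentiation time t in [0,1], knockouts shift t and/or the reporter
  directly, and cells are gated into low / medium / high reporter bins
  (the un-gated remainder stands in for the unsorted pool), from which
  guide UMI counts are drawn multinomially at a configured depth;
* a Perturb-seq experiment: negative-binomial counts whose progenitor
  programs fall and differentiation programs rise logistically along t,
  with mitochondrial genes, per-cell depth variation, on-target knockdown
  of the perturbed gene, and Poisson guide capture.

Every knockout effect is recorded in a :class:`GroundTruth` so downstream
stages can be tested for parameter recovery.  All randomness flows from
``SimConfig.seed`` through independent named streams, so outputs are
byte-identical for identical configs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .guideio import GuideLibrary, GuideCountTable


@dataclass(frozen=True)
class Effect:
    """Planted knockout effect for one target gene.

    delta shifts the cell's latent differentiation time (negative = cells
    held back near t=0, i.e. the gene is needed for differentiation);
    reporter is an additive shift of the sorting reporter in log-units.
    """

    delta: float = 0.0
    reporter: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [-1, 1], got {self.delta}")


@dataclass
class SimConfig:
    n_target_genes: int = 101
    guides_per_gene: int = 4
    n_safe_guides: int = 108
    n_nontarget_guides: int = 108
    n_cells: int = 5000
    n_expression_genes: int = 200
    n_progenitor_markers: int = 30
    n_differentiation_markers: int = 30
    mito_gene_fraction: float = 0.05
    moi: float = 0.3
    nb_dispersion: float = 0.3
    mean_depth: float = 2000.0
    effect_map: dict[str, Effect] = field(default_factory=dict)
    bin_quantiles: tuple[float, float, float] = (0.2, 0.5, 0.865)
    seed: int = 0
    # secondary knobs (defaults are the study conditions the model assumes)
    n_flow_replicates: int = 2
    flow_depth: int = 200_000
    reporter_span: float = 4.0
    reporter_midpoint: float = 0.6
    reporter_steepness: float = 8.0
    reporter_noise_sd: float = 0.5
    marker_midpoint: float = 0.5
    marker_steepness: float = 8.0
    marker_floor: float = 0.05
    mean_mito_fraction: float = 0.025
    knockdown_factor: float = 0.3
    guide_capture_mean: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "n_target_genes", "guides_per_gene", "n_cells",
            "n_expression_genes", "n_flow_replicates", "flow_depth",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_safe_guides", "n_nontarget_guides",
                     "n_progenitor_markers", "n_differentiation_markers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ValueError("mito_gene_fraction must be in [0, 1]")
        for name in ("moi", "nb_dispersion", "mean_depth", "guide_capture_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        q = tuple(self.bin_quantiles)
        if len(q) != 3 or not (0 < q[0] < q[1] < q[2] < 1):
            raise ValueError("bin_quantiles must be three strictly increasing fractions in (0,1)")
        self.bin_quantiles = q
        self.effect_map = {
            gene: eff if isinstance(eff, Effect) else Effect(**dict(eff))
            for gene, eff in self.effect_map.items()
        }
        n_special = (self.n_target_genes + self.n_progenitor_markers
                     + self.n_differentiation_markers
                     + self._n_mito_genes())
        if self.n_expression_genes < n_special:
            raise ValueError(
                f"n_expression_genes={self.n_expression_genes} cannot hold "
                f"{n_special} target/marker/mito genes"
            )

    def _n_mito_genes(self) -> int:
        return int(round(self.mito_gene_fraction * self.n_expression_genes))

    def validate_effects(self, library: GuideLibrary) -> None:
        targets = set(library.target_genes)
        extra = set(self.effect_map) - targets
        if extra:
            raise ValueError(f"effect_map keys not in library targets: {sorted(extra)}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["effect_map"] = {g: asdict(e) for g, e in self.effect_map.items()}
        d["bin_quantiles"] = list(self.bin_quantiles)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "bin_quantiles" in d:
            d["bin_quantiles"] = tuple(d["bin_quantiles"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized latent state of a simulation run.

    cells: one row per simulated cell (latent time before and after the
    knockout shift, guide list, and for the flow arm the reporter level
    and assigned bin).  effects: the configured per-target shifts.
    """

    cells: pd.DataFrame
    effects: pd.DataFrame

    def to_tsv(self, cells_path: str | Path, effects_path: str | Path) -> None:
        self.cells.to_csv(cells_path, sep="\t", index=False)
        self.effects.to_csv(effects_path, sep="\t", index=False)


def _stream(config: SimConfig, name: str) -> np.random.Generator:
    """Independent, named child RNG so stages never share streams."""
    return np.random.default_rng([config.seed, zlib.crc32(name.encode())])


def _random_spacers(rng: np.random.Generator, n: int) -> list[str]:
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=20)]) for _ in range(n)]


def target_gene_names(config: SimConfig) -> list[str]:
    width = max(3, len(str(config.n_target_genes)))
    return [f"GENE{i + 1:0{width}d}" for i in range(config.n_target_genes)]


def simulate_library(config: SimConfig) -> GuideLibrary:
    """Designed guide library: per-gene targeting guides plus controls."""
    rng = _stream(config, "library")
    rows = []
    for gene in target_gene_names(config):
        for j in range(config.guides_per_gene):
            rows.append((f"{gene}_sg{j + 1}", gene, "targeting"))
    for i in range(config.n_safe_guides):
        rows.append((f"SAFE_sg{i + 1:03d}", "", "safe_targeting"))
    for i in range(config.n_nontarget_guides):
        rows.append((f"NT_sg{i + 1:03d}", "", "non_targeting"))
    spacers = _random_spacers(rng, len(rows))
    table = pd.DataFrame(
        {
            "guide_id": [r[0] for r in rows],
            "spacer": spacers,
            "target_gene": [r[1] for r in rows],
            "category": [r[2] for r in rows],
        }
    )
    return GuideLibrary(table)


def _draw_integrations(rng: np.random.Generator, n: int, moi: float, max_guides: int) -> np.ndarray:
    """Integrations per surviving cell: Poisson(moi) conditioned on >= 1.

    Screened cells are drug-selected for the guide vector, so the observed
    population is the zero-truncated Poisson.
    """
    k = rng.poisson(moi, size=n)
    zero = k == 0
    while zero.any():
        k[zero] = rng.poisson(moi, size=int(zero.sum()))
        zero = k == 0
    return np.minimum(k, max_guides)


def _effect_arrays(config: SimConfig, library: GuideLibrary) -> tuple[np.ndarray, np.ndarray]:
    """Per-guide (delta, reporter) effect vectors aligned to the library."""
    g2g = library.guide_to_gene
    deltas = np.zeros(len(library))
    reporters = np.zeros(len(library))
    for i, gid in enumerate(library.guide_ids):
        eff = config.effect_map.get(g2g.get(gid, ""))
        if eff is not None:
            deltas[i] = eff.delta
            reporters[i] = eff.reporter
    return deltas, reporters


def reporter_baseline(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Expected reporter level (log-units) as a logistic function of latent time."""
    return config.reporter_span * expit(
        config.reporter_steepness * (t - config.reporter_midpoint)
    )


def _effects_frame(config: SimConfig, library: GuideLibrary) -> pd.DataFrame:
    rows = [
        {
            "target_gene": gene,
            "delta": config.effect_map.get(gene, Effect()).delta,
            "reporter_effect": config.effect_map.get(gene, Effect()).reporter,
        }
        for gene in library.target_genes
    ]
    return pd.DataFrame(rows)


def _exact_allocation(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of `total` across weights; sums exactly."""
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def simulate_flow_screen(
    config: SimConfig, library: GuideLibrary
) -> tuple[GuideCountTable, GroundTruth]:
    """Sorted-bin reporter screen with multinomial guide-UMI readout.

    Per replicate: single-integration cells get a guide, a latent time,
    and a reporter level ``baseline(t + delta) + reporter_effect + noise``;
    reporter quantiles at ``bin_quantiles`` gate cells into low / medium /
    unsorted / high bins (a partition of the population); per bin, guide
    UMI counts are multinomial over the guides its cells carry, at a depth
    proportional to bin size so each replicate totals ``flow_depth`` UMIs.
    """
    config.validate_effects(library)
    rng = _stream(config, "flow")
    deltas, rep_effects = _effect_arrays(config, library)
    q1, q2, q3 = config.bin_quantiles
    columns: dict[str, np.ndarray] = {}
    cell_rows = []
    for r in range(1, config.n_flow_replicates + 1):
        rep = f"rep{r}"
        k = _draw_integrations(rng, config.n_cells, config.moi, max_guides=len(library))
        single = k == 1  # multi-integration cells are dropped before binning
        n_single = int(single.sum())
        guide_idx = rng.integers(0, len(library), size=n_single)
        t = rng.uniform(0.0, 1.0, size=n_single)
        t_eff = np.clip(t + deltas[guide_idx], 0.0, 1.0)
        reporter = (
            reporter_baseline(config, t_eff)
            + rep_effects[guide_idx]
            + rng.normal(0.0, config.reporter_noise_sd, size=n_single)
        )
        cuts = np.quantile(reporter, [q1, q2, q3])
        bin_of = np.select(
            [reporter < cuts[0], reporter < cuts[1], reporter < cuts[2]],
            ["low", "medium", "unsorted"],
            default="high",
        )
        sizes = {b: int((bin_of == b).sum()) for b in ("unsorted", "low", "medium", "high")}
        empty = [b for b, s in sizes.items() if s == 0]
        if empty:
            raise ValueError(
                f"bins {empty} empty at n_cells={config.n_cells}; "
                "increase n_cells or widen bin_quantiles"
            )
        depths = _exact_allocation(
            config.flow_depth, np.array([sizes[b] for b in ("unsorted", "low", "medium", "high")], float)
        )
        for b, depth in zip(("unsorted", "low", "medium", "high"), depths):
            in_bin = guide_idx[bin_of == b]
            weights = np.bincount(in_bin, minlength=len(library)).astype(float)
            columns[f"{rep}:{b}"] = rng.multinomial(int(depth), weights / weights.sum())
        gid_arr = library.guide_ids.to_numpy()
        cell_rows.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{rep}_cell{i}" for i in range(n_single)],
                    "replicate_id": rep,
                    "guides": gid_arr[guide_idx],
                    "true_t": t,
                    "shifted_t": t_eff,
                    "reporter": reporter,
                    "bin": bin_of,
                }
            )
        )
    counts = pd.DataFrame(columns, index=library.guide_ids)
    counts.index.name = "guide_id"
    truth = GroundTruth(
        cells=pd.concat(cell_rows, ignore_index=True),
        effects=_effects_frame(config, library),
    )
    return GuideCountTable(counts), truth


def _marker_profile(config: SimConfig, t: np.ndarray, rising: bool) -> np.ndarray:
    """Logistic marker response in latent time, with a basal floor."""
    s = config.marker_steepness * (t - config.marker_midpoint)
    f = expit(s if rising else -s)
    return config.marker_floor + (1.0 - config.marker_floor) * f


def gene_panel(config: SimConfig) -> pd.DataFrame:
    """Gene ids and classes for the simulated transcriptome."""
    targets = target_gene_names(config)
    n_mito = config._n_mito_genes()
    prog = [f"PROG{i + 1:02d}" for i in range(config.n_progenitor_markers)]
    diff = [f"DIFF{i + 1:02d}" for i in range(config.n_differentiation_markers)]
    mito = [f"MT-{i + 1}" for i in range(n_mito)]
    n_fill = config.n_expression_genes - len(targets) - len(prog) - len(diff) - len(mito)
    fill = [f"FILL{i + 1:03d}" for i in range(n_fill)]
    ids = targets + prog + diff + mito + fill
    classes = (
        ["target"] * len(targets)
        + ["progenitor_marker"] * len(prog)
        + ["differentiation_marker"] * len(diff)
        + ["mito"] * len(mito)
        + ["other"] * len(fill)
    )
    return pd.DataFrame({"gene_id": ids, "gene_class": classes})


def simulate_perturb_seq(config: SimConfig, library: GuideLibrary):
    """Perturb-seq counts along a latent differentiation time.

    Returns an :class:`anndata.AnnData` (cells x genes, raw counts; guide
    capture UMIs in ``obsm['guide_umis']``) and the :class:`GroundTruth`.

    Cells draw t ~ Uniform(0,1), shifted by the summed delta of their
    guides' targets and clipped to [0,1].  Progenitor markers fall and
    differentiation markers rise logistically in t; target genes are flat
    but knocked down (x ``knockdown_factor``) in cells perturbing them;
    counts are negative binomial (Gamma-Poisson) with variance
    mu + nb_dispersion * mu^2 at a lognormal per-cell depth.
    """
    import anndata as ad

    config.validate_effects(library)
    rng = _stream(config, "perturb")
    n = config.n_cells
    panel = gene_panel(config)
    gene_ids = panel["gene_id"].to_numpy()
    gene_class = panel["gene_class"].to_numpy()
    n_genes = len(gene_ids)

    # guide capture
    k = _draw_integrations(rng, n, config.moi, max_guides=len(library))
    guide_lists = [rng.choice(len(library), size=int(ki), replace=False) for ki in k]
    gid_arr = library.guide_ids.to_numpy()
    deltas, _ = _effect_arrays(config, library)
    g2g = library.guide_to_gene

    t = rng.uniform(0.0, 1.0, size=n)
    t_eff = np.clip(t + np.array([deltas[g].sum() for g in guide_lists]), 0.0, 1.0)

    # per-gene relative abundance, modulated along t
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mito_mask = gene_class == "mito"
    if mito_mask.any():
        # scale mito abundance so its expected share of reads is mean_mito_fraction
        non_mito_mass = base[~mito_mask].sum()
        base[mito_mask] *= (
            config.mean_mito_fraction / (1 - config.mean_mito_fraction)
            * non_mito_mass / base[mito_mask].sum()
        )
    mean = np.tile(base, (n, 1))
    prog_mask = gene_class == "progenitor_marker"
    diff_mask = gene_class == "differentiation_marker"
    mean[:, prog_mask] *= _marker_profile(config, t_eff, rising=False)[:, None]
    mean[:, diff_mask] *= _marker_profile(config, t_eff, rising=True)[:, None]
    # per-cell mito load variation (drives the QC filter)
    mito_scale = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    mean[:, mito_mask] *= mito_scale[:, None]

    # on-target knockdown
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for ci, guides in enumerate(guide_lists):
        for g in guides:
            tgt = g2g.get(gid_arr[g], "")
            if tgt in gene_pos:
                mean[ci, gene_pos[tgt]] *= config.knockdown_factor

    depth = rng.lognormal(
        mean=np.log(config.mean_depth) - 0.25**2 / 2, sigma=0.25, size=n
    )
    mean *= (depth / mean.sum(axis=1))[:, None]

    # Gamma-Poisson mixture == NB with var = mu + alpha mu^2
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    counts = rng.poisson(lam).astype(np.int32)

    guide_umis = np.zeros((n, len(library)), dtype=np.int32)
    for ci, guides in enumerate(guide_lists):
        guide_umis[ci, guides] = rng.poisson(config.guide_capture_mean, size=len(guides)) + 1

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    total = counts.sum(axis=1)
    mito_counts = counts[:, mito_mask].sum(axis=1) if mito_mask.any() else np.zeros(n)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    obs = pd.DataFrame(
        {
            "total_counts": total,
            "mito_fraction": mito_frac,
            "n_guides": k,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {"gene_class": gene_class, "is_mito": mito_mask},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.obsm["guide_umis"] = pd.DataFrame(
        guide_umis, index=adata.obs_names, columns=gid_arr
    )
    adata.uns["simulation"] = {"seed": config.seed, "moi": config.moi}

    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "guides": [",".join(gid_arr[g]) for g in guide_lists],
                "true_t": t,
                "shifted_t": t_eff,
            }
        ),
        effects=_effects_frame(config, library),
    )
    return adata, truth
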