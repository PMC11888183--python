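"""Gene scoring for sorted-bin CRISPR screens.

The flow arm reads out guide abundance in FACS bins of a differentiation
reporter.  Scoring follows the robust-rank-aggregation family: guide
log2 fold changes between a sorted bin and the rest of the population are
ranked, and a gene's guides are summarized by the alpha-RRA statistic

    rho = min_{k : r_k <= alpha} BetaCDF(r_k; k, m - k + 1)

over its sorted normalized ranks r_1 <= ... <= r_m, i.e. the most
surprising order statistic among guides ranked inside the top alpha
fraction.  Significance comes from a permutation null drawing gene-sized
rank sets from a background pool (safe-targeting guides when available).

Evidence from the two complementary comparisons — enrichment in the high
bin with depletion in the low bin, or the converse — is combined by
Fisher's method.  Because the two comparisons share background samples
they are not independent, so the combination is reported as a
pseudo-p-value (psi_p) and should be used for ranking, not as a
calibrated error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .guideio import GuideCountTable, GuideLibrary

PRO_DIFFERENTIATION = "pro_differentiation"
PRO_PROGENITOR = "pro_progenitor"
NONE = "none"


def normalize_counts(table: GuideCountTable, min_common: int = 100):
    """Median-of-ratios size factors; normalized counts.

    The reference per guide is the geometric mean across samples, computed
    over guides with nonzero counts in every sample; each sample's size
    factor is the median ratio to that reference.  When fewer than
    ``min(min_common, n_guides)`` guides are common to all samples the
    estimator is unstable and total-count scaling is used instead.
    Returns (normalized DataFrame, size factor Series).
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    common = (x > 0).all(axis=1)
    if common.sum() >= min(min_common, x.shape[0]):
        logref = np.log(x[common]).mean(axis=1)
        factors = np.exp(np.median(np.log(x[common]) - logref[:, None], axis=0))
    else:
        totals = x.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / factors
    return normalized, factors


def guide_lfc(
    treatment: pd.Series | np.ndarray,
    reference: pd.Series | np.ndarray,
    pseudocount: float = 1.0,
):
    """log2((treatment + pc) / (reference + pc)) on normalized counts."""
    t = np.asarray(treatment, dtype=float)
    r = np.asarray(reference, dtype=float)
    out = np.log2((t + pseudocount) / (r + pseudocount))
    if isinstance(treatment, pd.Series):
        return pd.Series(out, index=treatment.index)
    return out


def _rho_from_ranks(ranks: np.ndarray, alpha: float) -> np.ndarray:
    """alpha-RRA statistic for each row of sorted normalized ranks.

    ranks: (n, m) array, rows sorted ascending.  For each row, the minimum
    over qualifying positions k (r_k <= alpha) of BetaCDF(r_k; k, m-k+1);
    rows with no qualifying guide score 1.
    """
    n, m = ranks.shape
    k = np.arange(1, m + 1)
    cdf = stats.beta.cdf(ranks, k[None, :], (m - k + 1)[None, :])
    cdf = np.where(ranks <= alpha, cdf, 1.0)
    return cdf.min(axis=1)


def alpha_rra(
    gene_ranks: dict[str, np.ndarray],
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """alpha-RRA score and permutation p per gene.

    gene_ranks maps gene -> normalized guide ranks in (0, 1] (rank / N over
    all guides in the comparison).  The permutation null draws gene-sized
    rank sets uniformly without replacement from ``background`` (default:
    the pooled observed ranks); the null distribution is shared across
    genes of equal guide count.  p = (1 + #{rho* <= rho}) / (n_perm + 1).
    """
    if not gene_ranks:
        raise ValueError("no genes to score")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for gene, r in gene_ranks.items():
        r = np.asarray(r, dtype=float)
        if r.size == 0:
            raise ValueError(f"gene {gene} has no guides")
        if (r <= 0).any() or (r > 1).any():
            raise ValueError(f"gene {gene}: ranks must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if background is None:
        background = np.concatenate([np.asarray(r, float) for r in gene_ranks.values()])
    background = np.asarray(background, dtype=float)

    sizes = sorted({len(np.asarray(r)) for r in gene_ranks.values()})
    null_by_size: dict[int, np.ndarray] = {}
    for m in sizes:
        if m > background.size:
            raise ValueError(f"gene size {m} exceeds background pool {background.size}")
        # vectorized sampling without replacement: argsort of uniforms
        u = rng.random((n_perm, background.size))
        idx = np.argpartition(u, m - 1, axis=1)[:, :m]
        draws = np.sort(background[idx], axis=1)
        null_by_size[m] = np.sort(_rho_from_ranks(draws, alpha))

    rows = []
    for gene, r in gene_ranks.items():
        r = np.sort(np.asarray(r, dtype=float))
        rho = float(_rho_from_ranks(r[None, :], alpha)[0])
        null = null_by_size[len(r)]
        p = (1 + int(np.searchsorted(null, rho, side="right"))) / (n_perm + 1)
        rows.append({"gene": gene, "rra_rho": rho, "p_perm": p})
    return pd.DataFrame(rows).set_index("gene")


def beta_score(guide_lfcs: np.ndarray | pd.Series) -> float:
    """Gene-level effect size: the median of its guides' log2 fold changes."""
    x = np.asarray(guide_lfcs, dtype=float)
    if x.size == 0:
        raise ValueError("no guide LFCs")
    return float(np.median(x))


def combine_pseudo_p(p_a: float, p_b: float) -> float:
    """Fisher combination of two one-sided p-values (chi^2, 4 df).

    The inputs share background samples in this screen design, so the
    result is a pseudo-p-value: a ranking score, not a calibrated p.
    """
    for p in (p_a, p_b):
        if not 0 < p <= 1:
            raise ValueError("p-values must be in (0, 1]")
    x = -2.0 * (np.log(p_a) + np.log(p_b))
    return float(stats.chi2.sf(x, df=4))


@dataclass
class ScreenDesign:
    """Which bins form each comparison, and scoring parameters."""

    high_bin: str = "high"
    low_bin: str = "low"
    rest_bins: tuple[str, ...] = ("unsorted", "low", "medium", "high")
    alpha: float = 0.25
    n_perm: int = 1000
    pseudocount: float = 1.0
    psi_alpha: float = 0.05

    def reference_bins(self, treatment: str) -> tuple[str, ...]:
        return tuple(b for b in self.rest_bins if b != treatment)


def _normalized_ranks(values: pd.Series, ascending: bool) -> pd.Series:
    """Average-tie ranks rescaled to (0, 1]; small rank = extreme value."""
    return values.rank(ascending=ascending, method="average") / len(values)


def _comparison_lfc(
    normalized: pd.DataFrame, table: GuideCountTable, design: ScreenDesign, treatment_bin: str
) -> pd.DataFrame:
    """Per-replicate guide LFC of a bin vs the mean of the other bins."""
    out = {}
    for rep in table.replicates:
        bins = {s.rsplit(":", 1)[1] for s in normalized.columns if s.startswith(f"{rep}:")}
        missing = ({treatment_bin} | set(design.reference_bins(treatment_bin))) - bins
        if missing:
            raise ValueError(f"replicate {rep} missing bins {sorted(missing)}")
        treat = normalized[f"{rep}:{treatment_bin}"]
        ref = normalized[
            [f"{rep}:{b}" for b in design.reference_bins(treatment_bin)]
        ].mean(axis=1)
        out[rep] = guide_lfc(treat, ref, design.pseudocount)
    return pd.DataFrame(out)


def _aggregate_ranks(lfc: pd.DataFrame, enrichment: bool) -> pd.Series:
    """Rank guides per replicate (enriched = top), average, re-normalize."""
    per_rep = pd.DataFrame(
        {rep: _normalized_ranks(lfc[rep], ascending=not enrichment) for rep in lfc.columns}
    )
    return _normalized_ranks(per_rep.mean(axis=1), ascending=True)


def score_screen(
    table: GuideCountTable,
    library: GuideLibrary,
    design: ScreenDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level scores for a paired sorted-bin screen.

    Per replicate, guides are compared high-vs-rest and low-vs-rest; ranks
    are averaged across replicates before alpha-RRA.  Each comparison is
    scored in both directions (enrichment and depletion).  A gene whose
    knockout blocks differentiation leaves cells reporter-low, so its
    evidence is enrichment in the low bin plus depletion in the high bin
    (psi_p_pro_differentiation); the mirrored combination nominates
    pro-progenitor genes.  Safe-targeting guide ranks form the permutation
    background when present.

    Returns one row per target gene: beta_score (median high-vs-rest guide
    LFC), rra_rho / p_perm for the high-bin enrichment, p_high / p_low
    (enrichment p of each bin), both direction pseudo-p combinations, the
    reported psi_p (the smaller), and the direction call at
    ``design.psi_alpha``.
    """
    design = design or ScreenDesign()
    if len(table.replicates) < 2:
        raise ValueError("paired scoring needs >= 2 replicates")
    rng = np.random.default_rng(seed)
    normalized, _ = normalize_counts(table)
    # restrict to guides present in the library
    normalized = normalized.loc[normalized.index.intersection(library.guide_ids)]

    genes = library.target_genes
    safe = [g for g in library.guides_in_category("safe_targeting") if g in normalized.index]

    lfc_high = _comparison_lfc(normalized, table, design, design.high_bin)
    lfc_low = _comparison_lfc(normalized, table, design, design.low_bin)

    rra: dict[tuple[str, bool], pd.DataFrame] = {}
    for name, lfc in (("high", lfc_high), ("low", lfc_low)):
        for enrichment in (True, False):
            ranks = _aggregate_ranks(lfc, enrichment=enrichment)
            gene_ranks = {
                g: ranks.loc[library.guides_for_gene(g)].to_numpy() for g in genes
            }
            background = ranks.loc[safe].to_numpy() if len(safe) >= 20 else None
            rra[(name, enrichment)] = alpha_rra(
                gene_ranks,
                alpha=design.alpha,
                n_perm=design.n_perm,
                seed=rng,
                background=background,
            )

    mean_lfc_high = lfc_high.mean(axis=1)
    rows = []
    for gene in genes:
        guides = library.guides_for_gene(gene)
        p_high = rra[("high", True)].loc[gene, "p_perm"]
        p_low = rra[("low", True)].loc[gene, "p_perm"]
        p_high_dep = rra[("high", False)].loc[gene, "p_perm"]
        p_low_dep = rra[("low", False)].loc[gene, "p_perm"]
        psi_diff = combine_pseudo_p(p_low, p_high_dep)
        psi_prog = combine_pseudo_p(p_high, p_low_dep)
        if psi_diff <= psi_prog:
            psi_p, direction = psi_diff, PRO_DIFFERENTIATION
        else:
            psi_p, direction = psi_prog, PRO_PROGENITOR
        if psi_p > design.psi_alpha:
            direction = NONE
        rows.append(
            {
                "gene": gene,
                "beta_score": beta_score(mean_lfc_high.loc[guides]),
                "rra_rho": rra[("high", True)].loc[gene, "rra_rho"],
                "p_perm": p_high,
                "p_high": p_high,
                "p_low": p_low,
                "p_high_depletion": p_high_dep,
                "p_low_depletion": p_low_dep,
                "psi_p_pro_differentiation": psi_diff,
                "psi_p_pro_progenitor": psi_prog,
                "psi_p": psi_p,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
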