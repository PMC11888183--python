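"""Combine the flow and Perturb-seq arms into one ranked candidate table.

Each arm independently orders genes along the pro-differentiation /
pro-progenitor axis: the flow arm by beta score (median high-bin guide
log2 fold change; negative when knockout keeps the reporter low) and the
Perturb-seq arm by the pseudotime shift Z.  The combined rank is the mean
of the two within-arm ranks with the pro-differentiation direction ranked
low, and the cross-arm agreement is summarized by the Spearman
correlation of beta score and shift Z.  Mean ranks are used rather than a
p-value combination because the two arms' significance measures are
dependent and differently calibrated.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .perturbstats import NONE


def integrate_screens(
    flow_results: pd.DataFrame,
    perturb_results: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Merge per-gene results from the two arms.

    flow_results needs columns beta_score, psi_p, direction (indexed by
    gene); perturb_results needs z_shift, p_shift_adj, classification.
    Only shared genes are ranked (>= 3 required).  Returns the integrated
    table sorted by combined_rank and the Spearman rho between beta_score
    and z_shift.
    """
    shared = flow_results.index.intersection(perturb_results.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared between arms; need >= 3")
    f = flow_results.loc[shared]
    p = perturb_results.loc[shared]
    rho = float(stats.spearmanr(f["beta_score"], p["z_shift"]).statistic)
    flow_rank = f["beta_score"].rank(method="average")  # most negative first
    perturb_rank = p["z_shift"].rank(method="average")
    combined = (flow_rank + perturb_rank) / 2.0
    concordant = (
        (f["direction"] == p["classification"]) & (f["direction"] != NONE)
    )
    out = pd.DataFrame(
        {
            "beta_score": f["beta_score"],
            "psi_p": f["psi_p"],
            "flow_direction": f["direction"],
            "z_shift": p["z_shift"],
            "p_shift_adj": p["p_shift_adj"],
            "perturb_classification": p["classification"],
            "flow_rank": flow_rank,
            "perturb_rank": perturb_rank,
            "combined_rank": combined,
            "concordant": concordant,
        },
        index=shared,
    ).sort_values("combined_rank", kind="stable")
    out.index.name = "gene"
    return out, rho
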