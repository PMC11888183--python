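import numpy as np
import pandas as pd
import pytest

from dualscreen import Effect, GuideLibrary, SimConfig, simulate_library


@pytest.fixture
def tiny_library() -> GuideLibrary:
    """Two target genes x 2 guides plus one control of each class."""
    rng = np.random.default_rng(0)
    spacers = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)]) for _ in range(7)]
    return GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": ["gA_1", "gA_2", "gB_1", "gB_2", "safe_1", "nt_1", "pos_1"],
                "spacer": spacers,
                "target_gene": ["A", "A", "B", "B", "", "", "POS"],
                "category": [
                    "targeting", "targeting", "targeting", "targeting",
                    "safe_targeting", "non_targeting", "positive_control",
                ],
            }
        )
    )


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        n_target_genes=10,
        guides_per_gene=4,
        n_safe_guides=8,
        n_nontarget_guides=4,
        n_cells=800,
        n_expression_genes=80,
        n_progenitor_markers=15,
        n_differentiation_markers=15,
        mean_depth=1500,
        flow_depth=40_000,
        seed=11,
    )


@pytest.fixture
def small_library(small_config) -> GuideLibrary:
    return simulate_library(small_config)


@pytest.fixture
def planted_config() -> SimConfig:
    """One strongly planted pro-differentiation target among nulls."""
    return SimConfig(
        n_target_genes=10,
        guides_per_gene=4,
        n_safe_guides=8,
        n_nontarget_guides=4,
        n_cells=1200,
        n_expression_genes=80,
        n_progenitor_markers=15,
        n_differentiation_markers=15,
        mean_depth=1500,
        flow_depth=60_000,
        effect_map={"GENE001": Effect(delta=-0.4, reporter=-2.0)},
        seed=3,
    )
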