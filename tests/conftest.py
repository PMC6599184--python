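import numpy as np
import pytest

from gutmir.io import MirnaCounts, OtuTable, parse_lineage
from gutmir.simulate import (
    CommunityConfig,
    combine_tables,
    simulate_community,
)


@pytest.fixture(scope="session")
def toy_table() -> OtuTable:
    """Four samples x five OTUs with genus-resolved lineages."""
    lineages = [
        parse_lineage("p_Bacteroidetes;c_Bacteroidia;o_Bacteroidales;"
                      "f_Prevotellaceae;g_Prevotella"),
        parse_lineage("p_Bacteroidetes;c_Bacteroidia;o_Bacteroidales;"
                      "f_Porphyromonadaceae;g_Parabacteroides"),
        parse_lineage("p_Firmicutes;c_Clostridia;o_Clostridiales;"
                      "f_Lachnospiraceae;g_Blautia"),
        parse_lineage("p_Firmicutes;c_Clostridia;o_Clostridiales;"
                      "f_Lachnospiraceae;g_Blautia"),
        parse_lineage("p_Firmicutes;c_Clostridia;o_Clostridiales;f_;g_"),
    ]
    counts = np.array([
        [10, 5, 3, 2, 1],
        [8, 7, 0, 4, 2],
        [0, 12, 6, 1, 3],
        [5, 5, 5, 5, 5],
    ])
    return OtuTable(
        sample_ids=["S1", "S2", "S3", "S4"],
        otu_ids=[f"OTU{i}" for i in range(5)],
        counts=counts,
        lineages=lineages,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact full-factorial study with planted effects.

    Taxon 1 carries a treatment x time effect (-4 log2 in AMP+NEO), taxon 7
    a strain-specific post-treatment shift (three-way interaction).
    """
    cfg = CommunityConfig(
        n_taxa=20,
        seed=42,
        depth_range=(11353, 30000),
        base_log2_taxa={0: 4.0, 1: 4.0, 7: 4.0},  # planted taxa common
        strain_effect_taxa={0: 2.0},
        treatment_effect_taxa={(1, "AMP+NEO"): -4.0},
        strain_interaction_taxa={7: 5.0},  # strain-specific bloom
    )
    pre, post, meta, truth = simulate_community(cfg)
    return combine_tables(pre, post), meta, truth


@pytest.fixture()
def mirna_counts() -> MirnaCounts:
    """Hand-built probe set: 3 endogenous, 4 negatives, 6 positives."""
    counts = np.array([
        [100.0, 200.0, 50.0],
        [30.0, 30.0, 30.0],
        [5.0, 5.0, 5.0],
        [10.0, 10.0, 10.0],
        [10.0, 10.0, 10.0],
        [10.0, 10.0, 10.0],
        [10.0, 10.0, 10.0],
        [8000, 8000, 8000],
        [2000, 2000, 2000],
        [500, 500, 500],
        [125, 125, 125],
        [32, 32, 32],
        [8, 8, 8],
    ])
    return MirnaCounts(
        probe_ids=["miR-a", "miR-b", "miR-c", "NEG0", "NEG1", "NEG2", "NEG3",
                   "POS0", "POS1", "POS2", "POS3", "POS4", "POS5"],
        probe_class=["endogenous"] * 3 + ["negative"] * 4 + ["positive"] * 6,
        sample_ids=["L1", "L2", "L3"],
        counts=counts,
    )
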