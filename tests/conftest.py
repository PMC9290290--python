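import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import triadseq as tq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_counts():
    """Tiny two-genotype count matrix with two replicates each."""
    counts = pd.DataFrame(
        {
            "A_r1": [100, 50, 0, 8],
            "A_r2": [110, 60, 0, 12],
            "B_r1": [100, 50, 0, 8],
            "B_r2": [110, 60, 0, 12],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    lengths = pd.Series([1000, 2000, 500, 1500], index=counts.index)
    return tq.CountMatrix(counts, lengths)


@pytest.fixture
def small_design():
    return tq.SampleDesign(
        pd.DataFrame(
            {
                "genotype": ["A", "A", "B", "B"],
                "role": ["other"] * 4,
                "replicate": [1, 2, 1, 2],
            },
            index=pd.Index(["A_r1", "A_r2", "B_r1", "B_r2"], name="sample_id"),
        )
    )


def make_triad_counts(p1, p2, f1, filler_library=1_000_000):
    """One focal gene plus a filler gene padding each library to a fixed size.

    Gives deterministic single-replicate triads whose focal-gene rates are
    exactly p1/p2/f1 per ``filler_library``.
    """
    counts = pd.DataFrame(
        {
            "P1_r1": [p1, filler_library - p1],
            "P2_r1": [p2, filler_library - p2],
            "F1_r1": [f1, filler_library - f1],
        },
        index=pd.Index(["focal", "filler"], name="gene_id"),
    )
    lengths = pd.Series([1000, 1000], index=counts.index)
    cm = tq.CountMatrix(counts, lengths)
    design = tq.SampleDesign(
        pd.DataFrame(
            {
                "genotype": ["P1", "P2", "F1"],
                "role": ["parent1", "parent2", "hybrid"],
                "replicate": [1, 1, 1],
            },
            index=pd.Index(["P1_r1", "P2_r1", "F1_r1"], name="sample_id"),
        )
    )
    return cm, design
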