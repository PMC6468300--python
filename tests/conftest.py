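import numpy as np
import pandas as pd
import pytest

from screensig.types import NormalizedMatrix, RawCountMatrix


def make_raw(counts: dict[str, list[int]], probe_classes: dict[str, str],
             spike_levels: dict[str, float] | None = None,
             perturbations: dict[str, str] | None = None,
             arm: str = "sirna") -> RawCountMatrix:
    """Assemble a small RawCountMatrix from plain dicts (samples -> columns)."""
    counts_df = pd.DataFrame(counts)
    counts_df.index = list(probe_classes)
    counts_df.index.name = "probe_id"
    spike_levels = spike_levels or {}
    annotation = pd.DataFrame(
        {
            "target_gene": [f"gene_{p}" for p in probe_classes],
            "probe_class": list(probe_classes.values()),
            "spike_level": [spike_levels.get(p, np.nan) for p in probe_classes],
        },
        index=counts_df.index,
    )
    perturbations = perturbations or {}
    design = pd.DataFrame(
        {
            "perturbation_id": [
                perturbations.get(s, "control") for s in counts_df.columns
            ],
            "arm": arm,
            "group": [
                "perturbed" if perturbations.get(s, "control") != "control"
                else "control"
                for s in counts_df.columns
            ],
        },
        index=pd.Index(counts_df.columns, name="sample_id"),
    )
    return RawCountMatrix(counts=counts_df, annotation=annotation, design=design)


@pytest.fixture
def small_screen() -> RawCountMatrix:
    """2 endogenous + 1 housekeeping + 2 positive spikes + 1 negative, 4 samples."""
    classes = {
        "E1": "endogenous",
        "E2": "endogenous",
        "HK1": "housekeeping",
        "POS_A": "positive_spike",
        "POS_B": "positive_spike",
        "NEG_1": "negative_spike",
    }
    counts = {
        "s1": [10, 40, 500, 800, 200, 2],
        "s2": [12, 38, 510, 790, 210, 1],
        "s3": [9, 45, 490, 810, 190, 3],
        "s4": [80, 41, 505, 805, 205, 2],
    }
    return make_raw(
        counts, classes, spike_levels={"POS_A": 8.0, "POS_B": 2.0},
        perturbations={"s3": "pertA", "s4": "pertB"},
    )


def normalized_from_values(values: pd.DataFrame) -> NormalizedMatrix:
    """Wrap plain values as a NormalizedMatrix with unit factors, no background."""
    ones = pd.Series(1.0, index=values.columns)
    return NormalizedMatrix(
        values=values, pos_factors=ones, hk_factors=ones,
        background=pd.Series(0.0, index=values.columns),
    )
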