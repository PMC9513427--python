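"""Shared helpers for the expression-quantification modules."""

from __future__ import annotations

import pandas as pd


class PairingError(ValueError):
    """Target and reference measurements cannot be matched sample-by-sample."""


def mean_tech_cq(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Cq scale.

    Returns one row per (gene, group, bio_rep) with the mean Cq of its
    non-missing technical replicates.  Samples whose wells are all missing
    are dropped here and surface later as pairing errors.
    """
    ok = cq_table.dropna(subset=["cq"])
    agg = (
        ok.groupby(["gene", "group", "bio_rep"], sort=False, as_index=False)["cq"]
        .mean()
    )
    return agg


def geometric_mean(values) -> float:
    """Geometric mean of positive values."""
    import numpy as np

    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.log(arr).mean()))
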