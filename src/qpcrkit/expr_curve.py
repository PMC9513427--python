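"""Expression quantification by inverse prediction from standard curves.

Each gene's mean Cq (over technical replicates) is converted to a relative
quantity through that gene's own standard curve, then normalized to a single
reference gene measured in the same (group, biological replicate).  Because
each gene uses its own curve, this method tolerates unequal amplification
efficiencies between target and reference.
"""

from __future__ import annotations

import warnings

import pandas as pd

from ._util import PairingError, mean_tech_cq
from .standard_curve import CurveFit


class ExtrapolationWarning(UserWarning):
    """A Cq fell outside the range spanned by the standard-curve points."""


def quantity_from_curve(cq: float, fit: CurveFit, extrapolation: str = "warn") -> float:
    """Relative quantity from a Cq via the inverse regression line.

    Returns ``10 ** ((cq - intercept) / slope)``.  A Cq outside the fitted
    points' range triggers an :class:`ExtrapolationWarning` (default) or a
    ValueError in ``extrapolation="forbid"`` mode.
    """
    if extrapolation not in ("warn", "forbid"):
        raise ValueError(f"extrapolation must be 'warn' or 'forbid', got {extrapolation!r}")
    if not fit.valid:
        raise ValueError(f"curve for gene {fit.gene!r} is invalid (slope {fit.slope} >= 0)")
    lo, hi = fit.cq_range
    if not (lo <= cq <= hi):
        msg = (f"Cq {cq:.3f} outside standard-curve range [{lo:.3f}, {hi:.3f}] "
               f"for gene {fit.gene!r}")
        if extrapolation == "forbid":
            raise ValueError(msg)
        warnings.warn(msg, ExtrapolationWarning, stacklevel=2)
    return 10.0 ** ((cq - fit.intercept) / fit.slope)


def expr_by_curve(cq_table: pd.DataFrame, fits: dict, reference_gene: str,
                  extrapolation: str = "warn") -> pd.DataFrame:
    """Per-replicate relative expression via the standard-curve method.

    For every (gene, group, bio_rep): technical-replicate mean Cq -> quantity
    through the gene's curve -> divide by the reference gene's quantity in the
    matching (group, bio_rep).  The reference gene is excluded from the output.

    Returns a DataFrame with columns ``gene, group, bio_rep, rel_expr, method``.
    """
    agg = mean_tech_cq(cq_table)
    genes = agg["gene"].unique().tolist()
    if reference_gene not in genes:
        raise PairingError(f"reference gene {reference_gene!r} not present in the Cq table")
    missing_fits = [g for g in genes if g not in fits]
    if missing_fits:
        raise ValueError(f"no standard curve supplied for genes: {missing_fits}")

    agg = agg.copy()
    agg["quantity"] = [
        quantity_from_curve(cq, fits[g], extrapolation=extrapolation)
        for g, cq in zip(agg["gene"], agg["cq"])
    ]
    ref = agg[agg["gene"] == reference_gene].set_index(["group", "bio_rep"])["quantity"]
    targets = agg[agg["gene"] != reference_gene]

    orphans = [
        (g, grp, rep) for g, grp, rep in
        zip(targets["gene"], targets["group"], targets["bio_rep"])
        if (grp, rep) not in ref.index
    ]
    if orphans:
        raise PairingError(
            f"no reference measurement for (gene, group, bio_rep): {orphans}"
        )
    out = targets.copy()
    out["rel_expr"] = [
        q / ref.loc[(grp, rep)]
        for q, grp, rep in zip(out["quantity"], out["group"], out["bio_rep"])
    ]
    out["method"] = "curve"
    return out[["gene", "group", "bio_rep", "rel_expr", "method"]].reset_index(drop=True)
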