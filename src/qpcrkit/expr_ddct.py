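"""The 2^-ddCt (Livak) relative quantification method.

Per (gene, group, biological replicate):

    dCt  = mean_tech(Cq_target) - mean_tech(Cq_reference)
    ddCt = dCt - mean over control-group replicates of dCt (per gene)
    fold_change = 2 ** -ddCt

The base is exactly 2, i.e. the method assumes both target and reference
amplify with near-100% efficiency; :func:`ddct_admissibility` reports whether
fitted efficiencies support that assumption.  Centering on the control-group
mean dCt makes the *geometric* mean of control fold changes exactly 1.
"""

from __future__ import annotations

import pandas as pd

from ._util import PairingError, mean_tech_cq


def expr_ddct(cq_table: pd.DataFrame, reference_gene: str, control_group: str) -> pd.DataFrame:
    """Per-replicate 2^-ddCt fold changes against a reference gene and control group.

    Returns a DataFrame with columns
    ``gene, group, bio_rep, delta_ct, delta_delta_ct, fold_change, method``;
    the reference gene is excluded from the output.
    """
    agg = mean_tech_cq(cq_table)
    if reference_gene not in set(agg["gene"]):
        raise PairingError(f"reference gene {reference_gene!r} not present in the Cq table")
    if control_group not in set(agg["group"]):
        raise ValueError(f"control group {control_group!r} not present in the Cq table")

    ref = agg[agg["gene"] == reference_gene].set_index(["group", "bio_rep"])["cq"]
    targets = agg[agg["gene"] != reference_gene].copy()

    orphans = [
        (g, grp, rep) for g, grp, rep in
        zip(targets["gene"], targets["group"], targets["bio_rep"])
        if (grp, rep) not in ref.index
    ]
    if orphans:
        raise PairingError(f"no reference Cq for (gene, group, bio_rep): {orphans}")

    targets["delta_ct"] = [
        cq - ref.loc[(grp, rep)]
        for cq, grp, rep in zip(targets["cq"], targets["group"], targets["bio_rep"])
    ]

    out = []
    for gene, sub in targets.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "delta_ct"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no measurements in control group "
                             f"{control_group!r}")
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - ctrl.mean()
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["fold_change"] = 2.0 ** (-res["delta_delta_ct"])
    res["method"] = "ddct"
    return res[["gene", "group", "bio_rep", "delta_ct", "delta_delta_ct",
                "fold_change", "method"]]


def ddct_admissibility(fits: dict, reference_gene: str, tolerance_pct: float = 5.0) -> pd.DataFrame:
    """Advisory check that target and reference efficiencies are close enough.

    For each target gene, flags whether
    ``|efficiency(target) - efficiency(reference)| <= tolerance_pct``.
    Purely informational — the 2^-ddCt computation is never blocked.
    """
    if not fits:
        return pd.DataFrame(columns=["gene", "efficiency_pct", "reference_efficiency_pct",
                                     "abs_diff_pct", "admissible"])
    if reference_gene not in fits:
        raise KeyError(f"no curve fit for reference gene {reference_gene!r}")
    ref_eff = fits[reference_gene].efficiency_pct
    rows = []
    for gene, fit in fits.items():
        if gene == reference_gene:
            continue
        diff = abs(fit.efficiency_pct - ref_eff)
        rows.append({
            "gene": gene,
            "efficiency_pct": fit.efficiency_pct,
            "reference_efficiency_pct": ref_eff,
            "abs_diff_pct": diff,
            "admissible": bool(diff <= tolerance_pct),
        })
    return pd.DataFrame(rows)
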