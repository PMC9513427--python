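"""Efficiency-corrected relative quantification with multiple reference genes.

For each gene g (with amplification factor A_g) and sample s (a group x
biological-replicate combination):

    RQ_{g,s}  = A_g ** (mean_over_samples(Cqbar_g) - Cqbar_{g,s})
    NF_s      = geometric mean over reference genes r of RQ_{r,s}
    NRQ_{g,s} = RQ_{g,s} / NF_s
    nrq_scaled = NRQ / geometric mean of NRQ over control-group replicates

RQ centering on the per-gene all-sample mean Cq is a presentation choice:
after normalization and control scaling any per-gene constant cancels.
Scaling by the *geometric* mean of the control NRQs makes the method reduce
exactly to 2^-ddCt when a single reference is used and every A_g = 2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._util import PairingError, geometric_mean, mean_tech_cq


def amp_factor_from_efficiency_pct(efficiency_pct: float) -> float:
    """Convert efficiency in percent (100 = doubling) to an amplification factor."""
    if efficiency_pct <= -100:
        raise ValueError("efficiency_pct must be > -100")
    return 1.0 + efficiency_pct / 100.0


def expr_rqpcr(cq_table: pd.DataFrame, reference_genes, efficiencies: dict,
               control_group: str) -> pd.DataFrame:
    """Efficiency-corrected normalized relative quantities (NRQ).

    Parameters
    ----------
    reference_genes : list of str
        One or more stably expressed genes; their per-sample quantities are
        combined into a geometric-mean normalization factor.
    efficiencies : dict
        Maps gene name to amplification factor (2.0 = 100% efficiency); use
        :func:`amp_factor_from_efficiency_pct` to convert percentages.
    control_group : str
        Group whose (geometric) mean NRQ anchors ``nrq_scaled`` at 1.

    Returns a DataFrame with columns
    ``gene, group, bio_rep, rq, nf, nrq, nrq_scaled, method`` for target
    genes only (reference genes are excluded from the output).
    """
    reference_genes = list(dict.fromkeys(reference_genes))
    if not reference_genes:
        raise ValueError("at least one reference gene is required")

    agg = mean_tech_cq(cq_table)
    genes = agg["gene"].unique().tolist()
    missing_refs = [r for r in reference_genes if r not in genes]
    if missing_refs:
        raise PairingError(f"reference genes absent from the Cq table: {missing_refs}")
    if control_group not in set(agg["group"]):
        raise ValueError(f"control group {control_group!r} not present in the Cq table")
    for g in genes:
        if g not in efficiencies:
            raise ValueError(f"no amplification factor supplied for gene {g!r}")
        if efficiencies[g] < 1:
            raise ValueError(f"amplification factor for {g!r} is {efficiencies[g]}; must be >= 1")

    # RQ per gene x sample, centered on the per-gene all-sample mean Cq
    agg = agg.copy()
    agg["rq"] = np.nan
    for gene, sub in agg.groupby("gene", sort=False):
        a = float(efficiencies[gene])
        center = sub["cq"].mean()
        agg.loc[sub.index, "rq"] = a ** (center - sub["cq"])

    samples = agg[["group", "bio_rep"]].drop_duplicates()
    ref_rq = agg[agg["gene"].isin(reference_genes)].set_index(["gene", "group", "bio_rep"])["rq"]
    nf = {}
    for grp, rep in samples.itertuples(index=False):
        try:
            vals = [ref_rq.loc[(r, grp, rep)] for r in reference_genes]
        except KeyError:
            missing = [r for r in reference_genes if (r, grp, rep) not in ref_rq.index]
            raise PairingError(
                f"sample (group={grp!r}, bio_rep={rep!r}) lacks reference genes {missing}"
            ) from None
        nf[(grp, rep)] = geometric_mean(vals)

    targets = agg[~agg["gene"].isin(reference_genes)].copy()
    if targets.empty:
        warnings.warn("every gene in the table is listed as a reference; no targets remain",
                      UserWarning, stacklevel=2)
        return pd.DataFrame(columns=["gene", "group", "bio_rep", "rq", "nf", "nrq",
                                     "nrq_scaled", "method"])
    targets["nf"] = [nf[(grp, rep)] for grp, rep in zip(targets["group"], targets["bio_rep"])]
    targets["nrq"] = targets["rq"] / targets["nf"]

    out = []
    for gene, sub in targets.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "nrq"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no measurements in control group "
                             f"{control_group!r}")
        sub = sub.copy()
        sub["nrq_scaled"] = sub["nrq"] / geometric_mean(ctrl)
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["method"] = "rqpcr"
    return res[["gene", "group", "bio_rep", "rq", "nf", "nrq", "nrq_scaled", "method"]]


def stability_rank(cq_table: pd.DataFrame, candidate_refs, efficiencies: dict) -> pd.DataFrame:
    """Rank candidate reference genes by expression stability across samples.

    Stability is measured as the standard deviation of log2(RQ) across all
    samples; a perfectly stable gene has sd 0 and rank 1.  Advisory only —
    it informs reference choice but gates nothing.
    """
    candidate_refs = list(dict.fromkeys(candidate_refs))
    if len(candidate_refs) < 2:
        raise ValueError("stability ranking needs at least 2 candidate reference genes")
    agg = mean_tech_cq(cq_table)
    rows = []
    for gene in candidate_refs:
        sub = agg[agg["gene"] == gene]
        if sub.empty:
            raise PairingError(f"candidate reference {gene!r} not present in the Cq table")
        a = float(efficiencies[gene])
        rq = a ** (sub["cq"].mean() - sub["cq"])
        rows.append({"gene": gene, "sd_log2_rq": float(np.std(np.log2(rq), ddof=1)),
                     "n_samples": len(sub)})
    out = pd.DataFrame(rows).sort_values("sd_log2_rq", kind="stable").reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out
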