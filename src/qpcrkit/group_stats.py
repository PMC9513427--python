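"""Group statistics for per-replicate expression values.

Two designs are supported: a two-group Welch t-test rendered as significance
stars (ns / * / ** / *** at p < 0.05 / 0.01 / 0.001), and one-way ANOVA
followed by all-pairs Tukey HSD rendered as a compact letter display (groups
sharing a letter are not significantly different at level alpha).

Tests operate on the per-replicate expression values produced by the
quantification methods, never on Cq values; an optional log2 transform is
available for strongly skewed fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: value column used by each quantification method's output
_VALUE_COLS = ("rel_expr", "fold_change", "nrq_scaled", "value")


@dataclass(frozen=True)
class Comparison:
    group_a: str
    group_b: str
    estimate: float  # mean(a) - mean(b)
    statistic: float
    df: float
    p_value: float
    adjusted: bool


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_two_groups(values_a, values_b, alpha: float = 0.05) -> Comparison:
    """Welch two-sided t-test between two groups of replicate values.

    Degenerate convention: if both groups have zero variance and equal means,
    p = 1 (nothing to distinguish).  Groups with fewer than 2 values error.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicate values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return Comparison("a", "b", 0.0, 0.0, float(len(a) + len(b) - 2), 1.0, False)
        raise ValueError("both groups have zero variance but different means; "
                         "a t-test is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return Comparison("a", "b", float(a.mean() - b.mean()), float(res.statistic),
                      float(res.df), float(res.pvalue), False)


def _compact_letter_display(groups, means, sig_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig_pairs`` is a set of frozensets of group pairs that differ
    significantly.  Groups are processed in descending-mean order (ties broken
    by name) so 'a' lands on the highest group; the result satisfies: two
    groups share a letter iff their pair is not in ``sig_pairs``.
    """
    order = sorted(groups, key=lambda g: (-means[g], str(g)))
    columns = [set(order)]
    for pair in sig_pairs:
        g1, g2 = sorted(pair, key=lambda g: order.index(g))
        new_cols = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.append(col - {g1})
                new_cols.append(col - {g2})
            else:
                new_cols.append(col)
        # absorb columns that are subsets of another
        columns = []
        for col in new_cols:
            if any(col < other for other in new_cols if col is not other):
                continue
            if col and col not in columns:
                columns.append(col)
    # letter order: sort columns by the position of their best group
    columns.sort(key=lambda col: min(order.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in order:
            if g in col:
                letters[g] += ch
    return letters


def anova_tukey(values_by_group: dict, alpha: float = 0.05):
    """One-way ANOVA plus all-pairs Tukey HSD with compact letter display.

    Returns ``(anova_p, comparisons, letters)`` where ``comparisons`` is a
    list of :class:`Comparison` with Tukey-adjusted p-values and ``letters``
    maps group name to its letter string.  If every observation is identical
    the convention is ``anova_p = 1`` and a single shared letter.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = {g: np.asarray(list(v), dtype=float) for g, v in values_by_group.items()}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has {len(arr)} values; at least 2 required")
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    pooled = np.concatenate(list(arrays.values()))
    if pooled.var(ddof=0) == 0:
        letters = {g: "a" for g in groups}
        comparisons = [
            Comparison(a, b, 0.0, 0.0, float(len(pooled) - len(groups)), 1.0, True)
            for i, a in enumerate(groups) for b in groups[i + 1:]
        ]
        return 1.0, comparisons, letters

    anova_p = float(stats.f_oneway(*arrays.values()).pvalue)
    hsd = stats.tukey_hsd(*[arrays[g] for g in groups])
    df_resid = float(len(pooled) - len(groups))
    comparisons = []
    sig_pairs = set()
    for i, a in enumerate(groups):
        for j in range(i + 1, len(groups)):
            b = groups[j]
            p = float(hsd.pvalue[i, j])
            comparisons.append(Comparison(a, b, means[a] - means[b],
                                          float(hsd.statistic[i, j]), df_resid, p, True))
            if p < alpha:
                sig_pairs.add(frozenset((a, b)))
    letters = _compact_letter_display(groups, means, sig_pairs)
    return anova_p, comparisons, letters


def summarize(records: pd.DataFrame, stat: str = "anova", alpha: float = 0.05,
              value_col: str | None = None, log2: bool = False) -> pd.DataFrame:
    """Per gene x group summary statistics with significance annotation.

    Parameters
    ----------
    records : DataFrame
        Per-replicate output of any quantification method; the value column
        (``rel_expr``, ``fold_change`` or ``nrq_scaled``) is auto-detected
        unless ``value_col`` is given.
    stat : {"ttest", "anova"}
        ``ttest`` requires exactly 2 groups per gene and labels with stars;
        ``anova`` labels with compact letters.
    log2 : bool
        Test log2-transformed values (summary columns stay on the raw scale).

    Returns one row per gene x group: ``n, mean, sd, se, signif_label`` plus
    the pairwise comparisons serialized in ``.attrs["comparisons"]``.
    """
    if stat not in ("ttest", "anova"):
        raise ValueError(f"stat must be 'ttest' or 'anova', got {stat!r}")
    if value_col is None:
        candidates = [c for c in _VALUE_COLS if c in records.columns]
        if not candidates:
            raise ValueError(f"no expression value column found among {_VALUE_COLS}")
        value_col = candidates[0]

    rows = []
    all_comparisons = []
    for gene, sub in records.groupby("gene", sort=False):
        by_group = {g: s[value_col].to_numpy(float) for g, s in sub.groupby("group", sort=False)}
        tvals = {g: np.log2(v) for g, v in by_group.items()} if log2 else by_group
        if stat == "ttest":
            if len(by_group) != 2:
                raise ValueError(
                    f"gene {gene!r} has {len(by_group)} groups; the t-test needs exactly 2 "
                    f"(use stat='anova' for more)"
                )
            (ga, va), (gb, vb) = tvals.items()
            cmp_ = ttest_two_groups(va, vb, alpha)
            cmp_ = Comparison(ga, gb, cmp_.estimate, cmp_.statistic, cmp_.df,
                              cmp_.p_value, False)
            label = {g: stars(cmp_.p_value) for g in by_group}
            comparisons = [cmp_]
        else:
            _, comparisons, label = anova_tukey(tvals, alpha)
        for g, vals in by_group.items():
            n = len(vals)
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            rows.append({
                "gene": gene, "group": g, "n": n,
                "mean": float(np.mean(vals)), "sd": sd,
                "se": sd / math.sqrt(n),
                "signif_label": label[g],
            })
        for c in comparisons:
            all_comparisons.append({"gene": gene, "group_a": c.group_a, "group_b": c.group_b,
                                    "estimate": c.estimate, "p_value": c.p_value,
                                    "adjusted": c.adjusted})
    out = pd.DataFrame(rows)
    out.attrs["comparisons"] = pd.DataFrame(all_comparisons)
    out.attrs["stat"] = stat
    out.attrs["alpha"] = alpha
    return out
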