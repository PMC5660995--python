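"""Significance screening of log2 relative quantities.

Per gene (and location and control reference) the biological-replicate log2
quantities are grouped by variety, with the control genotype's replicates as
one group, and tested by one-way ANOVA; when the ANOVA p-value falls below
alpha a Tukey HSD post-hoc test assigns adjusted p-values to every pairwise
difference. A variety's ratio is flagged significant when its Tukey-adjusted
comparison against the control is below alpha. No multiple-testing correction
is applied across genes (reported in the run summary).

The log2 transform is what renders relative quantities approximately normal,
so the classical parametric chain applies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import TOLERANT_CONTROL


@dataclass
class AnovaResult:
    """One gene's ANOVA with its (gated) Tukey pairs."""

    gene_id: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)

    def pair_p(self, a: str, b: str) -> float | None:
        for ga, gb, _, p in self.tukey_pairs:
            if {ga, gb} == {a, b}:
                return p
        return None


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA.

    Returns ``(F, df_between, df_within, p)``. Every group needs at least two
    observations. When both the between- and within-group variances are zero
    the F statistic is undefined and NaN is returned for F and p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need ≥ 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs ≥ 2 values")
    n = sum(a.size for a in arrays)
    k = len(arrays)
    df_b, df_w = k - 1, n - k
    grand = np.concatenate(arrays).mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_w == 0.0:
        if ss_b == 0.0:
            return float("nan"), df_b, df_w, float("nan")
        return float("inf"), df_b, df_w, 0.0
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    pairs_with: int | None = None,
) -> list[tuple[str, str, float, float]]:
    """Pairwise mean differences with studentized-range adjusted p-values
    (Tukey-Kramer for unequal group sizes).

    Returns ``(label_a, label_b, mean_a - mean_b, p_adj)``. ``pairs_with``
    restricts the output to pairs involving the group at that index — the
    adjusted p-values are identical to the all-pairs run (the studentized
    range always spans all k groups); skipping unneeded pairs only saves the
    expensive distribution evaluations.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need ≥ 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs ≥ 2 values")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    n = sum(a.size for a in arrays)
    df_w = n - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
    pairs_idx = [
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if pairs_with is None or pairs_with in (i, j)
    ]
    diffs, qs = [], []
    for i, j in pairs_idx:
        diff = arrays[i].mean() - arrays[j].mean()
        se2 = mse / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        diffs.append(float(diff))
        if se2 == 0:
            qs.append(np.inf if diff != 0 else 0.0)
        else:
            qs.append(abs(diff) / math.sqrt(se2))
    padj = sps.studentized_range.sf(np.asarray(qs), k, df_w)
    padj = np.clip(np.nan_to_num(padj, nan=0.0), 0.0, 1.0)
    return [
        (labels[i], labels[j], diffs[m], float(padj[m]))
        for m, (i, j) in enumerate(pairs_idx)
    ]


def anova_with_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    gene_id: str = "",
    pairs_with: int | None = None,
) -> AnovaResult:
    """ANOVA gate followed (only when it passes) by Tukey HSD."""
    f, df_b, df_w, p = one_way_anova(groups)
    pairs: list = []
    if np.isfinite(p) and p < alpha:
        pairs = tukey_hsd(groups, labels, pairs_with=pairs_with)
    return AnovaResult(gene_id, f, df_b, df_w, p, pairs)


def flag_significance(
    summary: pd.DataFrame,
    reps: pd.DataFrame,
    alpha: float = 0.05,
    control_variety: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill the ``significant`` column of a ratio summary table.

    For every (gene, location, control_ref) the groups are the per-variety
    biological-replicate log2 quantities of the stressed samples plus the
    control genotype's control-sample replicates. A variety is flagged when
    the ANOVA gate passes and its Tukey comparison against the control has an
    adjusted p-value below ``alpha``. Varieties with fewer than two usable
    replicates are never flagged (warning recorded in the ANOVA table).

    ``control_variety`` maps a ``control_ref`` label to the genotype holding
    the control samples (default: tolerant_control → TN, otherwise TR).

    Returns the summary with ``significant`` filled and an ANOVA table
    (one row per gene × location × control_ref).
    """
    if control_variety is None:
        control_variety = {}
    summary = summary.copy()
    summary["significant"] = False
    anova_rows = []
    for (gene, loc, cref), sub in reps.groupby(
        ["gene_id", "location", "control_ref"], sort=True
    ):
        ctrl_name = control_variety.get(
            cref, "TN" if cref == TOLERANT_CONTROL else "TR"
        )
        ctrl_vals = sub.loc[
            (sub["variety"] == ctrl_name) & (sub["treatment"] == "control"),
            "log2_ratio",
        ].dropna()
        test = sub[sub["treatment"] != "control"]
        groups, labels, skipped = [], [], []
        for variety, v in test.groupby("variety", sort=True):
            vals = v["log2_ratio"].dropna()
            if len(vals) >= 2:
                groups.append(vals.to_numpy())
                labels.append(variety)
            else:
                skipped.append(variety)
        if len(ctrl_vals) < 2 or not groups:
            anova_rows.append(
                dict(
                    gene_id=gene,
                    location=loc,
                    control_ref=cref,
                    f_stat=np.nan,
                    df_between=0,
                    df_within=0,
                    p_value=np.nan,
                    warning="insufficient replicates",
                )
            )
            continue
        ctrl_label = "__control__"
        res = anova_with_tukey(
            [ctrl_vals.to_numpy(), *groups],
            [ctrl_label, *labels],
            alpha=alpha,
            gene_id=gene,
            pairs_with=0,  # only the variety-vs-control comparisons are used
        )
        if skipped:
            warnings.warn(
                f"{gene}/{loc}/{cref}: varieties {skipped} have < 2 replicates; "
                "significance left False",
                stacklevel=2,
            )
        for variety in labels:
            p_adj = res.pair_p(ctrl_label, variety)
            if p_adj is not None and p_adj < alpha:
                mask = (
                    (summary["gene_id"] == gene)
                    & (summary["location"] == loc)
                    & (summary["control_ref"] == cref)
                    & (summary["variety"] == variety)
                    & (summary["treatment"] != "control")
                )
                summary.loc[mask, "significant"] = True
        anova_rows.append(
            dict(
                gene_id=gene,
                location=loc,
                control_ref=cref,
                f_stat=res.f_stat,
                df_between=res.df_between,
                df_within=res.df_within,
                p_value=res.p_value,
                warning="; ".join(f"{v}: <2 reps" for v in skipped),
            )
        )
    return summary, pd.DataFrame(anova_rows)
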