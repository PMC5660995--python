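"""Stress matrix, tolerance classification and expression summaries.

The stress matrix scores one variety × stress × location cell as the mean
|log2 expression ratio| of the stress's markers that *qualify*: |ratio| above
the threshold (default 1.5) **and** regulated in the expected direction.
A cell with no qualifying gene has an undefined score (NaN) — "no stress
signal" is distinct from "weak signal". Because every qualifying term exceeds
the threshold, a defined score always does too.

Tolerance is called by comparing a variety's per-gene log2 profile over a
stress's markers with the profiles of the tolerant and sensitive reference
genotypes: Pearson similarity to each, with a margin δ below which the call
is indeterminate.

Distribution summaries (five-number + 1.5×IQR whiskers, type-7 quartiles) and
functional-bin aggregates support the global expression-stability and
category-relevance views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import STRESSES, TOLERANT_CONTROL
from .panel import MarkerPanel


@dataclass(frozen=True)
class StressMatrixCell:
    variety: str
    location: str
    stress: str
    score: float  # NaN when no gene qualifies
    n_qualifying: int
    n_assigned: int


@dataclass(frozen=True)
class ToleranceCall:
    variety: str
    location: str
    stress: str
    sim_tolerant: float
    sim_sensitive: float
    margin: float  # sim_tolerant - sim_sensitive
    label: str  # tolerant | sensitive | indeterminate
    n_genes: int
    flag: str = ""


def _qualifies(mean: float, expected: str, threshold: float) -> bool:
    if not np.isfinite(mean) or abs(mean) <= threshold:
        return False
    return mean > 0 if expected == "up" else mean < 0


def stress_score(
    gene_means: Mapping[str, float],
    expected_directions: Mapping[str, str],
    threshold: float = 1.5,
    variety: str = "",
    location: str = "",
    stress: str = "",
) -> StressMatrixCell:
    """Score one variety × location cell for one stress.

    ``gene_means`` maps each assigned marker to its mean log2 ratio;
    ``expected_directions`` maps it to its a-priori direction. A marker
    qualifies when |mean| > threshold with the expected sign; the score is
    the mean of the qualifying |mean| values (NaN when none qualify).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not gene_means:
        raise ValueError("stress panel is empty")
    qual = [
        abs(m)
        for g, m in gene_means.items()
        if _qualifies(m, expected_directions[g], threshold)
    ]
    return StressMatrixCell(
        variety=variety,
        location=location,
        stress=stress,
        score=float(np.mean(qual)) if qual else float("nan"),
        n_qualifying=len(qual),
        n_assigned=len(gene_means),
    )


def build_stress_matrix(
    ratios: pd.DataFrame,
    panel: MarkerPanel,
    threshold: float = 1.5,
    control_ref: str = TOLERANT_CONTROL,
    varieties: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full variety × stress × location stress-matrix grid.

    Returns the cell table and the per-location marginal means over defined
    cells (which makes "location A imposed more stress than location B" a
    computable comparison).
    """
    stresses = sorted(
        {s for g in panel if not g.is_reference for s in g.stress_assignments},
        key=STRESSES.index,
    )
    sub = ratios[
        (ratios["control_ref"] == control_ref) & (ratios["treatment"] != "control")
    ]
    if varieties is not None:
        sub = sub[sub["variety"].isin(list(varieties))]
    cells = []
    for (variety, location), grp in sub.groupby(["variety", "location"], sort=True):
        means = dict(zip(grp["gene_id"], grp["log2_ratio_mean"]))
        for stress in stresses:
            genes = panel.markers_for_stress(stress)
            gene_means = {g.gene_id: means.get(g.gene_id, np.nan) for g in genes}
            expected = {g.gene_id: g.expected_direction for g in genes}
            cells.append(
                stress_score(
                    gene_means,
                    expected,
                    threshold,
                    variety=variety,
                    location=location,
                    stress=stress,
                )
            )
    matrix = pd.DataFrame(
        [c.__dict__ for c in cells],
        columns=["variety", "location", "stress", "score", "n_qualifying",
                 "n_assigned"],
    )
    marginals = (
        matrix.groupby("location", sort=True)["score"]
        .agg(mean_score="mean", n_defined="count")
        .reset_index()
    )
    return matrix, marginals


def classify_tolerance(
    profile: Mapping[str, float] | pd.Series,
    tolerant_ref: Mapping[str, float] | pd.Series,
    sensitive_ref: Mapping[str, float] | pd.Series,
    delta: float = 0.2,
    min_genes: int = 3,
    variety: str = "",
    location: str = "",
    stress: str = "",
) -> ToleranceCall:
    """Call a variety tolerant or sensitive by profile similarity.

    Pearson correlation of the variety's per-gene log2 profile with the
    tolerant and the sensitive reference profiles, over the genes defined in
    all three (pairwise-complete). The call is ``tolerant`` when the margin
    sim_tolerant − sim_sensitive exceeds ``delta``, ``sensitive`` below
    −``delta``, otherwise ``indeterminate``. Fewer than ``min_genes`` common
    genes or a zero-variance profile also yield ``indeterminate``.
    """
    p = pd.Series(dict(profile), dtype=float)
    t = pd.Series(dict(tolerant_ref), dtype=float)
    s = pd.Series(dict(sensitive_ref), dtype=float)
    common = sorted(
        g
        for g in p.index.intersection(t.index).intersection(s.index)
        if np.isfinite(p[g]) and np.isfinite(t[g]) and np.isfinite(s[g])
    )
    nan_call = lambda flag: ToleranceCall(  # noqa: E731
        variety, location, stress, float("nan"), float("nan"), float("nan"),
        "indeterminate", len(common), flag,
    )
    if len(common) < min_genes:
        return nan_call("insufficient data")
    pv, tv, sv = p[common].to_numpy(), t[common].to_numpy(), s[common].to_numpy()
    if np.std(pv) == 0 or np.std(tv) == 0 or np.std(sv) == 0:
        return nan_call("zero-variance profile")
    sim_t = float(np.corrcoef(pv, tv)[0, 1])
    sim_s = float(np.corrcoef(pv, sv)[0, 1])
    margin = sim_t - sim_s
    if margin > delta:
        label = "tolerant"
    elif margin < -delta:
        label = "sensitive"
    else:
        label = "indeterminate"
    return ToleranceCall(variety, location, stress, sim_t, sim_s, margin, label,
                         len(common))


def reference_profiles_from_ratios(
    ratios: pd.DataFrame,
    panel: MarkerPanel,
    tolerant_variety: str = "TN",
    sensitive_variety: str = "TR",
) -> pd.DataFrame:
    """Measured reference-genotype profiles, per location.

    The tolerant profile is the tolerant genotype's stressed expression
    relative to its own control samples (control_ref = tolerant_control), and
    symmetrically for the sensitive genotype. Returns
    ``gene_id, stress, location, tolerant, sensitive``.
    """
    frames = []
    for label, variety, col in (
        (TOLERANT_CONTROL, tolerant_variety, "tolerant"),
        ("sensitive_control", sensitive_variety, "sensitive"),
    ):
        sub = ratios[
            (ratios["control_ref"] == label)
            & (ratios["variety"] == variety)
            & (ratios["treatment"] != "control")
        ][["gene_id", "location", "log2_ratio_mean"]].rename(
            columns={"log2_ratio_mean": col}
        )
        frames.append(sub)
    merged = frames[0].merge(frames[1], on=["gene_id", "location"], how="outer")
    rows = []
    for g in panel:
        if g.is_reference:
            continue
        for stress in g.stress_assignments:
            hit = merged[merged["gene_id"] == g.gene_id]
            for _, r in hit.iterrows():
                rows.append(
                    dict(
                        gene_id=g.gene_id,
                        stress=stress,
                        location=r["location"],
                        tolerant=r["tolerant"],
                        sensitive=r["sensitive"],
                    )
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "stress", "location", "tolerant", "sensitive"]
    )


def classify_all(
    ratios: pd.DataFrame,
    panel: MarkerPanel,
    ref_profiles: pd.DataFrame,
    delta: float = 0.2,
    control_ref: str = TOLERANT_CONTROL,
    varieties: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tolerance calls for every variety × stress × location.

    ``ref_profiles`` carries columns ``gene_id, stress, tolerant, sensitive``
    and optionally ``location`` (location-specific measured profiles); without
    a location column the same profiles are used at every location.
    """
    sub = ratios[
        (ratios["control_ref"] == control_ref) & (ratios["treatment"] != "control")
    ]
    if varieties is not None:
        sub = sub[sub["variety"].isin(list(varieties))]
    per_location_refs = "location" in ref_profiles.columns
    calls = []
    for (variety, location), grp in sub.groupby(["variety", "location"], sort=True):
        means = dict(zip(grp["gene_id"], grp["log2_ratio_mean"]))
        refs = ref_profiles
        if per_location_refs:
            refs = ref_profiles[ref_profiles["location"] == location]
        for stress in STRESSES:
            stress_refs = refs[refs["stress"] == stress]
            if stress_refs.empty:
                continue
            genes = stress_refs["gene_id"].tolist()
            call = classify_tolerance(
                {g: means.get(g, np.nan) for g in genes},
                dict(zip(stress_refs["gene_id"], stress_refs["tolerant"])),
                dict(zip(stress_refs["gene_id"], stress_refs["sensitive"])),
                delta=delta,
                variety=variety,
                location=location,
                stress=stress,
            )
            calls.append(call.__dict__)
    return pd.DataFrame(
        calls,
        columns=["variety", "location", "stress", "sim_tolerant", "sim_sensitive",
                 "margin", "label", "n_genes", "flag"],
    )


def bin_aggregate(
    ratios: pd.DataFrame,
    panel: MarkerPanel,
    control_ref: str = TOLERANT_CONTROL,
    varieties: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean log2 ratio per variety × location × functional bin × a-priori
    direction, with a flag where a bin's observed mean inverts its a-priori
    direction (e.g. a downregulated category found upregulated)."""
    direction = {}
    bins = {}
    for g in panel:
        if g.is_reference:
            continue
        direction[g.gene_id] = g.expected_direction
        if not g.mapman_bin or g.mapman_bin == "not assigned":
            warnings.warn(f"{g.gene_id}: no bin label, using 'unknown'", stacklevel=2)
            bins[g.gene_id] = "unknown"
        else:
            bins[g.gene_id] = g.mapman_bin
    sub = ratios[
        (ratios["control_ref"] == control_ref)
        & (ratios["treatment"] != "control")
        & (ratios["gene_id"].isin(direction))
    ].copy()
    if varieties is not None:
        sub = sub[sub["variety"].isin(list(varieties))]
    sub["mapman_bin"] = sub["gene_id"].map(bins)
    sub["apriori_direction"] = sub["gene_id"].map(direction)
    out = (
        sub.groupby(
            ["variety", "location", "mapman_bin", "apriori_direction"], sort=True
        )["log2_ratio_mean"]
        .agg(mean_log2="mean", n_genes="count")
        .reset_index()
    )
    out = out[out["n_genes"] > 0]
    out["inverted"] = (
        (out["apriori_direction"] == "down") & (out["mean_log2"] > 0)
    ) | ((out["apriori_direction"] == "up") & (out["mean_log2"] < 0))
    return out


def distribution_summary(values: Sequence[float]) -> dict:
    """Five-number summary with 1.5×IQR whiskers and an IQR stability score.

    Quartiles use linear interpolation between order statistics (the common
    type-7 rule). ``stability`` equals the IQR — smaller means the gene set's
    expression is more stable.
    """
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size == 0:
        raise ValueError("need ≥ 1 finite value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = sorted(v[(v < lo_fence) | (v > hi_fence)].tolist())
    return dict(
        n=int(v.size),
        min=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(v.max()),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        stability=float(iqr),
    )


def distribution_table(
    ratios: pd.DataFrame,
    panel: MarkerPanel,
    control_ref: str = TOLERANT_CONTROL,
    varieties: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Distribution summaries per variety × location × a-priori direction."""
    direction = {
        g.gene_id: g.expected_direction for g in panel if not g.is_reference
    }
    sub = ratios[
        (ratios["control_ref"] == control_ref)
        & (ratios["treatment"] != "control")
        & (ratios["gene_id"].isin(direction))
    ].copy()
    if varieties is not None:
        sub = sub[sub["variety"].isin(list(varieties))]
    sub["apriori_direction"] = sub["gene_id"].map(direction)
    rows = []
    for (variety, location, direc), grp in sub.groupby(
        ["variety", "location", "apriori_direction"], sort=True
    ):
        vals = grp["log2_ratio_mean"].dropna()
        if vals.empty:
            continue
        d = distribution_summary(vals)
        d.pop("outliers")
        rows.append(
            dict(variety=variety, location=location, apriori_direction=direc, **d)
        )
    return pd.DataFrame(rows)
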