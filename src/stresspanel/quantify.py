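"""From raw amplification data to normalized log2 expression ratios.

The quantification chain:

1. :func:`call_cq` — baseline-subtract a fluorescence trace (least-squares
   line over cycles 5–17) and report the fractional cycle at which ΔRn
   crosses the 0.2 threshold.
2. :func:`fit_standard_curve` — amplification efficiency from a dilution
   series, ``E = 10^(-1/a) - 1`` with ``a`` the slope of Cq on log10(input);
   QC passes when 100·E lies in 100 ± 10% (slope 3.3 ± 0.33).
3. :func:`aggregate_technical` — mean Cq across technical replicates with a
   dispersion flag.
4. :func:`relative_quantity` / :func:`log2_ratio_table` — efficiency-corrected
   (Pfaffl-style) expression ratio of target over the geometric mean of the
   reference-gene normalization factors, sample versus control genotype, on
   the log2 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SENSITIVE_CONTROL, TOLERANT_CONTROL
from .synthdata import FluorTrace, _interp_crossing

NO_AMP = float("nan")


class InvalidTraceError(ValueError):
    """Trace already above threshold at cycle 1 — no baseline region."""


def call_cq(
    trace: FluorTrace,
    baseline_window: tuple[int, int] = (5, 17),
    rn_threshold: float = 0.2,
) -> float:
    """Call the quantification cycle of one fluorescence trace.

    A least-squares line is fitted to Rn over the (1-based, inclusive)
    ``baseline_window``; ΔRn is the residual fluorescence and Cq the first
    fractional cycle at which ΔRn crosses ``rn_threshold`` from below,
    linearly interpolated between the bracketing integer cycles.

    Returns NaN (no-amplification) when the threshold is never reached, and
    raises :class:`InvalidTraceError` when ΔRn is already above threshold at
    cycle 1.
    """
    lo, hi = baseline_window
    if rn_threshold <= 0:
        raise ValueError("rn_threshold must be > 0")
    if lo < trace.cycles[0] or hi > trace.cycles[-1] or lo >= hi:
        raise ValueError(f"baseline window {baseline_window} outside trace cycles")
    in_window = (trace.cycles >= lo) & (trace.cycles <= hi)
    slope, intercept = np.polyfit(trace.cycles[in_window], trace.rn[in_window], 1)
    delta_rn = trace.rn - (intercept + slope * trace.cycles)
    if delta_rn[0] >= rn_threshold:
        raise InvalidTraceError(
            f"{trace.well_id}: ΔRn above threshold already at cycle 1"
        )
    cq = _interp_crossing(delta_rn, rn_threshold)
    return NO_AMP if cq is None else float(cq)


@dataclass(frozen=True)
class StandardCurveFit:
    """Dilution-series regression and the derived amplification efficiency."""

    gene_id: str
    slope_a: float  # cycles per log10(input)
    intercept_b: float
    r2: float
    efficiency_E: float  # fraction; 1.0 = perfect doubling
    qc_pass: bool

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.efficiency_E


def efficiency_from_slope(slope_a: float) -> float:
    """``E = 10^(-1/a) - 1`` — per-cycle gain minus one from the slope of the
    Cq-versus-log10(input) regression."""
    return 10.0 ** (-1.0 / slope_a) - 1.0


def fit_standard_curve(
    dilution_points: pd.DataFrame | Iterable[tuple[float, float]],
    gene_id: str = "",
    efficiency_range_pct: tuple[float, float] = (90.0, 110.0),
) -> StandardCurveFit:
    """Fit a standard curve (OLS of Cq on log10 input quantity).

    ``dilution_points`` is a DataFrame with columns ``quantity, cq`` or an
    iterable of ``(quantity, cq)`` pairs; quantities must be positive and at
    least three distinct dilutions are required.
    """
    if isinstance(dilution_points, pd.DataFrame):
        qty = np.asarray(dilution_points["quantity"], dtype=float)
        cq = np.asarray(dilution_points["cq"], dtype=float)
    else:
        pts = list(dilution_points)
        qty = np.array([p[0] for p in pts], dtype=float)
        cq = np.array([p[1] for p in pts], dtype=float)
    if np.any(qty <= 0):
        raise ValueError("input quantities must be > 0")
    if len(np.unique(qty)) < 3:
        raise ValueError("need ≥ 3 distinct input quantities")
    x = np.log10(qty)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(input)")
    fit = sps.linregress(x, cq)
    eff = efficiency_from_slope(fit.slope)
    lo, hi = efficiency_range_pct
    return StandardCurveFit(
        gene_id=gene_id,
        slope_a=float(fit.slope),
        intercept_b=float(fit.intercept),
        r2=float(fit.rvalue**2),
        efficiency_E=float(eff),
        qc_pass=bool(lo <= 100.0 * eff <= hi),
    )


# ---------------------------------------------------------------------------
# replicate aggregation


@dataclass(frozen=True)
class TechAggregate:
    cq: float  # NaN when every technical replicate failed to amplify
    n_used: int
    high_spread: bool  # spread of amplifying replicates exceeded the flag limit
    partial: bool  # some technical replicates were no-amplification


def aggregate_technical(
    cq_values: Sequence[float], spread_flag: float = 0.5
) -> TechAggregate:
    """Mean Cq across one bio-rep's technical replicates.

    No-amplification replicates (NaN) are dropped; if all are missing the
    biological replicate is itself no-amplification. A QC flag is raised when
    the spread of the amplifying replicates exceeds ``spread_flag`` cycles.
    """
    vals = np.asarray(list(cq_values), dtype=float)
    if vals.size == 0:
        raise ValueError("need ≥ 1 technical replicate")
    ok = vals[np.isfinite(vals)]
    if ok.size == 0:
        return TechAggregate(NO_AMP, 0, False, True)
    return TechAggregate(
        cq=float(ok.mean()),
        n_used=int(ok.size),
        high_spread=bool(ok.size > 1 and np.ptp(ok) > spread_flag),
        partial=bool(ok.size < vals.size),
    )


def aggregate_technical_table(
    wells: pd.DataFrame, spread_flag: float = 0.5
) -> pd.DataFrame:
    """Vectorised technical aggregation of a long-format well table.

    Returns one row per gene × sample (variety, location, treatment, bio_rep)
    with columns ``cq, n_tech_used, high_spread, partial``.
    """
    keys = ["gene_id", "variety", "location", "treatment", "bio_rep"]
    grouped = wells.groupby(keys, sort=True)["cq"]
    agg = grouped.agg(
        cq="mean",
        n_tech_used="count",
        n_tech="size",
        _min="min",
        _max="max",
    ).reset_index()
    agg["high_spread"] = (agg["n_tech_used"] > 1) & (
        (agg["_max"] - agg["_min"]) > spread_flag
    )
    agg["partial"] = agg["n_tech_used"] < agg["n_tech"]
    return agg.drop(columns=["_min", "_max", "n_tech"])


# ---------------------------------------------------------------------------
# relative quantification


def relative_quantity(
    target_cq_sample: float,
    target_cq_control: float,
    ref_cq_sample: Mapping[str, float],
    ref_cq_control: Mapping[str, float],
    efficiencies: Mapping[str, float] | None = None,
    target_gene: str = "target",
) -> float:
    """Efficiency-corrected expression ratio of one target gene,
    sample versus control, normalized to the reference genes.

    ratio = (1+E_t)^(Cq_control,t − Cq_sample,t)
            / geomean_r (1+E_r)^(Cq_control,r − Cq_sample,r)

    Any missing Cq (NaN) makes the ratio undefined (NaN).
    """
    if set(ref_cq_sample) != set(ref_cq_control):
        raise ValueError("reference-gene sets differ between sample and control")
    eff = efficiencies or {}

    def _e(gene: str) -> float:
        return eff.get(gene, 1.0)

    log2r = (target_cq_control - target_cq_sample) * math.log2(1.0 + _e(target_gene))
    ref_terms = [
        (ref_cq_control[g] - ref_cq_sample[g]) * math.log2(1.0 + _e(g))
        for g in sorted(ref_cq_sample)
    ]
    if not ref_terms:
        raise ValueError("need ≥ 1 reference gene")
    log2r -= float(np.mean(ref_terms))
    return float(2.0**log2r)


@dataclass(frozen=True)
class ControlSet:
    """Which samples constitute one control genotype's control group."""

    label: str  # tolerant_control | sensitive_control
    variety: str
    treatment: str = "control"


def default_control_sets(
    tolerant_variety: str = "TN", sensitive_variety: str = "TR"
) -> dict[str, ControlSet]:
    return {
        TOLERANT_CONTROL: ControlSet(TOLERANT_CONTROL, tolerant_variety),
        SENSITIVE_CONTROL: ControlSet(SENSITIVE_CONTROL, sensitive_variety),
    }


def log2_ratio_table(
    wells: pd.DataFrame,
    reference_genes: Sequence[str],
    controls: Mapping[str, ControlSet],
    efficiencies: Mapping[str, float] | None = None,
    tech_spread_flag: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 expression ratios against each control genotype.

    For every control set the control Cq of a gene is the mean across the
    control samples' biological replicates (after technical aggregation).
    Each sample bio-rep then yields one log2 ratio (target ΔCq term minus the
    mean reference-gene ΔCq term, all efficiency-weighted); ratios are
    aggregated to mean / sd / n across biological replicates.

    Returns
    -------
    summary : DataFrame
        ``gene_id, variety, location, treatment, control_ref, log2_ratio_mean,
        log2_ratio_sd, n_bio, significant`` (significance filled later by the
        stats stage; sd is NaN when n_bio < 2).
    reps : DataFrame
        the per-bio-rep log2 ratios behind the summary.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("need ≥ 1 reference gene")
    eff = dict(efficiencies or {})
    agg = aggregate_technical_table(wells, spread_flag=tech_spread_flag)
    log2w = {g: math.log2(1.0 + eff.get(g, 1.0)) for g in agg["gene_id"].unique()}
    agg["_w"] = agg["gene_id"].map(log2w)

    rep_frames = []
    for label in sorted(controls):
        cs = controls[label]
        ctrl = agg[(agg["variety"] == cs.variety) & (agg["treatment"] == cs.treatment)]
        if ctrl.empty:
            raise ValueError(f"no control samples for {label} ({cs.variety})")
        ctrl_cq = (
            ctrl.groupby(["gene_id", "location"])["cq"].mean().rename("ctrl_cq")
        )
        d = agg.merge(ctrl_cq, on=["gene_id", "location"], how="left")
        missing = d.loc[d["ctrl_cq"].isna(), "gene_id"].unique()
        if len(missing):
            warnings.warn(
                f"{label}: no control Cq for genes {sorted(missing)}; "
                "their ratios are undefined",
                stacklevel=2,
            )
        d["term"] = (d["ctrl_cq"] - d["cq"]) * d["_w"]

        is_ref = d["gene_id"].isin(reference_genes)
        ref_norm = (
            d[is_ref]
            .groupby(["variety", "location", "treatment", "bio_rep"])["term"]
            .agg(ref_norm="mean", n_ref_used="count", n_ref="size")
            .reset_index()
        )
        # a missing reference-gene Cq makes the whole bio-rep undefined
        ref_norm.loc[ref_norm["n_ref_used"] < len(reference_genes), "ref_norm"] = np.nan
        d = d.merge(
            ref_norm[["variety", "location", "treatment", "bio_rep", "ref_norm"]],
            on=["variety", "location", "treatment", "bio_rep"],
            how="left",
        )
        d["log2_ratio"] = d["term"] - d["ref_norm"]
        d["control_ref"] = label
        rep_frames.append(
            d[
                [
                    "gene_id",
                    "variety",
                    "location",
                    "treatment",
                    "bio_rep",
                    "control_ref",
                    "log2_ratio",
                    "high_spread",
                    "partial",
                ]
            ]
        )
    reps = pd.concat(rep_frames, ignore_index=True)

    keys = ["gene_id", "variety", "location", "treatment", "control_ref"]
    summary = (
        reps.groupby(keys, sort=True)["log2_ratio"]
        .agg(log2_ratio_mean="mean", log2_ratio_sd="std", n_bio="count")
        .reset_index()
    )
    summary.loc[summary["n_bio"] < 2, "log2_ratio_sd"] = np.nan
    summary["significant"] = False
    return summary, reps
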