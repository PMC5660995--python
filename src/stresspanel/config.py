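"""Run-level configuration shared by every pipeline stage.

All analysis parameters live in one dataclass so that a run can be described,
echoed into reports and replayed from a single YAML file. Cycle indices are
1-based and the baseline window is inclusive on both ends.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Labels used for the two control genotypes throughout the package.
TOLERANT_CONTROL = "tolerant_control"
SENSITIVE_CONTROL = "sensitive_control"

#: Recognised stress treatments: water, heat, light and combined field stress.
STRESSES = ("WS", "HS", "LS", "FIELD")

#: Marker-match gates for panel selection.
GATES = ("sign", "sign+significant", "sign+threshold")


@dataclass
class RunConfig:
    """Parameters of a full analysis run.

    Parameters
    ----------
    baseline_window
        Inclusive 1-based cycle interval used to fit the fluorescence
        baseline before Cq calling (default ``(5, 17)``).
    rn_threshold
        ΔRn threshold crossed at the quantification cycle (default ``0.2``).
    efficiency_range_pct
        Acceptable amplification-efficiency band in percent
        (default ``(90, 110)``, i.e. 100 ± 10%).
    alpha
        Significance level for the ANOVA gate and the Tukey post-hoc test.
    matrix_threshold
        |log2 ratio| a gene must exceed (with the expected sign) to qualify
        for the stress matrix (default ``1.5``).
    tech_spread_flag
        Technical-replicate Cq spread (cycles) above which a QC flag is
        raised (default ``0.5``).
    margin_delta
        Minimum difference between the tolerant and sensitive similarity
        required for a confident tolerance call (default ``0.2``).
    gate
        Marker-match gate for panel selection; one of ``sign``,
        ``sign+significant``, ``sign+threshold``.
    min_effect
        Minimum |log2 ratio| for a variety to count as matching under the
        ``sign`` gate (default ``0.0``).
    control_variety_ids
        Mapping from control label (``tolerant_control`` / ``sensitive_control``)
        to the genotype name carrying the control samples.
    reference_gene_ids
        Reference (normalisation) genes; overrides the panel's
        ``is_reference`` flags when non-empty.
    seed
        Seed echoed into reports; used by stages that simulate.
    """

    baseline_window: tuple[int, int] = (5, 17)
    rn_threshold: float = 0.2
    efficiency_range_pct: tuple[float, float] = (90.0, 110.0)
    alpha: float = 0.05
    matrix_threshold: float = 1.5
    tech_spread_flag: float = 0.5
    margin_delta: float = 0.2
    gate: str = "sign"
    min_effect: float = 0.0
    control_variety_ids: dict = field(
        default_factory=lambda: {TOLERANT_CONTROL: "TN", SENSITIVE_CONTROL: "TR"}
    )
    reference_gene_ids: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference_gene_ids = tuple(self.reference_gene_ids)
        lo, hi = self.baseline_window
        if not (1 <= lo < hi):
            raise ValueError(f"invalid baseline window {self.baseline_window}")
        if self.rn_threshold <= 0:
            raise ValueError("rn_threshold must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.matrix_threshold <= 0:
            raise ValueError("matrix_threshold must be > 0")
        if self.gate not in GATES:
            raise ValueError(f"gate must be one of {GATES}, got {self.gate!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_window"] = list(self.baseline_window)
        d["efficiency_range_pct"] = list(self.efficiency_range_pct)
        d["reference_gene_ids"] = list(self.reference_gene_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "baseline_window" in kwargs:
            kwargs["baseline_window"] = tuple(kwargs["baseline_window"])
        if "efficiency_range_pct" in kwargs:
            kwargs["efficiency_range_pct"] = tuple(kwargs["efficiency_range_pct"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)
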