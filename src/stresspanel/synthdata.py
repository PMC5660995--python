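"""Synthetic qPCR experiment generator.

The study design emulated here is a field survey of grapevine varieties on a
custom stress array: a marker panel (plus stable reference genes) measured in
``n_varieties`` genotypes at two locations, three biological replicates and
two technical replicates per sample, alongside the two well-characterised
reference genotypes — a tolerant control (TN-like) and a sensitive control
(TR-like) — whose unstressed plants provide the control samples that anchor
relative quantification.

Sign convention (used everywhere in this package): upregulation by ``d`` log2
units lowers Cq by ``d`` cycles; the generator assumes 100% amplification
efficiency. The noise model is additive Gaussian on the Cq scale: biological
noise is drawn once per biological sample and gene (shared by that sample's
technical replicates), technical noise is i.i.d. per well. Cq values above
``dropout_cq_limit`` are recorded as no-amplification (missing).

Ground truth (the planted log2 effects) is always emitted next to the data so
every downstream stage can be tested against the generative model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import STRESSES

ARCHETYPES = ("tolerant", "sensitive", "mixed")

#: Stresses on which a "mixed" variety responds like the tolerant archetype;
#: on the remaining stresses it responds like the sensitive archetype.
MIXED_TOLERANT_STRESSES = frozenset({"WS", "LS"})


@dataclass(frozen=True)
class GeneSpec:
    """One panel entry with its planted per-stress effects.

    ``effects`` maps a stress label to ``(effect_tolerant, effect_sensitive)``
    in log2 units (positive = upregulated under stress relative to unstressed
    control plants). Reference genes carry no effects.
    """

    gene_id: str
    baseline_cq: float
    is_reference: bool = False
    expected_direction: str | None = None  # "up" | "down" | None
    stresses: tuple[str, ...] = ()
    mapman_bin: str = "not assigned"
    effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_reference:
            if self.stresses or self.expected_direction is not None:
                raise ValueError(
                    f"reference gene {self.gene_id} must not carry a direction "
                    "or stress assignments"
                )
            if any(e != (0.0, 0.0) for e in self.effects.values()):
                raise ValueError(
                    f"reference gene {self.gene_id} must have all effects = 0"
                )
        else:
            if not self.stresses:
                raise ValueError(f"marker gene {self.gene_id} needs ≥ 1 stress")
            if self.expected_direction not in ("up", "down"):
                raise ValueError(
                    f"marker gene {self.gene_id} needs expected_direction up/down"
                )
            unknown = set(self.stresses) - set(STRESSES)
            if unknown:
                raise ValueError(f"unknown stress labels {sorted(unknown)}")


@dataclass
class SimulationConfig:
    """Stated world of one synthetic experiment.

    ``variety_archetypes`` assigns each test genotype a stress-response
    archetype; the two control genotypes are always simulated in addition,
    with stressed samples (tolerant / sensitive archetype) and unstressed
    control samples.
    """

    genes: Sequence[GeneSpec]
    variety_archetypes: Mapping[str, str]
    stress_intensity: Mapping[str, Mapping[str, float]]  # location -> stress -> x
    n_bio: int = 3
    n_tech: int = 2
    sd_bio: float = 0.3
    sd_tech: float = 0.15
    dropout_cq_limit: float = 38.0
    n_cycles: int = 40
    tolerant_control: str = "TN"
    sensitive_control: str = "TR"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_bio < 0 or self.sd_tech < 0:
            raise ValueError("noise SDs must be ≥ 0")
        for variety, arch in self.variety_archetypes.items():
            if arch not in ARCHETYPES:
                raise ValueError(f"unknown archetype {arch!r} for {variety}")
        for loc, per_stress in self.stress_intensity.items():
            for stress, x in per_stress.items():
                if stress not in STRESSES:
                    raise ValueError(f"unknown stress {stress!r} in {loc}")
                if x < 0:
                    raise ValueError("stress intensities must be ≥ 0")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("need ≥ 1 biological and technical replicate")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_id in panel")

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(self.stress_intensity)


@dataclass
class CqDataset:
    """A simulated plate experiment plus its ground truth.

    Attributes
    ----------
    wells
        Long-format well table (one row per technical replicate) with the
        columns of the Cq-table CSV dialect.
    ground_truth
        Planted per-stress log2 effects:
        ``gene_id, variety, location, stress, planted_log2_effect``.
    cell_archetypes
        Resolved archetype per variety × stress (mixed varieties resolved
        stress-by-stress): ``variety, stress, archetype``.
    ref_profiles
        Planted reference-genotype profiles at unit stress intensity:
        ``gene_id, stress, tolerant, sensitive``.
    config
        The :class:`SimulationConfig` that generated the dataset.
    """

    wells: pd.DataFrame
    ground_truth: pd.DataFrame
    cell_archetypes: pd.DataFrame
    ref_profiles: pd.DataFrame
    config: SimulationConfig

    def total_effects(self) -> pd.DataFrame:
        """Planted total log2 ratio per gene × variety × location.

        This is what the quantification pipeline recovers: the sum over a
        gene's assigned stresses of archetype effect × location intensity.
        """
        out = (
            self.ground_truth.groupby(
                ["gene_id", "variety", "location"], as_index=False, sort=True
            )["planted_log2_effect"]
            .sum()
            .rename(columns={"planted_log2_effect": "planted_total_log2"})
        )
        return out


def _archetype_for(variety: str, archetype: str, stress: str) -> str:
    if archetype == "mixed":
        return "tolerant" if stress in MIXED_TOLERANT_STRESSES else "sensitive"
    return archetype


def resolve_cell_archetypes(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for variety, arch in config.variety_archetypes.items():
        for stress in STRESSES:
            rows.append((variety, stress, _archetype_for(variety, arch, stress)))
    return pd.DataFrame(rows, columns=["variety", "stress", "archetype"])


def simulate_experiment(config: SimulationConfig) -> CqDataset:
    """Simulate a full Cq experiment under the additive Gaussian Cq model.

    For every gene g, variety v, location l, biological replicate b and
    technical replicate t::

        Cq = baseline_cq(g)
             - sum over s in stresses(g) of effect(g, s, archetype(v, s)) * intensity(l, s)
             + bio_noise(g, v, l, b) + tech_noise

    Reference genes and unstressed control samples receive noise only.
    Cq values above ``dropout_cq_limit`` become no-amplification (NaN).
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    arch_idx = {"tolerant": 0, "sensitive": 1}

    # stressed samples for test varieties and both control genotypes
    stressed = dict(config.variety_archetypes)
    stressed.setdefault(config.tolerant_control, "tolerant")
    stressed.setdefault(config.sensitive_control, "sensitive")

    rows: list[tuple] = []
    truth: list[tuple] = []
    for location in config.locations:
        intensity = config.stress_intensity[location]
        samples: list[tuple[str, str, float | None]] = []  # (variety, treatment, _)
        for variety in stressed:
            samples.append((variety, "stressed"))
        for variety in (config.tolerant_control, config.sensitive_control):
            samples.append((variety, "control"))

        for gene in genes:
            for variety, treatment in samples:
                if treatment == "control" or gene.is_reference:
                    effect = 0.0
                else:
                    arch = stressed[variety]
                    effect = 0.0
                    for stress in gene.stresses:
                        a = _archetype_for(variety, arch, stress)
                        e = gene.effects.get(stress, (0.0, 0.0))[arch_idx[a]]
                        effect += e * intensity.get(stress, 0.0)
                for bio in range(1, config.n_bio + 1):
                    bio_noise = rng.normal(0.0, config.sd_bio) if config.sd_bio else 0.0
                    for tech in range(1, config.n_tech + 1):
                        tech_noise = (
                            rng.normal(0.0, config.sd_tech) if config.sd_tech else 0.0
                        )
                        cq = gene.baseline_cq - effect + bio_noise + tech_noise
                        rows.append(
                            (
                                f"{location}",
                                f"w{len(rows) % 96:02d}",
                                gene.gene_id,
                                f"{variety}:{location}:{treatment}:b{bio}",
                                variety,
                                location,
                                treatment,
                                bio,
                                tech,
                                np.nan if cq > config.dropout_cq_limit else cq,
                            )
                        )
        for gene in genes:
            if gene.is_reference:
                continue
            for variety in stressed:
                arch = stressed[variety]
                for stress in gene.stresses:
                    a = _archetype_for(variety, arch, stress)
                    e = gene.effects.get(stress, (0.0, 0.0))[arch_idx[a]]
                    truth.append(
                        (
                            gene.gene_id,
                            variety,
                            location,
                            stress,
                            e * intensity.get(stress, 0.0),
                        )
                    )

    wells = pd.DataFrame(
        rows,
        columns=[
            "plate",
            "well",
            "gene_id",
            "sample_id",
            "variety",
            "location",
            "treatment",
            "bio_rep",
            "tech_rep",
            "cq",
        ],
    )
    ground_truth = pd.DataFrame(
        truth,
        columns=["gene_id", "variety", "location", "stress", "planted_log2_effect"],
    )

    ref_rows = []
    for gene in genes:
        if gene.is_reference:
            continue
        for stress in gene.stresses:
            tol, sen = gene.effects.get(stress, (0.0, 0.0))
            ref_rows.append((gene.gene_id, stress, tol, sen))
    ref_profiles = pd.DataFrame(
        ref_rows, columns=["gene_id", "stress", "tolerant", "sensitive"]
    )

    return CqDataset(
        wells=wells,
        ground_truth=ground_truth,
        cell_archetypes=resolve_cell_archetypes(config),
        ref_profiles=ref_profiles,
        config=config,
    )


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass
class FluorTrace:
    """Raw fluorescence of one well: Rn per 1-based cycle, no gaps."""

    well_id: str
    cycles: np.ndarray
    rn: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.rn = np.asarray(self.rn, dtype=float)
        if self.cycles.ndim != 1 or self.rn.shape != self.cycles.shape:
            raise ValueError("cycles and rn must be 1-D arrays of equal length")
        if len(self.cycles) == 0 or self.cycles[0] != 1:
            raise ValueError("cycles must start at 1")
        if not np.all(np.diff(self.cycles) == 1):
            raise ValueError("cycles must be consecutive integers")
        if not np.all(np.isfinite(self.rn)):
            raise ValueError("rn must be finite")


def _interp_crossing(values: np.ndarray, threshold: float) -> float | None:
    """First fractional 1-based cycle at which `values` crosses `threshold`
    from below, linearly interpolated between the bracketing integer cycles."""
    above = values >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))  # first index at/above threshold
    if i == 0:
        return 1.0
    lo, hi = values[i - 1], values[i]
    return i + (threshold - lo) / (hi - lo)  # cycles are 1-based: index i -> cycle i+1


def simulate_trace(
    true_cq: float,
    plateau: float = 3.0,
    slope_k: float = 0.8,
    baseline_drift: float = 0.0,
    baseline_level: float = 0.05,
    noise_sd: float = 0.0,
    n_cycles: int = 40,
    rn_threshold: float = 0.2,
    baseline_window: tuple[int, int] = (5, 17),
    seed: int | None = None,
    well_id: str = "sim",
) -> FluorTrace:
    """Simulate one amplification curve whose called Cq equals ``true_cq``.

    The amplification component is a logistic sigmoid
    ``plateau / (1 + exp(-k (c - c0)))``; ``c0`` is calibrated numerically so
    that the full Cq-calling procedure — least-squares baseline over
    ``baseline_window``, then linear interpolation of the threshold crossing
    between integer cycles — returns exactly ``true_cq``. A linear baseline
    (level + drift·cycle) is added on top; being linear, it is absorbed by
    the caller's baseline fit without shifting the crossing.

    A plateau at or below the threshold yields a designed-negative trace
    (never crosses; Cq calling reports no-amplification).
    """
    if plateau <= 0:
        raise ValueError("plateau must be > 0")
    if not (baseline_window[1] + 1 <= true_cq <= n_cycles - 1):
        raise ValueError(
            "true_cq must lie between the end of the baseline window and the "
            "last cycle"
        )
    cycles = np.arange(1, n_cycles + 1)
    in_window = (cycles >= baseline_window[0]) & (cycles <= baseline_window[1])

    if plateau <= rn_threshold:  # designed negative: threshold unreachable
        c0 = true_cq
    else:

        def called(c0: float) -> float:
            s = plateau / (1.0 + np.exp(-slope_k * (cycles - c0)))
            coef = np.polyfit(cycles[in_window], s[in_window], 1)
            delta = s - np.polyval(coef, cycles)
            cq = _interp_crossing(delta, rn_threshold)
            return np.inf if cq is None else cq

        c0_cont = true_cq + math.log(plateau / rn_threshold - 1.0) / slope_k
        lo, hi = c0_cont - 2.0, c0_cont + 2.0
        c0 = brentq(lambda c: called(c) - true_cq, lo, hi, xtol=1e-10)

    signal = plateau / (1.0 + np.exp(-slope_k * (cycles - c0)))
    rn = baseline_level + baseline_drift * cycles + signal
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rn = rn + rng.normal(0.0, noise_sd, size=rn.shape)
    return FluorTrace(well_id=well_id, cycles=cycles, rn=rn)


def simulate_dilution_series(
    true_efficiency: float,
    top_cq: float = 20.0,
    n_points: int = 5,
    fold: float = 5.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a standard-curve dilution series.

    Starting from an undiluted input (relative quantity 1) and diluting
    ``fold``-fold per step, each step delays the quantification cycle by
    ``log(fold) / log(1 + E)`` cycles — at 100% efficiency a five-fold step
    costs log2(5) ≈ 2.32 cycles. Returns a table with columns
    ``quantity`` (relative input) and ``cq``.
    """
    if not (0.0 < true_efficiency <= 1.1):
        raise ValueError("true_efficiency must lie in (0, 1.1]")
    if n_points < 3:
        raise ValueError("need ≥ 3 dilution points")
    if fold <= 1.0:
        raise ValueError("fold must be > 1")
    k = np.arange(n_points)
    step = math.log(fold) / math.log(1.0 + true_efficiency)
    cq = top_cq + k * step
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cq = cq + rng.normal(0.0, noise_sd, size=cq.shape)
    return pd.DataFrame({"quantity": fold ** (-k.astype(float)), "cq": cq})


# ---------------------------------------------------------------------------
# default stated world


_BINS = (
    "stress",
    "protein metabolism",
    "secondary metabolism",
    "signalling",
    "transport",
    "regulation",
)

#: (responding archetypes, direction) classes cycled through each stress's
#: markers. Tolerant-only and sensitive-only responders make the two planted
#: archetype profiles distinguishable by correlation; shared responders give
#: every variety a stress signal.
_CLASSES = (
    (("tolerant",), "up"),
    (("sensitive",), "up"),
    (("tolerant", "sensitive"), "up"),
    (("tolerant",), "down"),
    (("sensitive",), "down"),
    (("tolerant", "sensitive"), "down"),
)


def default_genes(
    markers_per_stress: int = 12, effect_size: float = 2.0
) -> list[GeneSpec]:
    """Default panel: 3 reference genes + ``markers_per_stress`` markers for
    each of WS/HS/LS/FIELD, cycling through responder-class × direction."""
    genes: list[GeneSpec] = [
        GeneSpec("ACT", baseline_cq=21.0, is_reference=True),
        GeneSpec("TIF", baseline_cq=22.0, is_reference=True),
        GeneSpec("TIF-GTP", baseline_cq=23.0, is_reference=True),
    ]
    for stress in STRESSES:
        for j in range(markers_per_stress):
            responders, direction = _CLASSES[j % len(_CLASSES)]
            signed = effect_size if direction == "up" else -effect_size
            tol = signed if "tolerant" in responders else 0.0
            sen = signed if "sensitive" in responders else 0.0
            genes.append(
                GeneSpec(
                    gene_id=f"{stress}_{direction}{j + 1:02d}",
                    baseline_cq=23.0 + (j % 7),
                    expected_direction=direction,
                    stresses=(stress,),
                    mapman_bin=_BINS[j % len(_BINS)],
                    effects={stress: (tol, sen)},
                )
            )
    return genes


def default_simulation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default stated world.

    Ten test varieties — five tolerant, five sensitive — measured in two
    locations: a high-stress site (intensity 1.0 on every stress, Pegões-like)
    and a milder site (0.6, Dois Portos-like), with 3 biological × 2 technical
    replicates and conventional qPCR noise (sd_bio 0.3, sd_tech 0.15 cycles).
    """
    varieties = {}
    for i in range(1, 11):
        varieties[f"V{i:02d}"] = "tolerant" if i % 2 else "sensitive"
    defaults = dict(
        genes=default_genes(),
        variety_archetypes=varieties,
        stress_intensity={
            "HighStressSite": {s: 1.0 for s in STRESSES},
            "MildSite": {s: 0.6 for s in STRESSES},
        },
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
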