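"""Marker-panel retention by directional consistency.

A candidate marker carries an a-priori expected regulation direction (up or
down under its assigned stress). Per location, every evaluated variety either
matches that direction or fails it; a gene passes a location when the
failures are *not* a strict majority (fails ≤ floor(V/2) of the V varieties
evaluated there), and is retained only when it passes **every** location —
a marker meant for use across climates must work in all of them. Reference
genes are always retained. The retained markers plus the reference genes form
the final custom array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import GATES, STRESSES, TOLERANT_CONTROL


@dataclass(frozen=True)
class PanelGene:
    """One annotation row of the marker panel."""

    gene_id: str
    probeset_id: str = ""
    annotation: str = ""
    mapman_bin: str = "not assigned"
    expected_direction: str | None = None
    stress_assignments: tuple[str, ...] = ()
    is_reference: bool = False
    direction_source: str = TOLERANT_CONTROL  # control ref the direction refers to

    def __post_init__(self) -> None:
        if self.is_reference:
            if self.expected_direction is not None or self.stress_assignments:
                raise ValueError(
                    f"reference gene {self.gene_id} must carry no direction/stresses"
                )
        else:
            if self.expected_direction not in ("up", "down"):
                raise ValueError(
                    f"{self.gene_id}: expected_direction must be 'up' or 'down', "
                    f"got {self.expected_direction!r}"
                )
            if not self.stress_assignments:
                raise ValueError(f"{self.gene_id}: needs ≥ 1 stress assignment")
            unknown = set(self.stress_assignments) - set(STRESSES)
            if unknown:
                raise ValueError(f"{self.gene_id}: unknown stresses {sorted(unknown)}")


class MarkerPanel:
    """The gene list with directions, stress assignments, bins and flags."""

    def __init__(self, genes: Iterable[PanelGene]):
        self.genes: list[PanelGene] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_id in panel")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> PanelGene:
        return self._by_id[gene_id]

    @property
    def reference_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.is_reference]

    @property
    def marker_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if not g.is_reference]

    def markers_for_stress(self, stress: str) -> list[PanelGene]:
        return [
            g
            for g in self.genes
            if not g.is_reference and stress in g.stress_assignments
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                gene_id=g.gene_id,
                probeset_id=g.probeset_id,
                annotation=g.annotation,
                mapman_bin=g.mapman_bin,
                expected_direction=g.expected_direction or "",
                stress_assignments=";".join(g.stress_assignments),
                is_reference=g.is_reference,
                direction_source=g.direction_source,
            )
            for g in self.genes
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_simulation_genes(cls, genes) -> "MarkerPanel":
        """Build a panel from :class:`stresspanel.synthdata.GeneSpec` entries."""
        out = []
        for g in genes:
            out.append(
                PanelGene(
                    gene_id=g.gene_id,
                    mapman_bin=g.mapman_bin,
                    expected_direction=None if g.is_reference else g.expected_direction,
                    stress_assignments=() if g.is_reference else tuple(g.stresses),
                    is_reference=g.is_reference,
                )
            )
        return cls(out)


@dataclass
class LocationTally:
    n_match: int
    n_fail: int
    evaluable: bool
    pass_location: bool


@dataclass
class ConsistencyReport:
    """Per-location match counts and the retention verdict for one gene."""

    gene_id: str
    per_location: dict[str, LocationTally] = field(default_factory=dict)
    retained: bool = False


def _matches(
    row, expected: str, gate: str, min_effect: float, threshold: float
) -> bool:
    mean = row["log2_ratio_mean"]
    if not np.isfinite(mean):
        return False
    sign_ok = mean > 0 if expected == "up" else mean < 0
    if not sign_ok:
        return False
    if gate == "sign":
        return abs(mean) >= min_effect
    if gate == "sign+threshold":
        return abs(mean) > threshold
    if gate == "sign+significant":
        return bool(row.get("significant", False))
    raise ValueError(f"gate must be one of {GATES}, got {gate!r}")


def evaluate_marker(
    gene: PanelGene,
    ratios: pd.DataFrame,
    gate: str = "sign",
    min_effect: float = 0.0,
    threshold: float = 1.5,
    varieties: Sequence[str] | None = None,
    control_ref: str | None = None,
) -> ConsistencyReport:
    """Tally expected-direction matches for one marker, per location.

    ``ratios`` is the summary ratio table; only stressed samples (treatment
    != control) under the gene's ``direction_source`` control reference are
    evaluated (override with ``control_ref``). ``varieties`` restricts the
    genotypes entering the tally (typically the uncharacterised test set).

    A location with zero evaluable varieties counts as a failed location
    (retention requires evidence in every climate).
    """
    if gene.is_reference:
        raise ValueError(f"{gene.gene_id} is a reference gene")
    cref = control_ref or gene.direction_source
    sub = ratios[
        (ratios["gene_id"] == gene.gene_id)
        & (ratios["control_ref"] == cref)
        & (ratios["treatment"] != "control")
    ]
    if varieties is not None:
        sub = sub[sub["variety"].isin(list(varieties))]
    report = ConsistencyReport(gene_id=gene.gene_id)
    locations = sorted(ratios["location"].unique())
    if not locations:
        raise ValueError("ratio table carries no locations")
    for loc in locations:
        here = sub[sub["location"] == loc]
        here = here[np.isfinite(here["log2_ratio_mean"])]
        if here.empty:
            report.per_location[loc] = LocationTally(0, 0, False, False)
            continue
        n_match = int(
            sum(
                _matches(row, gene.expected_direction, gate, min_effect, threshold)
                for _, row in here.iterrows()
            )
        )
        n_eval = len(here)
        n_fail = n_eval - n_match
        # discard only when failures are a strict majority; ties pass
        report.per_location[loc] = LocationTally(
            n_match, n_fail, True, n_fail <= n_eval // 2
        )
    report.retained = all(t.pass_location for t in report.per_location.values())
    return report


def filter_panel(
    panel: MarkerPanel, reports: Mapping[str, ConsistencyReport]
) -> tuple[MarkerPanel, pd.DataFrame]:
    """Partition the panel into retained and discarded markers.

    Reference genes are always retained. Returns the retained panel and a
    per-gene discard table with the per-location tallies.
    """
    missing = set(panel.marker_ids) - set(reports)
    if missing:
        raise ValueError(f"no consistency report for markers {sorted(missing)}")
    retained, rows = [], []
    for gene in panel:
        if gene.is_reference:
            retained.append(gene)
            continue
        rep = reports[gene.gene_id]
        if rep.retained:
            retained.append(gene)
        for loc, tally in rep.per_location.items():
            rows.append(
                dict(
                    gene_id=gene.gene_id,
                    location=loc,
                    n_match=tally.n_match,
                    n_fail=tally.n_fail,
                    evaluable=tally.evaluable,
                    pass_location=tally.pass_location,
                    retained=rep.retained,
                )
            )
    columns = [
        "gene_id",
        "location",
        "n_match",
        "n_fail",
        "evaluable",
        "pass_location",
        "retained",
    ]
    discard = pd.DataFrame(rows, columns=columns)
    return MarkerPanel(retained), discard


def assemble_array(
    retained: MarkerPanel, reference_genes: Sequence[PanelGene] | None = None
) -> pd.DataFrame:
    """Final array layout: markers grouped by stress assignment, references last.

    ``reference_genes`` may supply the references explicitly (they must then
    be absent from ``retained``); otherwise the retained panel's own reference
    genes are used. Duplicate gene ids across markers and references raise.
    """
    markers = [g for g in retained if not g.is_reference]
    refs = list(reference_genes) if reference_genes is not None else [
        g for g in retained if g.is_reference
    ]
    ids = [g.gene_id for g in markers] + [g.gene_id for g in refs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene_id across markers and references")
    order = {s: i for i, s in enumerate(STRESSES)}

    def marker_key(g: PanelGene):
        return (min(order[s] for s in g.stress_assignments), g.gene_id)

    rows = []
    for g in sorted(markers, key=marker_key):
        rows.append(
            dict(
                slot=len(rows) + 1,
                gene_id=g.gene_id,
                role="marker",
                expected_direction=g.expected_direction,
                stress_assignments=";".join(g.stress_assignments),
                mapman_bin=g.mapman_bin,
            )
        )
    for g in sorted(refs, key=lambda g: g.gene_id):
        rows.append(
            dict(
                slot=len(rows) + 1,
                gene_id=g.gene_id,
                role="reference",
                expected_direction="",
                stress_assignments="",
                mapman_bin=g.mapman_bin,
            )
        )
    columns = [
        "slot",
        "gene_id",
        "role",
        "expected_direction",
        "stress_assignments",
        "mapman_bin",
    ]
    return pd.DataFrame(rows, columns=columns)
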