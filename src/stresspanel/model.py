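"""Model/Results facade over the full analysis chain.

:class:`StressArrayModel` is built from the data of one experiment — a
long-format well table and a marker panel, plus an optional
:class:`~stresspanel.config.RunConfig` — and :meth:`StressArrayModel.fit`
runs quantification, significance screening, panel selection, the stress
matrix and tolerance classification, returning a
:class:`StressArrayResults` that carries every stage's table and a text
``summary()``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as spio
from .config import RunConfig, SENSITIVE_CONTROL, TOLERANT_CONTROL
from .panel import MarkerPanel, assemble_array, evaluate_marker, filter_panel
from .quantify import ControlSet, StandardCurveFit, log2_ratio_table
from .stats import flag_significance
from .stressmatrix import (
    bin_aggregate,
    build_stress_matrix,
    classify_all,
    distribution_table,
    reference_profiles_from_ratios,
)


class StressArrayModel:
    """Relative-quantification model of one custom-array experiment.

    Parameters
    ----------
    wells
        Long-format well table (one technical replicate per row) with the
        Cq-table columns.
    panel
        The marker panel (directions, stress assignments, bins, reference
        flags).
    config
        Analysis parameters; defaults follow the standard run configuration.
    curves
        Optional per-gene standard-curve fits supplying amplification
        efficiencies (genes without a curve are treated as 100% efficient).
        Curves failing efficiency QC raise unless ``allow_failed_curves``.
    ref_profiles
        Optional externally supplied reference-genotype profiles
        (``gene_id, stress, tolerant, sensitive`` [, ``location``]); when
        absent the profiles are measured from the data's own reference
        genotypes.
    """

    def __init__(
        self,
        wells: pd.DataFrame,
        panel: MarkerPanel,
        config: RunConfig | None = None,
        curves: Sequence[StandardCurveFit] | None = None,
        ref_profiles: pd.DataFrame | None = None,
        allow_failed_curves: bool = False,
    ):
        self.wells = wells
        self.panel = panel
        self.config = config or RunConfig()
        self.curves = list(curves or [])
        failed = [c.gene_id for c in self.curves if not c.qc_pass]
        if failed and not allow_failed_curves:
            raise ValueError(
                f"standard curves outside the efficiency QC band: {failed}"
            )
        self.ref_profiles = ref_profiles
        refs = list(self.config.reference_gene_ids) or panel.reference_ids
        if not refs:
            raise ValueError("no reference genes in panel or config")
        self.reference_genes = refs
        missing = [g for g in refs if g not in set(wells["gene_id"])]
        if missing:
            raise ValueError(f"reference genes absent from dataset: {missing}")

    @classmethod
    def from_files(
        cls,
        cq_csv,
        panel_tsv,
        config: RunConfig | None = None,
        ref_profiles_tsv=None,
    ) -> "StressArrayModel":
        wells = spio.read_cq_table(cq_csv)
        panel = spio.read_panel(panel_tsv)
        profiles = (
            spio.read_ref_profiles(ref_profiles_tsv) if ref_profiles_tsv else None
        )
        return cls(wells, panel, config=config, ref_profiles=profiles)

    @classmethod
    def from_simulation(cls, dataset, config: RunConfig | None = None,
                        **kwargs) -> "StressArrayModel":
        """Build from a :class:`stresspanel.synthdata.CqDataset`."""
        panel = MarkerPanel.from_simulation_genes(dataset.config.genes)
        config = config or RunConfig(
            control_variety_ids={
                TOLERANT_CONTROL: dataset.config.tolerant_control,
                SENSITIVE_CONTROL: dataset.config.sensitive_control,
            },
            seed=dataset.config.seed,
        )
        return cls(dataset.wells, panel, config=config, **kwargs)

    @property
    def control_sets(self) -> dict[str, ControlSet]:
        ids = self.config.control_variety_ids
        return {
            label: ControlSet(label, variety) for label, variety in sorted(ids.items())
        }

    @property
    def test_varieties(self) -> list[str]:
        controls = set(self.config.control_variety_ids.values())
        return sorted(set(self.wells["variety"]) - controls)

    def fit(self, run_stats: bool = True) -> "StressArrayResults":
        """Run the full chain and return the results object.

        ``run_stats=False`` skips the ANOVA/Tukey screening (the
        ``significant`` column stays False), which is useful for large
        simulation sweeps where only ratio means are needed.
        """
        cfg = self.config
        efficiencies = {c.gene_id: c.efficiency_E for c in self.curves}
        ratios, reps = log2_ratio_table(
            self.wells,
            self.reference_genes,
            self.control_sets,
            efficiencies=efficiencies,
            tech_spread_flag=cfg.tech_spread_flag,
        )
        anova = None
        if run_stats:
            ratios, anova = flag_significance(
                ratios,
                reps,
                alpha=cfg.alpha,
                control_variety=dict(cfg.control_variety_ids),
            )

        reports = {
            g.gene_id: evaluate_marker(
                g,
                ratios,
                gate=cfg.gate,
                min_effect=cfg.min_effect,
                threshold=cfg.matrix_threshold,
                varieties=self.test_varieties,
            )
            for g in self.panel
            if not g.is_reference
        }
        retained, discard = filter_panel(self.panel, reports)
        array = assemble_array(retained)

        matrix, marginals = build_stress_matrix(
            ratios,
            retained,
            threshold=cfg.matrix_threshold,
            varieties=self.test_varieties,
        )
        profiles = self.ref_profiles
        if profiles is None:
            profiles = reference_profiles_from_ratios(
                ratios,
                self.panel,
                tolerant_variety=cfg.control_variety_ids[TOLERANT_CONTROL],
                sensitive_variety=cfg.control_variety_ids[SENSITIVE_CONTROL],
            )
        calls = classify_all(
            ratios,
            self.panel,
            profiles,
            delta=cfg.margin_delta,
            varieties=self.test_varieties,
        )
        bins = bin_aggregate(ratios, self.panel, varieties=self.test_varieties)
        dists = distribution_table(ratios, self.panel, varieties=self.test_varieties)

        return StressArrayResults(
            model=self,
            ratios=ratios,
            reps=reps,
            anova=anova,
            consistency=discard,
            retained_panel=retained,
            array=array,
            stress_matrix=matrix,
            location_marginals=marginals,
            tolerance_calls=calls,
            bin_means=bins,
            distributions=dists,
            ref_profiles_used=profiles,
        )


@dataclass
class StressArrayResults:
    """All stage outputs of one fitted experiment."""

    model: StressArrayModel
    ratios: pd.DataFrame
    reps: pd.DataFrame
    anova: pd.DataFrame | None
    consistency: pd.DataFrame
    retained_panel: MarkerPanel
    array: pd.DataFrame
    stress_matrix: pd.DataFrame
    location_marginals: pd.DataFrame
    tolerance_calls: pd.DataFrame
    bin_means: pd.DataFrame
    distributions: pd.DataFrame
    ref_profiles_used: pd.DataFrame = field(default=None)

    @property
    def n_retained_markers(self) -> int:
        return len(self.retained_panel.marker_ids)

    @property
    def n_discarded_markers(self) -> int:
        return len(self.model.panel.marker_ids) - self.n_retained_markers

    def summary(self) -> str:
        """Human-readable run summary."""
        buf = _io.StringIO()
        cfg = self.model.config
        n_total = len(self.model.panel.marker_ids)
        n_ref = len(self.model.panel.reference_ids)
        buf.write("Custom stress-array analysis\n")
        buf.write("=" * 60 + "\n")
        buf.write(
            f"Candidate markers: {n_total}  retained: {self.n_retained_markers}  "
            f"discarded: {self.n_discarded_markers}\n"
        )
        buf.write(
            f"Array slots: {len(self.array)} "
            f"({self.n_retained_markers} markers + {n_ref} references)\n"
        )
        buf.write(
            f"Gate: {cfg.gate} (min_effect {cfg.min_effect}); "
            f"matrix threshold {cfg.matrix_threshold}; "
            f"classification margin δ {cfg.margin_delta}\n"
        )
        buf.write("No multiple-testing correction across genes.\n\n")

        buf.write("Per-location mean stress score (defined cells):\n")
        for _, r in self.location_marginals.iterrows():
            buf.write(
                f"  {r['location']:>16}: {r['mean_score']:.3f} "
                f"(n={int(r['n_defined'])})\n"
            )
        if not self.tolerance_calls.empty:
            counts = (
                self.tolerance_calls.groupby("label")["variety"].count().to_dict()
            )
            buf.write("\nTolerance calls (variety × stress × location cells):\n")
            for label in ("tolerant", "sensitive", "indeterminate"):
                buf.write(f"  {label:>13}: {counts.get(label, 0)}\n")
        return buf.getvalue()

    def save(self, out_dir) -> None:
        """Write every stage table (TSV) and the bundled JSON report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spio.write_tsv(self.ratios, out / "ratios.tsv")
        if self.anova is not None:
            spio.write_tsv(self.anova, out / "anova.tsv")
        spio.write_tsv(self.consistency, out / "consistency.tsv")
        spio.write_panel(self.retained_panel, out / "retained_panel.tsv")
        spio.write_tsv(self.array, out / "array.tsv")
        spio.write_tsv(self.stress_matrix, out / "stress_matrix.tsv")
        spio.write_tsv(self.tolerance_calls, out / "tolerance_calls.tsv")
        spio.write_tsv(self.bin_means, out / "bin_means.tsv")
        spio.write_tsv(self.distributions, out / "distributions.tsv")
        spio.write_report(
            {
                "panel": {
                    "n_candidates": len(self.model.panel.marker_ids),
                    "n_retained": self.n_retained_markers,
                    "n_discarded": self.n_discarded_markers,
                    "array_slots": len(self.array),
                },
                "location_marginals": self.location_marginals,
                "tolerance_calls": self.tolerance_calls,
                "anova": None
                if self.anova is None
                else {"n_tests": int(len(self.anova))},
            },
            self.model.config,
            out / "report.json",
        )
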