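"""Majority-rule marker retention and array assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import stresspanel as sp
from stresspanel.panel import (
    ConsistencyReport,
    MarkerPanel,
    PanelGene,
    assemble_array,
    evaluate_marker,
    filter_panel,
)
from stresspanel.synthdata import GeneSpec

from conftest import make_ratio_table, small_config


def marker(gene_id="m1", direction="down", stresses=("WS",), **kw):
    return PanelGene(gene_id=gene_id, expected_direction=direction,
                     stress_assignments=stresses, **kw)


def ratio_rows(gene_id, means_by_location):
    rows = []
    for loc, means in means_by_location.items():
        for i, m in enumerate(means, start=1):
            rows.append((gene_id, f"V{i:02d}", loc, m))
    return make_ratio_table(rows)


class TestPanelGene:
    def test_reference_with_direction_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            PanelGene("ACT", is_reference=True, expected_direction="up")

    def test_marker_needs_direction_and_stress(self):
        with pytest.raises(ValueError, match="direction"):
            PanelGene("m", expected_direction="sideways", stress_assignments=("WS",))
        with pytest.raises(ValueError, match="stress"):
            PanelGene("m", expected_direction="up")


class TestEvaluateMarker:
    def test_minority_failures_pass(self):
        """Expected down, 7 of 10 negative: 3 fails is not a majority."""
        ratios = ratio_rows("m1", {"A": [-2, -1, -3, -0.5, -2, -1, -2, 1, 2, 0.5]})
        rep = evaluate_marker(marker(), ratios)
        tally = rep.per_location["A"]
        assert (tally.n_match, tally.n_fail) == (7, 3)
        assert rep.retained

    def test_exact_half_failures_pass(self):
        """Five fails out of ten is not *more* than half: the gene survives."""
        ratios = ratio_rows("m1", {"A": [1, 1, 1, 1, 1, -1, -1, -1, -1, -1]})
        rep = evaluate_marker(marker(direction="up"), ratios)
        assert rep.per_location["A"].n_fail == 5
        assert rep.retained

    def test_failure_in_one_location_discards(self):
        """Matching 8/10 in one climate cannot rescue 0/10 in the other."""
        ratios = ratio_rows(
            "m1",
            {"A": [-1] * 10, "B": [2, 2, 2, 2, 2, 2, 2, 2, -1, -1]},
        )
        rep = evaluate_marker(marker(direction="up"), ratios)
        assert not rep.per_location["A"].pass_location
        assert rep.per_location["B"].pass_location
        assert not rep.retained

    def test_non_evaluable_location_counts_as_fail(self):
        ratios = ratio_rows("m1", {"A": [2] * 6})
        other = ratio_rows("other", {"B": [1] * 6})
        rep = evaluate_marker(marker(direction="up"),
                              pd.concat([ratios, other], ignore_index=True))
        assert not rep.per_location["B"].evaluable
        assert not rep.retained

    def test_threshold_gate(self):
        ratios = ratio_rows("m1", {"A": [2.0, 1.0, 0.4, 1.7]})
        rep = evaluate_marker(marker(direction="up"), ratios,
                              gate="sign+threshold", threshold=1.5)
        assert rep.per_location["A"].n_match == 2

    def test_significance_gate(self):
        rows = ratio_rows("m1", {"A": [2.0, 1.8, 1.9, 1.7]})
        rows.loc[rows.variety.isin(["V01", "V02"]), "significant"] = False
        rep = evaluate_marker(marker(direction="up"), rows,
                              gate="sign+significant")
        assert rep.per_location["A"].n_match == 2

    def test_variety_order_invariance(self):
        means = [2, -1, 2, 2, -2, 2]
        base = ratio_rows("m1", {"A": means})
        rep1 = evaluate_marker(marker(direction="up"), base)
        shuffled = base.sample(frac=1.0, random_state=4).reset_index(drop=True)
        rep2 = evaluate_marker(marker(direction="up"), shuffled)
        assert rep1.per_location["A"] == rep2.per_location["A"]

    @given(min_effect=st.floats(0.0, 3.0))
    def test_match_gate_monotone(self, min_effect):
        """Raising min_effect can only shrink the match count."""
        rng = np.random.default_rng(8)
        ratios = ratio_rows("m1", {"A": rng.normal(1.0, 1.5, 10).tolist()})
        base = evaluate_marker(marker(direction="up"), ratios, min_effect=0.0)
        tight = evaluate_marker(marker(direction="up"), ratios,
                                min_effect=min_effect)
        assert tight.per_location["A"].n_match <= base.per_location["A"].n_match


class TestFilterPanel:
    def _panel(self):
        return MarkerPanel([
            PanelGene("ACT", is_reference=True),
            marker("m1"), marker("m2", direction="up"),
        ])

    def test_all_pass_identity(self):
        panel = self._panel()
        reports = {
            g: ConsistencyReport(g, retained=True) for g in ("m1", "m2")
        }
        retained, discard = filter_panel(panel, reports)
        assert retained.marker_ids == ["m1", "m2"]
        assert retained.reference_ids == ["ACT"]

    def test_empty_marker_panel(self):
        panel = MarkerPanel([PanelGene("ACT", is_reference=True)])
        retained, discard = filter_panel(panel, {})
        assert retained.marker_ids == []
        assert discard.empty

    def test_missing_report_rejected(self):
        with pytest.raises(ValueError, match="m2"):
            filter_panel(self._panel(), {"m1": ConsistencyReport("m1")})

    def test_planted_fault_recovery_single_run(self):
        """Markers planted against their expected direction are discarded."""
        genes = [
            GeneSpec("ACT", 21.0, is_reference=True),
            GeneSpec("TIF", 22.0, is_reference=True),
            GeneSpec("TIF-GTP", 23.0, is_reference=True),
            GeneSpec("good_up", 24.0, expected_direction="up", stresses=("WS",),
                     mapman_bin="stress", effects={"WS": (2.0, 2.0)}),
            GeneSpec("good_dn", 25.0, expected_direction="down", stresses=("HS",),
                     mapman_bin="transport", effects={"HS": (-2.0, -2.0)}),
            GeneSpec("bad_up", 26.0, expected_direction="up", stresses=("LS",),
                     mapman_bin="stress", effects={"LS": (-2.0, -2.0)}),
        ]
        ds = sp.simulate_experiment(small_config(seed=13, genes=genes))
        res = sp.StressArrayModel.from_simulation(ds).fit(run_stats=False)
        assert set(res.retained_panel.marker_ids) == {"good_up", "good_dn"}


class TestAssembleArray:
    def _markers(self, n):
        stresses = ("WS", "HS", "LS", "FIELD")
        return [
            marker(f"m{i:02d}", direction="up" if i % 2 else "down",
                   stresses=(stresses[i % 4],))
            for i in range(n)
        ]

    def _refs(self):
        return [PanelGene(g, is_reference=True) for g in ("ACT", "TIF", "TIF-GTP")]

    def test_forty_five_markers_plus_three_references(self):
        array = assemble_array(MarkerPanel(self._markers(45) + self._refs()))
        assert len(array) == 48
        assert (array["role"] == "reference").sum() == 3
        # references occupy the last slots
        assert array.tail(3)["role"].eq("reference").all()
        # markers are grouped by stress
        stress_order = array[array.role == "marker"]["stress_assignments"]
        firsts = [s.split(";")[0] for s in stress_order]
        assert firsts == sorted(firsts, key=("WS", "HS", "LS", "FIELD").index)

    def test_references_only(self):
        array = assemble_array(MarkerPanel(self._refs()))
        assert len(array) == 3

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_array(MarkerPanel(self._markers(3)),
                           reference_genes=[PanelGene("m00", is_reference=True)])
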