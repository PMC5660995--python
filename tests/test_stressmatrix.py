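"""Stress matrix scores, tolerance classification and summary views."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import stresspanel as sp
from stresspanel.panel import MarkerPanel, PanelGene
from stresspanel.stressmatrix import (
    bin_aggregate,
    build_stress_matrix,
    classify_tolerance,
    distribution_summary,
    reference_profiles_from_ratios,
    stress_score,
)

from conftest import make_ratio_table


class TestStressScore:
    def test_hand_enumerated_example(self):
        """Down at −2.0/−1.2, up at +2.6, inverted up at −3.0, threshold 1.5:
        only |−2.0| and |2.6| qualify → score 2.3."""
        cell = stress_score(
            {"a": -2.0, "b": -1.2, "c": 2.6, "d": -3.0},
            {"a": "down", "b": "down", "c": "up", "d": "up"},
            threshold=1.5,
        )
        assert cell.score == pytest.approx(2.3)
        assert (cell.n_qualifying, cell.n_assigned) == (2, 4)

    def test_nothing_exceeds_threshold_undefined(self):
        cell = stress_score({"a": 0.0, "b": 0.0}, {"a": "up", "b": "down"}, 1.5)
        assert np.isnan(cell.score) and cell.n_qualifying == 0

    def test_single_qualifying_gene(self):
        cell = stress_score({"a": 1.6}, {"a": "up"}, 1.5)
        assert cell.score == pytest.approx(1.6)

    @given(st.lists(st.floats(-6, 6), min_size=1, max_size=12))
    def test_defined_score_exceeds_threshold(self, means):
        """A defined score is a mean of terms each > threshold, so it is too."""
        gene_means = {f"g{i}": m for i, m in enumerate(means)}
        directions = {f"g{i}": ("up" if i % 2 else "down") for i in range(len(means))}
        cell = stress_score(gene_means, directions, threshold=1.5)
        if cell.n_qualifying:
            assert cell.score > 1.5
        else:
            assert np.isnan(cell.score)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            stress_score({}, {}, 1.5)


def two_marker_panel():
    return MarkerPanel([
        PanelGene("ACT", is_reference=True),
        PanelGene("u", expected_direction="up", stress_assignments=("WS",)),
        PanelGene("d", expected_direction="down", stress_assignments=("WS",)),
    ])


class TestBuildStressMatrix:
    def test_noise_free_location_monotonicity(self):
        """Uniformly stronger stress intensity yields cell-wise ≥ scores."""
        from conftest import small_config
        from stresspanel.config import STRESSES

        cfg = small_config(
            seed=1, sd_bio=0.0, sd_tech=0.0,
            stress_intensity={
                "SiteA": {s: 1.0 for s in STRESSES},
                "SiteB": {s: 0.9 for s in STRESSES},
            },
        )
        res = sp.StressArrayModel.from_simulation(
            sp.simulate_experiment(cfg)
        ).fit(run_stats=False)
        wide = res.stress_matrix.pivot_table(
            index=["variety", "stress"], columns="location", values="score"
        )
        both = wide.dropna()
        assert len(both) > 0
        assert (both["SiteA"] >= both["SiteB"] - 1e-12).all()

    def test_empty_ratio_table_all_undefined(self):
        ratios = make_ratio_table([("u", "V01", "A", 2.0)]).iloc[0:0]
        matrix, marginals = build_stress_matrix(ratios, two_marker_panel())
        assert matrix.empty

    def test_threshold_above_everything_undefined(self):
        ratios = make_ratio_table([("u", "V01", "A", 2.0), ("d", "V01", "A", -2.0)])
        matrix, _ = build_stress_matrix(ratios, two_marker_panel(), threshold=10.0)
        assert matrix["score"].isna().all()
        assert (matrix["n_qualifying"] == 0).all()


class TestClassifyTolerance:
    TOL = {"a": 2.0, "b": 0.1, "c": -1.5, "d": 0.5}
    SEN = {"a": 0.2, "b": 2.2, "c": 0.3, "d": -1.8}

    def test_identical_to_tolerant_reference(self):
        call = classify_tolerance(self.TOL, self.TOL, self.SEN)
        assert call.sim_tolerant == pytest.approx(1.0)
        assert call.label == "tolerant"

    def test_identical_to_sensitive_reference(self):
        call = classify_tolerance(self.SEN, self.TOL, self.SEN)
        assert call.label == "sensitive"

    def test_equidistant_profile_indeterminate(self):
        mid = {g: (self.TOL[g] + self.SEN[g]) / 2 for g in self.TOL}
        call = classify_tolerance(mid, self.TOL, self.SEN, delta=0.2)
        assert abs(call.margin) < 0.2
        assert call.label == "indeterminate"

    def test_too_few_common_genes(self):
        call = classify_tolerance({"a": 1.0, "b": 2.0}, self.TOL, self.SEN)
        assert call.label == "indeterminate"
        assert call.flag == "insufficient data"

    def test_zero_variance_profile(self):
        flat = {g: 1.0 for g in self.TOL}
        call = classify_tolerance(flat, self.TOL, self.SEN)
        assert call.label == "indeterminate"
        assert call.flag == "zero-variance profile"

    def test_gene_order_and_missing_gene_invariance(self):
        base = classify_tolerance(self.TOL, self.TOL, self.SEN)
        reordered = dict(reversed(list(self.TOL.items())))
        extra = {**reordered, "zz": np.nan}  # missing everywhere: excluded
        again = classify_tolerance(extra, self.TOL, self.SEN)
        assert again.sim_tolerant == pytest.approx(base.sim_tolerant)
        assert again.n_genes == base.n_genes


class TestClassifyAll:
    def test_recovers_archetypes_noise_free(self, noise_free_dataset,
                                            noise_free_results):
        calls = noise_free_results.tolerance_calls
        merged = calls.merge(noise_free_dataset.cell_archetypes,
                             on=["variety", "stress"])
        assert len(merged) > 0
        assert (merged["label"] == merged["archetype"]).all()

    def test_measured_reference_profiles_match_planted(self, noise_free_dataset,
                                                       noise_free_results):
        panel = MarkerPanel.from_simulation_genes(noise_free_dataset.config.genes)
        measured = reference_profiles_from_ratios(noise_free_results.ratios, panel)
        high = measured[measured.location == "HighStressSite"]
        planted = noise_free_dataset.ref_profiles
        j = high.merge(planted, on=["gene_id", "stress"], suffixes=("_m", "_p"))
        assert np.allclose(j["tolerant_m"], j["tolerant_p"], atol=1e-9)
        assert np.allclose(j["sensitive_m"], j["sensitive_p"], atol=1e-9)


class TestBinAggregate:
    def _panel(self):
        return MarkerPanel([
            PanelGene("u1", expected_direction="up", stress_assignments=("WS",),
                      mapman_bin="stress"),
            PanelGene("u2", expected_direction="up", stress_assignments=("WS",),
                      mapman_bin="stress"),
            PanelGene("d1", expected_direction="down", stress_assignments=("WS",),
                      mapman_bin="transport"),
        ])

    def test_bin_mean(self):
        ratios = make_ratio_table([
            ("u1", "V01", "A", 2.0), ("u2", "V01", "A", 4.0),
            ("d1", "V01", "A", -1.0),
        ])
        out = bin_aggregate(ratios, self._panel())
        stress = out[out.mapman_bin == "stress"].iloc[0]
        assert stress["mean_log2"] == pytest.approx(3.0)
        assert not stress["inverted"]

    def test_apriori_down_bin_upregulated_flagged(self):
        ratios = make_ratio_table([("d1", "V01", "A", 1.2)])
        out = bin_aggregate(ratios, self._panel())
        assert bool(out.iloc[0]["inverted"])

    def test_weighted_bin_means_conserve_overall_mean(self):
        rng = np.random.default_rng(2)
        rows = [(g, "V01", "A", float(rng.normal())) for g in ("u1", "u2", "d1")]
        ratios = make_ratio_table(rows)
        out = bin_aggregate(ratios, self._panel())
        weighted = (out["mean_log2"] * out["n_genes"]).sum() / out["n_genes"].sum()
        assert weighted == pytest.approx(ratios["log2_ratio_mean"].mean())

    def test_unlabelled_gene_goes_to_unknown(self):
        panel = MarkerPanel([
            PanelGene("x", expected_direction="up", stress_assignments=("WS",)),
        ])
        ratios = make_ratio_table([("x", "V01", "A", 1.0)])
        with pytest.warns(UserWarning, match="unknown"):
            out = bin_aggregate(ratios, panel)
        assert out.iloc[0]["mapman_bin"] == "unknown"


class TestDistributionSummary:
    def test_five_number_summary(self):
        d = distribution_summary([1, 2, 3, 4, 5])
        assert (d["q1"], d["median"], d["q3"], d["iqr"]) == (2, 3, 4, 2)
        assert d["whisker_low"] == 1 and d["whisker_high"] == 5
        assert d["outliers"] == []

    def test_constant_vector_maximally_stable(self):
        d = distribution_summary([2.0] * 6)
        assert d["iqr"] == 0 and d["stability"] == 0

    def test_single_value(self):
        d = distribution_summary([3.3])
        assert d["min"] == d["q1"] == d["median"] == d["q3"] == d["max"] == 3.3

    def test_outlier_detection(self):
        d = distribution_summary([1, 2, 3, 4, 5, 40])
        assert d["outliers"] == [40]
        assert d["whisker_high"] == 5
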