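import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunodyn.errors import ConfigurationError, PairingError, ValidationError
from immunodyn.feature_extraction import (DEFAULT_CELL_TYPES,
                                          DEFAULT_FUNCTIONAL_MARKERS,
                                          EventTable, FeatureMatrix,
                                          PanelConfig, arcsinh_transform,
                                          compute_basal_signaling,
                                          compute_frequencies,
                                          compute_stim_response,
                                          extract_features, feature_id)

from .conftest import make_events


class TestArcsinhTransform:
    def test_zero(self):
        assert arcsinh_transform(0, 5) == 0.0

    def test_closed_form(self):
        # asinh(1) = ln(1 + sqrt(2))
        assert arcsinh_transform(5, 5) == pytest.approx(
            math.log(1 + math.sqrt(2)), abs=1e-9)
        assert arcsinh_transform(5, 5) == pytest.approx(0.881374, abs=1e-6)

    @given(st.tuples(st.floats(0, 1e6), st.floats(0, 1e6)).filter(
        lambda t: t[0] != t[1]))
    @settings(max_examples=200, deadline=None)
    def test_strictly_monotone(self, pair):
        lo, hi = sorted(pair)
        assert arcsinh_transform(lo, 5) < arcsinh_transform(hi, 5)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            arcsinh_transform(-1.0, 5)

    def test_bad_cofactor(self):
        with pytest.raises(ConfigurationError):
            arcsinh_transform(1.0, 0)


class TestPanelConfig:
    def test_default_sizes(self):
        panel = PanelConfig()
        assert len(panel.cell_types) == 21
        assert len(panel.functional_markers) == 11
        assert panel.reference_condition == "unstim"

    def test_exclusion_mask_validated(self):
        with pytest.raises(ConfigurationError):
            PanelConfig(exclusion_mask={("nope", "pSTAT1", "LPS+IFNa")})

    def test_feature_counts(self):
        assert len(PanelConfig().feature_ids()) == 21 + 231 + 231

    def test_metadata_complete(self):
        panel = PanelConfig()
        meta = panel.feature_metadata()
        assert list(meta.index) == panel.feature_ids()
        assert set(meta["category"]) == {"frequency", "basal", "stim_response"}


class TestFrequencies:
    def test_direct_ratio(self, small_panel):
        ev = make_events(cell_types=("A", "B"), counts=(50, 150))
        freqs = compute_frequencies(ev, small_panel)
        assert freqs[feature_id("freq", "A")] == 25.0

    def test_absent_subset_zero(self, small_panel):
        ev = make_events(cell_types=("A",), counts=(10,))
        freqs = compute_frequencies(ev, small_panel)
        assert freqs[feature_id("freq", "C")] == 0.0

    def test_disjoint_partition_sums_to_100(self, small_panel):
        ev = make_events(cell_types=("A", "B", "C", "D"),
                         counts=(13, 7, 29, 51))
        assert compute_frequencies(ev, small_panel).sum() == pytest.approx(100.0)

    def test_zero_cells_errors(self, small_panel):
        ev = EventTable("P1", "T1", "unstim",
                        pd.DataFrame({"cell_type": []}))
        with pytest.raises(ValidationError, match="P1"):
            compute_frequencies(ev, small_panel)


class TestBasalSignaling:
    def test_zero_intensity_gives_zero(self, small_panel):
        ev = make_events(marker_values={("A", "m1"): 0.0, ("A", "m2"): 0.0,
                                        ("A", "m3"): 0.0,
                                        ("B", "m1"): 0.0, ("B", "m2"): 0.0,
                                        ("B", "m3"): 0.0})
        basal = compute_basal_signaling(ev, small_panel)
        assert basal[feature_id("basal", "A", "m1")] == 0.0

    def test_mean_of_transformed(self, small_panel):
        df = pd.DataFrame({"cell_type": ["A"] * 3,
                           "m1": [1.0, 2.0, 3.0],
                           "m2": [0.0] * 3, "m3": [0.0] * 3})
        ev = EventTable("P1", "T1", "unstim", df, transformed=True)
        basal = compute_basal_signaling(ev, small_panel)
        assert basal[feature_id("basal", "A", "m1")] == pytest.approx(2.0)

    def test_jensen_direction_on_lognormal(self, small_panel, rng):
        # asinh is concave on [0, inf): mean(asinh(x)) < asinh(mean(x))
        raw = rng.lognormal(2.0, 1.0, size=500)
        df = pd.DataFrame({"cell_type": ["A"] * 500, "m1": raw,
                           "m2": raw, "m3": raw})
        ev = EventTable("P1", "T1", "unstim", df)
        basal = compute_basal_signaling(ev, small_panel)
        transformed_mean = arcsinh_transform(raw.mean(), 5.0)
        assert basal[feature_id("basal", "A", "m1")] < transformed_mean

    def test_min_cells_flagged_missing(self, small_panel):
        ev = make_events(cell_types=("A", "B"), counts=(2, 50))
        basal = compute_basal_signaling(ev, small_panel)
        assert np.isnan(basal[feature_id("basal", "A", "m1")])
        assert np.isfinite(basal[feature_id("basal", "B", "m1")])

    def test_wrong_condition_rejected(self, small_panel):
        ev = make_events(condition="stim")
        with pytest.raises(PairingError):
            compute_basal_signaling(ev, small_panel)

    def test_unknown_marker_rejected(self, small_panel):
        df = pd.DataFrame({"cell_type": ["A"] * 5, "mystery": [1.0] * 5})
        ev = EventTable("P1", "T1", "unstim", df)
        with pytest.raises(ConfigurationError):
            compute_basal_signaling(ev, small_panel)


class TestStimResponse:
    def test_identity_gives_zero(self, small_panel):
        unstim = make_events(condition="unstim")
        stim = make_events(condition="stim")
        resp = compute_stim_response(stim, unstim, small_panel)
        assert (resp.dropna() == 0).all()

    def test_difference(self, small_panel):
        unstim = EventTable("P1", "T1", "unstim", pd.DataFrame(
            {"cell_type": ["A"] * 5, "m1": [0.5] * 5}), transformed=True)
        stim = EventTable("P1", "T1", "stim", pd.DataFrame(
            {"cell_type": ["A"] * 5, "m1": [2.0] * 5}), transformed=True)
        resp = compute_stim_response(stim, unstim, small_panel)
        assert resp[feature_id("stim", "A", "m1", "stim")] == pytest.approx(1.5)

    def test_exclusion_mask_drops_triple(self):
        panel = PanelConfig(cell_types=("A", "B"),
                            functional_markers=("m1",),
                            conditions=("unstim", "stim"),
                            exclusion_mask={("A", "m1", "stim")})
        unstim = make_events(markers=("m1",))
        stim = make_events(condition="stim", markers=("m1",))
        resp = compute_stim_response(stim, unstim, panel)
        assert feature_id("stim", "A", "m1", "stim") not in resp.index
        assert feature_id("stim", "B", "m1", "stim") in resp.index

    def test_mismatched_keys_rejected(self, small_panel):
        unstim = make_events(patient="P1")
        stim = make_events(patient="P2", condition="stim")
        with pytest.raises(PairingError):
            compute_stim_response(stim, unstim, small_panel)


class TestExtractFeatures:
    def _cohort(self, panel, patients=("P1", "P2")):
        tables = []
        for p in patients:
            for tp in ("T1", "T2"):
                for cond in panel.conditions:
                    tables.append(make_events(
                        patient=p, timepoint=tp, condition=cond,
                        cell_types=panel.cell_types,
                        counts=(40,) * len(panel.cell_types),
                        markers=panel.functional_markers))
        sheet = pd.DataFrame({"patient": list(patients)})
        return tables, sheet

    def test_all_excluded_column_count(self):
        mask = {(ct, m, "LPS+IFNa") for ct in DEFAULT_CELL_TYPES
                for m in DEFAULT_FUNCTIONAL_MARKERS}
        panel = PanelConfig(exclusion_mask=mask)
        assert len(panel.feature_ids()) == 252

    def test_empty_mask_column_count(self):
        assert len(PanelConfig().feature_ids()) == 483

    def test_empty_cohort(self, small_panel):
        fm = extract_features([], small_panel, pd.DataFrame({"patient": []}))
        assert fm.values.shape[0] == 0
        assert list(fm.values.columns) == small_panel.feature_ids()
        assert list(fm.meta.index) == small_panel.feature_ids()

    def test_missing_unstim_errors(self, small_panel):
        tables = [make_events(condition="stim")]
        with pytest.raises(PairingError, match="unstim"):
            extract_features(tables, small_panel,
                             pd.DataFrame({"patient": ["P1"]}))

    def test_row_order_invariance(self, small_panel, rng):
        tables, sheet = self._cohort(small_panel)
        fm1 = extract_features(tables, small_panel, sheet)
        shuffled = [EventTable(t.patient, t.timepoint, t.condition,
                               t.data.sample(frac=1, random_state=7)
                               .reset_index(drop=True))
                    for t in tables]
        fm2 = extract_features(shuffled, small_panel, sheet)
        pd.testing.assert_frame_equal(fm1.values, fm2.values)

    def test_doubling_cells_invariance(self, small_panel):
        tables, sheet = self._cohort(small_panel)
        doubled = [EventTable(t.patient, t.timepoint, t.condition,
                              pd.concat([t.data, t.data],
                                        ignore_index=True))
                   for t in tables]
        fm1 = extract_features(tables, small_panel, sheet)
        fm2 = extract_features(doubled, small_panel, sheet)
        pd.testing.assert_frame_equal(fm1.values, fm2.values)

    def test_synthetic_roundtrip_all_present_finite(self):
        from immunodyn.synthetic_data import CohortDesign, simulate_event_tables
        design = CohortDesign(n_control=2, n_case=2, events_per_sample=2000,
                              cell_types=("A", "B", "C", "D"),
                              functional_markers=("m1", "m2"),
                              conditions=("unstim", "stim"), seed=5)
        tables, sheet, _ = simulate_event_tables(design)
        fm = extract_features(tables, design.panel(), sheet)
        assert fm.values.shape == (8, len(design.feature_ids()))
        assert np.isfinite(fm.values.to_numpy()).all()


class TestFeatureMatrixIO:
    def test_csv_roundtrip(self, small_panel, tmp_path):
        tables = [make_events(patient=p, timepoint=tp, condition=c,
                              cell_types=small_panel.cell_types,
                              counts=(10, 20, 30, 40),
                              markers=small_panel.functional_markers)
                  for p in ("P1",) for tp in ("T1", "T2")
                  for c in small_panel.conditions]
        fm = extract_features(tables, small_panel,
                              pd.DataFrame({"patient": ["P1"]}))
        fm.to_csv(tmp_path / "fm.csv")
        back = FeatureMatrix.from_csv(tmp_path / "fm.csv")
        pd.testing.assert_frame_equal(fm.values, back.values)
        assert list(back.meta.index) == list(fm.meta.index)

    def test_frequency_range_enforced(self, small_panel):
        meta = small_panel.feature_metadata()
        idx = pd.MultiIndex.from_tuples([("P1", "T1")],
                                        names=["patient", "timepoint"])
        bad = pd.DataFrame({feature_id("freq", "A"): [150.0]}, index=idx)
        with pytest.raises(ValidationError):
            FeatureMatrix(bad, meta)
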