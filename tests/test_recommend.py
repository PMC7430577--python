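"""Resistor-selection logic over simulated candidate tables."""

import numpy as np
import pandas as pd
import pytest

from splitvent import PatientProfile, VentilatorSettings, predict_pair
from splitvent.recommend import (Recommendation, SelectionError,
                                 UnsafeModeError, select_resistor)


def make_table(rows):
    df = pd.DataFrame(rows)
    for col, default in (("tv_A_ml", 400.0), ("pmax_A_cmH2O", 20.0),
                         ("pmax_B_cmH2O", 18.0), ("assigned_limb", "B"),
                         ("cycles_used", 5), ("converged", True)):
        if col not in df:
            df[col] = default
    df["converged"] = [bool(v) if pd.notna(v) else True
                       for v in df["converged"]]
    return Recommendation(table=df, objective="equalize", resistor_limb="B")


class TestSelectResistor:
    def test_argmin_of_volume_difference(self):
        rec = make_table([{"resistor_mm": 3.0, "tv_B_ml": 360.0},
                          {"resistor_mm": 3.5, "tv_B_ml": 398.0},
                          {"resistor_mm": 4.0, "tv_B_ml": 460.0}])
        assert select_resistor(rec)["resistor_mm"] == 3.5

    def test_exact_tie_breaks_to_larger_lumen(self):
        rec = make_table([{"resistor_mm": 4.0, "tv_B_ml": 390.0},
                          {"resistor_mm": 4.5, "tv_B_ml": 410.0}])
        assert select_resistor(rec)["resistor_mm"] == 4.5

    def test_single_row(self):
        rec = make_table([{"resistor_mm": 5.0, "tv_B_ml": 500.0}])
        assert select_resistor(rec)["resistor_mm"] == 5.0

    def test_exactly_one_selected_row(self):
        rec = make_table([{"resistor_mm": v, "tv_B_ml": 380.0 + 10 * v}
                          for v in (3.0, 3.5, 4.0)])
        select_resistor(rec)
        assert rec.table["selected"].sum() == 1

    def test_unconverged_rows_excluded(self):
        rec = make_table([{"resistor_mm": 3.5, "tv_B_ml": 400.0,
                           "converged": False},
                          {"resistor_mm": 4.0, "tv_B_ml": 430.0}])
        assert select_resistor(rec)["resistor_mm"] == 4.0
        rec_bad = make_table([{"resistor_mm": 3.5, "tv_B_ml": 400.0,
                               "converged": False}])
        with pytest.raises(SelectionError):
            select_resistor(rec_bad)

    def test_per_patient_targets_objective(self):
        rec = make_table([{"resistor_mm": 3.5, "tv_B_ml": 350.0},
                          {"resistor_mm": 4.5, "tv_B_ml": 480.0}])
        row = select_resistor(rec, objective="per-patient-targets",
                              targets=(400.0, 470.0))
        assert row["resistor_mm"] == 4.5


SETTINGS = VentilatorSettings(mode="PC", pip=20, peep=5, respiratory_rate=20,
                              ie_ratio=(1, 2))


class TestPredictPair:
    def test_equalizing_resistor_is_3_5_mm(self, fig4_recommendation):
        """For the benchtop pairing (18 vs 35 ml/cmH2O) the 3.5 mm lumen
        minimizes the tidal-volume difference among 3.0-5.0 mm candidates."""
        assert fig4_recommendation.selected["resistor_mm"] == 3.5

    def test_3mm_overshoots_and_inverts_the_differential(self, fig4_recommendation):
        table = fig4_recommendation.table
        row = table[table["resistor_mm"] == 3.0].iloc[0]
        assert row["tv_A_ml"] > row["tv_B_ml"]  # low-C lung now gets more

    def test_no_resistor_row_always_present(self, fig4_recommendation):
        assert fig4_recommendation.table["resistor_mm"].isna().sum() == 1

    def test_resistor_assigned_to_higher_compliance_limb(self, fig4_recommendation):
        assert fig4_recommendation.resistor_limb == "B"
        rec = predict_pair(PatientProfile(compliance=35.0),
                           PatientProfile(compliance=18.0),
                           SETTINGS, resistor_options=[4.0])
        assert rec.resistor_limb == "A"

    def test_tv_on_resistor_limb_monotone_in_lumen(self, fig4_recommendation):
        t = fig4_recommendation.table.dropna(subset=["resistor_mm"])
        t = t.sort_values("resistor_mm")
        assert np.all(np.diff(t["tv_B_ml"]) > 0)

    def test_selection_invariant_to_option_order(self):
        rec = predict_pair(PatientProfile(compliance=18.0),
                           PatientProfile(compliance=35.0),
                           SETTINGS, resistor_options=[4.0, 3.0, 3.5])
        assert rec.selected["resistor_mm"] == 3.5

    def test_identical_patients_select_no_resistor(self):
        rec = predict_pair(PatientProfile(compliance=30.0),
                           PatientProfile(compliance=30.0),
                           SETTINGS, resistor_options=[4.0, 5.0])
        assert np.isnan(rec.selected["resistor_mm"])
        # symmetry holds for the unrestricted circuit; resistor rows
        # deliberately unbalance it (that is what a resistor is for)
        none_row = rec.table[rec.table["resistor_mm"].isna()].iloc[0]
        assert none_row["tv_A_ml"] == pytest.approx(none_row["tv_B_ml"],
                                                    rel=1e-3)
        with_res = rec.table.dropna(subset=["resistor_mm"])
        assert np.all(with_res["tv_B_ml"] < with_res["tv_A_ml"])

    def test_vc_mode_gated_behind_unsafe_flag(self):
        vc = VentilatorSettings(mode="VC", pip=20, peep=5, respiratory_rate=20,
                                target_tidal_volume=700.0)
        with pytest.raises(UnsafeModeError):
            predict_pair(PatientProfile(compliance=18.0),
                         PatientProfile(compliance=35.0), vc, [4.0])
        with pytest.warns(UserWarning, match="couples"):
            rec = predict_pair(PatientProfile(compliance=18.0),
                               PatientProfile(compliance=35.0), vc, [4.0],
                               allow_unsafe_vc=True)
        assert len(rec.table) == 2

    def test_json_serialization(self, fig4_recommendation):
        import json
        payload = json.loads(fig4_recommendation.to_json())
        assert payload["resistor_limb"] == "B"
        assert sum(row["selected"] for row in payload["options"]) == 1
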