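import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famh2.phenotypes import (CmrRecord, EcgRecord, LvhThresholds, bsa_dubois,
                              bsa_mosteller, chest_geometry, classify_lvh,
                              cmr_derived_measures, derive_phenotypes, ecg_lvm,
                              ecg_voltage_indices)

LEADS12 = tuple([1.0] * 12)


def make_ecg(**kw):
    base = dict(sv1=1.2, rv5=2.0, ravl=0.8, sv3=1.0, lead_amplitudes=LEADS12,
                qrs_duration_ms=90.0, sex="male", weight_kg=70.0)
    base.update(kw)
    return EcgRecord(**base)


class TestEcgIndices:
    def test_sokolow_lyon_and_product(self):
        idx = ecg_voltage_indices(make_ecg())
        assert idx["sokolow_lyon"] == pytest.approx(3.2)
        assert idx["sokolow_lyon_product"] == pytest.approx(288.0)

    @pytest.mark.parametrize("sex,expected", [("female", 2.4), ("male", 1.8)])
    def test_cornell_sex_correction(self, sex, expected):
        idx = ecg_voltage_indices(make_ecg(sex=sex))
        assert idx["cornell"] == pytest.approx(expected)

    def test_twelve_lead_sum(self):
        idx = ecg_voltage_indices(make_ecg())
        assert idx["twelve_lead_sum"] == pytest.approx(12.0)
        assert idx["twelve_lead_sum_product"] == pytest.approx(12.0 * 90.0)

    def test_missing_lead_marks_unphenotyped(self):
        idx = ecg_voltage_indices(make_ecg(sv1=float("nan")))
        assert all(math.isnan(v) for v in idx.values())

    @given(sv1=st.floats(0, 5), rv5=st.floats(0, 5), bump=st.floats(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_amplitudes(self, sv1, rv5, bump):
        lo = ecg_voltage_indices(make_ecg(sv1=sv1, rv5=rv5))
        hi = ecg_voltage_indices(make_ecg(sv1=sv1 + bump, rv5=rv5))
        assert hi["sokolow_lyon"] >= lo["sokolow_lyon"]

    @given(ravl=st.floats(0, 4), sv3=st.floats(0, 4))
    @settings(max_examples=50, deadline=None)
    def test_female_male_cornell_gap(self, ravl, sv3):
        f = ecg_voltage_indices(make_ecg(ravl=ravl, sv3=sv3, sex="female"))
        m = ecg_voltage_indices(make_ecg(ravl=ravl, sv3=sv3, sex="male"))
        assert f["cornell"] - m["cornell"] == pytest.approx(0.6)


class TestEcgLvm:
    def test_male_equation(self):
        rec = make_ecg(ravl=60.0, sv3=40.0, sex="male", weight_kg=70.0)
        assert ecg_lvm(rec, voltage_scale=1.0) == pytest.approx(
            0.026 * 100 + 1.25 * 70 + 34.4)

    def test_female_equation(self):
        rec = make_ecg(ravl=60.0, sv3=40.0, sex="female", weight_kg=70.0)
        assert ecg_lvm(rec, voltage_scale=1.0) == pytest.approx(
            0.020 * 100 + 1.12 * 70 + 36.2)

    def test_zero_voltage_reduces_to_weight_term(self):
        rec = make_ecg(ravl=0.0, sv3=0.0, sex="male", weight_kg=80.0)
        assert ecg_lvm(rec) == pytest.approx(1.25 * 80 + 34.4)

    def test_voltage_scale(self):
        rec = make_ecg(ravl=0.6, sv3=0.4, sex="male", weight_kg=70.0)
        assert ecg_lvm(rec, voltage_scale=100.0) == pytest.approx(
            0.026 * 100 + 1.25 * 70 + 34.4)


class TestLvhClassification:
    def test_thresholds(self):
        flags = classify_lvh({"sokolow_lyon": 36.0, "cornell": 19.0,
                              "sokolow_lyon_product": 2000.0,
                              "cornell_product": 2440.0}, sex="female")
        assert flags["lvh_sokolow_lyon"]
        assert not flags["lvh_cornell"]          # female cutoff 20
        assert not flags["lvh_sokolow_lyon_product"]
        assert flags["lvh_cornell_product"]      # boundary is >= by convention

    def test_male_cornell_cutoff(self):
        flags = classify_lvh({"sokolow_lyon": 0, "cornell": 25.0,
                              "sokolow_lyon_product": 0, "cornell_product": 0},
                             sex="male")
        assert not flags["lvh_cornell"]          # male cutoff 28

    @given(v=st.floats(0, 60), bump=st.floats(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_classification(self, v, bump):
        base = {"sokolow_lyon": v, "cornell": 0,
                "sokolow_lyon_product": 0, "cornell_product": 0}
        up = dict(base, sokolow_lyon=v + bump)
        lo = classify_lvh(base, "male")
        hi = classify_lvh(up, "male")
        assert hi["lvh_sokolow_lyon"] >= lo["lvh_sokolow_lyon"]


class TestCmr:
    def make_cmr(self, **kw):
        base = dict(lv_tissue_volume=100.0, rv_tissue_volume=60.0,
                    lv_edv=149.4, lv_esv=44.2, rv_edv=160.0, rv_esv=60.0,
                    chest_lateral_diameter=30.0, chest_ap_diameter=22.0,
                    chest_height=25.0, height_m=1.75, weight_kg=79.0,
                    sex="male")
        base.update(kw)
        return CmrRecord(**base)

    def test_mass_density(self):
        out = cmr_derived_measures(self.make_cmr())
        assert out["cmr_lvm"] == pytest.approx(105.0)
        assert out["rv_mass"] == pytest.approx(63.0)

    def test_index_is_value_over_bsa(self):
        rec = self.make_cmr()
        out = cmr_derived_measures(rec)
        assert out["cmr_lvm_index"] * out["bsa"] == pytest.approx(out["cmr_lvm"])

    def test_ejection_fraction(self):
        out = cmr_derived_measures(self.make_cmr())
        assert out["lv_ef"] == pytest.approx((149.4 - 44.2) / 149.4, abs=1e-6)
        assert out["lv_ef"] == pytest.approx(0.704, abs=5e-4)

    def test_edv_must_exceed_esv(self):
        with pytest.raises(ValueError):
            self.make_cmr(lv_esv=200.0)

    def test_bsa_formulas(self):
        assert bsa_dubois(175.0, 79.0) == pytest.approx(
            0.007184 * 175.0 ** 0.725 * 79.0 ** 0.425)
        assert bsa_mosteller(175.0, 79.0) == pytest.approx(
            math.sqrt(175.0 * 79.0 / 3600.0))


class TestChestGeometry:
    def test_cylinder_formula(self):
        assert chest_geometry(30.0, 25.0) == pytest.approx(
            math.pi * 225.0 * 25.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            chest_geometry(0.0, 25.0)

    def test_doubling_diameter_quadruples_volume(self):
        assert chest_geometry(40.0, 10.0) == pytest.approx(
            4.0 * chest_geometry(20.0, 10.0))


class TestTableDerivation:
    def test_matches_record_level(self, small_cohort):
        df = small_cohort.phenotypes
        d = derive_phenotypes(df, voltage_scale=100.0)
        row = d.dropna(subset=["sv1", "lv_tissue_vol"]).iloc[0]
        rec = EcgRecord(row["sv1"], row["rv5"], row["ravl"], row["sv3"],
                        tuple(row[f"lead_{i+1}"] for i in range(12)),
                        row["qrs_ms"],
                        "female" if row["sex"] == 2 else "male",
                        row["weight_kg"])
        idx = ecg_voltage_indices(rec)
        assert row["sokolow_lyon"] == pytest.approx(idx["sokolow_lyon"])
        assert row["cornell"] == pytest.approx(idx["cornell"])
        assert row["ecg_lvm"] == pytest.approx(ecg_lvm(rec, 100.0))
        assert row["chest_volume"] == pytest.approx(
            chest_geometry(row["chest_lat"], row["chest_height"]))

    def test_missing_ecg_propagates(self, small_cohort):
        d = derive_phenotypes(small_cohort.phenotypes, voltage_scale=100.0)
        miss = d["sv1"].isna()
        assert miss.any()
        assert d.loc[miss, "sokolow_lyon"].isna().all()
        assert d.loc[miss, "ecg_lvm"].isna().all()
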