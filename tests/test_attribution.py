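"""Daily HRD computation and the OTM / XHM / EDM aggregations."""

import numpy as np
import pandas as pd
import pytest

import heatmort as hm
from heatmort.climatology import RiskCoefficients

LINEAR_04 = RiskCoefficients(0.0, 0.0, 0.0, 0.04)  # rr = 1 + 0.04*(T-OT)


def clim_frame(regions, ot=28.0, smt=28.5, p95=31.0):
    return pd.DataFrame(
        {"OT": ot, "SMT": smt, "P95": p95},
        index=pd.Index(regions, name="region_id"),
    )


def temp_frame(region, dates, values):
    return pd.DataFrame(
        {"region_id": region, "date": pd.to_datetime(dates), "value": values}
    )


def mmtd_frame(region, years, mmtd):
    return pd.DataFrame({"region_id": region, "year": years, "mmtd": mmtd})


class TestDailyHRD:
    def test_zero_at_optimal_temperature(self):
        daily = hm.daily_hrd(
            temp_frame("A", ["2015-07-01"], [28.0]),
            clim_frame(["A"]),
            mmtd_frame("A", [2015], [50.0]),
            LINEAR_04,
        )
        assert daily["hrd"].iloc[0] == 0.0
        assert daily["rr"].iloc[0] == 1.0

    def test_linear_risk_times_baseline(self):
        # rr = 1.2 at OT+5, mmtd = 50 -> hrd = 10
        daily = hm.daily_hrd(
            temp_frame("A", ["2015-07-01"], [33.0]),
            clim_frame(["A"]),
            mmtd_frame("A", [2015], [50.0]),
            LINEAR_04,
        )
        assert daily["hrd"].iloc[0] == pytest.approx(10.0)

    def test_chained_quadratic_evaluation(self):
        # A=0.002, B=0.01 at OT+4 -> rr = 1.072; mmtd = 100 -> hrd = 7.2
        coeffs = RiskCoefficients(0.0, 0.002, 0.0, 0.01)
        daily = hm.daily_hrd(
            temp_frame("A", ["2015-07-01"], [32.0]),
            clim_frame(["A"]),
            mmtd_frame("A", [2015], [100.0]),
            coeffs,
        )
        assert daily["hrd"].iloc[0] == pytest.approx(7.2)

    def test_non_summer_days_carry_zero(self):
        daily = hm.daily_hrd(
            temp_frame("A", ["2015-01-15"], [35.0]),
            clim_frame(["A"]),
            mmtd_frame("A", [2015], [50.0]),
            LINEAR_04,
        )
        assert not daily["is_summer"].iloc[0]
        assert daily["hrd"].iloc[0] == 0.0

    def test_negative_mmtd_rejected(self):
        with pytest.raises(ValueError, match="negative MMTD"):
            hm.daily_hrd(
                temp_frame("A", ["2015-07-01"], [30.0]),
                clim_frame(["A"]),
                mmtd_frame("A", [2015], [-1.0]),
                LINEAR_04,
            )

    def test_flag_nesting(self, small_model):
        daily = small_model.daily_
        assert (daily.loc[daily["exceeds_p95"], "exceeds_ot"]).all()
        assert (daily.loc[~daily["exceeds_ot"], "hrd"] == 0).all()
        assert (daily["hrd"] >= 0).all()


def hand_daily(region, n_hot, hrd_each, year=2015, extreme=False):
    """n_hot summer days, each with fixed hrd; hot above OT, optionally above P95."""
    dates = pd.date_range(f"{year}-07-01", periods=n_hot)
    return pd.DataFrame(
        {
            "region_id": region,
            "date": dates,
            "year": year,
            "T": 32.0 if extreme else 29.0,
            "rr": 1.1,
            "mmtd": hrd_each / 0.1,
            "hrd": hrd_each,
            "is_summer": True,
            "exceeds_ot": True,
            "exceeds_p95": extreme,
        }
    )


class TestAggregation:
    def test_no_exceedance_gives_zero(self):
        daily = hand_daily("A", 3, 2.0)
        daily["exceeds_ot"] = False
        daily["hrd"] = 0.0
        otm = hm.aggregate_otm(daily)
        assert (otm["otm"] == 0).all()

    def test_additivity_over_days_and_regions(self):
        daily = pd.concat(
            [hand_daily("A", 10, 0.5), hand_daily("B", 7, 1.0)], ignore_index=True
        )
        otm = hm.aggregate_otm(daily).set_index(["scope", "year"])["otm"]
        assert otm[("A", 2015)] == pytest.approx(5.0)
        assert otm[("B", 2015)] == pytest.approx(7.0)
        assert otm[("state", 2015)] == pytest.approx(12.0)

    def test_xhm_restricts_to_extreme_days(self):
        daily = pd.concat(
            [hand_daily("A", 4, 1.0, extreme=True), hand_daily("A", 6, 1.0)],
            ignore_index=True,
        )
        # distinct dates needed: shift the moderate block
        daily.iloc[4:, daily.columns.get_loc("date")] = pd.date_range(
            "2015-08-01", periods=6
        )
        otm = hm.aggregate_otm(daily).set_index("scope")["otm"]
        xhm = hm.aggregate_xhm(daily).set_index("scope")["xhm"]
        assert otm["A"] == pytest.approx(10.0)
        assert xhm["A"] == pytest.approx(4.0)

    def test_xhm_never_exceeds_otm_on_synthetic_scenario(self, small_model):
        table = small_model.hrd_table_
        assert (table["xhm"] <= table["otm"] + 1e-9).all()
        assert (table["otm"] >= 0).all() and (table["xhm"] >= 0).all()

    def test_state_row_is_sum_of_regions(self, small_model):
        table = small_model.hrd_table_
        regions = table[table["scope"] != "state"]
        state = table[table["scope"] == "state"].set_index("year")
        summed = regions.groupby("year")[["otm", "xhm"]].sum()
        assert np.allclose(state[["otm", "xhm"]], summed)


class TestEDM:
    def test_reference_year_arithmetic(self):
        """With the published constant baseline (239.5/yr), the first two
        reference years give EDM 675.5 and 2614.5 — the published rounded
        675 and 2,615."""
        otm = pd.DataFrame(
            {"scope": "state", "year": [2010, 2011], "otm": [915.0, 2854.0]}
        )
        baseline = pd.Series({"state": 239.5})
        edm = hm.compute_edm(otm, baseline).set_index("year")["edm"]
        assert edm[2010] == pytest.approx(675.5)
        assert edm[2011] == pytest.approx(2614.5)

    def test_zero_baseline_gives_edm_equal_otm(self):
        otm = pd.DataFrame({"scope": "state", "year": [2015], "otm": [100.0]})
        edm = hm.compute_edm(otm, pd.Series({"state": 0.0}))
        assert edm["edm"].iloc[0] == 100.0

    def test_cool_years_go_negative(self):
        otm = pd.DataFrame({"scope": "state", "year": [2015], "otm": [50.0]})
        edm = hm.compute_edm(otm, pd.Series({"state": 80.0}))
        assert edm["edm"].iloc[0] == pytest.approx(-30.0)

    def test_baseline_never_above_ot_gives_zero(self):
        dates = pd.date_range("1955-06-01", "1955-09-30", freq="D")
        baseline_temps = temp_frame("A", dates, 20.0)
        const = hm.compute_baseline_otm(
            baseline_temps,
            clim_frame(["A"]),
            LINEAR_04,
            pd.Series({"A": 10.0}),
        )
        assert const["A"] == 0.0 and const["state"] == 0.0

    def test_two_baseline_years_average(self):
        # year 1: 10 hot days at OT+5 (rr 1.2), mmtd 50 -> 100 deaths
        # year 2: 14 such days -> 140; baseline constant = 120
        d1 = pd.date_range("1955-07-01", periods=10)
        d2 = pd.date_range("1956-07-01", periods=14)
        baseline_temps = pd.concat(
            [temp_frame("A", d1, 33.0), temp_frame("A", d2, 33.0)],
            ignore_index=True,
        )
        const = hm.compute_baseline_otm(
            baseline_temps, clim_frame(["A"]), LINEAR_04, pd.Series({"A": 50.0})
        )
        assert const["A"] == pytest.approx(120.0)

    def test_self_baseline_null(self, small_model, small_temps):
        """Baseline window equal to the study window with the fixed
        reference MMTD: mean EDM equals the year-to-year covariance of
        MMTD and heat exposure only — near zero, and exactly zero when
        OTM is recomputed with the same reference rate."""
        model = small_model
        table = model.add_edm(small_temps)
        state = table[table["scope"] == "state"]
        # exact null: recompute study OTM with the constant reference MMTD
        clim = model.climatology_.climatology_
        otm_ref = hm.compute_baseline_otm(
            small_temps,
            clim,
            model._coeffs(),
            model.reference_mmtd_,
            model._cfg().summer_months,
        )
        assert otm_ref["state"] == pytest.approx(
            model.otm_baseline_["state"], rel=1e-12
        )
        # and the realized mean EDM is small relative to mean OTM
        assert abs(state["edm"].mean()) < 0.05 * state["otm"].mean()

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="empty baseline"):
            hm.compute_baseline_otm(
                pd.DataFrame(columns=["region_id", "date", "value"]),
                clim_frame(["A"]),
                LINEAR_04,
                pd.Series({"A": 1.0}),
            )


class TestHeatAttributionModel:
    def test_not_fitted_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            hm.HeatAttributionModel().add_edm(pd.DataFrame())

    def test_attach_official_maps_statewide(self, small_model):
        official = pd.DataFrame(
            {
                "region_id": "statewide",
                "year": sorted(small_model.years_),
                "count": 10,
            }
        )
        table = small_model.attach_official(official)
        state = table[table["scope"] == "state"]
        assert (state["official"] == 10).all()
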