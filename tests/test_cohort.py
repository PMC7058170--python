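"""Cohort pipeline tests: VON import, eligibility filtering, delta-Z
derivation, the per-group interaction model, and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from pedigrowth import (
    ChartShape,
    CohortRecord,
    CohortSimParams,
    GestationalAge,
    GroupEffect,
    ModelFitError,
    apply_eligibility,
    compare_groups_tukey,
    compute_delta_z,
    fit_delta_z_model,
    lms_at,
    make_chart,
    recode_von,
    records_to_frame,
    simulate_cohort,
    summarize_by_group,
    UsageError,
    z_to_x,
)

VON_5ROW = """BYEAR,GAWEEKS,GADAYS,BWGT,LOS1,DWGT,LOCATE,DAYADMISS,FDISP,CMAL
2008,29,3,1250,49,2300,1,0,1,0
2009,31,0,1500,35,2200,1,0,2,0
2007,27,5,980,70,2500,2,3,1,0
2010,30,2,1400,42,,1,0,1,0
2011,33,6,2100,21,2650,1,0,3,1
"""


class TestRecodeVon:
    def test_ga_arithmetic(self):
        records, _ = recode_von(VON_5ROW, hospital="X")
        assert records[0].ga_birth == GestationalAge(29, 3)
        assert records[0].ga_birth.total_days == 206

    def test_field_mapping(self):
        records, _ = recode_von(VON_5ROW, hospital="X")
        r = records[0]
        assert (r.birth_year, r.birth_weight, r.los_days,
                r.discharge_weight) == (2008, 1250.0, 49, 2300.0)
        assert r.disposition == "home" and r.inborn and not r.malformation
        assert records[1].disposition == "transfer"
        assert records[2].inborn is False and records[2].admit_day == 3
        assert records[4].disposition == "death" and records[4].malformation

    def test_missing_discharge_weight_flagged_not_dropped(self):
        records, report = recode_von(VON_5ROW, hospital="X")
        assert report["n_rows"] == 5
        assert report["n_complete"] == 4
        assert report["flags"] == {"missing_discharge_weight": 1}
        assert records[3].flags == ["missing_discharge_weight"]

    def test_json_and_xml_give_same_records_as_csv(self):
        df = pd.read_csv(pd.io.common.StringIO(VON_5ROW), dtype=str)
        json_text = df.to_json(orient="records")
        xml_rows = "".join(
            "<patient>"
            + "".join(f"<{c}>{row[c]}</{c}>" for c in df.columns
                      if pd.notna(row[c]))
            + "</patient>"
            for _, row in df.iterrows()
        )
        xml_text = f"<export>{xml_rows}</export>"
        for alt in (json_text, xml_text):
            alt_records, alt_report = recode_von(alt, hospital="X")
            csv_records, csv_report = recode_von(VON_5ROW, hospital="X")
            assert alt_report == csv_report
            for a, b in zip(alt_records, csv_records):
                assert a == b

    def test_unreadable_source_rejected(self):
        with pytest.raises(UsageError):
            recode_von("/no/such/von_file.csv")

    def test_pma_discharge_from_los(self):
        records, _ = recode_von(VON_5ROW, hospital="X")
        assert records[0].pma_discharge.total_days == 206 + 49


class TestComputeDeltaZ:
    def test_median_weights_give_zero_delta(self, preterm_chart):
        ga = GestationalAge(29, 0)
        los = 56
        bw = lms_at(preterm_chart, None, 29.0).M
        dw = lms_at(preterm_chart, None, (ga.total_days + los) / 7.0).M
        rec = compute_delta_z(
            CohortRecord(ga_birth=ga, birth_weight=bw, los_days=los,
                         discharge_weight=dw),
            preterm_chart,
        )
        assert rec.delta_z == pytest.approx(0.0, abs=1e-12)

    def test_constructed_z_pair(self, preterm_chart):
        ga = GestationalAge(28, 0)
        los = 63
        bw = z_to_x(1.0, lms_at(preterm_chart, None, 28.0))
        dw = z_to_x(-1.0, lms_at(preterm_chart, None, 37.0))
        rec = compute_delta_z(
            CohortRecord(ga_birth=ga, birth_weight=bw, los_days=los,
                         discharge_weight=dw),
            preterm_chart,
        )
        assert rec.z_birth == pytest.approx(1.0, abs=1e-12)
        assert rec.z_discharge == pytest.approx(-1.0, abs=1e-12)
        assert rec.delta_z == pytest.approx(-2.0, abs=1e-12)

    def test_hand_computed_through_three_knot_chart(self):
        # L=1, constant S: z = (x - M)/(M*S); M linear between knots
        chart = make_chart(
            ChartShape(name="synthetic_3knot", age_min=28, age_max=30, step=1,
                       m_curve=("linear", 0.0, 50.0), s_curve=("constant", 0.1),
                       l_value=1.0)
        )
        ga = GestationalAge(28, 0)
        rec = compute_delta_z(
            CohortRecord(ga_birth=ga, birth_weight=1470.0, los_days=14,
                         discharge_weight=1530.0),
            chart,
        )
        # M(28) = 1400, z_birth = 70/140 = 0.5; M(30) = 1500,
        # z_discharge = 30/150 = 0.2
        assert rec.z_birth == pytest.approx(0.5, rel=1e-12)
        assert rec.z_discharge == pytest.approx(0.2, rel=1e-12)
        assert rec.delta_z == pytest.approx(-0.3, rel=1e-11)

    def test_discharge_beyond_chart_flagged(self, preterm_chart):
        rec = compute_delta_z(
            CohortRecord(ga_birth=GestationalAge(34, 0), birth_weight=2000.0,
                         los_days=140, discharge_weight=4500.0),
            preterm_chart,
        )
        assert "chart_range" in rec.flags and rec.delta_z is None


def _planted_cohort(chart):
    """10 records: 7 eligible, 3 planted violations, plus a Z exactly -4."""
    def rec(ga, z_b, z_d, los=56, **kw):
        bw = z_to_x(z_b, lms_at(chart, None, ga.total_days / 7.0))
        dw = z_to_x(z_d, lms_at(chart, None, (ga.total_days + los) / 7.0))
        kw.setdefault("disposition", "home")
        return CohortRecord(ga_birth=ga, birth_weight=bw, los_days=los,
                            discharge_weight=dw, **kw)

    records = [
        rec(GestationalAge(29, 0), 0.0, -0.8),
        rec(GestationalAge(31, 2), 0.5, -0.4),
        rec(GestationalAge(26, 4), -1.0, -1.9),
        rec(GestationalAge(23, 0), 0.2, -0.7),           # lower GA boundary: kept
        rec(GestationalAge(34, 6), 0.1, -0.5),           # upper GA boundary: kept
        rec(GestationalAge(30, 0), -4.0, -3.0),          # z exactly -4: kept
        rec(GestationalAge(33, 1), 0.0, -0.6),
        rec(GestationalAge(22, 6), 0.0, -0.5),           # violation: GA 22 6/7
        rec(GestationalAge(28, 0), 0.0, -0.5, disposition="death"),
        rec(GestationalAge(30, 0), 0.0, -4.5),           # violation: z < -4
    ]
    return records


class TestEligibility:
    def test_planted_violations_and_conservation(self, preterm_chart):
        records = _planted_cohort(preterm_chart)
        eligible, report = apply_eligibility(records, preterm_chart)
        assert report["n_input"] == 10
        assert report["n_eligible"] == 7
        assert report["excluded"] == {"ga_range": 1, "death": 1, "z_range": 1}
        assert report["n_eligible"] + sum(report["excluded"].values()) == 10

    def test_boundary_z_of_exactly_minus_four_retained(self, preterm_chart):
        records = _planted_cohort(preterm_chart)
        eligible, _ = apply_eligibility(records, preterm_chart)
        assert any(
            r.z_birth == pytest.approx(-4.0, abs=1e-12) for r in eligible
        )

    def test_ga_boundaries_inclusive(self, preterm_chart):
        eligible, _ = apply_eligibility(_planted_cohort(preterm_chart),
                                        preterm_chart)
        ga_days = {r.ga_birth.total_days for r in eligible}
        assert 23 * 7 in ga_days and 34 * 7 + 6 in ga_days

    def test_first_reason_attribution(self, preterm_chart):
        # a record violating GA range *and* dead counts only under ga_range
        rec = CohortRecord(ga_birth=GestationalAge(22, 0), birth_weight=600.0,
                           los_days=30, discharge_weight=900.0,
                           disposition="death")
        _, report = apply_eligibility([rec], preterm_chart)
        assert report["excluded"] == {"ga_range": 1}

    def test_missing_fields_tallied(self, preterm_chart):
        rec = CohortRecord(ga_birth=GestationalAge(29, 0), birth_weight=None,
                           los_days=30, discharge_weight=900.0,
                           disposition="home")
        _, report = apply_eligibility([rec], preterm_chart)
        assert report["excluded"] == {"missing_fields": 1}

    def test_chart_range_tallied(self, preterm_chart):
        rec = CohortRecord(ga_birth=GestationalAge(34, 0), birth_weight=2000.0,
                           los_days=150, discharge_weight=4500.0,
                           disposition="home")
        _, report = apply_eligibility([rec], preterm_chart)
        assert report["excluded"] == {"chart_range": 1}

    def test_optional_transfer_filter(self, preterm_chart):
        rec = CohortRecord(ga_birth=GestationalAge(29, 0), birth_weight=1200.0,
                           los_days=56, discharge_weight=2300.0,
                           disposition="transfer")
        eligible, _ = apply_eligibility([rec], preterm_chart)
        assert len(eligible) == 1  # transfers survive by default
        eligible, report = apply_eligibility([rec], preterm_chart,
                                             exclude_transfers=True)
        assert not eligible and report["excluded"] == {"disposition": 1}


class TestModelFit:
    def test_exact_line_recovered_noise_free(self, preterm_chart):
        ga = np.array([24.0, 26.0, 28.0, 30.0, 32.0, 34.0])
        df = pd.DataFrame({
            "group": "H",
            "ga_weeks": ga,
            "delta_z": -0.9 + 0.03 * (ga - 29.0),
        })
        fit = fit_delta_z_model(df, center_weeks=29.0)
        assert fit.groups.loc["H", "intercept"] == pytest.approx(-0.9, abs=1e-10)
        assert fit.groups.loc["H", "slope"] == pytest.approx(0.03, abs=1e-10)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-8)

    def test_two_group_recovery_within_three_se(self, preterm_chart):
        params = CohortSimParams(
            groups=(GroupEffect("P", -0.55, 0.0, 500),
                    GroupEffect("Q", -1.05, -0.03, 500)),
            noise_sd=0.4,
        )
        df = simulate_cohort(params, preterm_chart, seed=20240117)
        records, _ = recode_von(df)
        eligible, _ = apply_eligibility(records, preterm_chart)
        assert len(eligible) == 1000
        fit = fit_delta_z_model(eligible, reference="P")
        truth = {"P": (-0.55, 0.0), "Q": (-1.05, -0.03)}
        for g, (b0, b1) in truth.items():
            row = fit.groups.loc[g]
            assert abs(row["intercept"] - b0) < 3 * row["intercept_se"]
            assert abs(row["slope"] - b1) < 3 * row["slope_se"]
        # reference contrasts reproduce the per-group differences
        assert fit.contrasts.loc["Q", "intercept_diff"] == pytest.approx(
            fit.groups.loc["Q", "intercept"] - fit.groups.loc["P", "intercept"],
            abs=1e-10,
        )

    def test_record_order_invariance(self, preterm_chart):
        df = simulate_cohort(
            CohortSimParams(groups=(GroupEffect("P", -0.7, 0.02, 120),
                                    GroupEffect("Q", -0.9, 0.04, 120))),
            preterm_chart, seed=7,
        )
        records, _ = recode_von(df)
        eligible, _ = apply_eligibility(records, preterm_chart)
        fit_a = fit_delta_z_model(eligible)
        rng = np.random.default_rng(0)
        shuffled = list(eligible)
        rng.shuffle(shuffled)
        fit_b = fit_delta_z_model(shuffled)
        pd.testing.assert_frame_equal(fit_a.groups, fit_b.groups)

    def test_center_shift_moves_intercepts_by_slope(self, preterm_chart):
        df = simulate_cohort(
            CohortSimParams(groups=(GroupEffect("P", -0.7, 0.02, 200),)),
            preterm_chart, seed=11,
        )
        records, _ = recode_von(df)
        eligible, _ = apply_eligibility(records, preterm_chart)
        f29 = fit_delta_z_model(eligible, center_weeks=29.0)
        f27 = fit_delta_z_model(eligible, center_weeks=27.0)
        slope = f29.groups.loc["P", "slope"]
        assert f27.groups.loc["P", "slope"] == pytest.approx(slope, abs=1e-10)
        assert f27.groups.loc["P", "intercept"] == pytest.approx(
            f29.groups.loc["P", "intercept"] - 2.0 * slope, abs=1e-9
        )

    def test_common_line_groups_show_no_false_structure(self, preterm_chart):
        # both groups generated from one line: the difference contrast
        # should be within 3 SE of zero
        params = CohortSimParams(
            groups=(GroupEffect("P", -0.8, 0.03, 400),
                    GroupEffect("Q", -0.8, 0.03, 400)),
            noise_sd=0.4,
        )
        df = simulate_cohort(params, preterm_chart, seed=99)
        records, _ = recode_von(df)
        eligible, _ = apply_eligibility(records, preterm_chart)
        fit = fit_delta_z_model(eligible, reference="P")
        row = fit.contrasts.loc["Q"]
        assert abs(row["intercept_diff"]) < 3 * row["intercept_diff_se"]
        assert abs(row["slope_diff"]) < 3 * row["slope_diff_se"]

    def test_singular_group_named_in_error(self):
        df = pd.DataFrame({
            "group": ["P", "P", "Q", "Q"],
            "ga_weeks": [28.0, 30.0, 29.0, 29.0],
            "delta_z": [-0.8, -0.7, -0.9, -0.85],
        })
        with pytest.raises(ModelFitError, match="'Q'"):
            fit_delta_z_model(df)

    def test_group_with_one_record_rejected(self):
        df = pd.DataFrame({
            "group": ["P", "P", "Q"],
            "ga_weeks": [28.0, 30.0, 29.0],
            "delta_z": [-0.8, -0.7, -0.9],
        })
        with pytest.raises(ModelFitError, match="fewer than 2"):
            fit_delta_z_model(df)


class TestSummaries:
    def test_combined_row_conserves_n(self, preterm_chart):
        df = simulate_cohort(
            CohortSimParams(groups=(GroupEffect("P", -0.7, 0.02, 150),
                                    GroupEffect("Q", -0.9, 0.04, 250))),
            preterm_chart, seed=5,
        )
        records, _ = recode_von(df)
        eligible, _ = apply_eligibility(records, preterm_chart)
        table = summarize_by_group(eligible)
        assert table.loc["all", "n"] == table.loc["P", "n"] + table.loc["Q", "n"]

    def test_single_record_group_reports_missing_sd(self, preterm_chart):
        rec = compute_delta_z(
            CohortRecord(hospital="solo", ga_birth=GestationalAge(29, 0),
                         birth_weight=1200.0, los_days=56,
                         discharge_weight=2300.0),
            preterm_chart,
        )
        table = summarize_by_group([rec])
        assert table.loc["solo", "n"] == 1
        assert np.isnan(table.loc["solo", "delta_z_sd"])
        assert table.loc["solo", "delta_z_mean"] == pytest.approx(rec.delta_z)

    def test_planted_means_recovered_within_monte_carlo_tolerance(
        self, preterm_chart
    ):
        params = CohortSimParams(
            groups=(GroupEffect("P", -0.8, 0.0, 2000),), noise_sd=0.3
        )
        df = simulate_cohort(params, preterm_chart, seed=31)
        records, _ = recode_von(df)
        eligible, _ = apply_eligibility(records, preterm_chart)
        table = summarize_by_group(eligible)
        # SE of the mean ~ sqrt(0.3^2 + slope spread)/sqrt(2000) ~ 0.01
        assert table.loc["P", "delta_z_mean"] == pytest.approx(-0.8, abs=0.05)
        assert table.loc["P", "z_birth_mean"] == pytest.approx(-0.19, abs=0.08)

    def test_tukey_comparison_runs_and_flags_planted_difference(
        self, preterm_chart
    ):
        params = CohortSimParams(
            groups=(GroupEffect("P", -0.55, 0.0, 300),
                    GroupEffect("Q", -1.05, 0.0, 300)),
            noise_sd=0.4,
        )
        df = simulate_cohort(params, preterm_chart, seed=13)
        records, _ = recode_von(df)
        eligible, _ = apply_eligibility(records, preterm_chart)
        table = compare_groups_tukey(eligible)
        assert bool(table.loc[0, "reject"]) is True

    def test_records_to_frame_round_trip(self, preterm_chart):
        records = _planted_cohort(preterm_chart)
        eligible, _ = apply_eligibility(records, preterm_chart)
        frame = records_to_frame(eligible)
        assert len(frame) == len(eligible)
        assert {"ga_weeks", "delta_z", "z_birth"} <= set(frame.columns)
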