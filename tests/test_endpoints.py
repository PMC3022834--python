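import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cd4slope import (
    GeneratorConfig,
    TrueModel,
    build_endpoints,
    compute_slope,
    eligible_patients,
    generate_cohort,
    model_rows,
    pair_concurrent,
    period_from_days,
    phase_slope_summary,
    sensitivity_subset,
)
from cd4slope.endpoints import add_t_days

from conftest import make_cohort


# -------------------------------------------------------------------- pairing
def _pairs_for(labs_rows):
    cohort = make_cohort(labs=labs_rows)
    return add_t_days(pair_concurrent(cohort.labs), cohort)


def test_pair_inside_window():
    pairs = _pairs_for([("A", 200, "CD4", 300), ("A", 215, "VL", 1000)])
    assert len(pairs) == 1
    assert pairs.iloc[0]["days_apart"] == 15
    assert pairs.iloc[0]["t_days"] == 200


def test_no_pair_beyond_28_days():
    pairs = _pairs_for([("A", 200, "CD4", 300), ("A", 240, "VL", 1000)])
    assert len(pairs) == 0


def test_nearest_vl_wins():
    pairs = _pairs_for([
        ("A", 190, "VL", 500), ("A", 200, "CD4", 300), ("A", 205, "VL", 2000),
    ])
    assert len(pairs) == 1
    assert pairs.iloc[0]["log10_vl"] == pytest.approx(np.log10(2000))


def test_equidistant_tie_resolves_to_earlier_vl():
    pairs = _pairs_for([
        ("A", 195, "VL", 500), ("A", 200, "CD4", 300), ("A", 205, "VL", 2000),
    ])
    assert pairs.iloc[0]["log10_vl"] == pytest.approx(np.log10(500))


def test_each_vl_anchors_at_most_one_cd4():
    pairs = _pairs_for([
        ("A", 100, "CD4", 300), ("A", 110, "CD4", 310), ("A", 105, "VL", 1000),
    ])
    assert len(pairs) == 1  # second CD4 has no remaining VL within window


def test_sub_detection_vl_enters_at_the_limit():
    pairs = _pairs_for([("A", 200, "CD4", 300), ("A", 200, "VL", 200)])
    assert pairs.iloc[0]["log10_vl"] == pytest.approx(np.log10(400))


def test_empty_labs_give_empty_pairs():
    assert len(pair_concurrent(make_cohort(labs=[]).labs)) == 0


# ---------------------------------------------------------------- eligibility
def _lab_series(pid, days, cd4=300, vl=1000):
    rows = []
    for d in days:
        rows += [(pid, d, "CD4", cd4), (pid, d, "VL", vl)]
    return rows


def test_patient_with_two_late_pairs_excluded():
    cohort = make_cohort(labs=_lab_series("A", [200, 400]))
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    assert eligible_patients(cohort, pairs) == set()


def test_patient_with_three_late_pairs_on_triple_therapy_included():
    cohort = make_cohort(labs=_lab_series("A", [200, 400, 600]))
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    assert eligible_patients(cohort, pairs) == {"A"}


def test_dual_therapy_patient_excluded_despite_five_pairs():
    cohort = make_cohort(
        labs=_lab_series("A", [200, 400, 600, 800, 1000]),
        treatments=[("A", 0, 4000, "NRTI+NRTI")],
    )
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    assert eligible_patients(cohort, pairs) == set()


def test_pairs_before_6_months_do_not_count():
    cohort = make_cohort(labs=_lab_series("A", [30, 90, 150, 400, 600]))
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    assert eligible_patients(cohort, pairs) == set()  # only 2 pairs beyond 183


# -------------------------------------------------------------- compute_slope
def test_slope_of_exact_line():
    # equally spaced in days; 50 cells per 185 days = 98.72 cells/uL/yr
    expected = np.polyfit(np.array([180, 365, 550]) / 365.25, [200, 250, 300], 1)[0]
    assert compute_slope([180, 365, 550], [200, 250, 300]) == pytest.approx(expected)
    assert expected == pytest.approx(98.72, abs=0.01)


def test_slope_of_constant_series_is_zero():
    assert compute_slope([10, 250, 470], [333, 333, 333]) == 0.0


def test_slope_against_brute_force_normal_equations():
    # independent oracle: numpy polyfit on years
    t, y = [0, 100, 400], [100.0, 150.0, 160.0]
    expected = np.polyfit(np.asarray(t) / 365.25, y, 1)[0]
    assert compute_slope(t, y) == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(44.9538, abs=1e-3)


def test_duplicate_times_rejected():
    with pytest.raises(ValueError, match="increasing"):
        compute_slope([100, 100, 300], [1.0, 2.0, 3.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    t=st.lists(st.integers(min_value=0, max_value=2000), min_size=3, max_size=3,
               unique=True),
    y=st.lists(st.floats(min_value=0, max_value=2000), min_size=3, max_size=3),
    shift=st.floats(min_value=-500, max_value=500),
    scale=st.floats(min_value=0.1, max_value=10),
)
def test_slope_affine_invariances(t, y, shift, scale):
    t = sorted(t)
    base = compute_slope(t, y)
    assert compute_slope(t, [v + shift for v in y]) == pytest.approx(base, abs=1e-6)
    assert compute_slope(t, [v * scale for v in y]) == pytest.approx(base * scale,
                                                                     rel=1e-9, abs=1e-6)


# ------------------------------------------------------------------- periods
@pytest.mark.parametrize("day,period", [
    (100, "P0_6"), (183, "P0_6"), (184, "P6_12"), (365, "P6_12"),
    (366, "P12_18"), (547, "P12_18"), (548, "P18_24"), (730, "P18_24"),
    (731, "P24PLUS"), (3000, "P24PLUS"),
])
def test_period_boundaries_are_half_open(day, period):
    assert period_from_days(day) == period


# ------------------------------------------------------------ build_endpoints
def test_three_pairs_yield_exactly_one_interior_endpoint():
    cohort = make_cohort(labs=_lab_series("A", [200, 400, 600]))
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    ep = build_endpoints(cohort, pairs)
    assert len(ep) == 1
    assert ep.iloc[0]["t_days"] == 400
    assert ep.iloc[0]["period"] == "P12_18"


def test_endpoint_count_is_pairs_minus_two(small_cohort):
    pairs = add_t_days(pair_concurrent(small_cohort.labs), small_cohort)
    elig = eligible_patients(small_cohort, pairs)
    ep = build_endpoints(small_cohort, pairs, restrict=elig)
    counts = pairs[pairs["patient_id"].isin(elig)].groupby("patient_id").size()
    got = ep.groupby("patient_id").size()
    for pid in elig:
        assert got.get(pid, 0) == counts[pid] - 2


def test_stage_precedence_tb_over_adi():
    cohort = make_cohort(
        labs=_lab_series("A", [200, 300, 600]),
        events=[("A", 100, "TB_ADI"), ("A", 50, "NONTB_ADI")],
    )
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    ep = build_endpoints(cohort, pairs)
    assert ep.iloc[0]["stage"] == "TB_ADI"


def test_stage_reflects_only_events_on_or_before_t():
    cohort = make_cohort(
        labs=_lab_series("A", [200, 300, 600]),
        events=[("A", 450, "NONTB_ADI")],
    )
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    ep = build_endpoints(cohort, pairs)
    assert ep.iloc[0]["stage"] == "REF"  # endpoint at day 300 precedes the event


def test_haemoglobin_locf_and_median_fallback():
    cohort = make_cohort(
        patients=[{"patient_id": "A"}, {"patient_id": "B"}],
        labs=(_lab_series("A", [200, 300, 600]) + [("A", 10, "HB", 13.0),
                                                   ("A", 250, "HB", 11.0)]
              + _lab_series("B", [200, 300, 600])),
    )
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    ep = build_endpoints(cohort, pairs)
    a = ep[ep["patient_id"] == "A"].iloc[0]
    b = ep[ep["patient_id"] == "B"].iloc[0]
    assert a["haemoglobin"] == 11.0      # carried forward from day 250
    assert b["haemoglobin"] == 13.0      # cohort baseline median (only A tested)


def test_time_updated_age_in_decades():
    cohort = make_cohort(patients=[{"patient_id": "A", "age": 40.0}],
                         labs=_lab_series("A", [200, 365, 600]))
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    ep = build_endpoints(cohort, pairs)
    assert ep.iloc[0]["age_decades"] == pytest.approx((40.0 + 365 / 365.25) / 10, abs=1e-3)


def test_noiseless_equal_spacing_recovers_instantaneous_slopes():
    """On noiseless data from a model whose covariates are constant within
    patients, three-point slopes equal the generating linear predictor."""
    tm = TrueModel.zero()
    tm.constant = 70.0
    tm.beta_log10vl = -25.0
    cfg = GeneratorConfig(
        n_patients=25, seed=4, sigma_b=0.0, sigma_m=0.0, phase1_slope_sd=0.0,
        true_model=tm, p_still_suppressed_12m=0.83, prop_vl_missing=0.0,
        prop_vl_offset=0.0, tb_incidence=0.0, adi_incidence=0.0,
        n_early_visits=0, visit_interval_log_location=np.log(150.0),
        visit_interval_log_scale=0.0,
        baseline_cd4_log_location=np.log(600.0), baseline_cd4_log_scale=0.1,
    )
    cohort = generate_cohort(cfg)
    # exclude patients whose CD4 reaches the zero floor (slope flattens there)
    cd4 = cohort.labs[cohort.labs["analyte"] == "CD4"]
    floored = set(cd4.loc[cd4["value"] <= 0, "patient_id"])
    pairs = add_t_days(pair_concurrent(cohort.labs), cohort)
    pairs = pairs[~pairs["patient_id"].isin(floored)]
    ep = build_endpoints(cohort, pairs)
    # restrict to endpoints whose whole triplet is beyond the phase boundary
    ep = ep[ep["t_days"] >= 450 + 183]
    assert len(ep) > 30
    expected = tm.constant + tm.beta_log10vl * ep["log10_vl"]
    assert np.allclose(ep["slope"], expected, atol=1e-6)


# ---------------------------------------------------------------- phase summary
def test_phase_means_and_welch_p():
    rng = np.random.default_rng(0)
    early = pd.DataFrame({"t_days": 100, "slope": rng.normal(150, 5, 200)})
    late = pd.DataFrame({"t_days": 400, "slope": rng.normal(50, 5, 200)})
    s = phase_slope_summary(pd.concat([early, late], ignore_index=True))
    assert s.mean_slope_early == pytest.approx(150, abs=2)
    assert s.mean_slope_late == pytest.approx(50, abs=2)
    assert s.p_value < 1e-3
    assert s.n_early + s.n_late == 400


def test_identical_slopes_give_zero_difference_and_p_one():
    df = pd.DataFrame({"t_days": [100, 120, 400, 500], "slope": [60.0] * 4})
    s = phase_slope_summary(df)
    assert s.mean_slope_early == s.mean_slope_late
    assert s.p_value == 1.0


def test_empty_phase_flagged_undefined():
    df = pd.DataFrame({"t_days": [400, 500], "slope": [10.0, 20.0]})
    s = phase_slope_summary(df)
    assert s.undefined
    assert np.isnan(s.mean_slope_early)


# ------------------------------------------------------------- sensitivity subsets
def _endpoints_at(days, pid="A"):
    return pd.DataFrame({
        "patient_id": pid, "t_days": days, "slope": 10.0, "female": 0,
        "age_decades": 3.5, "stage": "REF", "haemoglobin": 14.0,
        "cd4_per100": 3.0, "log10_vl": 2.6, "hepatitis": 0,
        "period": [period_from_days(d) for d in days],
        "nnrti": 1, "boosted_pi": 0, "abacavir": 0,
    })


def test_initial_regimen_cuts_at_class_change():
    cohort = make_cohort(treatments=[
        ("A", 0, 500, "NRTI+NRTI+NNRTI"), ("A", 500, 2000, "NRTI+NRTI+bPI"),
    ])
    ep = _endpoints_at([400, 600])
    kept = sensitivity_subset(ep, cohort, "INITIAL_REGIMEN")
    assert list(kept["t_days"]) == [400]


def test_initial_regimen_cuts_at_gap_over_30_days():
    cohort = make_cohort(treatments=[
        ("A", 0, 700, "NRTI+NRTI+NNRTI"), ("A", 745, 2000, "NRTI+NRTI+NNRTI"),
    ])
    ep = _endpoints_at([600, 800])
    kept = sensitivity_subset(ep, cohort, "INITIAL_REGIMEN")
    assert list(kept["t_days"]) == [600]


def test_short_gap_does_not_cut():
    cohort = make_cohort(treatments=[
        ("A", 0, 700, "NRTI+NRTI+NNRTI"), ("A", 725, 2000, "NRTI+NRTI+NNRTI"),
    ])
    ep = _endpoints_at([600, 800])
    kept = sensitivity_subset(ep, cohort, "INITIAL_REGIMEN")
    assert list(kept["t_days"]) == [600, 800]


def test_initial_nnrti_requires_nnrti_regimen():
    cohort = make_cohort(
        patients=[{"patient_id": "A", "nnrti": 0, "bpi": 1}],
        treatments=[("A", 0, 2000, "NRTI+NRTI+bPI")],
    )
    ep = _endpoints_at([400, 600])
    assert len(sensitivity_subset(ep, cohort, "INITIAL_NNRTI")) == 0


def test_min4_drops_patients_with_three_endpoints():
    cohort = make_cohort(patients=[{"patient_id": "A"}, {"patient_id": "B"}])
    ep = pd.concat([_endpoints_at([300, 400, 500], "A"),
                    _endpoints_at([300, 400, 500, 600], "B")], ignore_index=True)
    kept = sensitivity_subset(ep, cohort, "MIN4")
    assert set(kept["patient_id"]) == {"B"}


def test_unknown_rule_rejected():
    with pytest.raises(ValueError, match="unknown sensitivity rule"):
        sensitivity_subset(_endpoints_at([400]), make_cohort(), "BOGUS")


def test_model_rows_are_strictly_beyond_183_days(small_cohort):
    pairs = add_t_days(pair_concurrent(small_cohort.labs), small_cohort)
    ep = build_endpoints(small_cohort, pairs,
                         restrict=eligible_patients(small_cohort, pairs))
    late = model_rows(ep)
    assert (late["t_days"] > 183).all()
    assert set(late["period"]) <= {"P6_12", "P12_18", "P18_24", "P24PLUS"}
    early = ep[ep["t_days"] <= 183]
    assert (early["period"] == "P0_6").all()
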