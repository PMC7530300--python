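import logging

import numpy as np
import pandas as pd
import pytest

from tvv.effect_models import (DesignError, build_analysis_dataset,
                               fit_pointwise_A, fit_pointwise_B,
                               fit_pointwise_C, phase_of, sum_contrasts)
from tvv.synthetic import study_b_table, study_c_table
from tvv.vcg import TRC_COLS


def _mini_table(rows):
    """rows: (subject, treatment, timepoint, replicate, trc_value)."""
    out = []
    for s, trt, tp, rep, v in rows:
        row = {"subject": s, "treatment": trt, "timepoint": tp,
               "replicate": rep, "RR_s": 1.0}
        row.update({c: v for c in TRC_COLS})
        out.append(row)
    return pd.DataFrame(out)


def test_dd_arithmetic():
    table = _mini_table([
        ("S1", "drug", 0.0, 0, 300.0), ("S1", "drug", 2.0, 0, 320.0),
        ("S1", "placebo", 0.0, 0, 298.0), ("S1", "placebo", 2.0, 0, 303.0),
        ("S2", "drug", 0.0, 0, 300.0), ("S2", "drug", 2.0, 0, 300.0),
        ("S2", "placebo", 0.0, 0, 300.0), ("S2", "placebo", 2.0, 0, 300.0),
    ])
    rec = build_analysis_dataset(table, "A")
    r = rec[rec["subject"] == "S1"].iloc[0]
    assert r["dd_100"] == pytest.approx(15.0)  # (320-300) - (303-298)
    assert rec[rec["subject"] == "S2"]["dd_1"].iloc[0] == pytest.approx(0.0)


def test_replicates_averaged_before_differencing():
    table = _mini_table([
        ("S1", "drug", 0.0, 0, 300.0), ("S1", "drug", 0.0, 1, 302.0),
        ("S1", "drug", 2.0, 0, 310.0), ("S1", "drug", 2.0, 1, 314.0),
        ("S1", "placebo", 0.0, 0, 300.0), ("S1", "placebo", 2.0, 0, 300.0),
    ])
    rec = build_analysis_dataset(table, "A")
    # mean(310,314) - mean(300,302) - 0 = 11
    assert rec["dd_50"].iloc[0] == pytest.approx(11.0)


def test_unmatched_placebo_timepoint_dropped(caplog):
    table = _mini_table([
        ("S1", "drug", 0.0, 0, 300.0), ("S1", "drug", 2.5, 0, 320.0),
        ("S1", "drug", 3.0, 0, 325.0),
        ("S1", "placebo", 0.0, 0, 300.0), ("S1", "placebo", 3.0, 0, 300.0),
    ])
    with caplog.at_level(logging.WARNING):
        rec = build_analysis_dataset(table, "A")
    assert len(rec) == 1
    assert rec["timepoint"].iloc[0] == 3.0
    assert any("S1" in m and "2.5" in m for m in caplog.messages)


def test_missing_baseline_drops_subject_period(caplog):
    table = _mini_table([
        ("S1", "drug", 2.0, 0, 320.0),
        ("S1", "placebo", 0.0, 0, 300.0), ("S1", "placebo", 2.0, 0, 300.0),
        ("S2", "drug", 0.0, 0, 300.0), ("S2", "drug", 2.0, 0, 310.0),
        ("S2", "placebo", 0.0, 0, 300.0), ("S2", "placebo", 2.0, 0, 305.0),
    ])
    with caplog.at_level(logging.WARNING):
        rec = build_analysis_dataset(table, "A")
    assert rec["subject"].tolist() == ["S2"]


def test_requires_trc_columns():
    df = pd.DataFrame({"subject": ["a"], "treatment": ["placebo"],
                       "timepoint": [1.0]})
    with pytest.raises(DesignError, match="Trc"):
        build_analysis_dataset(df, "A")


def test_phase_mapping():
    assert phase_of(0.5) == "morning"
    assert phase_of(4.0) == "afternoon"
    assert phase_of(9.5) == "evening"


def test_sum_contrasts():
    cols, names = sum_contrasts(pd.Series([1.0, 2.0, 3.0, 3.0]))
    assert names == ["nt_1.0", "nt_2.0"]
    np.testing.assert_array_equal(cols, [[1, 0], [0, 1], [-1, -1], [-1, -1]])
    assert cols.sum(axis=0) @ np.ones(2) == pytest.approx(-2.0)


# -- design A ----------------------------------------------------------------


def _records_a(theta0, theta1, n_subj=4, concs=(100.0, 500.0, 1000.0)):
    rows = []
    for i in range(n_subj):
        for k, c in enumerate(concs):
            rows.append({"subject": f"S{i}", "treatment": "drug",
                         "timepoint": float(k + 1), "conc": c,
                         "dd_50": theta0 + theta1 * c})
    return pd.DataFrame(rows)


def test_fit_a_exact_noise_free():
    rec = _records_a(0.0, 0.03)
    fit = fit_pointwise_A(rec, 50)
    assert abs(fit.coef("intercept")) < 1e-6
    assert fit.coef("slope") == pytest.approx(0.03, abs=1e-6)
    assert fit.predict_dd(1000.0) == pytest.approx(30.0, abs=1e-4)


def test_fit_a_linear_in_conc():
    rec = _records_a(2.0, 0.01)
    fit = fit_pointwise_A(rec, 50)
    d1 = fit.predict_dd(100.0) - fit.predict_dd(0.0)
    d2 = fit.predict_dd(200.0) - fit.predict_dd(100.0)
    assert d1 == pytest.approx(d2)


def test_fit_a_zero_conc_error():
    rec = _records_a(1.0, 0.0)
    rec["conc"] = 0.0
    with pytest.raises(DesignError, match="unidentifiable"):
        fit_pointwise_A(rec, 50)


def test_fit_a_parameter_recovery():
    rng = np.random.default_rng(17)
    hits = 0
    for rep in range(30):
        rows = []
        for i in range(12):
            b0 = rng.normal(0, 2.0)
            b1 = rng.normal(0, 0.002)
            for c in (0.0, 250.0, 500.0, 1000.0, 1500.0):
                rows.append({"subject": f"S{i}", "conc": c,
                             "dd_50": (1.0 + b0) + (0.01 + b1) * c
                             + rng.normal(0, 1.0)})
        fit = fit_pointwise_A(pd.DataFrame(rows), 50)
        if abs(fit.coef("slope") - 0.01) <= 2 * fit.se[1]:
            hits += 1
    assert hits >= 0.9 * 30 - 3  # ~95% nominal coverage, allow slack


# -- design B ----------------------------------------------------------------


def _records_b(values_by_subject, phase="morning"):
    rows = []
    for s, vals in values_by_subject.items():
        for k, v in enumerate(vals):
            rows.append({"subject": s, "phase": phase,
                         "timepoint": 0.5 + 0.5 * k, "dd_30": v})
    return pd.DataFrame(rows)


def test_fit_b_constant():
    rec = _records_b({"S1": [7.0, 7.0], "S2": [7.0, 7.0]})
    fit = fit_pointwise_B(rec, 30, "morning")
    assert fit.coef("intercept") == pytest.approx(7.0, abs=1e-6)


def test_fit_b_balanced_grand_mean():
    rec = _records_b({"S1": [5.0, 5.0], "S2": [9.0, 9.0]})
    fit = fit_pointwise_B(rec, 30, "morning")
    assert fit.coef("intercept") == pytest.approx(7.0, abs=1e-3)


def test_fit_b_empty_phase_errors():
    rec = _records_b({"S1": [5.0], "S2": [9.0]})
    with pytest.raises(DesignError, match="phase"):
        fit_pointwise_B(rec, 30, "evening")


def test_fit_b_sampling_distribution():
    rng = np.random.default_rng(23)
    hits = 0
    for rep in range(30):
        vals = {f"S{i}": list(rng.normal(-8.0 + rng.normal(0, 3.0), 1.0,
                                         size=4))
                for i in range(22)}
        fit = fit_pointwise_B(_records_b(vals), 30, "morning")
        if abs(fit.coef("intercept") - (-8.0)) <= 1.5:
            hits += 1
    assert hits >= 0.9 * 30 - 3


def test_study_b_pipeline_phase_effects():
    table, truth = study_b_table(n_subjects=10, seed=4)
    rec = build_analysis_dataset(table, "B")
    assert set(rec["phase"]) == {"morning", "afternoon", "evening"}
    fit = fit_pointwise_B(rec, 100, "morning")
    assert fit.coef("intercept") == pytest.approx(
        truth["phase_effects"]["morning"][-1], abs=2.5)


# -- design C ----------------------------------------------------------------


@pytest.fixture(scope="module")
def study_c_records():
    table, pk, truth = study_c_table(n_per_arm=10, g=None, theta1=2.0,
                                     seed=21)
    rec = build_analysis_dataset(table, "C", pk=pk)
    return rec, truth


def test_fit_c_prediction_structure(study_c_records):
    rec, truth = study_c_records
    fit = fit_pointwise_C(rec, 100)
    # prediction at C = 0 equals the treatment main effect
    assert fit.predict_dd({}) == pytest.approx(fit.coef("trt"))
    # linear in concentration
    d1 = fit.predict_dd({"drugC": 500.0}) - fit.predict_dd({})
    d2 = fit.predict_dd({"drugC": 1000.0}) - fit.predict_dd({"drugC": 500.0})
    assert d1 == pytest.approx(d2)


def test_fit_c_recovery(study_c_records):
    rec, truth = study_c_records
    fit = fit_pointwise_C(rec, 100)
    dd_hat = fit.predict_dd({"drugC": truth.cmax_gm})
    dd_true = truth.effect_at_cmax[-1]
    se = np.sqrt(fit.se[fit.names.index("trt")] ** 2
                 + (truth.cmax_gm * fit.se[fit.names.index("conc_drugC")]) ** 2)
    assert abs(dd_hat - dd_true) < 3 * se + 1.0


def test_fit_c_null_effect():
    table, pk, _ = study_c_table(n_per_arm=8, g=lambda p: np.zeros_like(p),
                                 theta1=0.0, seed=33)
    rec = build_analysis_dataset(table, "C", pk=pk)
    fit = fit_pointwise_C(rec, 50)
    assert abs(fit.predict_dd({"drugC": 1000.0})) < 2.5


def test_fit_c_requires_placebo(study_c_records):
    rec, _ = study_c_records
    active = rec[rec["trt"] == 1]
    with pytest.raises(DesignError, match="placebo"):
        fit_pointwise_C(active, 50)
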