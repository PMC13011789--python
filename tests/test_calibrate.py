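"""Three-level calibration algebra: anchors, head-to-head mappings, CM
conversion, pipeline calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centamine.calibrate import (
    CalibrationError,
    calibrate_pipeline,
    cm_mapped,
    cm_reference,
    fit_level2,
    fit_level3,
    level1_anchors,
    match_pairs,
    sbr_to_cm,
)
from centamine.tables import CmTable, SbrTable


def make_table(records):
    rows = []
    for subject, tracer, session, region, value in records:
        rows.append(
            {
                "subject": subject,
                "tracer": tracer,
                "session_years": session,
                "age": 65.0,
                "sex": 0,
                "region": region,
                "side": "bilateral",
                "value": value,
            }
        )
    return SbrTable(pd.DataFrame(rows))


def hc_table(region="striatum", values=(1.3, 1.5), tracer="ioflupane"):
    return make_table(
        [(f"H{i}", tracer, 0.0, region, v) for i, v in enumerate(values)]
    )


def paired_table(x, y, region="striatum", tracer_x="av133"):
    recs = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        recs.append((f"P{i}", "ioflupane", 0.0, region, xi))
        recs.append((f"P{i}", tracer_x, 0.0, region, yi))
    return make_table(recs)


def test_level1_mean_of_two(atlas_small=None):
    anchors = level1_anchors(hc_table(values=(1.3, 1.5)))
    a = anchors["striatum"]
    assert a.mu_hc == pytest.approx(1.4, abs=1e-12)
    assert a.sbr_cm0 == 0.0
    assert a.sbr_cm100 == pytest.approx(1.4)


def test_level1_single_record_raises():
    with pytest.raises(CalibrationError):
        level1_anchors(hc_table(values=(1.3,)))


def test_level1_rejects_mixed_tracers():
    t = hc_table().concat(hc_table(tracer="av133"))
    with pytest.raises(CalibrationError):
        level1_anchors(t)


def test_cm_reference_anchor_points():
    anchors = level1_anchors(hc_table(values=(1.40, 1.42)))  # mu = 1.41
    assert cm_reference(1.41, anchors, "striatum") == pytest.approx(100.0)
    assert cm_reference(0.0, anchors, "striatum") == 0.0
    assert cm_reference(0.705, anchors, "striatum") == pytest.approx(50.0)


def test_level2_exact_recovery_on_noise_free_line():
    a_true, b_true = 1.93, 0.64
    x = np.linspace(0.1, 2.0, 10)
    mapping = fit_level2(
        paired_table(x, a_true * x + b_true, region="putamen"),
        level1_anchors(hc_table(region="putamen", values=(1.50, 1.62))),
        "av133",
    )
    rm = mapping["putamen"]
    assert rm.slope == pytest.approx(a_true, abs=1e-10)
    assert rm.intercept == pytest.approx(b_true, abs=1e-10)
    assert rm.sbr_cm0 == pytest.approx(b_true, abs=1e-10)  # anchor identity
    assert rm.sbr_cm100 == pytest.approx(a_true * 1.56 + b_true, abs=1e-10)
    assert rm.valid


def test_level2_degenerate_predictor_raises():
    with pytest.raises(CalibrationError):
        fit_level2(
            paired_table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),
            level1_anchors(hc_table()),
            "av133",
        )


def test_level2_too_few_pairs_raises():
    with pytest.raises(CalibrationError):
        fit_level2(
            paired_table([1.0, 2.0], [1.5, 2.5]),
            level1_anchors(hc_table()),
            "av133",
        )


def test_level2_negative_slope_flagged_invalid():
    x = np.linspace(0.1, 2.0, 8)
    mapping = fit_level2(
        paired_table(x, -0.5 * x + 2.0),
        level1_anchors(hc_table()),
        "av133",
    )
    assert not mapping["striatum"].valid
    with pytest.raises(CalibrationError):
        cm_mapped(1.0, mapping, "striatum")


def test_pair_matching_window():
    recs = [
        ("P0", "ioflupane", 0.0, "striatum", 1.0),
        ("P0", "av133", 0.05, "striatum", 2.0),  # ~18 days: inside window
        ("P1", "ioflupane", 0.0, "striatum", 1.2),
        ("P1", "av133", 0.8, "striatum", 2.4),  # ~292 days: outside
    ]
    matched = match_pairs(make_table(recs), "av133", "ioflupane")
    assert matched["subject"].tolist() == ["P0"]


def test_cm_mapped_anchor_endpoints():
    anchors = level1_anchors(hc_table(values=(1.40, 1.42)))
    x = np.linspace(0.2, 2.2, 12)
    mapping = fit_level2(paired_table(x, 1.48 * x + 0.81), anchors, "av133")
    rm = mapping["striatum"]
    assert cm_mapped(rm.sbr_cm100, mapping, "striatum") == pytest.approx(100.0)
    assert cm_mapped(rm.sbr_cm0, mapping, "striatum") == pytest.approx(0.0)
    # published-coefficient spot value: a*mu + b at mu = 1.41
    assert cm_mapped(2.8968, mapping, "striatum") == pytest.approx(100.0, abs=1e-9)
    # below the CM0 anchor extrapolates to negative CM
    assert cm_mapped(rm.sbr_cm0 - 0.1, mapping, "striatum") < 0


def test_reference_self_mapping_matches_level1():
    """A level-2 fit on noise-free self-pairs (a=1, b=0) reproduces the
    level-1 conversion to 1e-10."""
    anchors = level1_anchors(hc_table(values=(1.3, 1.5)))
    x = np.linspace(0.1, 2.5, 9)
    mapping = fit_level2(paired_table(x, x), anchors, "av133")
    for sbr in (0.0, 0.7, 1.4, 2.1):
        assert cm_mapped(sbr, mapping, "striatum") == pytest.approx(
            cm_reference(sbr, anchors, "striatum"), abs=1e-10
        )


def test_level3_identity_composition():
    anchors = level1_anchors(hc_table(values=(1.3, 1.5)))
    x = np.linspace(0.2, 2.0, 8)
    map_x = fit_level2(paired_table(x, 1.5 * x + 0.5), anchors, "av133")
    pairs_xy = paired_table(1.5 * x + 0.5, 1.5 * x + 0.5, tracer_x="pe2i")
    # pairs table: tracer X plays the reference role in the Y-vs-X regression
    pairs_xy.df.loc[pairs_xy.df["tracer"] == "ioflupane", "tracer"] = "av133"
    map_y = fit_level3(pairs_xy, map_x, "pe2i")
    assert map_y["striatum"].sbr_cm0 == pytest.approx(map_x["striatum"].sbr_cm0, abs=1e-10)
    assert map_y["striatum"].sbr_cm100 == pytest.approx(map_x["striatum"].sbr_cm100, abs=1e-10)


def test_level3_equals_composed_level2_on_consistent_data():
    """Noise-free chain ref->X->Y: the level-3 conversion equals the direct
    composed linear map for every input, to 1e-10."""
    a1, b1 = 1.48, 0.81
    a2, b2 = 0.8, -0.2
    anchors = level1_anchors(hc_table(values=(1.40, 1.42)))  # mu = 1.41
    ref = np.linspace(0.1, 2.4, 10)
    xvals = a1 * ref + b1
    yvals = a2 * xvals + b2
    map_x = fit_level2(paired_table(ref, xvals), anchors, "av133")
    pairs_xy = make_table(
        [(f"P{i}", "av133", 0.0, "striatum", xv) for i, xv in enumerate(xvals)]
        + [(f"P{i}", "pe2i", 0.0, "striatum", yv) for i, yv in enumerate(yvals)]
    )
    map_y = fit_level3(pairs_xy, map_x, "pe2i")
    rm = map_y["striatum"]
    assert rm.composite_slope == pytest.approx(a2 * a1, abs=1e-10)
    assert rm.composite_intercept == pytest.approx(a2 * b1 + b2, abs=1e-10)
    for y in np.linspace(-0.5, 4.0, 7):
        direct = 100.0 * (y - (a2 * b1 + b2)) / (a2 * a1 * 1.41)
        assert cm_mapped(y, map_y, "striatum") == pytest.approx(direct, abs=1e-10)


def test_level3_degenerate_upstream_values_raise():
    anchors = level1_anchors(hc_table(values=(1.3, 1.5)))
    x = np.linspace(0.2, 2.0, 8)
    map_x = fit_level2(paired_table(x, 1.5 * x + 0.5), anchors, "av133")
    pairs = make_table(
        [(f"P{i}", "av133", 0.0, "striatum", 1.0) for i in range(5)]
        + [(f"P{i}", "pe2i", 0.0, "striatum", 1.0 + 0.1 * i) for i in range(5)]
    )
    with pytest.raises(CalibrationError):
        fit_level3(pairs, map_x, "pe2i")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(alpha=st.floats(0.1, 10.0))
def test_scale_equivariance(alpha):
    """Scaling all of tracer X's SBRs by alpha scales (a, b) by alpha and
    leaves every subject's CM unchanged."""
    anchors = level1_anchors(hc_table(values=(1.40, 1.42)))
    x = np.linspace(0.2, 2.2, 9)
    y = 1.48 * x + 0.81
    m1 = fit_level2(paired_table(x, y), anchors, "av133")
    m2 = fit_level2(paired_table(x, alpha * y), anchors, "av133")
    assert m2["striatum"].slope == pytest.approx(alpha * m1["striatum"].slope, rel=1e-9)
    assert m2["striatum"].intercept == pytest.approx(
        alpha * m1["striatum"].intercept, rel=1e-9
    )
    for yi in y:
        assert cm_mapped(alpha * yi, m2, "striatum") == pytest.approx(
            cm_mapped(yi, m1, "striatum"), rel=1e-9, abs=1e-9
        )


def test_sbr_to_cm_routes_by_tracer():
    anchors = level1_anchors(hc_table(values=(1.40, 1.42)))
    x = np.linspace(0.2, 2.2, 9)
    mapping = fit_level2(paired_table(x, 1.48 * x + 0.81), anchors, "av133")
    table = make_table(
        [("A", "ioflupane", 0.0, "striatum", 0.705),
         ("A", "av133", 0.0, "striatum", 2.8968)]
    )
    cm = sbr_to_cm(table, anchors, mapping)
    vals = dict(zip(cm.df["tracer"], cm.df["value"]))
    assert vals["ioflupane"] == pytest.approx(50.0)
    assert vals["av133"] == pytest.approx(100.0, abs=1e-9)
    assert isinstance(cm, CmTable)


def test_pipeline_calibration_identity_and_offsets():
    anchors = level1_anchors(hc_table(values=(1.40, 1.42)))
    mu = anchors["striatum"].mu_hc
    sbr = np.linspace(0.2, 2.0, 8)
    own = make_table([(f"P{i}", "ioflupane", 0.0, "striatum", s)
                      for i, s in enumerate(sbr)])
    provided = CmTable(own.df.assign(value=cm_reference(sbr, anchors, "striatum")))

    cal = calibrate_pipeline(own, provided)
    assert cal.regions["striatum"]["slope"] == pytest.approx(100.0 / mu, abs=1e-9)
    assert cal.regions["striatum"]["intercept"] == pytest.approx(0.0, abs=1e-9)
    assert cal.alignment_mean_abs_cm == pytest.approx(0.0, abs=1e-9)

    own2 = make_table([(f"P{i}", "ioflupane", 0.0, "striatum", 2.0 * s)
                       for i, s in enumerate(sbr)])
    cal2 = calibrate_pipeline(own2, provided)
    assert cal2.regions["striatum"]["slope"] == pytest.approx(50.0 / mu, abs=1e-9)
    assert cal2.regions["striatum"]["intercept"] == pytest.approx(0.0, abs=1e-9)

    delta = 0.3
    own3 = make_table([(f"P{i}", "ioflupane", 0.0, "striatum", s + delta)
                       for i, s in enumerate(sbr)])
    cal3 = calibrate_pipeline(own3, provided)
    slope3 = cal3.regions["striatum"]["slope"]
    assert cal3.regions["striatum"]["intercept"] == pytest.approx(
        -slope3 * delta, abs=1e-9
    )


def test_pipeline_calibration_empty_join_raises():
    own = make_table([("A", "ioflupane", 0.0, "striatum", 1.0)] )
    provided = CmTable(
        make_table([("B", "ioflupane", 0.0, "striatum", 50.0)]).df
    )
    with pytest.raises(CalibrationError):
        calibrate_pipeline(own, provided)
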