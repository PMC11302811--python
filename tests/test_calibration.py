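"""Quintic calibration: fitting, inversion, nominal averaging, schemes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from picketqa.calibration import (
    CalibrationSet,
    QuinticCalibrator,
    assemble_points,
    build_nominal_values,
    fit_curve,
    leaf_positions,
)
from picketqa.image import normalize_images
from picketqa.profiles import compute_features, extract_pair_profile
from picketqa.replication import ReplicationConfig, run_calibration
from picketqa.simulate import BeamModel, JitterModel


def test_exact_quintic_is_recovered():
    coef = np.array([0.3, 1.2, -0.4, 0.05, 0.01, -0.002])
    x = np.linspace(-1.0, 1.0, 13)
    y = np.polynomial.polynomial.polyval(x, coef)
    est = QuinticCalibrator().fit(x, y)
    resid = est.predict(x) - y
    assert np.abs(resid).max() <= 1e-8
    assert np.allclose(est.raw_coefficients_, coef, atol=1e-8)


def test_six_distinct_points_interpolate_exactly():
    x = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
    y = np.array([2.1, 4.2, 5.9, 8.3, 9.8, 12.2])
    est = QuinticCalibrator().fit(x, y)
    assert np.allclose(est.predict(x), y, atol=1e-8)


def test_duplicate_abscissae_rejected():
    x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.raises(ValueError, match="distinct feature"):
        QuinticCalibrator().fit(x, x)


def test_linear_curve_evaluates_like_its_formula():
    # width = 1 + 2 * feature: feature 3 -> 7
    x = np.linspace(0.5, 5.0, 13)
    curve = fit_curve((x, 1 + 2 * x))
    assert curve.estimate_width(3.0) == pytest.approx(7.0, abs=1e-9)
    assert np.allclose(curve.coefficients, [1, 2, 0, 0, 0, 0], atol=1e-7)


def test_prediction_outside_calibrated_range_raises():
    x = np.linspace(2.0, 14.0, 13)
    curve = fit_curve((x, x))
    with pytest.raises(ValueError, match="outside calibrated range"):
        curve.estimate_width(20.0)
    # within the 10% extrapolation slack it still answers
    assert curve.estimate_width(14.5) == pytest.approx(14.5, abs=1e-6)


def test_exact_fit_round_trip_at_every_point():
    rng = np.random.default_rng(7)
    x = np.sort(rng.uniform(2, 14, 6))
    y = rng.uniform(2, 14, 6)
    curve = fit_curve((x, y))
    for xi, yi in zip(x, y):
        assert curve.estimate_width(xi) == pytest.approx(yi, abs=1e-6)


@given(
    p=st.floats(-10, 10),
    w=st.floats(0.1, 20),
)
def test_leaf_positions_identities(p, w):
    pl, pr = leaf_positions(p, w)
    assert pr - pl == pytest.approx(w, abs=1e-12)
    assert (pl + pr) / 2 == pytest.approx(p, abs=1e-9)


def test_leaf_positions_hand_examples():
    assert leaf_positions(0.0, 5.0) == (-2.5, 2.5)
    assert leaf_positions(1.2, 8.0) == pytest.approx((-2.8, 5.2))
    with pytest.raises(ValueError):
        leaf_positions(0.0, -1.0)


def _feature_table(width, feature, strip=3, pair=0, method="fwhm"):
    return pd.DataFrame(
        [{"width_field": width, "strip": strip, "pair": pair, "method": method,
          "feature": feature}]
    )


def _log_table(width, actual, strip=3, pair=0):
    return pd.DataFrame(
        [{"width_field": width, "strip": strip, "pair": pair,
          "width_actual": actual, "left_edge": -actual / 2, "right_edge": actual / 2}]
    )


def test_nominal_values_are_per_cell_means():
    f1, f2 = _feature_table(5.0, 5.0), _feature_table(5.0, 5.2)
    g1, g2 = _log_table(5.0, 5.01), _log_table(5.0, 4.99)
    nom = build_nominal_values([f1, f2], [g1, g2])
    assert nom.features["feature"].iloc[0] == pytest.approx(5.1)
    assert nom.geometry["width_actual"].iloc[0] == pytest.approx(5.0)
    one = build_nominal_values([f1], [g1])
    assert one.features["feature"].iloc[0] == 5.0  # single session: identity


def test_missing_session_cell_is_named():
    f1 = pd.concat([_feature_table(5.0, 5.0), _feature_table(6.0, 6.0)])
    f2 = _feature_table(5.0, 5.2)  # session 2 lacks the 6 mm cell
    g = _log_table(5.0, 5.0)
    with pytest.raises(ValueError, match="session 2 missing feature cell"):
        build_nominal_values([f1, f2], [pd.concat([g, _log_table(6.0, 6.0)]), g])


def _synthetic_nominal(n_pairs=3, widths=range(2, 15)):
    f_rows, g_rows = [], []
    for w in widths:
        for j in range(n_pairs):
            for m in ("fwhm", "valley_area", "valley_depth"):
                f_rows.append({"width_field": float(w), "strip": 3, "pair": j,
                               "method": m, "feature": w + 0.1 * j})
            g_rows.append({"width_field": float(w), "strip": 3, "pair": j,
                           "width_actual": w + 0.01 * j, "left_edge": 0.0,
                           "right_edge": 0.0})
    return build_nominal_values([pd.DataFrame(f_rows)], [pd.DataFrame(g_rows)])


def test_scheme_point_assembly():
    nom = _synthetic_nominal()
    b = assemble_points(nom, "B", "fwhm")
    # Scheme B widths are exactly the planned nominal widths
    assert sorted(b[(3, 0)]["w_abu"]) == [float(w) for w in range(2, 15)]
    a = assemble_points(nom, "A", "fwhm")
    assert list(a) == [(3, None)]
    assert len(a[(3, None)]) == 13  # one point per calibration field
    # strip average over pairs
    assert a[(3, None)]["w_abu"].iloc[0] == pytest.approx(2 + 0.01)
    c = assemble_points(nom, "C", "fwhm")
    assert c[(3, 1)]["w_abu"].iloc[0] == pytest.approx(2.01)
    with pytest.raises(ValueError, match="calibration fields"):
        assemble_points(_synthetic_nominal(widths=range(2, 10)), "C", "fwhm")


def test_scheme_b_and_c_coincide_without_jitter(noiseless_calibration):
    _, nominal, _ = noiseless_calibration
    b = assemble_points(nominal, "B", "fwhm")
    c = assemble_points(nominal, "C", "fwhm")
    for key in b:
        assert np.allclose(b[key]["w_abu"], c[key]["w_abu"], atol=1e-9)
        assert np.allclose(b[key]["w_f"], c[key]["w_f"], atol=1e-12)


def test_uncalibrated_width_interpolates_accurately(noiseless_calibration, noiseless_cfg):
    sim, _, calset = noiseless_calibration
    plan = noiseless_cfg.plan(7.3)
    img, _ = sim.acquire_picket_fence(plan, 60)
    norm = normalize_images(img, sim.acquire_open_field(60))
    f = compute_features(extract_pair_profile(norm, plan, noiseless_cfg.beam, 3, 2))
    curve = calset.lookup("fwhm", "C", 3, 2)
    assert curve.estimate_width(f.fwhm) == pytest.approx(7.3, abs=0.05)


def test_multi_session_averaging_shrinks_feature_noise():
    # the 8-session nominal feature should be ~sqrt(8) steadier than a
    # single session's feature
    cfg = ReplicationConfig(
        n_pairs=4, n_sessions=8, calibration_widths=(5,), strips=(3,),
        beam=BeamModel(per_pair_response_sd=0.0), min_fields=7,
    )
    singles, nominals = [], []
    for rep in range(20):
        sim = cfg.simulator(seed=500 + rep)
        feats = []
        for session in range(cfg.n_sessions):
            open_img = sim.acquire_open_field(session)
            plan = cfg.plan(5.0)
            img, _ = sim.acquire_picket_fence(plan, session)
            norm = normalize_images(img, open_img)
            f = compute_features(extract_pair_profile(norm, plan, cfg.beam, 3, 1))
            feats.append(f.fwhm)
        singles.append(feats[0])
        nominals.append(np.mean(feats))
    ratio = np.std(nominals) / np.std(singles)
    assert 0.15 < ratio < 0.65  # ~ 1/sqrt(8) = 0.35


def test_calibration_set_json_roundtrip(noiseless_calibration, tmp_path):
    _, _, calset = noiseless_calibration
    path = tmp_path / "cal.json"
    calset.to_json(path)
    back = CalibrationSet.from_json(path)
    assert set(back.curves) == set(calset.curves)
    c1 = calset.lookup("valley_area", "C", 3, 2)
    c2 = back.lookup("valley_area", "C", 3, 2)
    probe = np.mean(c1.fit_domain)
    assert c1.estimate_width(probe) == pytest.approx(c2.estimate_width(probe), abs=1e-12)


def test_estimator_is_sklearn_compatible():
    est = QuinticCalibrator(degree=5, extrapolation=0.2)
    cloned = clone(est)
    assert cloned.get_params() == {"degree": 5, "extrapolation": 0.2}
    cloned.set_params(extrapolation=0.1)
    x = np.linspace(0, 1, 13)
    cloned.fit(x.reshape(-1, 1), 2 * x)
    assert cloned.coef_.shape == (6,)
    assert cloned.score(x.reshape(-1, 1), 2 * x) == pytest.approx(1.0)
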