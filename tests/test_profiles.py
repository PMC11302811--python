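"""Profile extraction and the three abutment features."""

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar

from picketqa.geometry import GeometryModel
from picketqa.image import NormalizedImage, normalize_images
from picketqa.plan import FieldPlan
from picketqa.profiles import (
    Extrema,
    NoAbutmentError,
    NormalizedProfile,
    compute_features,
    extract_pair_profile,
    extract_profile,
    find_extrema,
    fwhm,
    valley_area,
)
from picketqa.replication import compact_geometry
from picketqa.simulate import BeamModel, JitterModel, LinacSimulator


def _norm_image(values, geometry):
    return NormalizedImage(values=np.ma.MaskedArray(values), geometry=geometry)


def _v_profile(depth=0.6, flank_mm=3.0, plateau_mm=2.0):
    """Symmetric V: plateaus at 1.0, linear flanks down to 1 - depth."""
    step = 0.01
    n_fl, n_pl = int(flank_mm / step), int(plateau_mm / step)
    left = np.ones(n_pl)
    down = 1 - depth * np.arange(1, n_fl + 1) / n_fl
    up = down[::-1][1:]
    vals = np.concatenate([left, down, up, np.ones(n_pl + 1)])
    pos = (np.arange(vals.size) - vals.size // 2) * step
    return NormalizedProfile(positions=pos, values=vals)


def test_row_band_average_of_constant_rows():
    g = GeometryModel(rows=21, cols=40, pixel_pitch_panel=0.4)
    vals = np.zeros((21, 40))
    for i, level in enumerate([1, 2, 3, 4, 5]):
        vals[8 + i, :] = level  # the five central rows around origin_row=10
    vals[:8, :] = 99.0
    vals[13:, :] = 99.0
    prof = extract_profile(_norm_image(vals, g), x_center=0.0, y_center=0.0, half_window=2.0)
    assert np.allclose(prof.values, 3.0)


def test_interpolant_reproduces_averaged_samples():
    rng = np.random.default_rng(0)
    g = GeometryModel(rows=5, cols=60)
    vals = np.tile(rng.uniform(0.2, 1.0, 60), (5, 1))
    prof = extract_profile(_norm_image(vals, g), 0.0, 0.0, half_window=5.0)
    # fine grid contains the coarse sample positions (0.25 = 25 fine steps)
    assert np.allclose(prof.values[::25], vals[0, 10:50], atol=1e-9)
    assert np.allclose(np.diff(prof.positions), 0.01, atol=1e-9)


def test_out_of_image_band_and_masked_pixels_raise():
    g = GeometryModel(rows=10, cols=40)
    vals = np.ma.MaskedArray(np.ones((10, 40)), mask=False)
    with pytest.raises(ValueError, match="outside the image"):
        extract_profile(NormalizedImage(vals, g), 0.0, 20.0, half_window=2.0)
    vals.mask[5, 20] = True
    with pytest.raises(ValueError, match="masked pixels"):
        extract_profile(NormalizedImage(vals, g), 0.0, 0.0, half_window=2.0)


def test_fwhm_of_linear_flank_valley_is_exact():
    prof = _v_profile(depth=0.6, flank_mm=3.0)
    ext = find_extrema(prof)
    assert ext.valley_value == pytest.approx(0.4)
    width, pl, pr = fwhm(prof, ext)
    # half level 0.7 sits at the flank midpoints, 1.5 mm from the valley
    assert width == pytest.approx(3.00, abs=0.011)
    assert pr - pl == pytest.approx(width)


def test_valley_area_forced_hand_example():
    vals = np.array([1.0, 0.8, 0.4, 0.7, 1.0])
    pos = np.arange(5) * 0.01
    prof = NormalizedProfile(positions=pos, values=vals)
    ext = Extrema(2, pos[2], 0.4, 0, pos[0], 1.0, 4, pos[4], 1.0)
    assert valley_area(prof, ext) == pytest.approx(1.1)
    # no dip at all -> zero area
    flat = NormalizedProfile(positions=pos, values=np.ones(5))
    ext0 = Extrema(2, pos[2], 1.0, 0, pos[0], 1.0, 4, pos[4], 1.0)
    assert valley_area(flat, ext0) == 0.0


def test_flat_profile_reports_no_abutment():
    pos = np.arange(200) * 0.01
    with pytest.raises(NoAbutmentError):
        find_extrema(NormalizedProfile(positions=pos, values=np.ones(200)))


@pytest.fixture(scope="module")
def noiseless_profile():
    sim = LinacSimulator(beam=BeamModel.noiseless(), jitter=JitterModel.off(),
                         geometry=compact_geometry(4), n_pairs=4, seed=0)
    plan = FieldPlan(strip_nominal_width=5.0, n_pairs=4)
    img, _ = sim.acquire_picket_fence(plan, 0)
    norm = normalize_images(img, sim.acquire_open_field(0))
    return extract_pair_profile(norm, plan, sim.beam, 3, 1), plan, sim.beam


def test_noiseless_valley_centered_to_fine_grid(noiseless_profile):
    prof, plan, _ = noiseless_profile
    ext = find_extrema(prof)
    assert abs(ext.valley_pos - plan.strip_center_x(3)) <= 0.0100001


def test_fwhm_matches_continuous_model_rootfind(noiseless_profile):
    prof, plan, beam = noiseless_profile
    feats = compute_features(prof)
    sim = LinacSimulator(beam=beam, geometry=compact_geometry(4), n_pairs=4, seed=0)

    bank_a, bank_b = plan.commanded_bank_positions()

    def f(x):
        x = np.atleast_1d(np.asarray(x, float))
        T = np.zeros_like(x)
        for k in range(plan.n_segments):
            T += sim._edge(x - bank_a[k, 1]) - sim._edge(x - bank_b[k, 1])
        return beam.transmission + (1 - beam.transmission) * T

    c = plan.strip_center_x(3)
    valley = minimize_scalar(lambda x: f(x)[0], bounds=(c - 2, c + 2), method="bounded")
    v = f(valley.x)[0]
    lo, hi = prof.positions[0], prof.positions[-1]
    lp = -minimize_scalar(lambda x: -f(x)[0], bounds=(lo, valley.x), method="bounded").fun
    rp = -minimize_scalar(lambda x: -f(x)[0], bounds=(valley.x, hi), method="bounded").fun
    bl = brentq(lambda x: f(x)[0] - (lp + v) / 2, lo, valley.x)
    br = brentq(lambda x: f(x)[0] - (rp + v) / 2, valley.x, hi)
    assert feats.fwhm == pytest.approx(br - bl, abs=0.02)


def test_valley_area_matches_trapezoid_quadrature(noiseless_profile):
    prof, _, _ = noiseless_profile
    ext = find_extrema(prof)
    area = valley_area(prof, ext)
    xs = prof.positions[ext.left_peak_idx : ext.right_peak_idx + 1]
    chord = np.where(
        xs <= ext.valley_pos, ext.left_peak_value, ext.right_peak_value
    )
    deficit = chord - prof.values[ext.left_peak_idx : ext.right_peak_idx + 1]
    quad = np.trapezoid(deficit, dx=1.0)  # sample units, like the sum
    assert area == pytest.approx(quad, rel=0.01)


@pytest.fixture(scope="module")
def noiseless_feature_sweep():
    sim = LinacSimulator(beam=BeamModel.noiseless(), jitter=JitterModel.off(),
                         geometry=compact_geometry(4), n_pairs=4, seed=0)
    open_img = sim.acquire_open_field(0)
    out = {}
    for w in range(2, 15):
        plan = FieldPlan(strip_nominal_width=float(w), n_pairs=4)
        img, _ = sim.acquire_picket_fence(plan, 0)
        norm = normalize_images(img, open_img)
        out[w] = compute_features(extract_pair_profile(norm, plan, sim.beam, 3, 1))
    return out


def test_features_monotone_in_gap_width(noiseless_feature_sweep):
    sweep = noiseless_feature_sweep
    widths = sorted(sweep)
    fw = [sweep[w].fwhm for w in widths]
    ar = [sweep[w].valley_area for w in widths]
    vd = [sweep[w].valley_depth_feature for w in widths]
    assert np.all(np.diff(fw) > 0)
    assert np.all(np.diff(ar) > 0)
    assert np.all(np.diff(vd) < 0)  # deeper valley -> smaller value


def test_valley_depth_saturates_at_large_width(noiseless_feature_sweep):
    sweep = noiseless_feature_sweep
    slope_2 = sweep[3].valley_depth_feature - sweep[2].valley_depth_feature
    slope_12 = (sweep[13].valley_depth_feature - sweep[11].valley_depth_feature) / 2
    assert abs(slope_12) < 0.1 * abs(slope_2)


def test_translation_equivariance_and_fwhm_scale_invariance(noiseless_profile):
    prof, _, _ = noiseless_profile
    base = compute_features(prof)
    delta = 0.37
    shifted = compute_features(
        NormalizedProfile(positions=prof.positions + delta, values=prof.values.copy())
    )
    assert shifted.valley_pos - base.valley_pos == pytest.approx(delta, abs=1e-9)
    assert shifted.left_boundary - base.left_boundary == pytest.approx(delta, abs=1e-9)
    assert shifted.fwhm == pytest.approx(base.fwhm, abs=1e-9)
    assert shifted.valley_area == pytest.approx(base.valley_area, abs=1e-9)
    scaled = compute_features(
        NormalizedProfile(positions=prof.positions.copy(), values=prof.values * 1.7)
    )
    assert scaled.fwhm == pytest.approx(base.fwhm, abs=1e-9)
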