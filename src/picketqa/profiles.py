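"""Abutment profiles and the three scalar features.

For each (strip, leaf pair) the central 5 rows of the pair's band —
perpendicular to the leaf trajectory — are averaged to suppress interleaf
leakage, then resampled to a 0.01 mm grid with cubic B-spline interpolation.
Three scalar features are measured on the resulting valley:

* FWHM — distance between the half-level crossings on either side of the
  valley, the half level of each side being the mean of that side's peak
  value and the valley value;
* valley area — summed deficit of the profile below the flanking peak
  values, sample by sample (unitless x samples);
* valley depth — the valley value itself.

Boundary crossings are read directly off the fine grid (first sample at or
above the half level walking outward from the valley): the 0.01 mm grid
already bounds the quantization error at 0.005 mm, so no sub-sample
root-finding is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline
from scipy.signal import find_peaks

from .image import NormalizedImage
from .plan import FieldPlan
from .simulate import BeamModel

__all__ = [
    "NormalizedProfile",
    "Extrema",
    "ProfileFeatures",
    "FINE_STEP",
    "extract_profile",
    "extract_pair_profile",
    "find_extrema",
    "fwhm",
    "valley_area",
    "valley_depth_feature",
    "compute_features",
    "abutment_half_window",
]

FINE_STEP = 0.01  # mm, interpolation grid
N_AVERAGED_ROWS = 5

#: Minimum valley prominence for "an abutment is present": 10% of the
#: peak-to-valley depth of an ideal 2 mm strip under the default beam model
#: (depth ~0.63, so 0.06).  Configurable at every call site.
DEFAULT_PROMINENCE = 0.06


class NoAbutmentError(ValueError):
    """Raised when a profile shows no sufficiently prominent valley."""


@dataclass
class NormalizedProfile:
    """One abutment profile on the uniform 0.01 mm grid."""

    positions: np.ndarray  # mm, strictly increasing, uniform FINE_STEP
    values: np.ndarray
    strip: int = -1
    pair: int = -1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        steps = np.diff(self.positions)
        if steps.size and (np.any(steps <= 0) or np.max(np.abs(steps - FINE_STEP)) > 1e-9):
            raise ValueError("profile grid must be uniform 0.01 mm and increasing")

    @property
    def step(self) -> float:
        return FINE_STEP

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_mm": self.positions, "value": self.values})


@dataclass
class Extrema:
    valley_idx: int
    valley_pos: float
    valley_value: float
    left_peak_idx: int
    left_peak_pos: float
    left_peak_value: float
    right_peak_idx: int
    right_peak_pos: float
    right_peak_value: float


@dataclass
class ProfileFeatures:
    """The three scalar features plus the supporting landmark positions."""

    strip: int
    pair: int
    valley_pos: float
    valley_value: float
    left_peak_pos: float
    left_peak_value: float
    right_peak_pos: float
    right_peak_value: float
    left_boundary: float
    right_boundary: float
    fwhm: float
    valley_area: float
    valley_depth_feature: float

    def feature(self, method: str) -> float:
        return {
            "fwhm": self.fwhm,
            "valley_area": self.valley_area,
            "valley_depth": self.valley_depth_feature,
        }[method]


def abutment_half_window(plan: FieldPlan, beam: BeamModel) -> float:
    """Half-width of the search window around a nominal strip center.

    Nominal half-gap plus the penumbra extent (3 sigma of the core plus
    half the leaf-end ramp) plus a 2 mm guard, capped so the window never
    reaches the neighbouring abutments.
    """
    half = (
        plan.strip_nominal_width / 2.0
        + 3.0 * beam.penumbra_sigma
        + beam.leaf_end_ramp / 2.0
        + 2.0
    )
    return min(half, plan.segment_pitch / 2.0 + 2.0)


def extract_profile(
    norm: NormalizedImage,
    x_center: float,
    y_center: float,
    half_window: float,
    n_rows: int = N_AVERAGED_ROWS,
    strip: int = -1,
    pair: int = -1,
) -> NormalizedProfile:
    """Average the ``n_rows`` panel rows nearest ``y_center`` and resample.

    The averaged row is interpolated with a cubic B-spline onto the 0.01 mm
    grid spanning the window.  Raises if the band leaves the image or if any
    pixel inside the window is masked.
    """
    g = norm.geometry
    r0 = int(round(float(g.row_of_y(y_center))))
    half_rows = n_rows // 2
    rows = np.arange(r0 - half_rows, r0 - half_rows + n_rows)
    if rows[0] < 0 or rows[-1] >= norm.rows:
        raise ValueError(f"row band {rows[0]}..{rows[-1]} outside the image")

    c_lo = int(np.ceil(float(g.col_of_x(x_center - half_window))))
    c_hi = int(np.floor(float(g.col_of_x(x_center + half_window))))
    if c_lo < 0 or c_hi >= norm.cols or c_hi - c_lo < 3:
        raise ValueError("abutment window outside the image")

    block = norm.values[rows[0] : rows[-1] + 1, c_lo : c_hi + 1]
    if np.ma.getmaskarray(block).any():
        raise ValueError("masked pixels inside the abutment window")
    averaged = np.ma.getdata(block).mean(axis=0)

    x_coarse = g.x_of_col(np.arange(c_lo, c_hi + 1))
    spline = make_interp_spline(x_coarse, averaged, k=3)
    n_fine = int(np.floor((x_coarse[-1] - x_coarse[0]) / FINE_STEP + 1e-9)) + 1
    positions = x_coarse[0] + FINE_STEP * np.arange(n_fine)
    return NormalizedProfile(positions=positions, values=spline(positions), strip=strip, pair=pair)


def extract_pair_profile(
    norm: NormalizedImage, plan: FieldPlan, beam: BeamModel, strip: int, pair: int
) -> NormalizedProfile:
    """Profile of one (strip, pair) abutment under a field plan."""
    return extract_profile(
        norm,
        x_center=plan.strip_center_x(strip),
        y_center=plan.pair_center_y(pair),
        half_window=abutment_half_window(plan, beam),
        strip=strip,
        pair=pair,
    )


def find_extrema(profile: NormalizedProfile, prominence: float = DEFAULT_PROMINENCE) -> Extrema:
    """Locate the abutment valley and its flanking peaks.

    The valley is the most prominent local minimum in the window (ties
    broken toward the window center); each side's peak is the highest local
    maximum, falling back to the side's highest sample when the flank runs
    monotonically to the window edge.
    """
    v = profile.values
    minima, props = find_peaks(-v, prominence=prominence)
    if minima.size == 0:
        raise NoAbutmentError("no abutment detected: no valley with sufficient prominence")
    prom = props["prominences"]
    best = prom.max()
    candidates = minima[prom >= best - 1e-12]
    center = (v.size - 1) / 2.0
    iv = int(candidates[np.argmin(np.abs(candidates - center))])
    # wide abutments saturate to a flat transmission floor; recenter on the
    # midpoint of the (near-)flat bottom so the valley position stays the
    # gap center rather than an arbitrary quantization ripple
    lo_run = iv
    while lo_run > 0 and v[lo_run - 1] <= v[iv] + 1e-3:
        lo_run -= 1
    hi_run = iv
    while hi_run < v.size - 1 and v[hi_run + 1] <= v[iv] + 1e-3:
        hi_run += 1
    iv = int(round((lo_run + hi_run) / 2.0))

    def side_peak(lo, hi):
        # highest sample of the side: the flanking shoulder even when the
        # search window cuts it before it turns over
        seg = v[lo:hi]
        if seg.size == 0:
            raise NoAbutmentError("valley sits on the window edge")
        return int(np.argmax(seg)) + lo

    il = side_peak(0, iv)
    ir = side_peak(iv + 1, v.size)
    return Extrema(
        valley_idx=iv,
        valley_pos=float(profile.positions[iv]),
        valley_value=float(v[iv]),
        left_peak_idx=il,
        left_peak_pos=float(profile.positions[il]),
        left_peak_value=float(v[il]),
        right_peak_idx=ir,
        right_peak_pos=float(profile.positions[ir]),
        right_peak_value=float(v[ir]),
    )


def fwhm(profile: NormalizedProfile, extrema: Extrema):
    """Full width at half maximum of the valley, mm, plus the boundaries.

    Per side, the half level is (side peak value + valley value) / 2; the
    boundary is the first fine-grid sample at or above that level walking
    outward from the valley.
    """
    v = profile.values
    iv = extrema.valley_idx
    half_left = (extrema.left_peak_value + extrema.valley_value) / 2.0
    half_right = (extrema.right_peak_value + extrema.valley_value) / 2.0

    left_hits = np.nonzero(v[: iv + 1] >= half_left)[0]
    right_hits = np.nonzero(v[iv:] >= half_right)[0]
    if left_hits.size == 0 or right_hits.size == 0:
        raise ValueError("half level not crossed on one side of the valley")
    il = int(left_hits[-1])
    ir = iv + int(right_hits[0])
    width = float(profile.positions[ir] - profile.positions[il])
    return width, float(profile.positions[il]), float(profile.positions[ir])


def valley_area(profile: NormalizedProfile, extrema: Extrema) -> float:
    """Summed deficit below the flanking peaks (unitless x samples).

    Samples from the left peak through the valley are compared with the
    left peak value, samples after the valley through the right peak with
    the right peak value; the valley sample is counted once, on the left.
    """
    v = profile.values
    left = extrema.left_peak_value - v[extrema.left_peak_idx : extrema.valley_idx + 1]
    right = extrema.right_peak_value - v[extrema.valley_idx + 1 : extrema.right_peak_idx + 1]
    return float(abs(left.sum() + right.sum()))


def valley_depth_feature(extrema: Extrema) -> float:
    """The valley value itself (monotone pass-through)."""
    return float(extrema.valley_value)


def compute_features(
    profile: NormalizedProfile, prominence: float = DEFAULT_PROMINENCE
) -> ProfileFeatures:
    ext = find_extrema(profile, prominence=prominence)
    width, pl, pr = fwhm(profile, ext)
    return ProfileFeatures(
        strip=profile.strip,
        pair=profile.pair,
        valley_pos=ext.valley_pos,
        valley_value=ext.valley_value,
        left_peak_pos=ext.left_peak_pos,
        left_peak_value=ext.left_peak_value,
        right_peak_pos=ext.right_peak_pos,
        right_peak_value=ext.right_peak_value,
        left_boundary=pl,
        right_boundary=pr,
        fwhm=width,
        valley_area=valley_area(profile, ext),
        valley_depth_feature=valley_depth_feature(ext),
    )
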