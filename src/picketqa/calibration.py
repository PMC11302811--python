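"""Feature-to-width calibration: nominal values, quintic fits, inversion.

A calibration run measures the 13 picket-fence fields (nominal abutment
widths 2-14 mm) over several sessions (default 8).  Per (strip, leaf pair)
the session-averaged feature is the *nominal feature* and the
session-averaged log width the *nominal actual abutment width*.  A
fifth-order polynomial W_abu = c0 + c1*W_F + ... + c5*W_F^5 is then fitted
through the 13 (feature, width) points, under one of three data-processing
schemes:

* Scheme A — one curve per strip, features and log widths averaged over all
  leaf pairs of the strip;
* Scheme B — one curve per (strip, pair), against the TPS nominal widths;
* Scheme C — one curve per (strip, pair), against the log-derived widths.

Estimation is direct polynomial evaluation (the regression runs width on
feature, so no root-finding is needed), and the measured valley position
splits the estimated width into the two leaf positions:
P_left = P_peak - W/2, P_right = P_peak + W/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "METHODS",
    "SCHEMES",
    "QuinticCalibrator",
    "CalibrationCurve",
    "CalibrationSet",
    "NominalValues",
    "build_nominal_values",
    "assemble_points",
    "fit_curve",
    "estimate_width",
    "leaf_positions",
]

METHODS = ("fwhm", "valley_area", "valley_depth")
SCHEMES = ("A", "B", "C")


class QuinticCalibrator(BaseEstimator, RegressorMixin):
    """Least-squares polynomial regression of abutment width on a feature.

    Abscissae are centered and scaled to [-1, 1] before fitting (a raw
    quintic design matrix is badly conditioned); the stored transform makes
    the raw-coefficient form exactly recoverable via ``raw_coefficients_``.

    Parameters
    ----------
    degree : polynomial order (5 reproduces the published model).
    extrapolation : allowed excursion beyond the fitted feature domain,
        as a fraction of the domain span; queries beyond it raise.
    """

    def __init__(self, degree: int = 5, extrapolation: float = 0.10):
        self.degree = degree
        self.extrapolation = extrapolation

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have equal length")
        if np.unique(x).size < self.degree + 1:
            raise ValueError(
                f"need at least {self.degree + 1} distinct feature values, "
                f"got {np.unique(x).size}"
            )
        self.x_mean_ = float(x.mean())
        span = float(x.max() - x.min())
        self.x_scale_ = span / 2.0 if span > 0 else 1.0
        u = (x - self.x_mean_) / self.x_scale_
        self.coef_ = np.polynomial.polynomial.polyfit(u, y, self.degree)
        if not np.all(np.isfinite(self.coef_)):
            raise ValueError("ill-conditioned fit; center and scale the feature")
        self.domain_ = (float(x.min()), float(x.max()))
        self.n_features_in_ = 1
        return self

    def _check_domain(self, x):
        lo, hi = self.domain_
        slack = self.extrapolation * (hi - lo)
        bad = (x < lo - slack) | (x > hi + slack)
        if np.any(bad):
            raise ValueError(
                f"feature {float(np.asarray(x).reshape(-1)[np.argmax(bad)]):g} outside "
                f"calibrated range [{lo:g}, {hi:g}] (+/-{slack:g})"
            )

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float).reshape(-1)
        self._check_domain(x)
        u = (x - self.x_mean_) / self.x_scale_
        return np.polynomial.polynomial.polyval(u, self.coef_)

    @property
    def raw_coefficients_(self) -> np.ndarray:
        """c0..c_degree of the polynomial in the untransformed feature."""
        check_is_fitted(self, "coef_")
        p = Polynomial(self.coef_)
        raw = p(Polynomial([-self.x_mean_ / self.x_scale_, 1.0 / self.x_scale_]))
        out = np.zeros(self.degree + 1)
        out[: raw.coef.size] = raw.coef
        return out


@dataclass
class CalibrationCurve:
    """A fitted curve plus its scope and provenance."""

    method: str
    scheme: str
    strip: int
    pair: int | None  # None for strip-averaged (Scheme A) curves
    estimator: QuinticCalibrator
    provenance: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        return self.estimator.raw_coefficients_

    @property
    def fit_domain(self):
        return self.estimator.domain_

    def estimate_width(self, feature: float) -> float:
        return float(self.estimator.predict([feature])[0])


def fit_curve(points, method: str = "fwhm", scheme: str = "C", strip: int = -1, pair=None,
              degree: int = 5, provenance: dict | None = None) -> CalibrationCurve:
    """Fit one quintic curve through (feature, width) calibration points.

    ``points`` is anything with ``w_f``/``w_abu`` columns, or a pair of
    arrays (features, widths).
    """
    if isinstance(points, pd.DataFrame):
        wf, wa = points["w_f"].to_numpy(float), points["w_abu"].to_numpy(float)
    else:
        wf, wa = (np.asarray(p, float) for p in points)
    if np.any(wa <= 0):
        raise ValueError("abutment widths must be positive")
    est = QuinticCalibrator(degree=degree).fit(wf, wa)
    return CalibrationCurve(
        method=method, scheme=scheme, strip=strip, pair=pair, estimator=est,
        provenance=provenance or {},
    )


def estimate_width(curve: CalibrationCurve, feature: float) -> float:
    return curve.estimate_width(feature)


def leaf_positions(p_peak: float, width: float):
    """Split an abutment (valley center, width) into the two leaf edges."""
    if width <= 0:
        raise ValueError("width must be positive")
    return p_peak - width / 2.0, p_peak + width / 2.0


# ---------------------------------------------------------------------------
# Nominal values (multi-session averages) and scheme point assembly
# ---------------------------------------------------------------------------

@dataclass
class NominalValues:
    """Session-averaged calibration data.

    ``features``: tidy frame (width_field, strip, pair, method, feature);
    ``geometry``: tidy frame (width_field, strip, pair, width_actual,
    left_edge, right_edge) from the delivery logs.
    """

    features: pd.DataFrame
    geometry: pd.DataFrame
    n_sessions: int

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


_FEATURE_KEY = ["width_field", "strip", "pair", "method"]
_GEOM_KEY = ["width_field", "strip", "pair"]


def _check_same_grid(tables, key, what):
    ref = tables[0].set_index(key).index
    for i, t in enumerate(tables[1:], start=2):
        idx = t.set_index(key).index
        missing = ref.difference(idx)
        if len(missing):
            raise ValueError(f"session {i} missing {what} cell {tuple(missing[0])}")
        extra = idx.difference(ref)
        if len(extra):
            raise ValueError(f"session {i} has unexpected {what} cell {tuple(extra[0])}")


def build_nominal_values(feature_tables, log_tables) -> NominalValues:
    """Arithmetic per-cell means across sessions, features and log geometry
    averaged separately."""
    feature_tables = list(feature_tables)
    log_tables = list(log_tables)
    if not feature_tables or len(feature_tables) != len(log_tables):
        raise ValueError("need one feature table and one log table per session")
    _check_same_grid(feature_tables, _FEATURE_KEY, "feature")
    _check_same_grid(log_tables, _GEOM_KEY, "log")
    feats = (
        pd.concat(feature_tables)
        .groupby(_FEATURE_KEY, as_index=False)["feature"]
        .mean()
    )
    geom = (
        pd.concat(log_tables)
        .groupby(_GEOM_KEY, as_index=False)[["width_actual", "left_edge", "right_edge"]]
        .mean()
    )
    return NominalValues(features=feats, geometry=geom, n_sessions=len(feature_tables))


def assemble_points(nominal: NominalValues, scheme: str, method: str,
                    min_fields: int = 13) -> dict:
    """Per-scope (feature, width) point sets for one scheme and method.

    Returns ``{(strip, pair or None): DataFrame(w_f, w_abu)}`` with one row
    per calibration field (nominal width).  Scheme A averages features and
    log widths over the pairs of each strip; Scheme B pairs each feature
    with the TPS nominal width; Scheme C with the log-derived width.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if min_fields < 7:
        raise ValueError("min_fields must be >= 7")
    f = nominal.features[nominal.features["method"] == method]
    if f.empty:
        raise ValueError(f"no features for method {method!r}")
    n_fields = f["width_field"].nunique()
    if n_fields < min_fields:
        raise ValueError(f"only {n_fields} calibration fields, need >= {min_fields}")
    merged = f.merge(nominal.geometry, on=_GEOM_KEY, how="left")
    if merged["width_actual"].isna().any():
        row = merged[merged["width_actual"].isna()].iloc[0]
        raise ValueError(
            f"log geometry missing for strip {int(row.strip)} pair {int(row.pair)}"
        )

    out = {}
    if scheme == "A":
        g = merged.groupby(["strip", "width_field"], as_index=False)[
            ["feature", "width_actual"]
        ].mean()
        for strip, sub in g.groupby("strip"):
            out[(int(strip), None)] = pd.DataFrame(
                {"w_f": sub["feature"].to_numpy(), "w_abu": sub["width_actual"].to_numpy()}
            )
    else:
        target = "width_field" if scheme == "B" else "width_actual"
        for (strip, pair), sub in merged.groupby(["strip", "pair"]):
            out[(int(strip), int(pair))] = pd.DataFrame(
                {"w_f": sub["feature"].to_numpy(), "w_abu": sub[target].to_numpy(float)}
            )
    return out


@dataclass
class CalibrationSet:
    """All fitted curves of one calibration run, keyed for QA lookup."""

    curves: dict = field(default_factory=dict)  # (method, scheme, strip, pair) -> curve
    provenance: dict = field(default_factory=dict)

    def add(self, curve: CalibrationCurve) -> None:
        self.curves[(curve.method, curve.scheme, curve.strip, curve.pair)] = curve

    def lookup(self, method: str, scheme: str, strip: int, pair: int) -> CalibrationCurve:
        key = (method, scheme, strip, None if scheme == "A" else pair)
        try:
            return self.curves[key]
        except KeyError:
            raise KeyError(
                f"no {method} scheme-{scheme} curve for strip {strip}, pair {pair}"
            ) from None

    @classmethod
    def build(cls, nominal: NominalValues, schemes=SCHEMES, methods=METHODS,
              min_fields: int = 13, provenance: dict | None = None) -> "CalibrationSet":
        cs = cls(provenance=provenance or {"n_sessions": nominal.n_sessions})
        for scheme in schemes:
            for method in methods:
                for (strip, pair), pts in assemble_points(
                    nominal, scheme, method, min_fields=min_fields
                ).items():
                    cs.add(fit_curve(pts, method=method, scheme=scheme, strip=strip, pair=pair))
        return cs

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None):
        records = []
        for (method, scheme, strip, pair), c in sorted(
            self.curves.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], -1 if kv[0][3] is None else kv[0][3])
        ):
            est = c.estimator
            records.append(
                {
                    "method": method,
                    "scheme": scheme,
                    "strip": strip,
                    "pair": pair,
                    "degree": est.degree,
                    "x_mean": est.x_mean_,
                    "x_scale": est.x_scale_,
                    "coef_scaled": list(est.coef_),
                    "coef_raw": list(c.coefficients),
                    "fit_domain": list(est.domain_),
                    "provenance": c.provenance,
                }
            )
        doc = {"provenance": self.provenance, "curves": records}
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationSet":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        cs = cls(provenance=doc.get("provenance", {}))
        for rec in doc["curves"]:
            est = QuinticCalibrator(degree=rec["degree"])
            est.x_mean_ = rec["x_mean"]
            est.x_scale_ = rec["x_scale"]
            est.coef_ = np.asarray(rec["coef_scaled"], float)
            est.domain_ = tuple(rec["fit_domain"])
            est.n_features_in_ = 1
            cs.add(
                CalibrationCurve(
                    method=rec["method"],
                    scheme=rec["scheme"],
                    strip=rec["strip"],
                    pair=rec["pair"],
                    estimator=est,
                    provenance=rec.get("provenance", {}),
                )
            )
        return cs
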