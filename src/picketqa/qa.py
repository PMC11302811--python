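"""Field analysis: apply calibration, score leaf positions against the log.

For every analyzed (strip, leaf pair) the three features are measured, each
is inverted to an abutment width through its calibration curve, and the
measured valley center splits that width into the two leaf edges.  Errors
are *estimated minus log-actual* per leaf.  The integration method then
keeps, per leaf, whichever of the three estimates has the smallest absolute
error — the log file is part of the method, not just the reference — which
makes the integrated error exactly the per-leaf minimum.

Per-pair failures (no detectable abutment, feature outside the calibrated
range) degrade to an explicit failure list; leaves are never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import METHODS, CalibrationSet, leaf_positions
from .image import NormalizedImage
from .logfile import DeliveryLog, abutment_states, segment_states
from .plan import FieldPlan
from .profiles import DEFAULT_PROMINENCE, NoAbutmentError, compute_features, extract_pair_profile
from .simulate import BeamModel

__all__ = ["QAResult", "analyze_field", "integrate", "summarize", "error_summary"]

#: Tie-break priority when two methods give equal absolute error
#: (descending overall accuracy of the independent methods).
METHOD_PRIORITY = ("fwhm", "valley_area", "valley_depth")

DEFAULT_ACTION_LEVEL = 0.1  # mm
DEFAULT_INVESTIGATE_LEVEL = 0.2  # mm


@dataclass
class QAResult:
    """Per-leaf analysis of one picket-fence field.

    ``table``: one row per (strip, pair, method) with the estimated width,
    leaf edges, log-actual edges and signed per-leaf errors.
    ``integrated``: one row per (strip, pair, leaf) with the selected
    method and its signed error.
    ``failures``: explicit list of (strip, pair, method-or-None, reason).
    """

    table: pd.DataFrame
    integrated: pd.DataFrame
    failures: list = field(default_factory=list)
    scheme: str = "C"

    def leaf_errors(self, method: str) -> np.ndarray:
        """Signed per-leaf errors of one method (or 'integration')."""
        if method == "integration":
            return self.integrated["error"].to_numpy(float)
        sub = self.table[self.table["method"] == method]
        return np.concatenate([sub["err_left"].to_numpy(float), sub["err_right"].to_numpy(float)])


def integrate(errors: dict):
    """Select the method with the smallest absolute signed error.

    ``errors`` maps method name -> signed error (methods that failed are
    simply absent).  Ties go to the highest-priority method.  Raises when
    every method failed.
    """
    if not errors:
        raise ValueError("indeterminate: all methods failed for this leaf")
    best = min(abs(e) for e in errors.values())
    for m in METHOD_PRIORITY:
        if m in errors and abs(errors[m]) <= best + 1e-15:
            return m, errors[m]
    m, e = min(errors.items(), key=lambda kv: abs(kv[1]))  # non-standard method names
    return m, e


def analyze_field(
    norm: NormalizedImage,
    calibration: CalibrationSet,
    log: DeliveryLog,
    plan: FieldPlan,
    beam: BeamModel,
    scheme: str = "C",
    strips=None,
    pairs=None,
    methods=METHODS,
    prominence: float = DEFAULT_PROMINENCE,
) -> QAResult:
    """Run the full per-leaf-pair analysis of one measured field."""
    strips = list(plan.analyzed_strips if strips is None else strips)
    pairs = list(range(plan.n_pairs) if pairs is None else pairs)
    actual = abutment_states(segment_states(log)).set_index(["strip", "pair"])

    rows, integ_rows, failures = [], [], []
    for s in strips:
        for j in pairs:
            act = actual.loc[(s, j)]
            try:
                profile = extract_pair_profile(norm, plan, beam, s, j)
                feats = compute_features(profile, prominence=prominence)
            except (NoAbutmentError, ValueError) as exc:
                failures.append({"strip": s, "pair": j, "method": None, "reason": str(exc)})
                continue
            errs_left, errs_right = {}, {}
            for m in methods:
                try:
                    curve = calibration.lookup(m, scheme, s, j)
                    width = curve.estimate_width(feats.feature(m))
                    if width <= 0:
                        raise ValueError("calibration returned a non-positive width")
                    pl, pr = leaf_positions(feats.valley_pos, width)
                except (KeyError, ValueError) as exc:
                    failures.append({"strip": s, "pair": j, "method": m, "reason": str(exc)})
                    continue
                err_l = pl - act["left_edge"]
                err_r = pr - act["right_edge"]
                errs_left[m], errs_right[m] = err_l, err_r
                rows.append(
                    {
                        "strip": s,
                        "pair": j,
                        "method": m,
                        "feature": feats.feature(m),
                        "width_est": width,
                        "center": feats.valley_pos,
                        "pl_est": pl,
                        "pr_est": pr,
                        "pl_act": act["left_edge"],
                        "pr_act": act["right_edge"],
                        "err_left": err_l,
                        "err_right": err_r,
                    }
                )
            for leaf, errs in (("left", errs_left), ("right", errs_right)):
                if errs:
                    m, e = integrate(errs)
                    integ_rows.append({"strip": s, "pair": j, "leaf": leaf, "method": m, "error": e})
                else:
                    failures.append(
                        {"strip": s, "pair": j, "method": "integration", "reason": f"{leaf}: all methods failed"}
                    )
    return QAResult(
        table=pd.DataFrame(rows),
        integrated=pd.DataFrame(integ_rows),
        failures=failures,
        scheme=scheme,
    )


def error_summary(errors) -> dict:
    """Mean / SD / mean abs / SD abs / max abs of a signed error sample."""
    e = np.asarray(errors, float).ravel()
    if e.size == 0:
        raise ValueError("no errors to summarize")
    return {
        "mean": float(e.mean()),
        "sd": float(e.std(ddof=0)),
        "mean_abs": float(np.abs(e).mean()),
        "sd_abs": float(np.abs(e).std(ddof=0)),
        "max_abs": float(np.abs(e).max()),
        "n": int(e.size),
    }


def summarize(
    results,
    action_level: float = DEFAULT_ACTION_LEVEL,
    investigate_level: float = DEFAULT_INVESTIGATE_LEVEL,
    methods=METHODS + ("integration",),
) -> pd.DataFrame:
    """Summary table over one or many QA results.

    One row per method with mean/SD of signed and absolute errors, max
    absolute error and the fractions beyond the action and investigation
    levels; ``verdict`` is 'pass' when no leaf exceeds the action level,
    'action' when some exceed it, 'investigate' beyond the second level.
    """
    if isinstance(results, QAResult):
        results = [results]
    rows = []
    for m in methods:
        errs = np.concatenate([r.leaf_errors(m) for r in results if len(r.table)])
        s = error_summary(errs)
        frac_action = float(np.mean(np.abs(errs) > action_level))
        frac_inv = float(np.mean(np.abs(errs) > investigate_level))
        verdict = "pass"
        if s["max_abs"] > investigate_level:
            verdict = "investigate"
        elif s["max_abs"] > action_level:
            verdict = "action"
        rows.append(
            {
                "method": m,
                **s,
                "frac_beyond_action": frac_action,
                "frac_beyond_investigate": frac_inv,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).set_index("method")
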