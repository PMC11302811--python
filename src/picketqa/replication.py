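"""End-to-end study pipelines: calibration runs, error-injection validation.

These routines wire the simulator, log analysis, profile metrology and
calibration into the full QA loop: multi-session calibration at the 13
nominal widths (2-14 mm), then validation fields at 5, 8 and 11 mm carrying
deliberate leaf displacements of +-0.6, 0.8, 1.2, 1.8 and 2.4 mm in the
single-bank and both-bank patterns.

Problem sizes default to a desk-scale rendition of the study: 24 leaf pairs
(the two-adjacent-pair pattern occupies 20), one analyzed strip for the
error ensemble, and a panel cropped to the analyzed band.  Sessions (8),
widths, error magnitudes and patterns follow the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .calibration import METHODS, CalibrationSet, NominalValues, build_nominal_values
from .geometry import GeometryModel
from .image import normalize_images
from .logfile import LogErrorStats, abutment_states, segment_states, stats_from_errors
from .plan import (
    VALIDATION_ERROR_MAGNITUDES,
    FieldPlan,
    both_bank_error_plan,
    single_bank_error_plan,
)
from .profiles import compute_features, extract_pair_profile
from .qa import analyze_field
from .simulate import BeamModel, JitterModel, LinacSimulator

__all__ = [
    "ReplicationConfig",
    "compact_geometry",
    "measure_features",
    "run_calibration",
    "run_error_injection",
    "run_replication",
    "run_scheme_comparison",
    "jitter_error_sample",
    "fwhm_width_curve",
    "piecewise_linear_breakpoint",
]


def compact_geometry(
    n_pairs: int,
    leaf_width: float = 5.0,
    x_half: float = 66.0,
    y_margin: float = 12.0,
) -> GeometryModel:
    """Panel window just covering the analyzed band (0.25 mm iso pitch)."""
    g = GeometryModel()
    y_half = n_pairs * leaf_width / 2.0 + y_margin
    rows = 2 * int(np.ceil(y_half / g.pixel_pitch_iso)) + 1
    cols = 2 * int(np.ceil(x_half / g.pixel_pitch_iso)) + 1
    return GeometryModel(rows=rows, cols=cols)


@dataclass
class ReplicationConfig:
    """Study conditions for a calibration + error-injection replication."""

    n_pairs: int = 24
    n_sessions: int = 8
    calibration_widths: tuple = tuple(range(2, 15))
    validation_widths: tuple = (5.0, 8.0, 11.0)
    error_strip: int = 3
    magnitudes: tuple = VALIDATION_ERROR_MAGNITUDES
    single_bank_first_pair: int = 7
    both_bank_first_pair: int = 2
    strips: tuple = (3,)
    beam: BeamModel = field(default_factory=BeamModel)
    jitter: JitterModel = field(default_factory=JitterModel)
    schemes: tuple = ("C",)
    min_fields: int = 13

    def geometry(self) -> GeometryModel:
        return compact_geometry(self.n_pairs)

    def simulator(self, seed: int) -> LinacSimulator:
        return LinacSimulator(
            beam=self.beam,
            jitter=self.jitter,
            geometry=self.geometry(),
            n_pairs=self.n_pairs,
            seed=seed,
        )

    def plan(self, width: float, **kw) -> FieldPlan:
        return FieldPlan(strip_nominal_width=float(width), n_pairs=self.n_pairs, **kw)


def measure_features(norm, plan, beam, strips, pairs) -> pd.DataFrame:
    """Feature table (strip, pair, method, feature) for one normalized field."""
    rows = []
    for s in strips:
        for j in pairs:
            feats = compute_features(extract_pair_profile(norm, plan, beam, s, j))
            for m in METHODS:
                rows.append({"strip": s, "pair": j, "method": m, "feature": feats.feature(m)})
    return pd.DataFrame(rows)


def _log_geometry(log, strips) -> pd.DataFrame:
    ab = abutment_states(segment_states(log))
    ab = ab[ab["strip"].isin(strips)]
    return ab.rename(columns={"width": "width_actual"})[
        ["strip", "pair", "width_actual", "left_edge", "right_edge"]
    ]


def run_calibration(sim: LinacSimulator, cfg: ReplicationConfig) -> tuple:
    """Acquire all calibration sessions; returns (NominalValues, CalibrationSet)."""
    pairs = list(range(cfg.n_pairs))
    feature_tables, log_tables = [], []
    for session in range(cfg.n_sessions):
        open_img = sim.acquire_open_field(session)
        f_rows, g_rows = [], []
        for width in cfg.calibration_widths:
            plan = cfg.plan(width)
            img, log = sim.acquire_picket_fence(plan, session)
            norm = normalize_images(img, open_img)
            f = measure_features(norm, plan, cfg.beam, cfg.strips, pairs)
            f.insert(0, "width_field", float(width))
            g = _log_geometry(log, cfg.strips)
            g.insert(0, "width_field", float(width))
            f_rows.append(f)
            g_rows.append(g)
        feature_tables.append(pd.concat(f_rows, ignore_index=True))
        log_tables.append(pd.concat(g_rows, ignore_index=True))
    nominal = build_nominal_values(feature_tables, log_tables)
    calset = CalibrationSet.build(
        nominal, schemes=cfg.schemes, methods=METHODS, min_fields=cfg.min_fields,
        provenance={"seed": sim.seed, "n_sessions": cfg.n_sessions},
    )
    return nominal, calset


def _injected_leaves(plan: FieldPlan):
    """(strip, pair, leaf side, signed offset) for every displaced leaf."""
    out = []
    for e in plan.error_map:
        if e.bank in ("B", "both"):
            out.append((e.strip, e.pair, "left", e.offset))
        if e.bank in ("A", "both"):
            out.append((e.strip, e.pair, "right", e.offset))
    return out


def validation_plans(cfg: ReplicationConfig, width: float):
    """The two deliberate-displacement patterns for one nominal width."""
    single = single_bank_error_plan(
        width, strip=cfg.error_strip, magnitudes=cfg.magnitudes,
        first_pair=cfg.single_bank_first_pair, n_pairs=cfg.n_pairs,
    )
    both = both_bank_error_plan(
        width, strip=cfg.error_strip, magnitudes=cfg.magnitudes,
        first_pair=cfg.both_bank_first_pair, n_pairs=cfg.n_pairs,
    )
    return {"single_bank": single, "both_bank": both}


def run_error_injection(
    sim: LinacSimulator, calset: CalibrationSet, cfg: ReplicationConfig, scheme: str = "C",
    session_base: int = 1000,
) -> pd.DataFrame:
    """Analyze all validation fields of one machine.

    Returns one row per analyzed leaf with the integrated signed error,
    whether the leaf carried an injected displacement, and (for injected
    leaves) the recovered displacement = injected offset + signed error,
    i.e. the estimated position referred to where the leaf would have been
    without the deliberate displacement.
    """
    rows = []
    session = session_base
    for width in cfg.validation_widths:
        for pattern, plan in validation_plans(cfg, width).items():
            open_img = sim.acquire_open_field(session)
            img, log = sim.acquire_picket_fence(plan, session)
            norm = normalize_images(img, open_img)
            result = analyze_field(
                norm, calset, log, plan, cfg.beam, scheme=scheme, strips=[cfg.error_strip]
            )
            injected = {(s, p, leaf): off for s, p, leaf, off in _injected_leaves(plan)}
            for r in result.integrated.itertuples(index=False):
                off = injected.get((r.strip, r.pair, r.leaf))
                rows.append(
                    {
                        "width": width,
                        "pattern": pattern,
                        "strip": r.strip,
                        "pair": r.pair,
                        "leaf": r.leaf,
                        "method": r.method,
                        "error": r.error,
                        "injected": off is not None,
                        "offset": 0.0 if off is None else off,
                        "recovered": np.nan if off is None else off + r.error,
                    }
                )
            session += 1
    return pd.DataFrame(rows)


def run_replication(seeds, cfg: ReplicationConfig | None = None, scheme: str = "C") -> pd.DataFrame:
    """Full calibration + validation loop over an ensemble of machines."""
    cfg = cfg or ReplicationConfig()
    tables = []
    for seed in seeds:
        sim = cfg.simulator(int(seed))
        _, calset = run_calibration(sim, cfg)
        t = run_error_injection(sim, calset, cfg, scheme=scheme)
        t.insert(0, "seed", int(seed))
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def run_scheme_comparison(seeds, cfg: ReplicationConfig | None = None) -> pd.DataFrame:
    """Mean absolute width-estimation error per data-processing scheme.

    Calibrates Schemes A, B and C on the same sessions, then analyzes
    error-free validation fields; the score of a scheme is the absolute
    difference between each method's estimated abutment width and the
    log-derived actual width, pooled over the three independent methods.
    """
    cfg = cfg or ReplicationConfig()
    cfg = replace(cfg, schemes=("A", "B", "C"))
    rows = []
    for seed in seeds:
        sim = cfg.simulator(int(seed))
        _, calset = run_calibration(sim, cfg)
        session = 2000
        for width in cfg.validation_widths:
            plan = cfg.plan(width)
            open_img = sim.acquire_open_field(session)
            img, log = sim.acquire_picket_fence(plan, session)
            norm = normalize_images(img, open_img)
            for scheme in ("A", "B", "C"):
                res = analyze_field(
                    norm, calset, log, plan, cfg.beam, scheme=scheme, strips=[cfg.error_strip]
                )
                t = res.table
                width_err = t["width_est"] - (t["pr_act"] - t["pl_act"])
                rows.append(
                    {
                        "seed": int(seed),
                        "width": width,
                        "scheme": scheme,
                        "mean_abs": float(np.abs(width_err).mean()),
                        "n": len(width_err),
                    }
                )
            session += 1
    return pd.DataFrame(rows)


def jitter_error_sample(
    jitter: JitterModel | None = None,
    n_machines: int = 20,
    n_pairs: int = 48,
    seed: int = 0,
    thresholds=(0.1, 0.2),
) -> LogErrorStats:
    """Per-record error statistics over an ensemble of simulated deliveries.

    Each machine redraws its persistent leaf biases; each delivery its
    offsets and record jitter.  One 8-segment, 100 MU delivery of a
    48-pair field contributes n_segments x 272 x 2 x n_pairs leaf-position
    samples, so the default ensemble holds several million.
    """
    jitter = jitter or JitterModel()
    plan = FieldPlan(strip_nominal_width=5.0, n_pairs=n_pairs)
    pos, wid = [], []
    for m in range(n_machines):
        sim = LinacSimulator(
            beam=BeamModel.noiseless(), jitter=jitter,
            geometry=compact_geometry(4), n_pairs=n_pairs, seed=seed * 10007 + m,
        )
        rng = np.random.default_rng([sim.seed, 303, 0])
        log = sim._deliver(plan, rng)
        # pool raw per-record samples so the ensemble statistics are exact
        cmd_a, cmd_b = plan.commanded_bank_positions()
        for seg in log.segments:
            a, b = log.bank_arrays(segment=seg, beam_on_only=True)
            ea = a - cmd_a[seg][None, :]
            eb = b - cmd_b[seg][None, :]
            pos.extend([ea.ravel(), eb.ravel()])
            wid.append((eb - ea).ravel())
    return stats_from_errors(np.concatenate(pos), np.concatenate(wid), thresholds)


def fwhm_width_curve(
    beam: BeamModel | None = None,
    widths=tuple(range(2, 15)),
    strip: int = 3,
):
    """Noiseless FWHM feature per nominal width (single central pair)."""
    beam = beam or BeamModel.noiseless()
    geometry = compact_geometry(4)
    sim = LinacSimulator(
        beam=beam, jitter=JitterModel.off(), geometry=geometry, n_pairs=4, seed=0
    )
    feats = []
    open_img = sim.acquire_open_field(0)
    for width in widths:
        plan = FieldPlan(strip_nominal_width=float(width), n_pairs=4)
        img, _ = sim.acquire_picket_fence(plan, 0)
        norm = normalize_images(img, open_img)
        f = compute_features(extract_pair_profile(norm, plan, beam, strip, 1))
        feats.append(f.fwhm)
    return np.asarray(widths, float), np.asarray(feats)


def piecewise_linear_breakpoint(x, y) -> float:
    """Knot of the best continuous two-segment linear fit to (x, y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def sse(b):
        X = np.column_stack([np.ones_like(x), x - b, np.clip(x - b, 0.0, None)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    res = minimize_scalar(sse, bounds=(x[1], x[-2]), method="bounded")
    return float(res.x)
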