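"""Delivery-log records: parsing, per-segment averaging, jitter statistics.

The accelerator writes one record every 40 ms during delivery with the
instantaneous position of every leaf of both banks.  The CSV dialect used
here (a documented stand-in for the binary ``.trf`` treatment record file)
has columns::

    time_ms, segment, beam_on, bankA_leaf_001..N, bankB_leaf_001..N

with positions in isocenter-plane mm.  Leaves jitter around their commanded
positions during delivery, so the per-segment *actual* leaf position is
defined as the arithmetic mean over that segment's beam-on records, and the
*actual* abutment width as the difference of the opposing mean edges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plan import FieldPlan

__all__ = [
    "LogRecord",
    "DeliveryLog",
    "SegmentLeafState",
    "LogErrorStats",
    "parse_log",
    "average_segment_positions",
    "abutment_states",
    "error_stats",
    "stats_from_errors",
]


@dataclass(frozen=True)
class LogRecord:
    """One 40 ms snapshot of both leaf banks."""

    time_ms: float
    segment: int
    beam_on: bool
    bank_a: np.ndarray
    bank_b: np.ndarray


def _bank_columns(n_pairs: int):
    a = [f"bankA_leaf_{i + 1:03d}" for i in range(n_pairs)]
    b = [f"bankB_leaf_{i + 1:03d}" for i in range(n_pairs)]
    return a, b


class DeliveryLog:
    """A parsed delivery log; thin wrapper over a validated DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        a_cols = sorted(c for c in frame.columns if c.startswith("bankA_leaf_"))
        b_cols = sorted(c for c in frame.columns if c.startswith("bankB_leaf_"))
        self._a_cols, self._b_cols = a_cols, b_cols

    @property
    def n_pairs(self) -> int:
        return len(self._a_cols)

    @property
    def segments(self):
        return sorted(self.frame["segment"].unique())

    def bank_arrays(self, segment=None, beam_on_only: bool = True):
        """(bank_a, bank_b) position arrays, shape (n_records, n_pairs)."""
        df = self.frame
        if segment is not None:
            df = df[df["segment"] == segment]
        if beam_on_only:
            df = df[df["beam_on"].astype(bool)]
        return df[self._a_cols].to_numpy(float), df[self._b_cols].to_numpy(float)

    def records(self):
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            yield LogRecord(
                time_ms=float(d["time_ms"]),
                segment=int(d["segment"]),
                beam_on=bool(d["beam_on"]),
                bank_a=np.array([d[c] for c in self._a_cols], dtype=float),
                bank_b=np.array([d[c] for c in self._b_cols], dtype=float),
            )

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def build(cls, time_ms, segment, beam_on, bank_a, bank_b) -> "DeliveryLog":
        n_pairs = np.asarray(bank_a).shape[1]
        a_cols, b_cols = _bank_columns(n_pairs)
        frame = pd.DataFrame(
            {"time_ms": time_ms, "segment": segment, "beam_on": np.asarray(beam_on, int)}
        )
        frame[a_cols] = np.asarray(bank_a, float)
        frame[b_cols] = np.asarray(bank_b, float)
        return cls(frame)


def parse_log(source) -> DeliveryLog:
    """Parse the CSV log dialect, validating structure as it goes.

    ``source`` may be a path or any readable buffer.  Raises ``ValueError``
    naming the offending column or row for malformed input.
    """
    if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("time_ms"):
        frame = pd.read_csv(source)
    elif isinstance(source, str):
        frame = pd.read_csv(io.StringIO(source))
    else:
        frame = pd.read_csv(source)

    for col in ("time_ms", "segment", "beam_on"):
        if col not in frame.columns:
            raise ValueError(f"log file missing required column {col!r}")
    a_cols = sorted(c for c in frame.columns if c.startswith("bankA_leaf_"))
    b_cols = sorted(c for c in frame.columns if c.startswith("bankB_leaf_"))
    if not a_cols or not b_cols:
        raise ValueError("log file missing leaf position columns")
    a_ids = [c.split("bankA_leaf_")[1] for c in a_cols]
    b_ids = [c.split("bankB_leaf_")[1] for c in b_cols]
    if a_ids != b_ids:
        missing = set(a_ids) ^ set(b_ids)
        raise ValueError(f"bank length mismatch: unmatched leaf columns {sorted(missing)}")

    t = frame["time_ms"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(f"non-monotonic time_ms at row {int(bad[0]) + 1}")

    null_rows = frame[a_cols + b_cols].isna().any(axis=1)
    if null_rows.any():
        raise ValueError(f"missing leaf position at row {int(np.nonzero(null_rows.to_numpy())[0][0])}")

    return DeliveryLog(frame.sort_values("time_ms", kind="stable"))


@dataclass
class SegmentLeafState:
    """Per-segment actual (record-averaged) leaf positions of both banks."""

    segment: int
    bank_a: np.ndarray  # (n_pairs,) mean positions, mm
    bank_b: np.ndarray
    n_records: int

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("a segment state needs at least one record")
        if self.bank_a.shape != self.bank_b.shape:
            raise ValueError("bank arrays must have equal length")


def average_segment_positions(log: DeliveryLog, segment: int) -> SegmentLeafState:
    """Mean beam-on leaf positions for one segment."""
    a, b = log.bank_arrays(segment=segment, beam_on_only=True)
    if a.shape[0] == 0:
        raise ValueError(f"no beam-on records for segment {segment}")
    return SegmentLeafState(
        segment=segment, bank_a=a.mean(axis=0), bank_b=b.mean(axis=0), n_records=a.shape[0]
    )


def segment_states(log: DeliveryLog) -> dict:
    return {s: average_segment_positions(log, s) for s in log.segments}


def abutment_states(states) -> pd.DataFrame:
    """Actual abutment geometry from per-segment states.

    The gap at strip ``s`` is bounded by segment ``s``'s bank-B leaf (left)
    and segment ``s + 1``'s bank-A leaf (right); the actual abutment width is
    the difference of the two record-averaged edges.

    Returns a tidy frame with columns strip, pair, left_edge, right_edge,
    width, center.
    """
    if isinstance(states, dict):
        states = [states[k] for k in sorted(states)]
    states = sorted(states, key=lambda s: s.segment)
    rows = []
    for left, right in zip(states[:-1], states[1:]):
        if right.segment != left.segment + 1:
            continue
        for j in range(left.bank_b.shape[0]):
            le, re = left.bank_b[j], right.bank_a[j]
            rows.append(
                {
                    "strip": left.segment,
                    "pair": j,
                    "left_edge": le,
                    "right_edge": re,
                    "width": re - le,
                    "center": (re + le) / 2.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Jitter statistics (the per-record error table)
# ---------------------------------------------------------------------------

@dataclass
class LogErrorStats:
    """Summary of per-record leaf-position and abutment-width errors (mm).

    Signed rows report the max of the signed distribution; absolute rows the
    max magnitude.  ``position_exceedance``/``width_exceedance`` map each
    threshold to the fraction of records strictly beyond +-threshold.
    """

    position_mean: float
    position_sd: float
    position_max: float
    abs_position_mean: float
    abs_position_sd: float
    abs_position_max: float
    width_mean: float
    width_sd: float
    width_max: float
    abs_width_mean: float
    abs_width_sd: float
    abs_width_max: float
    position_exceedance: dict = field(default_factory=dict)
    width_exceedance: dict = field(default_factory=dict)
    n_position: int = 0
    n_width: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Render in the conventional four-row (mean, SD, max) layout."""
        return pd.DataFrame(
            {
                "Mean": [self.position_mean, self.abs_position_mean, self.width_mean, self.abs_width_mean],
                "SD": [self.position_sd, self.abs_position_sd, self.width_sd, self.abs_width_sd],
                "Max": [self.position_max, self.abs_position_max, self.width_max, self.abs_width_max],
            },
            index=[
                "Leaf position error (mm)",
                "Abs leaf position error (mm)",
                "Abutment width error (mm)",
                "Abs abutment width error (mm)",
            ],
        )


def stats_from_errors(position_errors, width_errors, thresholds=(0.1, 0.2)) -> LogErrorStats:
    p = np.asarray(position_errors, float).ravel()
    w = np.asarray(width_errors, float).ravel()
    if p.size == 0:
        raise ValueError("no position errors supplied")
    return LogErrorStats(
        position_mean=p.mean(),
        position_sd=p.std(ddof=0),
        position_max=p.max(),
        abs_position_mean=np.abs(p).mean(),
        abs_position_sd=np.abs(p).std(ddof=0),
        abs_position_max=np.abs(p).max(),
        width_mean=w.mean() if w.size else np.nan,
        width_sd=w.std(ddof=0) if w.size else np.nan,
        width_max=w.max() if w.size else np.nan,
        abs_width_mean=np.abs(w).mean() if w.size else np.nan,
        abs_width_sd=np.abs(w).std(ddof=0) if w.size else np.nan,
        abs_width_max=np.abs(w).max() if w.size else np.nan,
        position_exceedance={t: float(np.mean(np.abs(p) > t)) for t in thresholds},
        width_exceedance={t: float(np.mean(np.abs(w) > t)) for t in thresholds} if w.size else {},
        n_position=p.size,
        n_width=w.size,
    )


def error_stats(log: DeliveryLog, plan: FieldPlan, thresholds=(0.1, 0.2)) -> LogErrorStats:
    """Per-record delivery errors against the commanded positions.

    Signed position error = recorded - commanded, on the common x axis, over
    every beam-on record and every leaf of both banks.  The per-record width
    error of a pair is the difference of its two opposing leaves' signed
    errors (the leaf-pair gap of the delivering segment), so width errors
    carry sqrt(2) of the single-leaf jitter.
    """
    cmd_a, cmd_b = plan.commanded_bank_positions(include_errors=not plan.epid_only_errors)
    if plan.n_pairs != log.n_pairs:
        raise ValueError(
            f"plan has {plan.n_pairs} leaf pairs but log has {log.n_pairs}"
        )
    pos_err, width_err = [], []
    for seg in log.segments:
        a, b = log.bank_arrays(segment=seg, beam_on_only=True)
        if a.shape[0] == 0:
            continue
        ea = a - cmd_a[seg][None, :]
        eb = b - cmd_b[seg][None, :]
        pos_err.append(ea.ravel())
        pos_err.append(eb.ravel())
        width_err.append((eb - ea).ravel())
    return stats_from_errors(np.concatenate(pos_err), np.concatenate(width_err), thresholds)
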