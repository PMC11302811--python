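"""Picket-fence field plans: segment layout, commanded leaf positions, errors.

A picket-fence test is a train of adjacent step-and-shoot segments (default
eight, 20 mm pitch, 24 cm long) with an intentional abutment gap of nominal
width W at every internal segment boundary.  "Strip" means one such abutment:
the band blocked in both neighbouring segments, receiving only penumbra tails
and transmission.  Leaf pairs stack perpendicular to the motion axis.

All positions are isocenter-plane millimetres on one common x axis (positive
rightward).  For the gap at strip ``s`` of pair ``j``, the *left* edge is the
bank-B leaf of segment ``s`` and the *right* edge is the bank-A leaf of
segment ``s + 1``; gap width = right - left, so a positive width error means
the delivered gap is wider than planned.

Deliberate position errors (the validation patterns) are TPS-commanded real
leaf displacements: they move the leaf in both the image and the delivery
log.  An "EPID-only" mode applies them to the image alone, for exercising
detection of leaf-versus-log disagreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "LeafError",
    "FieldPlan",
    "single_bank_error_plan",
    "both_bank_error_plan",
    "VALIDATION_ERROR_MAGNITUDES",
]

#: Signed leaf displacements used by the error-injection validation, mm.
VALIDATION_ERROR_MAGNITUDES = (0.6, -0.6, 0.8, -0.8, 1.2, -1.2, 1.8, -1.8, 2.4, -2.4)


@dataclass(frozen=True)
class LeafError:
    """One deliberate leaf displacement: (strip, pair, bank, offset mm)."""

    strip: int
    pair: int
    bank: str  # 'A', 'B' or 'both'
    offset: float

    def __post_init__(self) -> None:
        if self.bank not in ("A", "B", "both"):
            raise ValueError(f"bank must be 'A', 'B' or 'both', got {self.bank!r}")
        if not np.isfinite(self.offset):
            raise ValueError("error offset must be finite")


@dataclass
class FieldPlan:
    """Nominal description of one picket-fence field."""

    strip_nominal_width: float
    n_segments: int = 8
    segment_pitch: float = 20.0
    n_pairs: int = 48
    leaf_width: float = 5.0
    segment_mu: float = 100.0
    n_strips_analyzed: int = 5
    error_map: tuple = field(default_factory=tuple)
    epid_only_errors: bool = False

    def __post_init__(self) -> None:
        if self.strip_nominal_width <= 0:
            raise ValueError("strip_nominal_width must be positive")
        if self.n_segments < 2:
            raise ValueError("need at least two segments to form an abutment")
        if self.strip_nominal_width >= self.segment_pitch:
            raise ValueError("abutment width must be smaller than the segment pitch")
        self.error_map = tuple(
            e if isinstance(e, LeafError) else LeafError(*e) for e in self.error_map
        )
        for e in self.error_map:
            if not (0 <= e.strip < self.n_strips):
                raise ValueError(f"error strip {e.strip} outside 0..{self.n_strips - 1}")
            if not (0 <= e.pair < self.n_pairs):
                raise ValueError(f"error pair {e.pair} outside the field")
        # a pushed-together gap is undeliverable
        if (self.commanded_widths(include_errors=True) <= 0).any():
            raise ValueError("degenerate abutment: an injected error closes a gap")

    # -- layout ---------------------------------------------------------
    @property
    def n_strips(self) -> int:
        """Number of internal abutments."""
        return self.n_segments - 1

    @property
    def analyzed_strips(self) -> tuple:
        """Central ``n_strips_analyzed`` abutments (the outer ones only
        contribute scatter and are excluded from analysis)."""
        n = min(self.n_strips_analyzed, self.n_strips)
        first = (self.n_strips - n) // 2
        return tuple(range(first, first + n))

    @property
    def x_start(self) -> float:
        return -self.segment_pitch * self.n_segments / 2.0

    def strip_center_x(self, strip: int) -> float:
        """x of the abutment between segments ``strip`` and ``strip + 1``."""
        return self.x_start + self.segment_pitch * (strip + 1)

    def pair_center_y(self, pair: int) -> float:
        return (pair - (self.n_pairs - 1) / 2.0) * self.leaf_width

    @property
    def y_half_extent(self) -> float:
        return self.n_pairs * self.leaf_width / 2.0

    # -- commanded positions --------------------------------------------
    def commanded_bank_positions(self, include_errors: bool = True):
        """Commanded leaf positions, shape (n_segments, n_pairs) per bank.

        Bank A leaves travel in from the left and set each segment's left
        edge; bank B leaves set the right edge.  Gaps are carved
        symmetrically (W/2 per side) at internal boundaries only.
        """
        W = self.strip_nominal_width
        k = np.arange(self.n_segments, dtype=float)
        a_edge = self.x_start + self.segment_pitch * k + np.where(k > 0, W / 2.0, 0.0)
        b_edge = self.x_start + self.segment_pitch * (k + 1) - np.where(
            k < self.n_segments - 1, W / 2.0, 0.0
        )
        bank_a = np.tile(a_edge[:, None], (1, self.n_pairs))
        bank_b = np.tile(b_edge[:, None], (1, self.n_pairs))
        if include_errors:
            for e in self.error_map:
                if e.bank in ("B", "both"):
                    bank_b[e.strip, e.pair] += e.offset
                if e.bank in ("A", "both"):
                    bank_a[e.strip + 1, e.pair] += e.offset
        return bank_a, bank_b

    def commanded_widths(self, include_errors: bool = True) -> np.ndarray:
        """Commanded gap widths, shape (n_strips, n_pairs)."""
        bank_a, bank_b = self.commanded_bank_positions(include_errors)
        return bank_a[1:, :] - bank_b[:-1, :]

    def gap_edges(self, include_errors: bool = True):
        """Commanded (left, right) gap edges, each (n_strips, n_pairs)."""
        bank_a, bank_b = self.commanded_bank_positions(include_errors)
        return bank_b[:-1, :], bank_a[1:, :]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "strip_nominal_width": self.strip_nominal_width,
            "n_segments": self.n_segments,
            "segment_pitch": self.segment_pitch,
            "n_pairs": self.n_pairs,
            "leaf_width": self.leaf_width,
            "segment_mu": self.segment_mu,
            "n_strips_analyzed": self.n_strips_analyzed,
            "epid_only_errors": self.epid_only_errors,
            "error_map": [
                {"strip": e.strip, "pair": e.pair, "bank": e.bank, "offset": e.offset}
                for e in self.error_map
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldPlan":
        d = dict(d)
        errors = tuple(
            LeafError(e["strip"], e["pair"], e["bank"], e["offset"])
            for e in d.pop("error_map", [])
        )
        return cls(error_map=errors, **d)

    def save(self, path) -> None:
        text = (
            json.dumps(self.to_dict(), indent=2)
            if str(path).endswith(".json")
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "FieldPlan":
        with open(path) as fh:
            text = fh.read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


def single_bank_error_plan(
    width: float,
    strip: int,
    magnitudes=VALIDATION_ERROR_MAGNITUDES,
    bank: str = "A",
    first_pair: int = 1,
    **plan_kwargs,
) -> FieldPlan:
    """Validation pattern (a): each error on a unique pair, one bank only."""
    errors = tuple(
        LeafError(strip, first_pair + m, bank, off) for m, off in enumerate(magnitudes)
    )
    return FieldPlan(strip_nominal_width=width, error_map=errors, **plan_kwargs)


def both_bank_error_plan(
    width: float,
    strip: int,
    magnitudes=VALIDATION_ERROR_MAGNITUDES,
    first_pair: int = 1,
    **plan_kwargs,
) -> FieldPlan:
    """Validation pattern (b): each error on two consecutive adjacent pairs,
    both banks displaced together (the gap translates, its width is kept)."""
    errors = []
    for m, off in enumerate(magnitudes):
        for sub in (0, 1):
            errors.append(LeafError(strip, first_pair + 2 * m + sub, "both", off))
    return FieldPlan(strip_nominal_width=width, error_map=tuple(errors), **plan_kwargs)


def without_errors(plan: FieldPlan) -> FieldPlan:
    return replace(plan, error_map=())
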