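"""Synthetic linac: picket-fence and open-field portal images with logs.

The fluence model convolves each segment aperture with a two-component
penumbra kernel: a Gaussian core (focal-spot blur and panel glare, sigma
``penumbra_sigma``) mixed with a uniform ramp of full width
``leaf_end_ramp`` (weight ``ramp_fraction``) that represents the gradual
transmission change through the rounded leaf end.  The ramp component is
what makes the FWHM-versus-width calibration curve bend: below the ramp
width the abutment valley keeps filling in as the gap narrows, so the
measured FWHM responds sub-linearly, while above it the curve runs at unit
slope.  Defaults were fixed by a parameter sweep (``scripts/tune_penumbra.py``)
that places the two-segment piecewise-linear elbow of the FWHM curve at
8 mm.

Leaf motion during delivery is jittery: every 40 ms record draws a fresh
Gaussian perturbation around the commanded position, on top of a persistent
per-leaf calibration bias and a per-delivery systematic offset.  The image
is rendered from the per-segment *realized mean* positions (the same means
the log analysis recovers), so image and log agree exactly in the noiseless
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .geometry import GeometryModel
from .image import EpidImage, encode_signal
from .logfile import DeliveryLog
from .plan import FieldPlan

__all__ = [
    "BeamModel",
    "JitterModel",
    "LinacSimulator",
    "make_open_field",
    "make_picket_fence",
    "edge_response",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _ramp_antideriv(z):
    """Antiderivative of the standard normal CDF: z*Phi(z) + phi(z)."""
    return z * ndtr(z) + np.exp(-0.5 * z * z) / _SQRT2PI


def edge_response(
    x,
    sigma: float,
    ramp: float = 0.0,
    ramp_fraction: float = 0.0,
    glare_fraction: float = 0.0,
    glare_sigma: float = 8.0,
):
    """Relative fluence across a single collimated edge at x = 0.

    Rises from 0 (blocked) to 1 (open) with increasing x.  Mixture of a
    Gaussian-core edge, a boxcar-smoothed (rounded-leaf-end) edge and a
    broad Gaussian glare tail (long-range optical/radiative scatter in the
    panel), the last of which keeps the abutment valley weakly sensitive to
    width even after the core components have saturated.
    """
    x = np.asarray(x, dtype=float)
    core = ndtr(x / sigma)
    out = (1.0 - ramp_fraction - glare_fraction) * core
    if ramp_fraction > 0.0 and ramp > 0.0:
        h = ramp / 2.0
        box = (sigma / ramp) * (
            _ramp_antideriv((x + h) / sigma) - _ramp_antideriv((x - h) / sigma)
        )
        out += ramp_fraction * box
    elif ramp_fraction > 0.0:
        out += ramp_fraction * core
    if glare_fraction > 0.0:
        out += glare_fraction * ndtr(x / glare_sigma)
    return out


@dataclass
class BeamModel:
    """Beam, collimator and panel response parameters.

    penumbra_sigma : Gaussian core of the edge blur, mm at the isocenter
        plane.
    leaf_end_ramp / ramp_fraction : full width (mm) and mixture weight of
        the uniform rounded-leaf-end transmission ramp.
    glare_fraction / glare_sigma : weight and sigma (mm) of the broad
        panel-glare tail of the edge kernel.
    transmission : fluence fraction under fully blocking leaves.
    interleaf_leakage_amp : amplitude of narrow leakage ridges along the
        leaf-pair boundaries (motivation for averaging only the central
        rows of each pair band).
    per_pair_response : optional explicit multiplicative factor per pair;
        when None, factors are drawn N(1, per_pair_response_sd) per machine.
    output_fluctuation_sd : session-to-session output factor SD, shared by
        all images of a session (cancelled by open-field normalization).
    noise_sd : multiplicative Gaussian noise per pixel.
    signal_scale : decoded open-field signal level at 100 MU.
    """

    penumbra_sigma: float = 0.7
    leaf_end_ramp: float = 8.0
    ramp_fraction: float = 0.4
    glare_fraction: float = 0.05
    glare_sigma: float = 8.0
    transmission: float = 0.01
    interleaf_leakage_amp: float = 0.02
    per_pair_response: dict | None = None
    per_pair_response_sd: float = 0.02
    output_fluctuation_sd: float = 0.02
    noise_sd: float = 0.01
    signal_scale: float = 40000.0

    def __post_init__(self) -> None:
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be positive")
        if not (0.0 <= self.transmission < 1.0):
            raise ValueError("transmission must lie in [0, 1)")
        if self.per_pair_response is not None:
            for j, r in self.per_pair_response.items():
                if not (0.8 < r < 1.2):
                    raise ValueError(f"per-pair response {r} for pair {j} outside (0.8, 1.2)")

    @classmethod
    def noiseless(cls, **kw) -> "BeamModel":
        """Deterministic variant: no noise, no fluctuation, uniform response."""
        kw.setdefault("noise_sd", 0.0)
        kw.setdefault("output_fluctuation_sd", 0.0)
        kw.setdefault("per_pair_response_sd", 0.0)
        kw.setdefault("interleaf_leakage_amp", 0.0)
        return cls(**kw)


@dataclass
class JitterModel:
    """Leaf-motion jitter during delivery.

    The signed per-record error of a leaf decomposes as

        error = leaf bias + delivery offset + record jitter

    with the persistent per-leaf bias ~ N(systematic_offset_mean,
    leaf_bias_sd) drawn once per machine, the per-delivery offset
    ~ N(0, systematic_offset_sd) redrawn each session per (segment, leaf),
    and the record term ~ N(0, per_record_sd) fresh every 40 ms.  The
    defaults give a marginal per-record SD of
    sqrt(0.060^2 + 0.020^2 + 0.010^2) ~= 0.064 mm about a -0.033 mm mean.
    """

    record_interval_ms: float = 40.0
    records_per_100mu: int = 272
    per_record_sd: float = 0.060
    systematic_offset_mean: float = -0.033
    systematic_offset_sd: float = 0.010
    leaf_bias_sd: float = 0.020
    interseg_records: int = 2  # beam-off records written between segments

    def __post_init__(self) -> None:
        if self.record_interval_ms <= 0:
            raise ValueError("record_interval_ms must be positive")
        for name in ("per_record_sd", "systematic_offset_sd", "leaf_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def off(cls, **kw) -> "JitterModel":
        """Leaves land exactly on their commanded positions."""
        kw.setdefault("per_record_sd", 0.0)
        kw.setdefault("systematic_offset_mean", 0.0)
        kw.setdefault("systematic_offset_sd", 0.0)
        kw.setdefault("leaf_bias_sd", 0.0)
        return cls(**kw)

    def records_for(self, mu: float) -> int:
        return int(round(self.records_per_100mu * mu / 100.0))


class LinacSimulator:
    """A virtual linac with fixed machine traits.

    Per-machine traits (per-pair response factors and per-leaf calibration
    biases) are drawn once from ``seed`` and persist across sessions, which
    is what lets repeated calibration sessions average down random noise
    while leaving machine personality in place.
    """

    def __init__(
        self,
        beam: BeamModel | None = None,
        jitter: JitterModel | None = None,
        geometry: GeometryModel | None = None,
        n_pairs: int = 48,
        seed: int = 0,
    ):
        self.beam = beam or BeamModel()
        self.jitter = jitter or JitterModel()
        self.geometry = geometry or GeometryModel()
        self.n_pairs = n_pairs
        self.seed = int(seed)

        rng = np.random.default_rng([self.seed, 101])
        if self.beam.per_pair_response is not None:
            self.pair_response = np.ones(n_pairs)
            for j, r in self.beam.per_pair_response.items():
                self.pair_response[j] = r
        elif self.beam.per_pair_response_sd > 0:
            self.pair_response = np.clip(
                rng.normal(1.0, self.beam.per_pair_response_sd, n_pairs), 0.801, 1.199
            )
        else:
            self.pair_response = np.ones(n_pairs)
        # persistent per-leaf calibration bias, (bank, pair)
        self.leaf_bias = self.jitter.systematic_offset_mean + (
            rng.normal(0.0, 1.0, (2, n_pairs)) * self.jitter.leaf_bias_sd
        )

    def _edge(self, x):
        b = self.beam
        return edge_response(
            x, b.penumbra_sigma, b.leaf_end_ramp, b.ramp_fraction, b.glare_fraction, b.glare_sigma
        )

    # -- session-level randomness ---------------------------------------
    def _session_output(self, session: int) -> float:
        if self.beam.output_fluctuation_sd <= 0:
            return 1.0
        rng = np.random.default_rng([self.seed, 202, int(session)])
        return float(rng.normal(1.0, self.beam.output_fluctuation_sd))

    # -- delivery log ----------------------------------------------------
    def _deliver(self, plan: FieldPlan, rng: np.random.Generator) -> DeliveryLog:
        jm = self.jitter
        cmd_a, cmd_b = plan.commanded_bank_positions(include_errors=not plan.epid_only_errors)
        n_rec = jm.records_for(plan.segment_mu)
        if n_rec < 1:
            raise ValueError("segment_mu too small: no records would be generated")

        offsets = rng.normal(0.0, 1.0, (plan.n_segments, 2, self.n_pairs)) * jm.systematic_offset_sd

        times, segments, beam_on, rows_a, rows_b = [], [], [], [], []
        t = 0.0
        for k in range(plan.n_segments):
            base_a = cmd_a[k] + self.leaf_bias[0] + offsets[k, 0]
            base_b = cmd_b[k] + self.leaf_bias[1] + offsets[k, 1]
            jit = rng.normal(0.0, 1.0, (n_rec, 2, self.n_pairs)) * jm.per_record_sd
            for r in range(n_rec):
                times.append(t)
                segments.append(k)
                beam_on.append(1)
                rows_a.append(base_a + jit[r, 0])
                rows_b.append(base_b + jit[r, 1])
                t += jm.record_interval_ms
            if k < plan.n_segments - 1:
                nxt_a = cmd_a[k + 1] + self.leaf_bias[0] + offsets[k + 1, 0]
                nxt_b = cmd_b[k + 1] + self.leaf_bias[1] + offsets[k + 1, 1]
                for frac in np.linspace(0.4, 1.0, jm.interseg_records):
                    times.append(t)
                    segments.append(k + 1)
                    beam_on.append(0)
                    rows_a.append(base_a + frac * (nxt_a - base_a))
                    rows_b.append(base_b + frac * (nxt_b - base_b))
                    t += jm.record_interval_ms
        return DeliveryLog.build(times, segments, beam_on, np.array(rows_a), np.array(rows_b))

    # -- rendering -------------------------------------------------------
    def _render(self, edges_a, edges_b, plan: FieldPlan, level: float, rng) -> EpidImage:
        """Render an image from per-segment leaf edges (n_segments, n_pairs)."""
        beam, g = self.beam, self.geometry
        x = g.x_of_col(np.arange(g.cols))
        y = g.y_of_row(np.arange(g.rows))

        # group pairs with identical leaf settings; compute each unique
        # x-profile once (most pairs share the commanded positions)
        cols_key = np.vstack([edges_a, edges_b]).T  # (n_pairs, 2*n_segments)
        uniq, inverse = np.unique(cols_key, axis=0, return_inverse=True)
        profiles = np.empty((uniq.shape[0], x.size))
        ns = plan.n_segments
        for u in range(uniq.shape[0]):
            a_e, b_e = uniq[u, :ns], uniq[u, ns:]
            T = np.zeros_like(x)
            for k in range(ns):
                T += self._edge(x - a_e[k])
                T -= self._edge(x - b_e[k])
            profiles[u] = np.clip(T, 0.0, None)

        # row -> pair map (rows outside the leaf bank are fully blocked)
        y0 = -plan.y_half_extent
        pair_of_row = np.floor((y - y0) / plan.leaf_width).astype(int)
        in_band = (pair_of_row >= 0) & (pair_of_row < self.n_pairs)
        safe_pair = np.where(in_band, pair_of_row, 0)

        T_rows = profiles[inverse[safe_pair]]  # (rows, cols)
        resp = np.where(in_band, self.pair_response[safe_pair], 0.0)
        aperture = resp[:, None] * T_rows

        if beam.interleaf_leakage_amp > 0:
            bounds = y0 + plan.leaf_width * np.arange(1, self.n_pairs)
            ridge = np.zeros_like(y)
            for yb in bounds:
                ridge += np.exp(-0.5 * ((y - yb) / 0.4) ** 2)
            ridge *= beam.interleaf_leakage_amp
            aperture += np.where(in_band, ridge, 0.0)[:, None] * (1.0 - T_rows)

        # soft field border along y (jaw penumbra, Gaussian core only)
        vy = ndtr((y - y0) / beam.penumbra_sigma) - ndtr((y + y0) / beam.penumbra_sigma)
        aperture *= vy[:, None]

        frac = beam.transmission + (1.0 - beam.transmission) * np.clip(aperture, 0.0, None)
        signal = frac * level
        if beam.noise_sd > 0:
            signal = signal * (1.0 + rng.normal(0.0, beam.noise_sd, signal.shape))
        return EpidImage(pixels=encode_signal(signal), geometry=g)

    # -- public acquisitions ---------------------------------------------
    def acquire_open_field(self, session: int = 0, half_size: float = 130.0, mu: float = 100.0) -> EpidImage:
        """A square open field (default 26 x 26 cm^2 at the isocenter)."""
        beam, g = self.beam, self.geometry
        rng = np.random.default_rng([self.seed, 404, int(session)])
        x = g.x_of_col(np.arange(g.cols))
        y = g.y_of_row(np.arange(g.rows))
        ax = self._edge(x + half_size) - self._edge(x - half_size)
        ay = ndtr((y + half_size) / beam.penumbra_sigma) - ndtr((y - half_size) / beam.penumbra_sigma)
        aperture = ay[:, None] * ax[None, :]
        frac = beam.transmission + (1.0 - beam.transmission) * aperture
        level = beam.signal_scale * (mu / 100.0) * self._session_output(session)
        signal = frac * level
        if beam.noise_sd > 0:
            signal = signal * (1.0 + rng.normal(0.0, beam.noise_sd, signal.shape))
        img = EpidImage(pixels=encode_signal(signal), geometry=g)
        img.metadata.update({"kind": "open", "seed": self.seed, "session": int(session)})
        return img

    def acquire_picket_fence(self, plan: FieldPlan, session: int = 0):
        """Deliver one picket-fence field; returns (image, delivery log)."""
        if plan.n_pairs != self.n_pairs:
            raise ValueError("plan n_pairs does not match the simulator")
        tag = int(round(plan.strip_nominal_width * 100))
        rng = np.random.default_rng([self.seed, 303, int(session), tag, len(plan.error_map)])
        log = self._deliver(plan, rng)

        # realized mean positions seen by the panel during each segment
        mean_a = np.empty((plan.n_segments, self.n_pairs))
        mean_b = np.empty_like(mean_a)
        for k in range(plan.n_segments):
            a, b = log.bank_arrays(segment=k, beam_on_only=True)
            mean_a[k], mean_b[k] = a.mean(axis=0), b.mean(axis=0)
        if plan.epid_only_errors:
            base_a, base_b = plan.commanded_bank_positions(include_errors=False)
            err_a, err_b = plan.commanded_bank_positions(include_errors=True)
            mean_a += err_a - base_a
            mean_b += err_b - base_b

        level = self.beam.signal_scale * (plan.segment_mu / 100.0) * self._session_output(session)
        img = self._render(mean_a, mean_b, plan, level, rng)
        img.metadata.update(
            {
                "kind": "picket_fence",
                "seed": self.seed,
                "session": int(session),
                "nominal_width": plan.strip_nominal_width,
            }
        )
        return img, log


def make_open_field(beam: BeamModel, geometry: GeometryModel, seed: int, session: int = 0) -> EpidImage:
    return LinacSimulator(beam=beam, geometry=geometry, seed=seed).acquire_open_field(session)


def make_picket_fence(
    plan: FieldPlan,
    beam: BeamModel,
    jitter: JitterModel,
    geometry: GeometryModel,
    seed: int = 0,
    session: int = 0,
):
    sim = LinacSimulator(beam=beam, jitter=jitter, geometry=geometry, n_pairs=plan.n_pairs, seed=seed)
    return sim.acquire_picket_fence(plan, session)
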