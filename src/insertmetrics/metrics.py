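"""The five insertion-quality metrics computed on a force trace F(t).

Given the scalar force norm over the insertion window, the metrics are:

(i)   **peak force** — max F(t), in N; bounds the worst instantaneous load
      on intracochlear structures.
(ii)  **force momentum (impulse)** I = ∫ F(t) dt, in N·s; the total
      mechanical exposure over the insertion.
(iii) **over-threshold occurrences** Th — number of excursions of F above a
      fixed 0.1 N threshold (the force scale previously associated with
      intracochlear damage).
(iv)  **sudden-rise count** G — the number of steps on a coarse 0.1 s grid
      where the force at least doubles, F(t)/F(t−h) ≥ 2; a proxy for the
      local discontinuities produced by grasp–release ("fits and starts")
      advancement.
(v)   **jerk RMS** — root mean square of J = dF/dt, in N·s⁻¹; a smoothness
      measure of the gesture.

Counts (iii) and (iv) have deliberately event-like semantics: Th counts
maximal contiguous excursions (configurable to sample counting), and G is
evaluated on a grid decimated to the h = 0.1 s step with a denominator floor
at the 3 mN sensor resolution, below which ratios are noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import ForceTrace, ValidationError

__all__ = [
    "MetricConfig",
    "MetricSet",
    "peak_force",
    "momentum",
    "over_threshold_count",
    "sudden_rise_count",
    "jerk_rms",
    "compute_metric_set",
]

_DERIVATIVE_SCHEMES = ("native_diff", "lagged_diff")
_INTEGRATION_SCHEMES = ("trapezoid", "left_riemann")
_OVER_THRESHOLD_MODES = ("events", "samples")


@dataclass(frozen=True)
class MetricConfig:
    """Parameters of the metric suite.

    threshold : N — excursion threshold for Th (default 0.1).
    rise_ratio : ratio defining a sudden rise (default 2.0, i.e. a doubling;
        1.5 matches a literal "+50%" reading).
    rise_step_h : s — grid step for the sudden-rise scan (default 0.1).
    denom_floor : N — ratios with a denominator below this are skipped
        (default 0.003, the sensor resolution).
    derivative_scheme : 'native_diff' differentiates at the native sampling;
        'lagged_diff' over the rise_step_h grid.
    integration_scheme : 'trapezoid' (default) or 'left_riemann', both on
        the actual timestamps (irregular sampling is tolerated).
    over_threshold_mode : 'events' (contiguous excursions, default) or
        'samples' (raw count of samples above threshold).
    """

    threshold: float = 0.1
    rise_ratio: float = 2.0
    rise_step_h: float = 0.1
    denom_floor: float = 0.003
    derivative_scheme: str = "native_diff"
    integration_scheme: str = "trapezoid"
    over_threshold_mode: str = "events"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if not self.rise_ratio > 1:
            raise ValueError("rise_ratio must exceed 1")
        if not self.rise_step_h > 0:
            raise ValueError("rise_step_h must be positive")
        if self.denom_floor < 0:
            raise ValueError("denom_floor cannot be negative")
        if self.derivative_scheme not in _DERIVATIVE_SCHEMES:
            raise ValueError(f"derivative_scheme must be one of {_DERIVATIVE_SCHEMES}")
        if self.integration_scheme not in _INTEGRATION_SCHEMES:
            raise ValueError(f"integration_scheme must be one of {_INTEGRATION_SCHEMES}")
        if self.over_threshold_mode not in _OVER_THRESHOLD_MODES:
            raise ValueError(f"over_threshold_mode must be one of {_OVER_THRESHOLD_MODES}")


@dataclass(frozen=True)
class MetricSet:
    """The five metric values for one insertion, plus its duration."""

    peak: float
    momentum_I: float
    over_threshold_Th: int
    sudden_rise_G: int
    jerk_rms: float
    duration: float

    def __post_init__(self) -> None:
        if self.peak < 0 or self.momentum_I < 0 or self.jerk_rms < 0:
            raise ValidationError("metric values cannot be negative")
        if self.over_threshold_Th < 0 or self.sudden_rise_G < 0:
            raise ValidationError("counts cannot be negative")

    def as_dict(self) -> dict:
        """Metric values keyed by the cohort-table column names."""
        return {
            "peak_n": self.peak,
            "momentum_ns": self.momentum_I,
            "over_threshold_n": self.over_threshold_Th,
            "sudden_rise_n": self.sudden_rise_G,
            "jerk_rms_n_per_s": self.jerk_rms,
            "duration_s": self.duration,
        }


def _require(trace: ForceTrace, min_len: int, what: str) -> None:
    if trace.n_samples < min_len:
        raise ValidationError(
            f"{what} requires at least {min_len} samples, got {trace.n_samples}"
        )


def peak_force(trace: ForceTrace) -> float:
    """Maximum force over the trace, in N."""
    _require(trace, 1, "peak_force")
    return float(np.max(trace.force))


def momentum(trace: ForceTrace, cfg: MetricConfig = MetricConfig()) -> float:
    """Force momentum (impulse) I = ∫ F(t) dt over the trace, in N·s.

    Integrated numerically against the actual timestamps; trapezoid by
    default (exact for piecewise-linear signals).
    """
    _require(trace, 2, "momentum")
    dt = np.diff(trace.time)
    if cfg.integration_scheme == "left_riemann":
        return float(np.sum(trace.force[:-1] * dt))
    return float(np.trapezoid(trace.force, trace.time))


def over_threshold_count(trace: ForceTrace, cfg: MetricConfig = MetricConfig()) -> int:
    """Number of over-threshold occurrences Th.

    Default semantics: maximal contiguous excursions with force strictly
    above the threshold (an excursion already in progress at the first
    sample counts as one).  ``over_threshold_mode='samples'`` counts samples
    instead.
    """
    _require(trace, 1, "over_threshold_count")
    above = trace.force > cfg.threshold
    if cfg.over_threshold_mode == "samples":
        return int(np.count_nonzero(above))
    if not above.any():
        return 0
    rises = np.count_nonzero(above[1:] & ~above[:-1])
    return int(rises + (1 if above[0] else 0))


def _grid_indices(time: np.ndarray, h: float) -> np.ndarray:
    """Indices of the samples nearest to the grid t0, t0+h, t0+2h, ...

    A small tolerance absorbs float accumulation so a grid point landing on
    (numerically almost on) the last sample is kept.
    """
    span = time[-1] - time[0]
    n_steps = int(np.floor(span / h + 1e-9))
    grid = time[0] + h * np.arange(n_steps + 1)
    pos = np.clip(np.searchsorted(time, grid), 1, time.size - 1)
    left_closer = (grid - time[pos - 1]) < (time[pos] - grid)
    return np.where(left_closer, pos - 1, pos)


def sudden_rise_count(trace: ForceTrace, cfg: MetricConfig = MetricConfig()) -> int:
    """Sudden-rise count G: steps on the h-grid where force jumps by ≥ rise_ratio.

    The trace is decimated to a grid with spacing ``rise_step_h`` (nearest
    native sample to each grid time); G counts consecutive grid pairs with
    ``F(t)/F(t−h) ≥ rise_ratio`` and a denominator at or above
    ``denom_floor`` (ratios over a below-resolution denominator are noise
    and are skipped; a zero denominator never counts).
    """
    _require(trace, 2, "sudden_rise_count")
    if trace.duration <= cfg.rise_step_h:
        raise ValidationError(
            f"trace duration {trace.duration} s must exceed rise_step_h "
            f"{cfg.rise_step_h} s"
        )
    f = trace.force[_grid_indices(trace.time, cfg.rise_step_h)]
    prev, curr = f[:-1], f[1:]
    valid = (prev >= cfg.denom_floor) & (prev > 0)
    return int(np.count_nonzero(valid & (curr >= cfg.rise_ratio * prev)))


def jerk_rms(trace: ForceTrace, cfg: MetricConfig = MetricConfig()) -> float:
    """RMS of the jerk J = dF/dt, in N·s⁻¹.

    ``native_diff`` (default) uses first differences at the native sampling;
    ``lagged_diff`` differentiates over the coarser rise_step_h grid.  The
    RMS is taken over the n derivative samples, sqrt((1/n) Σ Jᵢ²).
    """
    _require(trace, 3, "jerk_rms")
    if cfg.derivative_scheme == "lagged_diff":
        idx = _grid_indices(trace.time, cfg.rise_step_h)
        if idx.size < 2:
            raise ValidationError("trace too short for lagged differentiation")
        t, f = trace.time[idx], trace.force[idx]
    else:
        t, f = trace.time, trace.force
    jerk = np.diff(f) / np.diff(t)
    return float(np.sqrt(np.mean(jerk**2)))


def compute_metric_set(trace: ForceTrace, cfg: MetricConfig = MetricConfig()) -> MetricSet:
    """All five metrics of a single trace, plus its duration."""
    _require(trace, 3, "compute_metric_set")
    return MetricSet(
        peak=peak_force(trace),
        momentum_I=momentum(trace, cfg),
        over_threshold_Th=over_threshold_count(trace, cfg),
        sudden_rise_G=sudden_rise_count(trace, cfg),
        jerk_rms=jerk_rms(trace, cfg),
        duration=trace.duration,
    )
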