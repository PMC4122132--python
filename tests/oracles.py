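"""Independent naive-loop reference implementations of the five metrics.

Deliberately written with explicit Python loops and no shared code with the
package, so that agreement with :mod:`insertmetrics.metrics` is a genuine
cross-check and not a tautology.
"""

from __future__ import annotations

import math


def peak_oracle(force) -> float:
    best = 0.0
    for f in force:
        if f > best:
            best = f
    return best


def momentum_trapezoid_oracle(time, force) -> float:
    total = 0.0
    for i in range(1, len(time)):
        total += 0.5 * (force[i] + force[i - 1]) * (time[i] - time[i - 1])
    return total


def momentum_fine_riemann_oracle(time, force, refine: int = 10) -> float:
    """Left Riemann sum on a linearly interpolated refinement of the trace."""
    total = 0.0
    for i in range(1, len(time)):
        t0, t1 = time[i - 1], time[i]
        f0, f1 = force[i - 1], force[i]
        dt = (t1 - t0) / refine
        for k in range(refine):
            frac = k / refine
            total += (f0 + (f1 - f0) * frac) * dt
    return total


def over_threshold_oracle(force, threshold: float) -> int:
    count = 0
    inside = False
    for f in force:
        if f > threshold and not inside:
            count += 1
            inside = True
        elif f <= threshold:
            inside = False
    return count


def _nearest_index_oracle(time, target) -> int:
    best, best_d = 0, abs(time[0] - target)
    for i in range(1, len(time)):
        d = abs(time[i] - target)
        if d < best_d:
            best, best_d = i, d
    return best


def sudden_rise_oracle(time, force, h: float, ratio: float, floor: float) -> int:
    """Eq.-style counter on the h-spaced decimated grid (nearest samples)."""
    span = time[-1] - time[0]
    n_steps = int(math.floor(span / h + 1e-9))
    grid = [time[0] + h * k for k in range(n_steps + 1)]
    decimated = [force[_nearest_index_oracle(time, g)] for g in grid]
    count = 0
    for k in range(1, len(decimated)):
        prev, curr = decimated[k - 1], decimated[k]
        if prev >= floor and prev > 0 and curr / prev >= ratio:
            count += 1
    return count


def jerk_rms_oracle(time, force) -> float:
    total = 0.0
    n = len(time) - 1
    for i in range(1, len(time)):
        j = (force[i] - force[i - 1]) / (time[i] - time[i - 1])
        total += j * j
    return math.sqrt(total / n)
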