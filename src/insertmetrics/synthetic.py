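"""Synthetic force-profile archetypes for the three insertion techniques.

No cadaver recordings are publicly deposited, so every downstream stage is
exercised on simulated traces that reproduce the qualitative profile shapes
reported for each technique, under the instrument model of the study
(100 Hz sampling, 3 mN force resolution, peaks of roughly 0.25–0.33 N):

* **forceps** — low force in the first half with transient peaks from
  repeated grasp–release cycles ("fits and starts"); peak amplitudes grow
  towards the end of the insertion.
* **motorized** — low, flat force for the first half, then a smooth,
  peak-free monotone rise to a maximum at the very end (constant-speed
  advancement at 0.8 mm/s over a 17 mm active array length sets the
  ~21 s timescale).
* **hifocus_tool** — intermediate: the slowly rising backbone of the
  motorized profile decorated with small-amplitude transients.

Tremor is the dominant high-frequency noise source and differs by
technique: both manual techniques are hand-held (forceps with two hands,
the commercial tool with one hand plus a stabilizer), while the motorized
tool hangs from a flexible arm and carries essentially only sensor noise.
The per-technique ``noise_sd`` defaults encode that, and they — not the
backbones — set the jerk-RMS ordering of the techniques.

Generation is a pure function of parameters + seed.  Forces are quantized
to the sensor resolution and clipped at zero (a norm cannot be negative),
so every generated value is a non-negative integer multiple of the
quantization step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import TECHNIQUES, ForceRecording, ValidationError

__all__ = [
    "ArchetypeParams",
    "CohortConfig",
    "default_params",
    "simulate",
    "simulate_forceps",
    "simulate_hifocus",
    "simulate_motorized",
    "simulate_cohort",
]

# Per-technique defaults: (duration s, base_peak N, n_transients, noise_sd N).
# Durations: motorized = 17 mm / 0.8 mm s⁻¹ = 21.25 s; the manual techniques
# take longer because of re-grasping pauses.  Peaks follow the reported
# scale (forceps/motorized ≈ 0.26 N, commercial tool ≈ 0.33 N).  noise_sd is
# the tremor model described in the module docstring.
_DEFAULTS = {
    "forceps": (40.0, 0.26, 12, 0.004),
    "hifocus_tool": (30.0, 0.33, 5, 0.003),
    "motorized": (21.25, 0.26, 0, 0.0015),
}


@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of one synthetic insertion.

    ``baseline`` is a small contact/friction pedestal (N) present once the
    array engages the cochlea; it keeps the quiet first half of the
    tool-guided profiles away from the quantization floor, where
    consecutive-sample ratios are pure noise.
    """

    technique: str
    duration: float
    base_peak: float
    n_transients: int
    transient_width: float = 0.3
    noise_sd: float = 0.004
    quantization: float = 0.003
    sample_rate: float = 100.0
    baseline: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValidationError(f"technique must be one of {TECHNIQUES}")
        if not self.duration > 1.0:
            raise ValidationError("duration must exceed 1 s")
        for name in ("base_peak", "transient_width", "noise_sd", "quantization", "baseline"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} cannot be negative")
        if self.n_transients < 0:
            raise ValidationError("n_transients cannot be negative")
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")


def default_params(technique: str, seed: int = 0, **overrides) -> ArchetypeParams:
    """Archetype parameters with the per-technique defaults."""
    if technique not in _DEFAULTS:
        raise ValidationError(f"technique must be one of {TECHNIQUES}")
    duration, base_peak, n_transients, noise_sd = _DEFAULTS[technique]
    p = ArchetypeParams(
        technique=technique,
        duration=duration,
        base_peak=base_peak,
        n_transients=n_transients,
        noise_sd=noise_sd,
        seed=seed,
    )
    return replace(p, **overrides) if overrides else p


def _time_grid(p: ArchetypeParams) -> np.ndarray:
    n = int(round(p.duration * p.sample_rate)) + 1
    return np.arange(n) / p.sample_rate


def _rise_backbone(t: np.ndarray, p: ArchetypeParams) -> np.ndarray:
    """Flat pedestal for the first half, then a smoothstep rise to base_peak.

    Monotone non-decreasing; reaches its maximum at the final sample.
    Shared by the motorized and hifocus archetypes so that the hifocus
    profile with no transients coincides with the motorized backbone.
    """
    x = np.clip((t - 0.5 * p.duration) / (0.5 * p.duration), 0.0, 1.0)
    s = x * x * (3.0 - 2.0 * x)
    return p.baseline + (p.base_peak - p.baseline) * s


def _bumps(
    t: np.ndarray,
    rng: np.random.Generator,
    p: ArchetypeParams,
    *,
    amp_scale: float,
    grow_with_time: bool,
) -> np.ndarray:
    """Sum of Gaussian transients at random times.

    Each transient models one grasp–release (or slide-push) event.  With
    ``grow_with_time`` the drawn amplitudes scale up with the transient's
    position in the insertion, reproducing the late amplitude growth of the
    forceps profiles.
    """
    if p.n_transients == 0:
        return np.zeros_like(t)
    centers = rng.uniform(0.08, 0.97, size=p.n_transients) * p.duration
    jitter = rng.lognormal(mean=0.0, sigma=0.25, size=p.n_transients)
    frac = centers / p.duration
    growth = (0.25 + 0.75 * frac) if grow_with_time else np.ones_like(frac)
    amps = amp_scale * p.base_peak * growth * jitter
    sigma = p.transient_width / 2.0
    out = np.zeros_like(t)
    for c, a in zip(centers, amps):
        out += a * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return out


def _finalize(t: np.ndarray, backbone: np.ndarray, rng: np.random.Generator,
              p: ArchetypeParams) -> ForceRecording:
    """Add tremor noise, quantize to the sensor resolution, clip at zero."""
    force = backbone + rng.normal(0.0, p.noise_sd, size=t.size) if p.noise_sd > 0 \
        else backbone.copy()
    if p.quantization > 0:
        force = np.round(force / p.quantization) * p.quantization
    force = np.clip(force, 0.0, None)
    # The insertion axis is aligned with the sensor's D_z axis; the norm of
    # the synthetic signal therefore lives on fz.
    zeros = np.zeros_like(force)
    return ForceRecording(
        time=t,
        fx=zeros,
        fy=zeros.copy(),
        fz=force,
        sample_rate=p.sample_rate,
        specimen_id=f"sim-{p.technique}-{p.seed}",
        technique=p.technique,
        insertion_order=1,
        seed=p.seed,
    )


def simulate_motorized(p: ArchetypeParams) -> ForceRecording:
    """Motorized archetype: quiet first half, smooth peak-free rise to the end."""
    if p.technique != "motorized":
        raise ValidationError("params.technique must be 'motorized'")
    rng = np.random.default_rng(p.seed)
    t = _time_grid(p)
    return _finalize(t, _rise_backbone(t, p), rng, p)


def simulate_hifocus(p: ArchetypeParams) -> ForceRecording:
    """Commercial-tool archetype: rising backbone plus small transients."""
    if p.technique != "hifocus_tool":
        raise ValidationError("params.technique must be 'hifocus_tool'")
    rng = np.random.default_rng(p.seed)
    t = _time_grid(p)
    backbone = _rise_backbone(t, p) + _bumps(
        t, rng, p, amp_scale=0.18, grow_with_time=False
    )
    return _finalize(t, backbone, rng, p)


def simulate_forceps(p: ArchetypeParams) -> ForceRecording:
    """Forceps archetype: shallow ramp with amplitude-growing transient peaks.

    The noise-free backbone is rescaled so its global maximum equals
    ``base_peak``; with amplitudes growing along the insertion the maximum
    lands late, as observed for manual insertions.
    """
    if p.technique != "forceps":
        raise ValidationError("params.technique must be 'forceps'")
    rng = np.random.default_rng(p.seed)
    t = _time_grid(p)
    ramp = 0.005 + 0.035 * t / p.duration
    backbone = ramp + _bumps(t, rng, p, amp_scale=1.0, grow_with_time=True)
    peak = backbone.max()
    if peak > 0:
        backbone *= p.base_peak / peak
    return _finalize(t, backbone, rng, p)


_SIMULATORS = {
    "forceps": simulate_forceps,
    "hifocus_tool": simulate_hifocus,
    "motorized": simulate_motorized,
}


def simulate(p: ArchetypeParams) -> ForceRecording:
    """Dispatch to the technique-specific simulator."""
    return _SIMULATORS[p.technique](p)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated study cohort.

    ``param_jitter`` is the relative spread (SD of a multiplicative normal
    factor) applied to base_peak and duration across pseudo-specimens,
    emulating anatomical variability.  ``order_assignment`` labels each
    recording with an insertion order: ``'cycle'`` rotates 1,2,3 within each
    technique (balanced, the default); ``'random'`` draws uniformly.
    ``order_effects`` optionally maps an insertion order to a base_peak
    multiplier, e.g. ``{3: 0.5}`` injects the force drop expected when a
    cochlea has been widened by earlier insertions.
    """

    n_per_technique: dict = field(
        default_factory=lambda: {"forceps": 10, "hifocus_tool": 8, "motorized": 8}
    )
    param_jitter: float = 0.15
    master_seed: int = 0
    order_assignment: str = "cycle"
    order_effects: dict | None = None

    def __post_init__(self) -> None:
        for tech, n in self.n_per_technique.items():
            if tech not in TECHNIQUES:
                raise ValidationError(f"unknown technique {tech!r}")
            if int(n) < 1:
                raise ValidationError("counts must be at least 1")
        if self.param_jitter < 0:
            raise ValidationError("param_jitter cannot be negative")
        if self.order_assignment not in ("cycle", "random"):
            raise ValidationError("order_assignment must be 'cycle' or 'random'")
        if self.order_effects is not None:
            for order, mult in self.order_effects.items():
                if int(order) not in (1, 2, 3) or mult < 0:
                    raise ValidationError("order_effects maps orders 1-3 to factors >= 0")


def simulate_cohort(config: CohortConfig) -> list[ForceRecording]:
    """Simulate a labelled cohort of insertions.

    Child seeds and jitter factors are drawn from a single generator seeded
    with ``master_seed``, in a fixed technique order, so the cohort is a
    pure function of its configuration.
    """
    rng = np.random.default_rng(config.master_seed)
    effects = {int(k): float(v) for k, v in (config.order_effects or {}).items()}
    recordings: list[ForceRecording] = []
    for tech in TECHNIQUES:
        n = int(config.n_per_technique.get(tech, 0))
        for i in range(n):
            child_seed = int(rng.integers(0, 2**31 - 1))
            f_peak, f_dur = 1.0 + config.param_jitter * rng.standard_normal(2)
            f_peak = float(np.clip(f_peak, 0.5, 1.5))
            f_dur = float(np.clip(f_dur, 0.5, 1.5))
            if config.order_assignment == "random":
                order = int(rng.integers(1, 4))
            else:
                order = i % 3 + 1
            base = default_params(tech, seed=child_seed)
            p = replace(
                base,
                base_peak=base.base_peak * f_peak * effects.get(order, 1.0),
                duration=base.duration * f_dur,
            )
            rec = simulate(p)
            rec.specimen_id = f"S-{tech}-{i + 1:02d}"
            rec.insertion_order = order
            recordings.append(rec)
    if not recordings:
        raise ValidationError("cohort configuration produces no recordings")
    return recordings
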