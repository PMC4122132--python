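"""Reading, validating and preparing insertion-force recordings.

A recording is the raw output of a 6-axis force/torque sensor (three linear
force channels in newtons, optionally three torque channels) sampled at a
nominal 100 Hz while an electrode array is advanced into the cochlea.  All
downstream metrics operate on the scalar Euclidean norm of the three linear
channels, the *force trace* F(t); torque channels are carried along but never
enter any metric.

File format: delimited text (CSV, or TSV for ``.tsv``/``.tab`` extensions)
with columns ``time_s, fx_n, fy_n, fz_n[, tx_nm, ty_nm, tz_nm]`` or, for
pre-normed data, ``time_s, f_norm_n``.  Study labels (``specimen_id``,
``technique``, ``insertion_order``) may appear as constant columns or be
passed explicitly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TECHNIQUES",
    "FormatError",
    "ValidationError",
    "ForceRecording",
    "ForceTrace",
    "read_recording",
    "write_recording",
    "force_norm",
    "trim_to_insertion",
    "write_trace",
    "read_trace",
]

#: The three insertion techniques under study.
TECHNIQUES = ("forceps", "hifocus_tool", "motorized")

_FORCE_COLS = ("fx_n", "fy_n", "fz_n")
_TORQUE_COLS = ("tx_nm", "ty_nm", "tz_nm")
_META_COLS = ("specimen_id", "technique", "insertion_order")


class FormatError(ValueError):
    """A file does not conform to the expected delimited-text layout."""


class ValidationError(ValueError):
    """Data violate a structural invariant (monotone time, finiteness, ...)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


def _check_finite(arr: np.ndarray, name: str) -> None:
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValidationError(f"non-finite value in {name} at row {bad[0]}")


@dataclass
class ForceRecording:
    """Raw multi-channel force series with sampling metadata and study labels.

    Parameters
    ----------
    time : array of float
        Sample timestamps in seconds, strictly increasing.
    fx, fy, fz : array of float
        Linear force channels (D_x, D_y, D_z) in newtons.  By experimental
        setup the insertion axis is aligned with D_z.
    tx, ty, tz : array of float, optional
        Torque channels in N·mm.  Stored but ignored by all metrics.
    sample_rate : float
        Nominal sampling rate in Hz (default 100).
    specimen_id : str
        Label of the temporal-bone specimen (or synthetic pseudo-specimen).
    technique : str, optional
        One of ``forceps``, ``hifocus_tool``, ``motorized``.
    insertion_order : int, optional
        Position of this insertion in the per-specimen sequence (1–3).
    seed : int, optional
        Generator seed when the recording is synthetic; ``None`` for real data.
    """

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    tx: np.ndarray | None = None
    ty: np.ndarray | None = None
    tz: np.ndarray | None = None
    sample_rate: float = 100.0
    specimen_id: str = "unknown"
    technique: str | None = None
    insertion_order: int | None = None
    seed: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        for name in ("fx", "fy", "fz"):
            arr = _as_float_array(getattr(self, name), name)
            if arr.shape != self.time.shape:
                raise ValidationError(f"{name} length differs from time")
            _check_finite(arr, name)
            setattr(self, name, arr)
        for name in ("tx", "ty", "tz"):
            val = getattr(self, name)
            if val is not None:
                arr = _as_float_array(val, name)
                if arr.shape != self.time.shape:
                    raise ValidationError(f"{name} length differs from time")
                setattr(self, name, arr)
        if self.time.size == 0:
            raise ValidationError("recording is empty")
        _check_finite(self.time, "time")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.technique is not None and self.technique not in TECHNIQUES:
            raise ValidationError(
                f"technique must be one of {TECHNIQUES}, got {self.technique!r}"
            )
        if self.insertion_order is not None:
            order = int(self.insertion_order)
            if order not in (1, 2, 3):
                raise ValidationError("insertion_order must be 1, 2 or 3")
            self.insertion_order = order

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def has_torque(self) -> bool:
        return self.tx is not None


@dataclass
class ForceTrace:
    """Scalar force-norm series F(t) over the insertion window.

    ``force`` is a Euclidean norm, hence non-negative everywhere.  Metrics
    requiring derivatives or integrals demand at least 2–3 samples; the
    per-operation preconditions enforce that.
    """

    time: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        self.force = _as_float_array(self.force, "force")
        if self.time.size == 0:
            raise ValidationError("trace is empty")
        if self.force.shape != self.time.shape:
            raise ValidationError("time and force lengths differ")
        _check_finite(self.time, "time")
        _check_finite(self.force, "force")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(self.force < 0):
            raise ValidationError("force norm cannot be negative")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def _sep_for(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab") else ","


def read_recording(
    path,
    *,
    time_unit: str = "seconds",
    sample_rate: float = 100.0,
    specimen_id: str | None = None,
    technique: str | None = None,
    insertion_order: int | None = None,
) -> ForceRecording:
    """Read a force recording from delimited text.

    ``time_unit="samples"`` interprets the time column as sample indices and
    converts via ``sample_rate``.  Metadata columns in the file populate the
    study labels unless overridden by the explicit keyword arguments.

    Raises
    ------
    FormatError
        If a required column is missing (the message names the column).
    ValidationError
        On non-monotone time or non-finite values (with the row index).
    """
    if time_unit not in ("seconds", "samples"):
        raise ValueError("time_unit must be 'seconds' or 'samples'")
    df = pd.read_csv(path, sep=_sep_for(path))
    if "time_s" not in df.columns:
        raise FormatError("missing required column 'time_s'")

    time = df["time_s"].to_numpy(dtype=float)
    if time_unit == "samples":
        time = time / float(sample_rate)

    if "f_norm_n" in df.columns and not all(c in df.columns for c in _FORCE_COLS):
        # Pre-normed dialect: store the norm on the insertion axis (D_z); the
        # transverse channels are zero so force_norm reproduces it exactly.
        norm = df["f_norm_n"].to_numpy(dtype=float)
        _check_finite(norm, "f_norm_n")
        if np.any(norm < 0):
            raise ValidationError("f_norm_n cannot be negative")
        channels = {"fx": np.zeros_like(norm), "fy": np.zeros_like(norm), "fz": norm}
    else:
        for col in _FORCE_COLS:
            if col not in df.columns:
                raise FormatError(f"missing required column '{col}'")
        channels = {
            "fx": df["fx_n"].to_numpy(dtype=float),
            "fy": df["fy_n"].to_numpy(dtype=float),
            "fz": df["fz_n"].to_numpy(dtype=float),
        }

    torques = {}
    if all(c in df.columns for c in _TORQUE_COLS):
        torques = {
            "tx": df["tx_nm"].to_numpy(dtype=float),
            "ty": df["ty_nm"].to_numpy(dtype=float),
            "tz": df["tz_nm"].to_numpy(dtype=float),
        }

    def _meta(col, override, cast=str):
        if override is not None:
            return override
        if col in df.columns:
            return cast(df[col].iloc[0])
        return None

    sid = _meta("specimen_id", specimen_id) or "unknown"
    tech = _meta("technique", technique)
    order = _meta("insertion_order", insertion_order, cast=int)

    return ForceRecording(
        time=time,
        sample_rate=sample_rate,
        specimen_id=sid,
        technique=tech,
        insertion_order=order,
        **channels,
        **torques,
    )


def write_recording(rec: ForceRecording, path) -> None:
    """Write a recording (channels plus study labels) as delimited text."""
    data = {
        "time_s": rec.time,
        "fx_n": rec.fx,
        "fy_n": rec.fy,
        "fz_n": rec.fz,
    }
    if rec.has_torque:
        data.update({"tx_nm": rec.tx, "ty_nm": rec.ty, "tz_nm": rec.tz})
    df = pd.DataFrame(data)
    df["specimen_id"] = rec.specimen_id
    if rec.technique is not None:
        df["technique"] = rec.technique
    if rec.insertion_order is not None:
        df["insertion_order"] = rec.insertion_order
    df.to_csv(path, sep=_sep_for(path), index=False)


def force_norm(rec: ForceRecording) -> ForceTrace:
    """Euclidean norm of the three linear force channels.

    ``force[i] = sqrt(fx[i]² + fy[i]² + fz[i]²)``; torque channels, if
    present, are ignored.  The result is invariant under any rotation of the
    sensor frame and reduces to ``|fz|`` when the insertion axis is exactly
    aligned with D_z.
    """
    force = np.sqrt(rec.fx**2 + rec.fy**2 + rec.fz**2)
    return ForceTrace(time=rec.time.copy(), force=force)


def trim_to_insertion(
    trace: ForceTrace,
    t_start: float | None = None,
    t_end: float | None = None,
) -> ForceTrace:
    """Restrict a trace to the insertion window [t_start, t_end], inclusive.

    The start and end timestamps come from an external source (video review
    in the original protocol) and are explicit inputs here.  Either bound may
    be omitted, defaulting to the trace support.  Time is re-zeroed so the
    trimmed trace starts at 0 s.
    """
    t0 = float(trace.time[0]) if t_start is None else float(t_start)
    t1 = float(trace.time[-1]) if t_end is None else float(t_end)
    if t0 >= t1:
        raise ValidationError("t_start must be earlier than t_end")
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not mask.any():
        raise ValidationError(
            f"window [{t0}, {t1}] does not overlap trace support "
            f"[{trace.time[0]}, {trace.time[-1]}]"
        )
    time = trace.time[mask]
    return ForceTrace(time=time - time[0], force=trace.force[mask])


def write_trace(trace: ForceTrace, path) -> None:
    """Write a force trace as delimited text with columns time_s, f_norm_n."""
    pd.DataFrame({"time_s": trace.time, "f_norm_n": trace.force}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_trace(path) -> ForceTrace:
    """Read a force trace written by :func:`write_trace`."""
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("time_s", "f_norm_n"):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}'")
    return ForceTrace(
        time=df["time_s"].to_numpy(dtype=float),
        force=df["f_norm_n"].to_numpy(dtype=float),
    )
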