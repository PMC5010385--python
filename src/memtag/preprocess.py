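"""Raw-trace preprocessing: filtering, differentiation, per-trial metrics.

Position and force traces sampled at 1 kHz are zero-phase low-pass filtered
(4th-order Butterworth, 10 Hz cutoff), velocities are obtained by numerical
differentiation, and each trial is reduced to a scalar read at the sample
of peak handle velocity: the lateral force against the channel on
error-clamp trials (rightward positive) or the lateral deviation on
force-field trials. Baseline trial values are subtracted per participant
before any analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .schedule import TrialSpec

__all__ = [
    "FilterSpec",
    "lowpass",
    "differentiate",
    "trial_metrics",
    "subtract_baseline",
    "VELOCITY_RANGE",
]

log = logging.getLogger("memtag.preprocess")

#: instructed peak-velocity window (m/s); outside it the rig warns Slow/Fast
VELOCITY_RANGE = (0.35, 0.45)


@dataclass(frozen=True)
class FilterSpec:
    cutoff_hz: float = 10.0
    order: int = 4
    fs_hz: float = 1000.0


def lowpass(trace: pd.DataFrame, spec: FilterSpec = FilterSpec()) -> pd.DataFrame:
    """Zero-phase Butterworth low-pass over every non-time column.

    Applied forward and backward (``filtfilt``), which squares the magnitude
    response and cancels phase lag; DC gain is exactly 1.
    """
    min_len = 6 * spec.order + 1
    if len(trace) <= min_len:
        raise ValueError(
            f"trace too short to filter: {len(trace)} samples <= {min_len}"
        )
    b, a = butter(spec.order, spec.cutoff_hz, fs=spec.fs_hz)
    out = trace.copy()
    for col in trace.columns:
        if col == "t_s":
            continue
        out[col] = filtfilt(b, a, trace[col].to_numpy())
    return out


def differentiate(position: np.ndarray, fs_hz: float = 1000.0) -> np.ndarray:
    """Velocity by numerical differentiation.

    Central differences in the interior, one-sided at the ends.
    """
    pos = np.asarray(position, dtype=float)
    if pos.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(pos, 1.0 / fs_hz)


def _peak_velocity_index(
    vx: np.ndarray, vy: np.ndarray, use_speed: bool = True
) -> int:
    speed = np.hypot(vx, vy) if use_speed else np.abs(vy)
    peaks = np.flatnonzero(speed == speed.max())
    if len(peaks) > 1:
        log.info("multiple identical speed maxima; taking the earliest")
    return int(peaks[0])


def trial_metrics(
    trace: pd.DataFrame,
    trial: TrialSpec,
    use_speed: bool = True,
    filter_spec: FilterSpec | None = FilterSpec(),
) -> dict[str, float]:
    """Reduce a filtered trace to the per-trial scalars.

    Returns a dict with ``peak_vel_mps`` and either ``force_N`` (clamp
    trials: lateral channel force at peak velocity, rightward positive) or
    ``lateral_dev_m`` (field trials: lateral deviation at peak velocity).
    Velocities outside the instructed range are logged as Slow/Fast.
    """
    if filter_spec is not None:
        trace = lowpass(trace, filter_spec)
    fs = filter_spec.fs_hz if filter_spec is not None else 1000.0
    if "vx_mps" in trace.columns and "vy_mps" in trace.columns:
        vx = trace["vx_mps"].to_numpy()
        vy = trace["vy_mps"].to_numpy()
    else:
        vx = differentiate(trace["x_m"].to_numpy(), fs)
        vy = differentiate(trace["y_m"].to_numpy(), fs)
    i = _peak_velocity_index(vx, vy, use_speed)
    peak = float(np.hypot(vx[i], vy[i]) if use_speed else abs(vy[i]))
    if peak < VELOCITY_RANGE[0]:
        log.warning("Slow trial: peak velocity %.3f m/s", peak)
    elif peak > VELOCITY_RANGE[1]:
        log.warning("Fast trial: peak velocity %.3f m/s", peak)
    out = {"peak_vel_mps": peak}
    if trial.trial_type == "clamp":
        out["force_N"] = float(trace["f_lat_N"].to_numpy()[i])
    else:
        out["lateral_dev_m"] = float(trace["x_m"].to_numpy()[i])
    return out


def subtract_baseline(records: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-participant baseline means from forces and deviations.

    For each participant the mean baseline error-clamp force is subtracted
    from every clamp force and the mean baseline deviation from every
    deviation. Baseline rows are retained, flagged by ``baseline_ref=True``.
    """
    if "phase" not in records.columns:
        raise ValueError("records need a 'phase' column")
    out = records.copy()
    out["baseline_ref"] = out["phase"] == "baseline"
    for pid, grp in records.groupby("participant_id"):
        base = grp[grp["phase"] == "baseline"]
        if base.empty:
            raise ValueError(f"participant {pid!r} has no baseline trials")
        clamp_base = base.loc[base["trial_type"] == "clamp", "force_N"].dropna()
        if clamp_base.empty:
            raise ValueError(f"participant {pid!r} has no baseline clamp forces")
        mask = out["participant_id"] == pid
        out.loc[mask, "force_N"] = out.loc[mask, "force_N"] - clamp_base.mean()
        dev_base = base["lateral_dev_m"].dropna()
        if not dev_base.empty:
            out.loc[mask, "lateral_dev_m"] = (
                out.loc[mask, "lateral_dev_m"] - dev_base.mean()
            )
    return out
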