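"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates three layers of a polarity-tagged force-field
experiment:

* **test-period force output** -- a shared double-exponential memory decay
  plus a polarity-locked square-wave modulation plus Gaussian trial noise:
  ``F(n) = A1 exp(B1 n) + A2 exp(B2 n) + C + polarity_sign * s(n) * m/2 + eps``,
  where ``s(n)`` is +1 under cathodal stimulation, -1 under anodal and 0
  under sham/off;
* **training-period adaptation** -- a context-gated two-state learner whose
  lateral deviations shrink within each block and whose between-field
  interference is controlled by a gating parameter ``gamma`` (1 = fully
  separate memories per context, 0 = one shared memory);
* **raw kinematics** -- 1 kHz minimum-jerk reach traces whose metric at peak
  velocity equals the requested per-trial scalar, for exercising the
  preprocessing stage end to end.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawns; equal seeds give byte-identical
cohort CSVs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import (
    Schedule,
    TrialSpec,
    generate_schedule,
    TARGET_DISTANCE_M,
)

__all__ = [
    "GenerativeParams",
    "CohortConfig",
    "simulate_test_force",
    "simulate_training",
    "simulate_trace",
    "simulate_cohort",
    "expected_block_order_contrast",
]

#: minimum-jerk peak-velocity factor: vpeak = 1.875 * d / T
MINJERK_PEAK_FACTOR = 1.875


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the synthetic cohort generator.

    Test-period force model (N): amplitudes ``A1`` (fast), ``A2`` (slow),
    offset ``C``, per-trial decay rates ``B1, B2 <= 0``, polarity modulation
    ``m`` (peak-to-peak, so each polarity contributes ±m/2), trial noise SD
    ``sigma_trial`` and between-subject SD ``sigma_subject`` applied to the
    amplitudes (A1, A2, C, m) only, keeping per-participant rate fits
    well-posed at 88 trials. ``polarity_sign=+1`` maps cathodal stimulation
    to a positive (rightward) force contribution.

    Training-period learner: retention ``a``, learning rate ``b``, context
    gating ``gamma`` in [0, 1]; lateral deviations scale with ``dev_scale``
    (m per unit of uncompensated field) plus noise ``sigma_dev``.

    Kinematics: peak velocity drawn from N(vel_mean, vel_sd), optionally
    modulated by polarity with amplitude ``vel_polarity_mod`` (peak-to-peak,
    used for velocity-control power simulations). ``baseline_offset_sd``
    injects a constant per-participant force offset into every clamp trial,
    which baseline subtraction must remove.
    """

    A1: float = -1.5
    B1: float = -0.15
    A2: float = -0.5
    B2: float = -0.01
    C: float = 0.0
    m: float = 0.7
    sigma_trial: float = 0.3
    sigma_subject: float = 0.2
    polarity_sign: float = 1.0
    gamma: float = 0.5
    a: float = 0.9
    b: float = 0.3
    dev_scale: float = 0.018
    sigma_dev: float = 0.002
    vel_mean: float = 0.40
    vel_sd: float = 0.015
    vel_polarity_mod: float = 0.0
    baseline_offset_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.B1 > 0 or self.B2 > 0:
            raise ValueError("decay rates B1, B2 must be <= 0")
        for name in ("sigma_trial", "sigma_subject", "sigma_dev", "vel_sd",
                     "baseline_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gamma", "a", "b"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.polarity_sign not in (-1.0, 1.0, -1, 1):
            raise ValueError("polarity_sign must be +1 or -1")

    def replace(self, **kw) -> "GenerativeParams":
        return dataclasses.replace(self, **kw)


def _polarity_square_wave(trials: tuple[TrialSpec, ...]) -> np.ndarray:
    """s(n): +1 under cathodal, -1 under anodal, 0 under sham/off."""
    code = {"cathodal": 1.0, "anodal": -1.0, "sham": 0.0, "off": 0.0}
    return np.array([code[t.polarity] for t in trials])


def simulate_test_force(
    schedule: Schedule,
    params: GenerativeParams,
    participant_draws: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the 88-trial test-period force series (N) for one participant.

    ``participant_draws`` may carry subject-level values for ``A1``, ``A2``,
    ``C`` and ``m`` (e.g. population draws); missing keys default to the
    population parameters. ``rng`` supplies the trial noise; with ``None``
    the series is noiseless.
    """
    test = schedule.phase_trials("test")
    if not test:
        raise ValueError("schedule has no test phase")
    d = participant_draws or {}
    A1 = d.get("A1", params.A1)
    A2 = d.get("A2", params.A2)
    C = d.get("C", params.C)
    m = d.get("m", params.m)
    n = np.arange(1, len(test) + 1, dtype=float)
    decay = A1 * np.exp(params.B1 * n) + A2 * np.exp(params.B2 * n) + C
    s = _polarity_square_wave(test)
    force = decay + params.polarity_sign * s * m / 2.0
    if rng is not None and params.sigma_trial > 0:
        force = force + rng.normal(0.0, params.sigma_trial, size=len(test))
    return force


def draw_participant(
    params: GenerativeParams, rng: np.random.Generator
) -> dict[str, float]:
    """Subject-level amplitude draws (A1, A2, C, m) for one participant."""
    s = params.sigma_subject
    return {
        "A1": params.A1 + rng.normal(0.0, s),
        "A2": params.A2 + rng.normal(0.0, s),
        "C": params.C + rng.normal(0.0, s),
        "m": params.m + rng.normal(0.0, s),
    }


def simulate_training(
    schedule: Schedule,
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate training-period behavior with a context-gated state model.

    Two memory states (one per field context) and one shared state are
    updated on field trials. On a trial in context ``c`` the motor output is
    ``gamma * x_c + (1 - gamma) * x_shared`` (in signed units of full field
    compensation, rightward-field compensation positive); the update routes
    the error with the same gating, ``x_c += gamma * b * e`` and
    ``x_shared += (1 - gamma) * b * e`` after retention ``a``. Lateral
    deviation on a field trial is ``dev_scale`` times the uncompensated
    field, signed so that deviation follows the field push direction
    (rightward field pushes rightward-positive). Clamp-trial force readout
    is ``-output * full_force`` (compensation opposes the expected field).

    Returns a frame over all trials with columns ``trial_global`` (within the
    returned training+rest subset ordering preserved), ``deviation_m`` (field
    trials) and ``force_N`` (clamp trials).
    """
    training = [t for t in schedule.trials if t.phase in ("training", "rest_clamp")]
    if not any(t.phase == "training" for t in training):
        raise ValueError("schedule has no training phase")
    gamma, a, b = params.gamma, params.a, params.b
    x = {"rightward": 0.0, "leftward": 0.0}
    x_shared = 0.0
    full_force = None
    rows = []
    for t in training:
        if t.trial_type == "field":
            sign = 1.0 if t.field.direction == "rightward" else -1.0
            ideal = sign  # full compensation in signed units
            out = gamma * x[t.field.direction] + (1.0 - gamma) * x_shared
            err = ideal - out
            dev = params.dev_scale * err
            if rng is not None and params.sigma_dev > 0:
                dev = dev + rng.normal(0.0, params.sigma_dev)
            rows.append({"deviation_m": dev, "force_N": np.nan})
            x[t.field.direction] = a * x[t.field.direction] + gamma * b * err
            x_shared = a * x_shared + (1.0 - gamma) * b * err
            if full_force is None:
                full_force = t.field.viscosity * params.vel_mean
        else:
            # clamp readout: predictive compensation for the block's context
            if t.phase == "training":
                ctx = "rightward" if t.block_index % 2 == 1 else "leftward"
                if schedule.group == "Tffrev-T":
                    ctx = "leftward" if t.block_index % 2 == 1 else "rightward"
                out = gamma * x[ctx] + (1.0 - gamma) * x_shared
            else:  # rest clamp, no stimulation: shared readout only
                out = x_shared
            ff = full_force if full_force is not None else 10.0 * params.vel_mean
            force = -out * ff
            if rng is not None and params.sigma_trial > 0:
                force = force + rng.normal(0.0, params.sigma_trial)
            rows.append({"deviation_m": np.nan, "force_N": force})
    return pd.DataFrame(rows)


def minimum_jerk_duration(distance_m: float, peak_velocity_mps: float) -> float:
    """Movement time of a minimum-jerk reach with the given peak velocity."""
    if peak_velocity_mps <= 0:
        raise ValueError("peak velocity must be > 0")
    return MINJERK_PEAK_FACTOR * distance_m / peak_velocity_mps


def simulate_trace(
    trial: TrialSpec,
    force_N: float | None = None,
    deviation_m: float | None = None,
    peak_velocity_mps: float = 0.4,
    distance_m: float = TARGET_DISTANCE_M,
    fs_hz: float = 1000.0,
    pad_s: float = 0.1,
) -> pd.DataFrame:
    """Build a 1 kHz kinematic/force trace realizing the requested metrics.

    The forward profile is a minimum-jerk reach over ``distance_m`` with the
    requested peak velocity. On clamp trials the lateral channel force
    follows a velocity-shaped bell whose value at peak velocity equals
    ``force_N`` (lateral position is clamped at zero); on field trials the
    lateral deviation is a bell whose value at peak velocity equals
    ``deviation_m``. Columns: ``t_s, x_m, y_m, vx_mps, vy_mps, f_lat_N``.
    """
    if peak_velocity_mps <= 0:
        raise ValueError("peak velocity must be > 0")
    T = minimum_jerk_duration(distance_m, peak_velocity_mps)
    dt = 1.0 / fs_hz
    n_pad = int(round(pad_s * fs_hz))
    # symmetric grid around the velocity peak so that tau = 1/2 (where the
    # peak velocity is attained) falls exactly on a sample
    half = int(np.ceil(T / 2.0 * fs_hz))
    n_move = 2 * half + 1
    tau = np.clip((np.arange(n_move) - half) * dt / T + 0.5, 0.0, 1.0)
    y = distance_m * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vy = (distance_m / T) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    bell = vy / vy.max()  # 1 exactly at peak velocity

    zeros = np.zeros(n_pad)
    t = np.arange(n_move + 2 * n_pad) * dt
    y_full = np.concatenate([zeros, y, np.full(n_pad, y[-1])])
    vy_full = np.concatenate([zeros, vy, zeros])
    bell_full = np.concatenate([zeros, bell, zeros])

    if trial.trial_type == "clamp":
        if force_N is None:
            raise ValueError("clamp trials need a force metric")
        x = np.zeros_like(t)
        f_lat = force_N * bell_full
    else:
        if deviation_m is None:
            raise ValueError("field trials need a deviation metric")
        x = deviation_m * bell_full
        f = trial.field
        k = f.viscosity if f.direction != "none" else 0.0
        sgn = {"rightward": 1.0, "leftward": -1.0, "none": 0.0}[f.direction]
        f_lat = sgn * k * vy_full
    vx = np.gradient(x, dt)
    return pd.DataFrame(
        {"t_s": t, "x_m": x, "y_m": y_full, "vx_mps": vx, "vy_mps": vy_full,
         "f_lat_N": f_lat}
    )


@dataclass(frozen=True)
class CohortConfig:
    """Which groups to simulate, how many participants, with which params."""

    groups: tuple[str, ...] = ("T-T",)
    n_per_subgroup: int = 8
    params: GenerativeParams = dataclasses.field(default_factory=GenerativeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_subgroup <= 0:
            raise ValueError("n_per_subgroup must be > 0")


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a tidy cohort table, one row per trial per participant.

    Columns: participant_id, group, subgroup, phase, block, trial_in_block,
    trial_global, trial_type, polarity, field_direction, force_N,
    lateral_dev_m, peak_vel_mps. Deterministic given ``config.seed``.
    """
    params = config.params
    root = np.random.SeedSequence(config.seed)
    frames = []
    pid = 0
    for group in config.groups:
        for subgroup in ("ACAC", "CACA"):
            sched = generate_schedule(group, subgroup)
            test_trials = sched.phase_trials("test")
            for _ in range(config.n_per_subgroup):
                pid += 1
                rng = np.random.default_rng(root.spawn(1)[0])
                draws = draw_participant(params, rng)
                offset = rng.normal(0.0, params.baseline_offset_sd)
                df = sched.to_frame(participant_id=f"P{pid:03d}")
                df["force_N"] = np.nan
                df["lateral_dev_m"] = np.nan

                vel = rng.normal(params.vel_mean, params.vel_sd, size=len(df))
                if params.vel_polarity_mod != 0.0:
                    s = _polarity_square_wave(sched.trials)
                    vel = vel + params.vel_polarity_mod * s / 2.0
                df["peak_vel_mps"] = vel

                is_clamp = df["trial_type"].to_numpy() == "clamp"
                base_mask = (df["phase"] == "baseline").to_numpy()
                # baseline: offset + noise on clamp forces, noise-only deviations
                n_base = int(base_mask.sum())
                base_force = offset + rng.normal(0, params.sigma_trial, n_base)
                base_dev = rng.normal(0, params.sigma_dev, n_base)
                force = np.full(len(df), np.nan)
                dev = np.full(len(df), np.nan)
                force[base_mask & is_clamp] = base_force[is_clamp[base_mask]]
                dev[base_mask & ~is_clamp] = base_dev[~is_clamp[base_mask]]

                train = simulate_training(sched, params, rng)
                train_mask = df["phase"].isin(["training", "rest_clamp"]).to_numpy()
                force[train_mask] = train["force_N"].to_numpy() + offset
                dev[train_mask] = train["deviation_m"].to_numpy()

                test_mask = (df["phase"] == "test").to_numpy()
                force[test_mask] = (
                    simulate_test_force(sched, params, draws, rng) + offset
                )
                df["force_N"] = force
                df["lateral_dev_m"] = dev
                frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, float_format="%.9g")


def expected_block_order_contrast(params: GenerativeParams) -> float:
    """Closed-form expectation of the block-order contrast BO on T-T cohorts.

    With the CACA-minus-ACAC orientation, each test block's expected
    trialwise difference is ``polarity_sign * m`` in blocks 1 and 3 and the
    negation in blocks 2 and 4, so
    ``E[BO] = b2 + b4 - b1 - b3 = -4 * polarity_sign * m``.
    """
    return -4.0 * params.polarity_sign * params.m
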