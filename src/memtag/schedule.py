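"""Experimental design and manipulandum physics.

This module builds the full per-participant trial schedule of a
polarity-tagged force-field adaptation experiment and provides the exact
force laws of the environment: a velocity-dependent curl force field
(``f = B v`` with ``B = [[0, k], [-k, 0]]``), a stiff spring--damper force
channel used on error-clamp trials, and the transcranial direct-current
stimulation (tDCS) current profile that alternates polarity every block.

Coordinate convention: x is rightward-positive, y points from the start
position toward the target (10 cm ahead); the start is at the origin.

A schedule contains 373 reaching trials:

* baseline -- 20 trials without field or stimulation, 12 of them error-clamp;
* training -- 12 blocks of 22 trials; trials 1-2 and 21-22 of each block are
  error-clamp trials (they cover the stimulation ramps), the middle 18 are
  force-field trials; field direction and stimulation polarity alternate
  every block;
* one error-clamp trial without stimulation after the mid-training rest;
* test -- 4 blocks of 22 error-clamp trials, polarity alternating, starting
  anodal for the ACAC subgroup and cathodal for CACA.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SUBGROUPS",
    "ForceFieldSpec",
    "ChannelSpec",
    "StimSpec",
    "TrialSpec",
    "Schedule",
    "generate_schedule",
    "field_force",
    "channel_force",
    "stim_current",
]

GROUPS = ("T-T", "S-T", "T-S", "Tffrev-T", "PPC")
SUBGROUPS = ("ACAC", "CACA")

#: design constants (number of trials / blocks)
N_BASELINE = 20
N_BASELINE_CLAMP = 12
N_TRAINING_BLOCKS = 12
N_TEST_BLOCKS = 4
TRIALS_PER_BLOCK = 22
INTER_TRIAL_INTERVAL_S = 6.0
BLOCK_DURATION_S = TRIALS_PER_BLOCK * INTER_TRIAL_INTERVAL_S  # 132 s
TARGET_DISTANCE_M = 0.10


@dataclass(frozen=True)
class ForceFieldSpec:
    """Velocity-dependent curl field: force perpendicular to hand velocity.

    ``direction`` is ``"rightward"``, ``"leftward"`` or ``"none"``;
    ``viscosity`` is the field gain in N/(m/s) (default 10).
    """

    direction: str = "none"
    viscosity: float = 10.0

    def __post_init__(self) -> None:
        if self.direction not in ("rightward", "leftward", "none"):
            raise ValueError(f"unknown field direction: {self.direction!r}")
        if not self.viscosity >= 0:
            raise ValueError("viscosity must be >= 0")


@dataclass(frozen=True)
class ChannelSpec:
    """Virtual spring--damper force channel of an error-clamp trial."""

    stiffness: float = 15_000.0  # N/m
    damping: float = 100.0  # N/(m/s)

    def __post_init__(self) -> None:
        if self.stiffness < 0 or self.damping < 0:
            raise ValueError("channel stiffness and damping must be >= 0")


@dataclass(frozen=True)
class StimSpec:
    """tDCS current profile for one block.

    Active stimulation ramps linearly from 0 to ±``amplitude`` mA over
    ``ramp_s`` seconds and then holds. Sham is identical for the first
    ``ramp_s + sham_hold_s`` seconds, then ramps back to 0 over ``ramp_s``
    and stays off, mimicking skin sensation without sustained current.
    """

    polarity: str = "off"  # anodal | cathodal | sham | off
    amplitude: float = 2.0  # mA
    ramp_s: float = 6.0
    sham_hold_s: float = 3.0

    def __post_init__(self) -> None:
        if self.polarity not in ("anodal", "cathodal", "sham", "off"):
            raise ValueError(f"unknown polarity: {self.polarity!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class TrialSpec:
    """One reaching trial's design metadata."""

    phase: str  # baseline | training | test | rest_clamp
    block_index: int  # 1-based within phase (0 for baseline / rest_clamp)
    trial_in_block: int  # 1-based
    trial_type: str  # field | clamp
    polarity: str  # anodal | cathodal | sham | off
    field: ForceFieldSpec = dc_field(default_factory=ForceFieldSpec)

    def __post_init__(self) -> None:
        if self.phase not in ("baseline", "training", "test", "rest_clamp"):
            raise ValueError(f"unknown phase: {self.phase!r}")
        if self.trial_type not in ("field", "clamp"):
            raise ValueError(f"unknown trial_type: {self.trial_type!r}")
        if self.trial_type == "clamp" and self.field.direction != "none":
            raise ValueError("clamp trials carry no force field")
        if self.phase == "test" and self.trial_type != "clamp":
            raise ValueError("test-period trials are all error-clamp trials")


@dataclass(frozen=True)
class Schedule:
    """Ordered trial list for one participant of one group/subgroup."""

    group: str
    subgroup: str
    trials: tuple[TrialSpec, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialSpec]:
        return iter(self.trials)

    def phase_trials(self, phase: str) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.phase == phase)

    def to_frame(self, participant_id: str | None = None) -> pd.DataFrame:
        """Tidy one-row-per-trial table (the schedule CSV layout)."""
        rows = []
        for i, t in enumerate(self.trials, start=1):
            rows.append(
                {
                    "participant_id": participant_id,
                    "group": self.group,
                    "subgroup": self.subgroup,
                    "phase": t.phase,
                    "block": t.block_index,
                    "trial_in_block": t.trial_in_block,
                    "trial_global": i,
                    "trial_type": t.trial_type,
                    "polarity": t.polarity,
                    "field_direction": t.field.direction,
                }
            )
        df = pd.DataFrame(rows)
        if participant_id is None:
            df = df.drop(columns=["participant_id"])
        return df


def _baseline_is_clamp(trial_index: int) -> bool:
    # deterministic interleaving: 12 clamp trials among 20; no analysis
    # depends on the within-baseline ordering, only on the count
    return trial_index % 5 in (1, 2, 3)


def _training_polarity(group: str, block: int) -> str:
    """Stimulation polarity of training block ``block`` (1-based)."""
    if group == "S-T":
        return "sham"
    # odd blocks anodal, even cathodal, for every active-training group
    return "anodal" if block % 2 == 1 else "cathodal"


def _training_field(group: str, block: int, viscosity: float) -> ForceFieldSpec:
    """Field direction of training block ``block``.

    Odd blocks are rightward for all groups except Tffrev-T, whose
    field--polarity pairing is reversed (leftward field first, so leftward
    is learned under anodal stimulation).
    """
    odd = block % 2 == 1
    if group == "Tffrev-T":
        direction = "leftward" if odd else "rightward"
    else:
        direction = "rightward" if odd else "leftward"
    return ForceFieldSpec(direction=direction, viscosity=viscosity)


def _test_polarity(group: str, subgroup: str, block: int) -> str:
    if group == "T-S":
        return "sham"
    first = "anodal" if subgroup == "ACAC" else "cathodal"
    second = "cathodal" if first == "anodal" else "anodal"
    return first if block % 2 == 1 else second


def generate_schedule(
    group: str,
    subgroup: str,
    viscosity: float = 10.0,
) -> Schedule:
    """Build the deterministic 373-trial schedule for one participant.

    Parameters
    ----------
    group
        ``"T-T"`` (active stimulation during training and test), ``"S-T"``
        (sham during training), ``"T-S"`` (sham during test), ``"Tffrev-T"``
        (field--polarity pairing reversed) or ``"PPC"`` (control stimulation
        site; identical schedule to T-T).
    subgroup
        ``"ACAC"`` or ``"CACA"`` -- the test-period polarity order
        (anodal-first vs cathodal-first). Training is identical for both.
    viscosity
        Curl-field gain in N/(m/s).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if subgroup not in SUBGROUPS:
        raise ValueError(
            f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}"
        )

    none_field = ForceFieldSpec(direction="none", viscosity=viscosity)
    trials: list[TrialSpec] = []

    for i in range(1, N_BASELINE + 1):
        trials.append(
            TrialSpec(
                phase="baseline",
                block_index=0,
                trial_in_block=i,
                trial_type="clamp" if _baseline_is_clamp(i) else "field",
                polarity="off",
                field=none_field,
            )
        )

    for block in range(1, N_TRAINING_BLOCKS + 1):
        polarity = _training_polarity(group, block)
        block_field = _training_field(group, block, viscosity)
        for j in range(1, TRIALS_PER_BLOCK + 1):
            is_clamp = j <= 2 or j >= TRIALS_PER_BLOCK - 1
            trials.append(
                TrialSpec(
                    phase="training",
                    block_index=block,
                    trial_in_block=j,
                    trial_type="clamp" if is_clamp else "field",
                    polarity=polarity,
                    field=none_field if is_clamp else block_field,
                )
            )
        if block == 8:  # 3-min rest, then one clamp trial without tDCS
            trials.append(
                TrialSpec(
                    phase="rest_clamp",
                    block_index=0,
                    trial_in_block=1,
                    trial_type="clamp",
                    polarity="off",
                    field=none_field,
                )
            )

    for block in range(1, N_TEST_BLOCKS + 1):
        polarity = _test_polarity(group, subgroup, block)
        for j in range(1, TRIALS_PER_BLOCK + 1):
            trials.append(
                TrialSpec(
                    phase="test",
                    block_index=block,
                    trial_in_block=j,
                    trial_type="clamp",
                    polarity=polarity,
                    field=none_field,
                )
            )

    return Schedule(group=group, subgroup=subgroup, trials=tuple(trials))


def field_force(velocity: Sequence[float], field: ForceFieldSpec) -> np.ndarray:
    """Curl-field force (N) for a hand velocity (m/s).

    The rightward field applies ``f = (k vy, -k vx)``; the leftward field is
    its negation. The force is always perpendicular to the velocity, so the
    field does no work on the hand.
    """
    v = np.asarray(velocity, dtype=float)
    if v.shape != (2,):
        raise ValueError("velocity must be a 2-vector (vx, vy)")
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    k = field.viscosity
    if field.direction == "none":
        return np.zeros(2)
    f = np.array([k * v[1], -k * v[0]])
    return f if field.direction == "rightward" else -f


def channel_force(
    lateral_displacement: float,
    lateral_velocity: float,
    channel: ChannelSpec = ChannelSpec(),
) -> float:
    """Restoring lateral force (N) of the error-clamp channel.

    A stiff virtual spring--damper pulls the handle back toward the straight
    start-to-target line: ``-(stiffness * x + damping * vx)``.
    """
    if not (np.isfinite(lateral_displacement) and np.isfinite(lateral_velocity)):
        raise ValueError("channel inputs must be finite")
    return -(channel.stiffness * lateral_displacement + channel.damping * lateral_velocity)


def stim_current(t_in_block: float, spec: StimSpec) -> float:
    """Stimulation current (mA) at time ``t_in_block`` seconds into a block.

    Active polarity ramps linearly to ±amplitude over ``ramp_s`` and holds
    for the rest of the block; sham follows the active profile for
    ``ramp_s + sham_hold_s`` seconds then ramps back to zero; ``off``
    delivers no current.
    """
    t = float(t_in_block)
    if t < 0:
        raise ValueError("time within block must be >= 0")
    if spec.polarity == "off":
        return 0.0
    sign = -1.0 if spec.polarity == "cathodal" else 1.0
    amp = sign * spec.amplitude
    if t < spec.ramp_s:
        level = amp * t / spec.ramp_s
    else:
        level = amp
    if spec.polarity != "sham":
        return level
    t_down = spec.ramp_s + spec.sham_hold_s
    if t < t_down:
        return level
    if t < t_down + spec.ramp_s:
        return amp * (1.0 - (t - t_down) / spec.ramp_s)
    return 0.0


def nominal_polarity(trial: TrialSpec, group: str) -> str:
    """Polarity *slot* of a trial, resolving sham to its active-schedule slot.

    Sham blocks occupy the same alternating positions as active blocks; for
    analyses that code blocks by polarity (e.g. the training-period ANOVA)
    the slot is derived from block parity, identical for all groups except
    that field--polarity pairing is reversed for Tffrev-T.
    """
    if trial.polarity in ("anodal", "cathodal"):
        return trial.polarity
    if trial.phase == "training":
        return "anodal" if trial.block_index % 2 == 1 else "cathodal"
    return trial.polarity
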