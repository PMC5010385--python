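"""Model-free test-period analysis: ΔForce, bootstrap bands, permutation tests.

The test period holds 4 blocks of 22 error-clamp trials with stimulation
polarity alternating every block and counterbalanced across two subgroups
(ACAC: anodal first; CACA: cathodal first). Because both subgroups share
the same training, the trialwise difference of their mean force outputs
(ΔForce = F̄_CACA − F̄_ACAC by default) cancels the common exponential decay
of motor memory and leaves any polarity-locked modulation as a square wave
across blocks.

Contrasts on the block means of ΔForce:

* block-order contrast ``BO = b2 + b4 − (b1 + b3)`` — the headline statistic;
* period × block-order interaction ``(b2 − b1) − (b4 − b3)`` — stability of
  the modulation across the two halves of the test period;
* consecutive block changes ``b_{i+1} − b_i``.

Uncertainty bands come from bootstrapping participants with replacement
within each subgroup; inference comes from permutation tests that relabel
participants across subgroups (or across groups, subgroup labels retained)
without replacement, with exact enumeration on small cohorts.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "DeltaForceSeries",
    "PermutationResult",
    "delta_force",
    "bootstrap_delta_force",
    "block_order_contrast",
    "period_blockorder_interaction",
    "consecutive_block_change",
    "permutation_test",
    "between_group_permutation",
    "moving_average",
    "ModelFreeAnalysis",
    "ModelFreeResults",
    "STATISTICS",
]

log = logging.getLogger("memtag.model_free")

N_TEST_TRIALS = 88
TRIALS_PER_BLOCK = 22
N_BLOCKS = 4


@dataclass
class DeltaForceSeries:
    """Trialwise subgroup-difference series over the test period."""

    values: np.ndarray  # (88,)
    block_means: np.ndarray  # (4,)
    orientation: str = "caca_minus_acac"
    boot_mean: np.ndarray | None = None
    boot_sd: np.ndarray | None = None
    boot_block_mean: np.ndarray | None = None
    boot_block_sd: np.ndarray | None = None
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_TEST_TRIALS,):
            raise ValueError(f"ΔForce series must have {N_TEST_TRIALS} trials")
        self.block_means = np.asarray(self.block_means, dtype=float)
        if self.block_means.shape != (N_BLOCKS,):
            raise ValueError("need 4 block means")


@dataclass
class PermutationResult:
    """Observed statistic, resampled null and p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    n_resamples: int
    sidedness: str
    exact: bool = False
    seed: int | None = None
    statistic: str = ""
    message: str = ""

    def __repr__(self) -> str:  # compact, results-object style
        kind = "exact" if self.exact else f"{self.n_resamples} resamples"
        return (
            f"PermutationResult({self.statistic or 'stat'}={self.observed:.4g}, "
            f"p={self.p_value:.4g}, {self.sidedness}, {kind})"
        )


# ---------------------------------------------------------------- utilities


def test_force_matrix(records: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Participant × 88 matrix of test-period clamp forces.

    Rows are ordered by participant id; trials by their order within the
    test period. Missing trials are rejected.
    """
    test = records[records["phase"] == "test"].copy()
    if test.empty:
        raise ValueError("no test-phase records")
    test = test.sort_values(["participant_id", "trial_global"])
    test["test_trial"] = test.groupby("participant_id").cumcount() + 1
    pivot = test.pivot(index="participant_id", columns="test_trial",
                       values="force_N")
    if pivot.shape[1] != N_TEST_TRIALS or pivot.isna().any().any():
        raise ValueError("every participant must cover all 88 test trials")
    return pivot.to_numpy(), list(pivot.index)


def _series_from_matrices(
    caca: np.ndarray, acac: np.ndarray, orientation: str
) -> DeltaForceSeries:
    values = caca.mean(axis=0) - acac.mean(axis=0)
    if orientation == "acac_minus_caca":
        values = -values
    elif orientation != "caca_minus_acac":
        raise ValueError(f"unknown orientation {orientation!r}")
    block_means = values.reshape(N_BLOCKS, TRIALS_PER_BLOCK).mean(axis=1)
    return DeltaForceSeries(values=values, block_means=block_means,
                            orientation=orientation)


def _split_subgroups(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    caca, _ = test_force_matrix(records[records["subgroup"] == "CACA"])
    acac, _ = test_force_matrix(records[records["subgroup"] == "ACAC"])
    return caca, acac


# ------------------------------------------------------------------- ΔForce


def delta_force(
    records_caca: pd.DataFrame,
    records_acac: pd.DataFrame,
    orientation: str = "caca_minus_acac",
) -> DeltaForceSeries:
    """Trialwise difference of subgroup mean forces over the test period."""
    caca, ids_c = test_force_matrix(records_caca)
    acac, ids_a = test_force_matrix(records_acac)
    if len(ids_c) < 2 or len(ids_a) < 2:
        raise ValueError("need at least 2 participants per subgroup")
    return _series_from_matrices(caca, acac, orientation)


def bootstrap_delta_force(
    records: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = 0,
    orientation: str = "caca_minus_acac",
) -> DeltaForceSeries:
    """ΔForce with bootstrap mean/SD bands.

    Participants are resampled with replacement independently within each
    subgroup; the per-trial and per-block mean and standard deviation over
    the replicates are attached to the returned series.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be > 0")
    caca, acac = _split_subgroups(records)
    series = _series_from_matrices(caca, acac, orientation)
    rng = np.random.default_rng(seed)
    n_c, n_a = caca.shape[0], acac.shape[0]
    reps = np.empty((n_boot, N_TEST_TRIALS))
    for i in range(n_boot):
        ci = rng.integers(0, n_c, size=n_c)
        ai = rng.integers(0, n_a, size=n_a)
        reps[i] = caca[ci].mean(axis=0) - acac[ai].mean(axis=0)
    if orientation == "acac_minus_caca":
        reps = -reps
    blocks = reps.reshape(n_boot, N_BLOCKS, TRIALS_PER_BLOCK).mean(axis=2)
    series.boot_mean = reps.mean(axis=0)
    series.boot_sd = reps.std(axis=0, ddof=0)
    series.boot_block_mean = blocks.mean(axis=0)
    series.boot_block_sd = blocks.std(axis=0, ddof=0)
    series.n_boot = n_boot
    series.seed = seed
    return series


# ---------------------------------------------------------------- contrasts


def _block_means(series) -> np.ndarray:
    if isinstance(series, DeltaForceSeries):
        return series.block_means
    b = np.asarray(series, dtype=float)
    if b.shape != (N_BLOCKS,):
        raise ValueError("need 4 block means")
    return b


def block_order_contrast(series) -> float:
    """BO = b2 + b4 − (b1 + b3): second-of-pair minus first-of-pair blocks."""
    b = _block_means(series)
    return float(b[1] + b[3] - b[0] - b[2])


def period_blockorder_interaction(series) -> float:
    """(b2 − b1) − (b4 − b3): change of the modulation across period halves."""
    b = _block_means(series)
    return float((b[1] - b[0]) - (b[3] - b[2]))


def consecutive_block_change(series, i: int) -> float:
    """b_{i+1} − b_i for i in 1..3."""
    if not 1 <= i <= 3:
        raise ValueError("block index i must be 1, 2 or 3")
    b = _block_means(series)
    return float(b[i] - b[i - 1])


#: named statistics usable in permutation tests and the CLI
STATISTICS = {
    "block_order": block_order_contrast,
    "period_block_order": period_blockorder_interaction,
    "change_1_2": lambda s: consecutive_block_change(s, 1),
    "change_2_3": lambda s: consecutive_block_change(s, 2),
    "change_3_4": lambda s: consecutive_block_change(s, 3),
}


# ------------------------------------------------------------- permutation


def _p_from_null(
    observed: float,
    null: np.ndarray,
    sidedness: str,
    exact: bool,
    correction: bool,
) -> tuple[float, str]:
    tol = 1e-12 * max(1.0, abs(observed))
    if sidedness == "two_sided":
        hits = np.abs(null) >= abs(observed) - tol
    elif sidedness == "one_sided_greater":
        hits = null >= observed - tol
    elif sidedness == "one_sided_less":
        hits = null <= observed + tol
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    count = int(hits.sum())
    message = ""
    if np.allclose(null, null[0]) and math.isclose(
        observed, float(null[0]), abs_tol=tol
    ):
        message = "degenerate statistic: all relabelings identical"
        log.warning(message)
        return 1.0, message
    if exact:
        return count / len(null), message
    if correction:
        return (count + 1) / (len(null) + 1), message
    return count / len(null), message


def permutation_test(
    records: pd.DataFrame,
    statistic=block_order_contrast,
    n_resamples: int = 10_000,
    seed: int | None = 0,
    sidedness: str = "two_sided",
    orientation: str = "caca_minus_acac",
    correction: bool = True,
    exact_threshold: int = 12,
) -> PermutationResult:
    """Permutation test of a ΔForce contrast for one group.

    The null is built by randomly reassigning the group's participants to
    two pseudo-subgroups of the original sizes (without replacement) and
    recomputing the statistic on each relabeling. With at most
    ``exact_threshold`` participants all label assignments are enumerated
    instead of sampled. The p-value is the fraction of the null at least as
    extreme as the observed value (with a +1/(N+1) finite-sample correction
    when sampling; disable with ``correction=False`` for the raw proportion).
    """
    caca, acac = _split_subgroups(records)
    if caca.shape[0] < 2 or acac.shape[0] < 2:
        raise ValueError("need at least 2 participants per subgroup")
    observed = statistic(_series_from_matrices(caca, acac, orientation))
    pool = np.vstack([caca, acac])
    n_total, n_c = pool.shape[0], caca.shape[0]

    exact = n_total <= exact_threshold
    if exact:
        combos = list(itertools.combinations(range(n_total), n_c))
        null = np.empty(len(combos))
        all_idx = frozenset(range(n_total))
        for i, combo in enumerate(combos):
            rest = sorted(all_idx - set(combo))
            null[i] = statistic(
                _series_from_matrices(pool[list(combo)], pool[rest], orientation)
            )
        n_resamples = len(combos)
    else:
        if n_resamples <= 0:
            raise ValueError("n_resamples must be > 0")
        rng = np.random.default_rng(seed)
        null = np.empty(n_resamples)
        idx = np.arange(n_total)
        for i in range(n_resamples):
            rng.shuffle(idx)
            null[i] = statistic(
                _series_from_matrices(pool[idx[:n_c]], pool[idx[n_c:]], orientation)
            )
    p, message = _p_from_null(observed, null, sidedness, exact, correction)
    name = getattr(statistic, "__name__", "")
    return PermutationResult(
        observed=observed, null_values=null, p_value=p,
        n_resamples=n_resamples, sidedness=sidedness, exact=exact,
        seed=seed, statistic=name, message=message,
    )


def between_group_permutation(
    records_g1: pd.DataFrame,
    records_g2: pd.DataFrame,
    statistic=block_order_contrast,
    n_resamples: int = 10_000,
    seed: int | None = 0,
    sidedness: str = "two_sided",
    orientation: str = "caca_minus_acac",
    correction: bool = True,
    exact_threshold: int = 12,
) -> PermutationResult:
    """Permutation test of a between-group difference of a ΔForce contrast.

    Observed value: ``statistic(G1) − statistic(G2)``. The null reassigns
    participants across the two groups while retaining their subgroup
    (ACAC/CACA) labels, preserving the original group sizes within each
    subgroup stratum.
    """
    mats = {}
    for gname, rec in (("g1", records_g1), ("g2", records_g2)):
        for sub in ("CACA", "ACAC"):
            m, _ = test_force_matrix(rec[rec["subgroup"] == sub])
            mats[gname, sub] = m

    def stat_of(groups: dict[str, dict[str, np.ndarray]]) -> float:
        s1 = _series_from_matrices(groups["g1"]["CACA"], groups["g1"]["ACAC"],
                                   orientation)
        s2 = _series_from_matrices(groups["g2"]["CACA"], groups["g2"]["ACAC"],
                                   orientation)
        return statistic(s1) - statistic(s2)

    observed = stat_of(
        {g: {s: mats[g, s] for s in ("CACA", "ACAC")} for g in ("g1", "g2")}
    )

    pools = {s: np.vstack([mats["g1", s], mats["g2", s]]) for s in ("CACA", "ACAC")}
    n1 = {s: mats["g1", s].shape[0] for s in ("CACA", "ACAC")}
    n_total = sum(p.shape[0] for p in pools.values())

    def split(sub: str, idx_g1) -> tuple[np.ndarray, np.ndarray]:
        pool = pools[sub]
        mask = np.zeros(pool.shape[0], dtype=bool)
        mask[list(idx_g1)] = True
        return pool[mask], pool[~mask]

    exact = n_total <= exact_threshold
    if exact:
        combos_c = list(itertools.combinations(range(pools["CACA"].shape[0]),
                                               n1["CACA"]))
        combos_a = list(itertools.combinations(range(pools["ACAC"].shape[0]),
                                               n1["ACAC"]))
        null = np.empty(len(combos_c) * len(combos_a))
        k = 0
        for cc in combos_c:
            c1, c2 = split("CACA", cc)
            for ca in combos_a:
                a1, a2 = split("ACAC", ca)
                null[k] = stat_of(
                    {"g1": {"CACA": c1, "ACAC": a1},
                     "g2": {"CACA": c2, "ACAC": a2}}
                )
                k += 1
        n_resamples = len(null)
    else:
        if n_resamples <= 0:
            raise ValueError("n_resamples must be > 0")
        rng = np.random.default_rng(seed)
        null = np.empty(n_resamples)
        for i in range(n_resamples):
            groups: dict[str, dict[str, np.ndarray]] = {"g1": {}, "g2": {}}
            for sub in ("CACA", "ACAC"):
                idx = rng.permutation(pools[sub].shape[0])
                g1m, g2m = split(sub, idx[: n1[sub]])
                groups["g1"][sub] = g1m
                groups["g2"][sub] = g2m
            null[i] = stat_of(groups)
    p, message = _p_from_null(observed, null, sidedness, exact, correction)
    name = getattr(statistic, "__name__", "")
    return PermutationResult(
        observed=observed, null_values=null, p_value=p,
        n_resamples=n_resamples, sidedness=sidedness, exact=exact,
        seed=seed, statistic=f"between_group({name})", message=message,
    )


def moving_average(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving mean with symmetric shrinking windows at the edges."""
    x = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(x):
        raise ValueError("window longer than series")
    h = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        hh = min(h, i, len(x) - 1 - i)
        out[i] = x[i - hh : i + hh + 1].mean()
    return out


# --------------------------------------------------- Model/Results wrapper


class ModelFreeAnalysis:
    """Model-free analysis of one group's test-period forces.

    Parameters
    ----------
    records
        Tidy trial table (cohort CSV layout), baseline-subtracted.
    group
        Optional group filter when ``records`` holds several groups.
    orientation
        ΔForce orientation; default subtracts the ACAC subgroup from CACA.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        group: str | None = None,
        orientation: str = "caca_minus_acac",
    ) -> None:
        if group is not None:
            records = records[records["group"] == group]
        if records.empty:
            raise ValueError("no records for the requested group")
        self.records = records
        self.group = group
        self.orientation = orientation

    def fit(
        self,
        statistics: tuple[str, ...] = tuple(STATISTICS),
        n_boot: int = 10_000,
        n_resamples: int = 10_000,
        seed: int | None = 0,
        sidedness: str = "two_sided",
        correction: bool = True,
    ) -> "ModelFreeResults":
        series = bootstrap_delta_force(
            self.records, n_boot=n_boot, seed=seed, orientation=self.orientation
        )
        tests = {}
        for name in statistics:
            tests[name] = permutation_test(
                self.records, STATISTICS[name], n_resamples=n_resamples,
                seed=seed, sidedness=sidedness, orientation=self.orientation,
                correction=correction,
            )
        return ModelFreeResults(series=series, tests=tests, group=self.group)


@dataclass
class ModelFreeResults:
    series: DeltaForceSeries
    tests: dict[str, PermutationResult] = dc_field(default_factory=dict)
    group: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "statistic": name,
                "observed": r.observed,
                "p_value": r.p_value,
                "sidedness": r.sidedness,
                "n_resamples": r.n_resamples,
                "exact": r.exact,
            }
            for name, r in self.tests.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Model-free ΔForce analysis"
            + (f" — group {self.group}" if self.group else ""),
            f"orientation: {self.series.orientation}; "
            f"bootstrap replicates: {self.series.n_boot}",
            "block means of ΔForce (N): "
            + ", ".join(f"b{i+1}={v:.3f}" for i, v in
                        enumerate(self.series.block_means)),
            "",
        ]
        df = self.to_frame()
        if not df.empty:
            lines.append(df.to_string(index=False,
                                      float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
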