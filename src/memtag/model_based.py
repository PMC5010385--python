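"""Model-based test-period analysis: exponential fits and mixed ANOVA.

Each participant's 88-trial test-period force series is fitted with a sum
of two exponentials, ``y = A1 exp(B1 n) + A2 exp(B2 n) + C`` (or the
single-exponential variant ``y = A exp(B n) + C``), capturing the natural
decay of motor memory; a polarity-locked effect then survives in the
residuals as a square wave across blocks. Blockwise residual means are
analyzed with a balanced mixed repeated-measures ANOVA whose factors code
the counterbalanced design:

* ``period`` — first vs second half of the 4-block test period (within);
* ``block_order`` — first vs second block of each half (within); because
  polarity alternates every block, this factor encodes stimulation polarity
  opposite-wise in the two subgroups;
* ``subgroup`` — ACAC vs CACA (between); a polarity-locked effect appears
  as the subgroup × block_order interaction;
* optionally ``group`` (between) for 4-way contrasts between experimental
  groups.

The ANOVA engine computes sums of squares for balanced factorial designs by
inclusion–exclusion over marginal means, tests between-subject effects
against the subjects-within-groups stratum and each within-subject effect
against its subject × factor interaction stratum, and reports partial eta
squared ``SS_effect / (SS_effect + SS_error)`` per effect.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schedule import nominal_polarity  # noqa: F401  (re-exported context helper)

__all__ = [
    "ExponentialDecayModel",
    "ExponentialDecayResults",
    "fit_exponential",
    "residual_block_means",
    "residual_block_table",
    "MixedAnova",
    "AnovaResults",
    "mixed_anova",
    "residual_anova",
    "velocity_anova",
    "training_anova",
]

log = logging.getLogger("memtag.model_based")

N_TEST_TRIALS = 88
TRIALS_PER_BLOCK = 22

#: deterministic multi-start grid of decay rates (per trial)
RATE_GRID = (-1.0, -0.3, -0.1, -0.03, -0.01)


# ------------------------------------------------------- exponential decay


@dataclass
class ExponentialDecayResults:
    """Per-participant exponential-decay fit."""

    model: str  # "double" | "single"
    params: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    sse: float
    converged: bool
    n_restarts_used: int

    def summary(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (
            f"{self.model}-exponential decay fit: {pars}; "
            f"SSE={self.sse:.4g} over {len(self.residuals)} trials; "
            f"converged={self.converged} ({self.n_restarts_used} starts)"
        )


class ExponentialDecayModel:
    """Sum-of-exponentials decay model of a test-period force series.

    ``y(n) = A1 exp(B1 n) + A2 exp(B2 n) + C`` with trial index ``n``
    running 1..len(y) and rates constrained non-positive. Fitted by
    variable projection: nonlinear least squares over the rates only, with
    the amplitudes profiled out by linear least squares at every step,
    started from a deterministic grid of rate pairs; the best sum of
    squared errors wins. Rate labels are canonicalized so that
    ``|B1| >= |B2|`` (fast component first).
    """

    def __init__(self, y, model: str = "double") -> None:
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or np.sum(np.isfinite(self.y)) < 10:
            raise ValueError("need a 1-D series with at least 10 finite values")
        if model not in ("double", "single"):
            raise ValueError("model must be 'double' or 'single'")
        self.model = model
        self.n = np.arange(1, len(self.y) + 1, dtype=float)

    # amplitudes given rates, by linear least squares
    def _profile(self, rates: tuple[float, ...]) -> tuple[np.ndarray, float]:
        cols = [np.exp(b * self.n) for b in rates] + [np.ones_like(self.n)]
        X = np.column_stack(cols)
        amps, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ amps
        return amps, float(resid @ resid)

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        if self.model == "double":
            a1, b1, a2, b2, c = theta
            return a1 * np.exp(b1 * self.n) + a2 * np.exp(b2 * self.n) + c
        a, b, c = theta
        return a * np.exp(b * self.n) + c

    def fit(self, xtol: float = 1e-10, ftol: float = 1e-10) -> ExponentialDecayResults:
        y = self.y
        if np.ptp(y) == 0.0:  # degenerate constant series
            c = float(y[0])
            params = (
                {"A1": 0.0, "B1": 0.0, "A2": 0.0, "B2": 0.0, "C": c}
                if self.model == "double"
                else {"A": 0.0, "B": 0.0, "C": c}
            )
            fitted = np.full_like(y, c)
            return ExponentialDecayResults(
                self.model, params, fitted, y - fitted, 0.0, True, 0
            )

        if self.model == "double":
            starts = list(itertools.combinations_with_replacement(RATE_GRID, 2))
        else:
            starts = [(b,) for b in RATE_GRID]
        n_rates = len(starts[0])

        def rate_residuals(rates: np.ndarray) -> np.ndarray:
            # variable projection: amplitudes profiled out by linear lsq
            cols = [np.exp(b * self.n) for b in rates] + [np.ones_like(self.n)]
            X = np.column_stack(cols)
            amps, *_ = np.linalg.lstsq(X, y, rcond=None)
            return X @ amps - y

        # rank starts by profiled SSE and refine only the most promising
        ranked = sorted(starts, key=lambda r: self._profile(r)[1])[:4]
        best = None
        n_used = 0
        any_success = False
        for rates in ranked:
            try:
                res = optimize.least_squares(
                    rate_residuals, np.asarray(rates, dtype=float),
                    bounds=([-5.0] * n_rates, [0.0] * n_rates),
                    method="trf", xtol=xtol, ftol=ftol, gtol=1e-12,
                    max_nfev=2000,
                )
            except Exception:  # solver failure on one start is not fatal
                continue
            n_used += 1
            any_success = any_success or bool(res.success)
            sse = float(2.0 * res.cost)
            if best is None or sse < best[0]:
                best = (sse, res.x)
        if best is None:
            raise RuntimeError("exponential fit failed from every start")
        sse, final_rates = best
        amps, sse = self._profile(tuple(final_rates))
        if self.model == "double":
            (a1, a2, c), (b1, b2) = (amps[0], amps[1], amps[2]), final_rates
            if abs(b1) < abs(b2):  # canonical order: fast component first
                a1, b1, a2, b2 = a2, b2, a1, b1
            params = {"A1": float(a1), "B1": float(b1), "A2": float(a2),
                      "B2": float(b2), "C": float(c)}
            theta = np.array([params["A1"], params["B1"], params["A2"],
                              params["B2"], params["C"]])
        else:
            params = {"A": float(amps[0]), "B": float(final_rates[0]),
                      "C": float(amps[1])}
            theta = np.array([params["A"], params["B"], params["C"]])
        fitted = self._predict(theta)
        return ExponentialDecayResults(
            self.model, params, fitted, y - fitted, sse, any_success, n_used
        )


def fit_exponential(forces, model: str = "double") -> ExponentialDecayResults:
    """Fit the decay model to one participant's test-period force series."""
    return ExponentialDecayModel(forces, model=model).fit()


# ------------------------------------------------- residual block structure

_BLOCK_PERIOD = ("first_half", "first_half", "second_half", "second_half")
_BLOCK_ORDER = ("first", "second", "first", "second")


def residual_block_means(residuals: np.ndarray | ExponentialDecayResults) -> np.ndarray:
    """Mean residual per test block (4 means over 22 trials each)."""
    if isinstance(residuals, ExponentialDecayResults):
        residuals = residuals.residuals
    r = np.asarray(residuals, dtype=float)
    if r.shape != (N_TEST_TRIALS,):
        raise ValueError(f"need {N_TEST_TRIALS} residuals")
    return r.reshape(4, TRIALS_PER_BLOCK).mean(axis=1)


def residual_block_table(
    records: pd.DataFrame, model: str = "double"
) -> pd.DataFrame:
    """Per-participant blockwise residual means in ANOVA-ready long format.

    Fits the decay model to every participant's test-period forces and
    returns one row per participant per block with factor columns
    ``period`` and ``block_order`` plus ``group`` and ``subgroup``.
    Participants whose fit does not converge from any start are excluded
    with a log entry.
    """
    from .model_free import test_force_matrix

    rows = []
    for (group, subgroup), sub in records.groupby(["group", "subgroup"]):
        mat, ids = test_force_matrix(sub)
        for pid, y in zip(ids, mat):
            fit = fit_exponential(y, model=model)
            if not fit.converged:
                log.warning("fit did not converge for %s; excluded", pid)
                continue
            bm = residual_block_means(fit)
            for b, val in enumerate(bm):
                rows.append(
                    {"participant_id": pid, "group": group,
                     "subgroup": subgroup, "block": b + 1,
                     "period": _BLOCK_PERIOD[b],
                     "block_order": _BLOCK_ORDER[b], "residual": val}
                )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- mixed ANOVA


@dataclass
class AnovaResults:
    """F table of a balanced mixed factorial design."""

    table: pd.DataFrame
    dv: str = ""
    within: tuple[str, ...] = ()
    between: tuple[str, ...] = ()

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect named {name!r}")
        return hit.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def summary(self) -> str:
        head = (
            f"Mixed ANOVA on {self.dv!r}: within={list(self.within)}, "
            f"between={list(self.between)}"
        )
        body = self.table.to_string(
            index=False, float_format=lambda v: f"{v:.4g}"
        )
        return head + "\n" + body


class MixedAnova:
    """Balanced mixed repeated-measures ANOVA.

    Parameters
    ----------
    data
        Long-format frame: one or more observations per subject per
        within-factor cell (replicates are averaged into cell means first,
        and the replicate count must be constant for balance).
    dv, subject
        Column names of the dependent variable and the subject identifier.
    within, between
        Factor column names. Every subject must hold every within cell;
        between cells must contain equally many subjects.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        within: tuple[str, ...] | list[str],
        between: tuple[str, ...] | list[str] = (),
        subject: str = "participant_id",
    ) -> None:
        self.dv = dv
        self.within = tuple(within)
        self.between = tuple(between)
        self.subject = subject
        cols = [subject, dv, *self.within, *self.between]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = data[cols].dropna(subset=[dv]).copy()
        # collapse replicates to subject × within-cell means
        keys = [subject, *self.within, *self.between]
        counts = df.groupby(keys, observed=True)[dv].count()
        if counts.nunique() != 1:
            raise ValueError(
                "unbalanced design: unequal replicate counts per "
                "subject × cell (the supported designs are balanced)"
            )
        df = df.groupby(keys, observed=True, as_index=False)[dv].mean()
        self._validate_balance(df)
        self.data = df

    def _validate_balance(self, df: pd.DataFrame) -> None:
        subj = self.subject
        # each subject sits in exactly one between cell
        if self.between:
            ncells = df.groupby(subj, observed=True)[list(self.between)].nunique()
            if (ncells > 1).any().any():
                raise ValueError("a subject appears in several between cells")
        # full within grid per subject
        n_within = int(np.prod([df[w].nunique() for w in self.within])) \
            if self.within else 1
        per_subj = df.groupby(subj, observed=True).size()
        if per_subj.nunique() != 1 or per_subj.iloc[0] != n_within:
            raise ValueError(
                "unbalanced design: every subject must hold the full "
                "within-factor grid exactly once"
            )
        # equal subjects per between cell
        if self.between:
            sizes = (
                df.drop_duplicates(subj)
                .groupby(list(self.between), observed=True)
                .size()
            )
            full = int(np.prod([df[b].nunique() for b in self.between]))
            if len(sizes) != full or sizes.nunique() != 1:
                raise ValueError(
                    "unbalanced design: between cells must contain equally "
                    "many subjects"
                )

    # --- sums of squares by inclusion–exclusion over marginal means ------

    def _marginal(self, df: pd.DataFrame, keys: tuple[str, ...]) -> np.ndarray:
        if not keys:
            return np.full(len(df), df[self.dv].mean())
        return df.groupby(list(keys), observed=True)[self.dv].transform("mean").to_numpy()

    def _ss_fixed(self, df: pd.DataFrame, term: tuple[str, ...]) -> float:
        est = np.zeros(len(df))
        for k in range(len(term) + 1):
            sign = (-1.0) ** (len(term) - k)
            for sub in itertools.combinations(term, k):
                est += sign * self._marginal(df, sub)
        return float(est @ est)

    def _ss_subject_error(self, df: pd.DataFrame) -> tuple[float, int]:
        m_subj = self._marginal(df, (self.subject,))
        m_cell = self._marginal(df, self.between)
        diff = m_subj - m_cell
        n_subj = df[self.subject].nunique()
        n_bcells = int(np.prod([df[b].nunique() for b in self.between])) \
            if self.between else 1
        return float(diff @ diff), n_subj - n_bcells

    def _ss_within_error(
        self, df: pd.DataFrame, vset: tuple[str, ...]
    ) -> tuple[float, int]:
        # subject × vset interaction within between cells
        est = np.zeros(len(df))
        for k in range(len(vset) + 1):
            for sub in itertools.combinations(vset, k):
                sign = (-1.0) ** (len(vset) - k)
                est += sign * self._marginal(df, (self.subject, *sub))
                est -= sign * self._marginal(df, (*self.between, *sub))
        n_subj = df[self.subject].nunique()
        n_bcells = int(np.prod([df[b].nunique() for b in self.between])) \
            if self.between else 1
        df_err = (n_subj - n_bcells) * int(
            np.prod([df[w].nunique() - 1 for w in vset])
        )
        return float(est @ est), df_err

    def fit(self) -> AnovaResults:
        df = self.data
        factors = [*self.between, *self.within]
        y = df[self.dv].to_numpy()
        # floating-point dust threshold: sums of squares this far below the
        # data's own scale are exact zeros of the design
        tiny = 1e-12 * (float(y @ y) + 1e-300)
        ss_subj, df_subj = self._ss_subject_error(df)
        if ss_subj < tiny:
            ss_subj = 0.0
        werr: dict[tuple[str, ...], tuple[float, int]] = {}
        rows = []
        for k in range(1, len(factors) + 1):
            for term in itertools.combinations(factors, k):
                vset = tuple(f for f in term if f in self.within)
                ss = self._ss_fixed(df, term)
                if ss < tiny:
                    ss = 0.0
                df_num = int(np.prod([df[f].nunique() - 1 for f in term]))
                if vset:
                    if vset not in werr:
                        e, d = self._ss_within_error(df, vset)
                        werr[vset] = (0.0 if e < tiny else e, d)
                    ss_err, df_err = werr[vset]
                else:
                    ss_err, df_err = ss_subj, df_subj
                if df_err <= 0:
                    raise ValueError("no residual degrees of freedom")
                ms, ms_err = ss / df_num, ss_err / df_err
                F = ms / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
                p = float(stats.f.sf(F, df_num, df_err)) if np.isfinite(F) else 0.0
                eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
                rows.append(
                    {"effect": ":".join(term), "SS": ss, "df_num": df_num,
                     "SS_err": ss_err, "df_den": df_err, "F": F, "p": p,
                     "eta_p_sq": eta}
                )
        return AnovaResults(
            table=pd.DataFrame(rows), dv=self.dv,
            within=self.within, between=self.between,
        )


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, ...] | list[str],
    between: tuple[str, ...] | list[str] = (),
    subject: str = "participant_id",
) -> AnovaResults:
    """Functional front-end for :class:`MixedAnova`."""
    return MixedAnova(data, dv, within, between, subject).fit()


# ----------------------------------------------------------- canned designs


def residual_anova(
    records: pd.DataFrame,
    model: str = "double",
    with_group_factor: bool | None = None,
) -> AnovaResults:
    """Blockwise residual ANOVA of the test period.

    Runs the 3-way design subgroup × period × block_order (between ×
    within × within); with several groups present (or
    ``with_group_factor=True``) the between factor ``group`` is added,
    giving the 4-way design. A polarity-locked force effect shows up as
    the ``subgroup:block_order`` interaction.
    """
    table = residual_block_table(records, model=model)
    between = ["subgroup"]
    n_groups = table["group"].nunique()
    if with_group_factor or (with_group_factor is None and n_groups > 1):
        between = ["group", "subgroup"]
    return mixed_anova(table, "residual", within=("period", "block_order"),
                       between=between)


def velocity_anova(records: pd.DataFrame) -> AnovaResults:
    """Same factorial machinery applied to blockwise peak-velocity means.

    A control analysis: stimulation polarity should not modulate movement
    speed, so the subgroup × block_order interaction should stay null.
    """
    test = records[records["phase"] == "test"].copy()
    if test.empty:
        raise ValueError("no test-phase records")
    test = test.sort_values(["participant_id", "trial_global"])
    test["test_trial"] = test.groupby("participant_id").cumcount()
    b = test["test_trial"] // TRIALS_PER_BLOCK
    test["period"] = np.where(b < 2, "first_half", "second_half")
    test["block_order"] = np.where(b % 2 == 0, "first", "second")
    agg = (
        test.groupby(
            ["participant_id", "group", "subgroup", "period", "block_order"],
            observed=True, as_index=False,
        )["peak_vel_mps"].mean()
    )
    between = ["subgroup"] if agg["group"].nunique() == 1 else ["group", "subgroup"]
    return mixed_anova(agg, "peak_vel_mps", within=("period", "block_order"),
                       between=between)


#: default mapping of groups to the training-period stimulation type
STIM_TYPE = {"T-T": "active", "T-S": "active", "Tffrev-T": "active",
             "PPC": "active", "S-T": "sham"}


def training_deviation_table(
    records: pd.DataFrame,
    measure: str = "first_trial",
    stim_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-participant training-period deviations in ANOVA-ready form.

    For each of the 12 training blocks, extracts either the first
    force-field trial's lateral deviation (``first_trial``: the
    interference readout) or the mean of the last two field trials
    (``last_two``: the end-of-block learning readout). Deviations are
    signed along the field push direction (rightward field positive), so
    larger values mean less compensation. Blocks are coded by nominal
    polarity slot (odd blocks anodal, even cathodal) and repetition 1..6
    within polarity; the between factor is the training stimulation type.
    """
    if measure not in ("first_trial", "last_two"):
        raise ValueError("measure must be 'first_trial' or 'last_two'")
    stim_map = stim_map or STIM_TYPE
    train = records[(records["phase"] == "training")
                    & (records["trial_type"] == "field")].copy()
    if train.empty:
        raise ValueError("no training-phase field trials")
    sign = train["field_direction"].map({"rightward": 1.0, "leftward": -1.0})
    train["aligned_dev"] = train["lateral_dev_m"] * sign
    rows = []
    for (pid, group, subgroup, block), blk in train.groupby(
        ["participant_id", "group", "subgroup", "block"], observed=True
    ):
        blk = blk.sort_values("trial_global")
        if measure == "first_trial":
            val = blk["aligned_dev"].iloc[0]
        else:
            val = blk["aligned_dev"].iloc[-2:].mean()
        rows.append(
            {"participant_id": pid, "group": group, "subgroup": subgroup,
             "stim_type": stim_map.get(group, "active"),
             "polarity": "anodal" if block % 2 == 1 else "cathodal",
             "block_rep": (block + 1) // 2, "deviation_m": val}
        )
    out = pd.DataFrame(rows)
    if out.groupby("participant_id").size().nunique() != 1 or \
            out.groupby("participant_id").size().iloc[0] != 12:
        raise ValueError("every participant needs 12 training blocks")
    return out


def training_anova(
    records: pd.DataFrame,
    measure: str = "first_trial",
    stim_map: dict[str, str] | None = None,
) -> AnovaResults:
    """Training-period deviation ANOVA: polarity × block within, stimulation type between.

    ``polarity`` has 2 levels (anodal/cathodal slots) and ``block_rep`` 6
    levels (the six repetitions of each polarity); the between factor is
    the training stimulation type (dropped automatically when only one
    level is present).
    """
    table = training_deviation_table(records, measure=measure, stim_map=stim_map)
    between = ("stim_type",) if table["stim_type"].nunique() > 1 else ()
    return mixed_anova(table, "deviation_m", within=("polarity", "block_rep"),
                       between=between)
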