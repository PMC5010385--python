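"""End-to-end pipeline: simulate → preprocess → analyze → report.

A :class:`RunConfig` (YAML-serializable) fixes the cohort composition, the
generative parameters, the resampling sizes and a single seed; a run writes
the cohort CSV, model-free and model-based result JSONs, the PPV block,
optional figures, and a manifest recording seeds and versions so a run can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .meta_ppv import PPVInputs, compute_ppv
from .model_based import residual_anova, velocity_anova, training_anova
from .model_free import ModelFreeAnalysis, between_group_permutation, STATISTICS
from .preprocess import subtract_baseline
from .schedule import (
    N_BASELINE,
    N_TEST_BLOCKS,
    N_TRAINING_BLOCKS,
    TRIALS_PER_BLOCK,
)
from .synthcohort import CohortConfig, GenerativeParams, simulate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_cohort"]

log = logging.getLogger("memtag.pipeline")


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    groups: tuple[str, ...] = ("T-T", "S-T")
    n_per_subgroup: int = 8
    params: GenerativeParams = dc_field(default_factory=GenerativeParams)
    n_boot: int = 10_000
    n_resamples: int = 10_000
    sidedness: str = "two_sided"
    orientation: str = "caca_minus_acac"
    group_pairs: tuple[tuple[str, str], ...] = ()
    make_figures: bool = False
    out_dir: str = "memtag_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["group_pairs"] = [list(p) for p in self.group_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = GenerativeParams(**d["params"])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        if "group_pairs" in d:
            d["group_pairs"] = tuple(tuple(p) for p in d["group_pairs"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _anova_to_dict(res) -> list[dict]:
    return res.to_frame().to_dict(orient="records")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and write all outputs.

    Returns the report dict (also written to ``report.json``); outputs are
    the cohort CSV, per-group model-free tests, between-group contrasts for
    every configured group pair, residual/velocity/training ANOVA tables,
    the PPV block and a manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(
        CohortConfig(groups=config.groups, n_per_subgroup=config.n_per_subgroup,
                     params=config.params, seed=config.seed)
    )
    write_cohort(cohort, out / "cohort.csv")
    analyzed = subtract_baseline(cohort)

    report: dict = {"version": __version__, "seed": config.seed}

    model_free: dict = {}
    for group in config.groups:
        res = ModelFreeAnalysis(
            analyzed, group=group, orientation=config.orientation
        ).fit(
            n_boot=config.n_boot, n_resamples=config.n_resamples,
            seed=config.seed, sidedness=config.sidedness,
        )
        model_free[group] = {
            "block_means": res.series.block_means.tolist(),
            "boot_block_sd": None if res.series.boot_block_sd is None
            else res.series.boot_block_sd.tolist(),
            "tests": {
                name: {
                    "observed": t.observed, "p_value": t.p_value,
                    "n_resamples": t.n_resamples, "exact": t.exact,
                    "sidedness": t.sidedness, "seed": t.seed,
                }
                for name, t in res.tests.items()
            },
        }
        if config.make_figures:
            from .plotting import plot_delta_force

            ax = plot_delta_force(res.series)
            ax.set_title(f"ΔForce — {group}")
            ax.figure.savefig(out / f"delta_force_{group.replace('/', '_')}.svg")
    for g1, g2 in config.group_pairs:
        t = between_group_permutation(
            analyzed[analyzed["group"] == g1], analyzed[analyzed["group"] == g2],
            STATISTICS["block_order"], n_resamples=config.n_resamples,
            seed=config.seed, sidedness=config.sidedness,
            orientation=config.orientation,
        )
        model_free[f"{g1} vs {g2}"] = {
            "observed": t.observed, "p_value": t.p_value,
            "n_resamples": t.n_resamples, "exact": t.exact,
        }
    (out / "model_free.json").write_text(json.dumps(model_free, indent=2))
    report["model_free"] = model_free

    model_based: dict = {}
    for group in config.groups:
        sub = analyzed[analyzed["group"] == group]
        model_based[group] = {
            "residual_anova": _anova_to_dict(residual_anova(sub)),
            "velocity_anova": _anova_to_dict(velocity_anova(sub)),
        }
    if len(config.groups) > 1:
        model_based["all_groups"] = {
            "residual_anova_4way": _anova_to_dict(residual_anova(analyzed)),
        }
    try:
        model_based["training_anova"] = _anova_to_dict(training_anova(analyzed))
    except ValueError as err:  # e.g. unbalanced stimulation-type cells
        model_based["training_anova"] = {"skipped": str(err)}
        log.warning("training ANOVA skipped: %s", err)
    (out / "model_based.json").write_text(json.dumps(model_based, indent=2))
    report["model_based"] = model_based

    ppv_inputs = PPVInputs()
    report["ppv"] = {
        "power": ppv_inputs.power, "alpha": ppv_inputs.alpha,
        "k_significant": ppv_inputs.k_significant, "n_groups": ppv_inputs.n_groups,
        "ppv": compute_ppv(ppv_inputs),
    }

    manifest = {
        "memtag_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


# ----------------------------------------------------------------- checks

_PHASE_COUNTS = {
    "baseline": N_BASELINE,
    "training": N_TRAINING_BLOCKS * TRIALS_PER_BLOCK,
    "rest_clamp": 1,
    "test": N_TEST_BLOCKS * TRIALS_PER_BLOCK,
}


def validate_cohort(cohort: pd.DataFrame) -> list[str]:
    """Check schedule invariants of a cohort table; return violation messages.

    Per participant: 373 trials split 20/264/1/88 across phases, all test
    trials error-clamp, training clamp trials at block positions 1-2 and
    21-22, and stimulation polarity alternating between consecutive active
    blocks. Violations are reported without aborting.
    """
    problems: list[str] = []
    for pid, grp in cohort.groupby("participant_id"):
        total = len(grp)
        if total != sum(_PHASE_COUNTS.values()):
            problems.append(f"{pid}: {total} trials, expected 373")
        for phase, expect in _PHASE_COUNTS.items():
            got = int((grp["phase"] == phase).sum())
            if got != expect:
                problems.append(f"{pid}: phase {phase} has {got} trials, "
                                f"expected {expect}")
        test = grp[grp["phase"] == "test"]
        if not (test["trial_type"] == "clamp").all():
            problems.append(f"{pid}: non-clamp trials in the test period")
        train = grp[grp["phase"] == "training"]
        clamp_pos = train.loc[train["trial_type"] == "clamp", "trial_in_block"]
        if not clamp_pos.isin([1, 2, TRIALS_PER_BLOCK - 1, TRIALS_PER_BLOCK]).all():
            problems.append(f"{pid}: training clamp trials misplaced")
        for phase in ("training", "test"):
            ph = grp[grp["phase"] == phase]
            pol = (
                ph[ph["polarity"].isin(["anodal", "cathodal"])]
                .groupby("block")["polarity"]
                .agg(lambda s: s.iloc[0] if s.nunique() == 1 else "mixed")
            )
            if (pol == "mixed").any():
                problems.append(f"{pid}: mixed polarity within a {phase} block")
            vals = pol[pol != "mixed"]
            if len(vals) > 1 and (vals.values[1:] == vals.values[:-1]).any():
                problems.append(f"{pid}: polarity does not alternate in {phase}")
    return problems
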