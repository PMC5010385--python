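"""Independent brute-force oracles shared by the test suite.

Everything here recomputes quantities from first principles (explicit
enumeration, contrast projections) without touching the package's own
implementation paths.
"""

import itertools

import numpy as np
import pandas as pd


def enumeration_permutation_p(forces: np.ndarray, n_first: int) -> tuple[float, float]:
    """Exhaustive two-sided permutation p for the block-order contrast.

    ``forces`` is a (participants × 88) matrix whose first ``n_first`` rows
    form one subgroup. Returns (observed, p). Computed directly from block
    means and explicit enumeration of all subgroup assignments.
    """
    n_total = forces.shape[0]
    bm = forces.reshape(n_total, 4, 22).mean(axis=2)
    contrast = bm[:, 1] + bm[:, 3] - bm[:, 0] - bm[:, 2]
    obs = contrast[:n_first].mean() - contrast[n_first:].mean()
    null = []
    for combo in itertools.combinations(range(n_total), n_first):
        rest = [i for i in range(n_total) if i not in combo]
        null.append(contrast[list(combo)].mean() - contrast[rest].mean())
    null = np.asarray(null)
    p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
    return float(obs), p


def bruteforce_anova_2x2x2(df: pd.DataFrame) -> tuple[dict, float, dict]:
    """Sums of squares of a balanced 2(between)×2×2(within) design.

    Built from explicit ±1 contrast projections over the observation vector
    and direct subject-mean arithmetic for the error strata. Returns
    (fixed-effect SS by name, subjects-within-groups SS, within-error SS by
    within-term name). Expects columns participant_id, between, P, Q, y.
    """
    df = df.sort_values(["participant_id", "P", "Q"]).reset_index(drop=True)
    y = df["y"].to_numpy()
    cg = np.where(df["between"] == "g1", 1.0, -1.0)
    cp = np.where(df["P"] == "p1", 1.0, -1.0)
    cq = np.where(df["Q"] == "q1", 1.0, -1.0)
    ss = {}
    for name, x in [
        ("between", cg), ("P", cp), ("Q", cq), ("between:P", cg * cp),
        ("between:Q", cg * cq), ("P:Q", cp * cq),
        ("between:P:Q", cg * cp * cq),
    ]:
        ss[name] = (x @ y) ** 2 / (x @ x)
    subj_means = df.groupby("participant_id")["y"].mean()
    group_of = df.drop_duplicates("participant_id").set_index(
        "participant_id"
    )["between"]
    grp_means = subj_means.groupby(group_of).mean()
    ss_subj = 4 * sum(
        (subj_means[s] - grp_means[group_of[s]]) ** 2 for s in subj_means.index
    )
    err = {}
    for name, cw in (("P", cp), ("Q", cq), ("P:Q", cp * cq)):
        scores = pd.Series(cw * y, index=df["participant_id"]).groupby(level=0).mean()
        grp_sc = scores.groupby(group_of).mean()
        err[name] = 4 * sum(
            (scores[s] - grp_sc[group_of[s]]) ** 2 for s in scores.index
        )
    return ss, float(ss_subj), err
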