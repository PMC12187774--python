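"""Group-level evaluation of patient-sorting rules.

Individual treatment effects are never observed, so an uplift model is
scored on aggregates: patients are sorted by descending predicted uplift
and, for each cumulative fraction p of the cohort, the incremental number
of beneficial outcomes attributable to treatment in that head is

    q(p) = Y_T(p) - Y_C(p) * N_T(p) / N_C(p),

where Y/N are beneficial-outcome sums and patient counts among treated and
controls within the head.  The curve of q over p is the Qini curve; its
trapezoidal area (on the q / N_T normalized scale, with the origin
prepended) is the AUQC.  Two benchmarks bracket any model: the expected
AUQC of a random ordering (a straight line to q(1), area q_norm(1)/2) and
an idealized ordering built from the observed outcomes.

Also here: uplift-by-decile summaries, the Mann-Whitney AUROC and Wald
proportion intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


def default_grid() -> np.ndarray:
    """p = 0.01, 0.02, ..., 1.00 (dense enough that trapezoid error is
    negligible at cohort sizes used here)."""
    return np.round(np.arange(1, 101) / 100.0, 2)


@dataclass
class QiniCurve:
    grid: np.ndarray
    q_raw: np.ndarray
    q_norm: np.ndarray
    n_treated: int
    n_control: int

    @property
    def auqc(self) -> float:
        return auqc(self)


def _check_arms(arms: np.ndarray) -> None:
    if arms.min() == arms.max():
        raise ValueError("evaluation set must contain both arms")


def order_by_scores(scores: np.ndarray, tie_seed: int = 0) -> np.ndarray:
    """Permutation sorting scores descending; ties broken by a seeded
    random permutation (applied once, reproducibly)."""
    scores = np.asarray(scores, dtype=float)
    perm = np.random.default_rng(tie_seed).permutation(len(scores))
    return np.lexsort((perm, -scores))


def qini_from_ordering(
    ordering: np.ndarray,
    arms: np.ndarray,
    outcomes: np.ndarray,
    grid: np.ndarray | None = None,
) -> QiniCurve:
    """Qini curve for an explicit patient ordering.

    The head at quantile p holds the first ceil(p * N) patients.  A head
    with no controls contributes q(p) = Y_T(p) (the control term is taken
    as 0 — the only finite continuous completion at small p).
    """
    arms = np.asarray(arms, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_arms(arms)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    n = len(arms)
    a = arms[ordering]
    y = outcomes[ordering]
    cum_ty = np.cumsum(y * a)
    cum_cy = np.cumsum(y * (1 - a))
    cum_t = np.cumsum(a)
    cum_c = np.cumsum(1 - a)
    heads = np.ceil(grid * n).astype(int) - 1
    nc = cum_c[heads]
    with np.errstate(divide="ignore", invalid="ignore"):
        penalty = np.where(nc > 0, cum_cy[heads] * cum_t[heads] / np.maximum(nc, 1), 0.0)
    q_raw = cum_ty[heads] - penalty
    n_t = int(arms.sum())
    return QiniCurve(
        grid=grid,
        q_raw=q_raw,
        q_norm=q_raw / n_t,
        n_treated=n_t,
        n_control=n - n_t,
    )


def qini_curve(
    scores: np.ndarray,
    arms: np.ndarray,
    outcomes: np.ndarray,
    grid: np.ndarray | None = None,
    tie_seed: int = 0,
) -> QiniCurve:
    """Qini curve of a scoring rule (patients sorted by descending score)."""
    return qini_from_ordering(order_by_scores(scores, tie_seed), arms, outcomes, grid)


def auqc(curve: QiniCurve) -> float:
    """Trapezoidal area under the normalized Qini curve, from the origin."""
    if len(curve.grid) < 2:
        raise ValueError("need at least 2 grid points to integrate")
    p = np.concatenate(([0.0], curve.grid))
    q = np.concatenate(([0.0], curve.q_norm))
    return float(np.trapezoid(q, p))


def random_benchmark_auqc(
    arms: np.ndarray,
    outcomes: np.ndarray,
    n_reps: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[float, tuple[float, float]]:
    """Mean AUQC (with percentile 95% CI) over uniformly random orderings.

    In expectation a random ordering gives a straight-line Qini curve, so
    the mean approaches q_norm(1) / 2.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(np.asarray(arms))
    values = np.empty(n_reps)
    for r in range(n_reps):
        curve = qini_from_ordering(rng.permutation(n), arms, outcomes, grid)
        values[r] = auqc(curve)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(values.mean()), (float(lo), float(hi))


def optimal_ordering(
    arms: np.ndarray, outcomes: np.ndarray, mode: str = "persuadable_proxy"
) -> np.ndarray:
    """Idealized best-case ordering built from the observed outcomes.

    ``persuadable_proxy`` (default): treated successes, then control
    failures, then treated failures, finally control successes.  Placing
    every treated success first and every control success last attains the
    maximum achievable AUQC under the zero-control-head convention (the
    middle blocks leave the curve flat).  ``treated_successes_first`` is the
    stricter reading in which only treated successes count as identifiable
    Persuadables and the middle block keeps input order.  Ties within a
    block keep input order.
    """
    arms = np.asarray(arms, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    if mode == "persuadable_proxy":
        rank = np.select(
            [
                (arms == 1) & (outcomes == 1),
                (arms == 0) & (outcomes == 0),
                (arms == 1) & (outcomes == 0),
            ],
            [0, 1, 2],
            default=3,
        )
    elif mode == "treated_successes_first":
        rank = np.select(
            [(arms == 1) & (outcomes == 1), (arms == 0) & (outcomes == 1)],
            [0, 2],
            default=1,
        )
    else:
        raise ValueError(f"unknown optimal-ordering mode {mode!r}")
    return np.argsort(rank, kind="stable")


def optimal_benchmark_auqc(
    arms: np.ndarray,
    outcomes: np.ndarray,
    grid: np.ndarray | None = None,
    mode: str = "persuadable_proxy",
) -> float:
    """AUQC of the idealized ordering (upper benchmark for any model)."""
    ordering = optimal_ordering(arms, outcomes, mode)
    return auqc(qini_from_ordering(ordering, arms, outcomes, grid))


@dataclass
class DecileSummary:
    """Observed uplift per predicted-uplift decile (bin 1 = top 0-10%)."""

    table: pd.DataFrame  # columns: decile, n_treat, n_control, mean_treat,
    #                      mean_control, uplift (NaN where an arm is empty)


def uplift_by_decile(
    scores: np.ndarray, arms: np.ndarray, outcomes: np.ndarray
) -> DecileSummary:
    """Bin patients by deciles of the pooled score distribution and report
    the observed treated-minus-control outcome difference per bin.

    Bins that lack one arm (or, with heavily tied scores, lack patients
    entirely) carry NaN uplift — flagged missing rather than zero.
    """
    scores = np.asarray(scores, dtype=float)
    arms = np.asarray(arms, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_arms(arms)
    edges = np.quantile(scores, np.linspace(0.0, 1.0, 11))
    # ascending bin index 0..9; right-closed interior edges so ties collapse
    asc = np.digitize(scores, edges[1:-1], right=True)
    decile = 10 - asc  # 1 = highest scores
    rows = []
    for d in range(1, 11):
        mask = decile == d
        nt = int((arms[mask] == 1).sum())
        nc = int((arms[mask] == 0).sum())
        mt = float(outcomes[mask][arms[mask] == 1].mean()) if nt else np.nan
        mc = float(outcomes[mask][arms[mask] == 0].mean()) if nc else np.nan
        rows.append(
            {
                "decile": d,
                "n_treat": nt,
                "n_control": nc,
                "mean_treat": mt,
                "mean_control": mc,
                "uplift": mt - mc if nt and nc else np.nan,
            }
        )
    return DecileSummary(pd.DataFrame(rows))


def auroc(outcomes: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney form; ties count 1/2)."""
    outcomes = np.asarray(outcomes, dtype=int)
    if outcomes.min() == outcomes.max():
        raise ValueError("AUROC needs both outcome classes")
    return float(roc_auc_score(outcomes, np.asarray(scores, dtype=float)))


def proportion_ci_wald(k: int, n: int) -> tuple[float, float, float]:
    """Point estimate and 95% Wald interval for a binomial proportion,
    clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return p, float(max(p - half, 0.0)), float(min(p + half, 1.0))
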