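"""Exposure dichotomization, propensity scores, IPTW and the ATE.

The joint continuous exposure (fluid balance, norepinephrine rate) is split
into two arms by a straight line in the (TIFB, NE) plane: patients *below*
the line — high fluid balance with little norepinephrine — form the
treatment arm (T = 1), the rest the control arm (T = 0).  Confounded arm
assignment is corrected by inverse-probability-of-treatment weighting
(IPTW): a logistic propensity model on a configured adjustment set yields
weights 1/e(x) for treated and 1/(1 - e(x)) for controls, from which a
confounder-balanced pseudo-population of size 2n is sampled and on which all
outcome models are fit.  The average treatment effect is the Hajek
(per-arm-normalized) weighted outcome difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .cohort import Cohort


@dataclass(frozen=True)
class DichotomizationRule:
    """Line ``ne = offset + slope * tifb`` splitting the exposure plane.

    slope is in ug/kg/min per mL/kg/h; offset in ug/kg/min.  ``offset_grid``
    is the ladder of alternative offsets used for sensitivity analyses.
    """

    slope: float = 0.02
    offset: float = -0.04
    offset_grid: tuple[float, ...] = (-0.12, -0.08, -0.04, 0.0, 0.04, 0.08)

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        grid = np.asarray(self.offset_grid, dtype=float)
        if not (np.diff(grid) > 0).all():
            raise ValueError("offset_grid must be strictly increasing")
        if not np.isclose(grid, self.offset).any():
            raise ValueError("offset_grid must contain the primary offset")

    def with_offset(self, offset: float) -> "DichotomizationRule":
        grid = tuple(sorted(set(self.offset_grid) | {offset}))
        return DichotomizationRule(self.slope, offset, grid)


def dichotomize(tifb, ne, rule: DichotomizationRule) -> np.ndarray:
    """Arm labels: 1 (treatment, high TIFB / low NE) iff ne is strictly
    below the line; points on the line go to control."""
    tifb = np.asarray(tifb, dtype=float)
    ne = np.asarray(ne, dtype=float)
    if not (np.isfinite(tifb).all() and np.isfinite(ne).all()):
        raise ValueError("tifb and ne must be finite")
    return (ne < rule.offset + rule.slope * tifb).astype(int)


@dataclass
class PropensityResult:
    scores: np.ndarray                 # P(T=1 | adjustment set), clipped
    adjustment_set: list[str]
    overlap_summary: dict
    params: pd.Series                  # logistic coefficients (incl. const)
    bse: pd.Series                     # their standard errors
    clip_epsilon: float


def fit_propensity(
    cohort: Cohort,
    arms: np.ndarray,
    adjustment_set: list[str],
    clip_epsilon: float = 0.01,
) -> PropensityResult:
    """Main-effects logistic regression of the arm on the adjustment set.

    Scores are clipped to [eps, 1 - eps] so downstream weights stay finite.
    Perfect separation (or a non-converged fit) raises with advice rather
    than returning degenerate scores.
    """
    arms = np.asarray(arms, dtype=int)
    if arms.sum() == 0 or arms.sum() == len(arms):
        raise ValueError("both arms must be non-empty to fit a propensity model")
    if not adjustment_set:
        raise ValueError("adjustment_set must be non-empty")
    X = cohort.features(list(adjustment_set)).astype(float)
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            # convergence is validated explicitly below; near-separated
            # resamples otherwise flood the log with optimizer warnings
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            fit = sm.Logit(arms, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "propensity model failed (perfect separation?); widen clip_epsilon "
            "or use a smaller adjustment_set"
        ) from exc
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params).max() > 1e3:
        raise ValueError(
            "propensity model did not converge (quasi-separation?); "
            "use a smaller adjustment_set"
        )
    raw = np.asarray(fit.predict(design))
    scores = np.clip(raw, clip_epsilon, 1.0 - clip_epsilon)
    qs = (0.0, 0.025, 0.25, 0.5, 0.75, 0.975, 1.0)
    overlap = {
        "quantiles": qs,
        "treatment": np.quantile(scores[arms == 1], qs).tolist(),
        "control": np.quantile(scores[arms == 0], qs).tolist(),
        "shared_support": (
            float(max(scores[arms == 1].min(), scores[arms == 0].min())),
            float(min(scores[arms == 1].max(), scores[arms == 0].max())),
        ),
    }
    return PropensityResult(
        scores=scores,
        adjustment_set=list(adjustment_set),
        overlap_summary=overlap,
        params=fit.params,
        bse=fit.bse,
        clip_epsilon=clip_epsilon,
    )


@dataclass
class IPTWWeights:
    weights: np.ndarray

    def __post_init__(self) -> None:
        if (self.weights < 1.0 - 1e-12).any():
            raise ValueError("IPTW weights must all be >= 1")


def iptw_weights(propensity: PropensityResult, arms: np.ndarray) -> IPTWWeights:
    """w_i = T_i / e_i + (1 - T_i) / (1 - e_i)."""
    arms = np.asarray(arms, dtype=float)
    e = propensity.scores
    if len(arms) != len(e):
        raise ValueError("arms and propensity scores are misaligned")
    return IPTWWeights(arms / e + (1.0 - arms) / (1.0 - e))


def replication_counts(weights: np.ndarray, multiplier: int) -> np.ndarray:
    """Integer copy counts for the super-population: round(w * multiplier),
    half away from zero (weights are positive, so this is floor(x + 0.5))."""
    x = np.asarray(weights, dtype=float) * multiplier
    return np.floor(x + 0.5).astype(np.int64)


@dataclass
class PseudoPopulation:
    """A confounder-balanced resample: n_per_arm records per arm, each
    tracing back (via ``indices``) to a source-cohort patient."""

    cohort: Cohort
    indices: np.ndarray       # positions into the source cohort, length 2*n_per_arm
    arm: np.ndarray           # arm label per sampled record
    provenance: dict

    def __len__(self) -> int:
        return len(self.indices)

    def features(self, names: list[str] | None = None) -> pd.DataFrame:
        return self.cohort.features(names).iloc[self.indices].reset_index(drop=True)

    @property
    def outcomes(self) -> np.ndarray:
        return self.cohort.outcomes[self.indices]


def build_and_sample_pseudo_population(
    cohort: Cohort,
    arms: np.ndarray,
    weights: IPTWWeights,
    n_per_arm: int,
    multiplier: int = 10_000,
    seed: int = 0,
) -> PseudoPopulation:
    """Replicate each patient round(w * multiplier) times into a per-arm
    super-population, then draw n_per_arm records per arm with replacement.

    The draw is implemented without materializing the super-population:
    sampling patient i with probability count_i / sum(counts) is identical to
    a uniform draw from the replicated rows.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    arms = np.asarray(arms, dtype=int)
    counts = replication_counts(weights.weights, multiplier)
    rng = np.random.default_rng(seed)
    parts, part_arms = [], []
    for arm_value in (1, 0):
        members = np.flatnonzero(arms == arm_value)
        total = counts[members].sum()
        if total == 0:
            raise ValueError(
                f"arm {arm_value} has zero total replication count; "
                "cannot sample a pseudo-population"
            )
        p = counts[members] / total
        parts.append(rng.choice(members, size=n_per_arm, replace=True, p=p))
        part_arms.append(np.full(n_per_arm, arm_value))
    return PseudoPopulation(
        cohort=cohort,
        indices=np.concatenate(parts),
        arm=np.concatenate(part_arms),
        provenance={"multiplier": multiplier, "seed": seed, "n_source": len(cohort)},
    )


def hajek_ate(outcomes, arms, weights: IPTWWeights) -> float:
    """Hajek IPTW estimate: weighted outcome mean difference, weights
    renormalized within each arm (bounded in [-1, 1] for binary outcomes)."""
    y = np.asarray(outcomes, dtype=float)
    t = np.asarray(arms, dtype=float)
    w = weights.weights
    mean1 = np.sum(w * y * t) / np.sum(w * t)
    mean0 = np.sum(w * y * (1.0 - t)) / np.sum(w * (1.0 - t))
    return float(mean1 - mean0)


def estimate_ate(
    cohort: Cohort,
    arms: np.ndarray,
    weights: IPTWWeights,
    n_boot: int = 200,
    seed: int = 0,
    adjustment_set: list[str] | None = None,
    clip_epsilon: float = 0.01,
) -> tuple[float, float, float]:
    """Point estimate plus percentile-bootstrap 95% CI over patients.

    When ``adjustment_set`` is given the propensity model is refit inside
    every bootstrap replicate (the recommended, honest interval); otherwise
    the supplied weights are resampled as-is.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    arms = np.asarray(arms, dtype=int)
    point = hajek_ate(cohort.outcomes, arms, weights)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    estimates = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        b_arms = arms[idx]
        if b_arms.sum() in (0, n):
            continue
        y = cohort.outcomes[idx]
        if adjustment_set is None:
            w = IPTWWeights(weights.weights[idx])
        else:
            sub = cohort.subset(idx)
            try:
                prop = fit_propensity(sub, b_arms, adjustment_set, clip_epsilon)
            except ValueError:
                continue
            w = iptw_weights(prop, b_arms)
        estimates.append(hajek_ate(y, b_arms, w))
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return point, float(lo), float(hi)


def standardized_mean_differences(
    X: pd.DataFrame, arms: np.ndarray, weights: np.ndarray | None = None
) -> pd.Series:
    """Per-covariate SMD between arms, optionally under IPTW weights.

    The denominator is always the unweighted pooled standard deviation, so
    weighted and unweighted SMDs are on the same scale (the usual balance
    diagnostic; |SMD| < 0.1 is the conventional balance threshold).
    """
    arms = np.asarray(arms, dtype=bool)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        s_pooled = np.sqrt(0.5 * (x[arms].var(ddof=1) + x[~arms].var(ddof=1)))
        m1 = np.average(x[arms], weights=w[arms])
        m0 = np.average(x[~arms], weights=w[~arms])
        out[col] = (m1 - m0) / s_pooled if s_pooled > 0 else 0.0
    return pd.Series(out, name="smd")
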