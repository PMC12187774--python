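"""Orchestration of the full observational uplift study.

For each bootstrap resample of the cohort (with replacement, original
size): re-dichotomize, refit the propensity model, build IPTW weights and
the per-arm super-population; draw several pseudo-population samples of
size 2n; within each, run cross-validation splits that train all models on
a 60% fraction (stratified by arm and outcome) and evaluate AUQC / AUROC /
response types on the held-out 40%, alongside the random and idealized
benchmarks on the same evaluation set.  Metrics are aggregated as the mean
with a percentile 2.5/97.5 interval across all replicates.

Every replicate (b, s, c) derives its random state purely from the master
seed and its own coordinates, so runs are reproducible and replicates are
independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation as ev
from .cohort import Cohort
from .synthetic import DEFAULT_ADJUSTMENT_SET
from .treatment import (
    DichotomizationRule,
    dichotomize,
    estimate_ate,
    fit_propensity,
    hajek_ate,
    iptw_weights,
    build_and_sample_pseudo_population,
)
from .uplift import (
    LearnerSpec,
    classify_response_type,
    fit_baseline_prediction,
    fit_two_model,
    predict_beneficial,
    predict_uplift,
)

#: short column tags per learner kind
_TAGS = {"logistic_regression": "lr", "random_forest": "rf"}

_RESPONSE_KEYS = {
    "SureThing": "sure_thing",
    "LostCause": "lost_cause",
    "Persuadable": "persuadable",
    "DoNotDisturb": "do_not_disturb",
}


def default_learner_specs() -> dict[str, LearnerSpec]:
    """Desk-scale learner pair (the forest is trimmed to 100 trees; the
    design default of 500 is used by :meth:`ExperimentConfig.full`)."""
    return {
        "logistic_regression": LearnerSpec("logistic_regression"),
        "random_forest": LearnerSpec("random_forest", {"n_trees": 100}),
    }


@dataclass
class ExperimentConfig:
    """Nested-resampling layout and modeling choices.

    The reference layout is 500 bootstraps x 5 pseudo-samples x 2 CV splits
    with a 60/40 train/evaluation fraction and a 10,000x weight multiplier;
    the default here is the desk-scale 20 x 2 x 2 profile, with the full
    layout available via :meth:`full` (or ``scale_factor``).
    """

    n_bootstrap: int = 20
    n_pseudo_samples: int = 2
    n_cv_splits: int = 2
    train_fraction: float = 0.6
    learner_specs: dict[str, LearnerSpec] = field(default_factory=default_learner_specs)
    rule: DichotomizationRule = field(default_factory=DichotomizationRule)
    adjustment_set: list[str] = field(
        default_factory=lambda: list(DEFAULT_ADJUSTMENT_SET)
    )
    multiplier: int = 10_000
    clip_epsilon: float = 0.01
    master_seed: int = 0
    scale_factor: float = 1.0
    max_failure_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0,1)")
        for name in ("n_bootstrap", "n_pseudo_samples", "n_cv_splits", "multiplier"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError("scale_factor must lie in (0,1]")
        for spec in self.learner_specs.values():
            if spec.kind not in _TAGS:
                raise ValueError(f"unsupported learner kind {spec.kind!r}")

    @classmethod
    def full(cls, **overrides) -> "ExperimentConfig":
        """The reference 500 x 5 x 2 layout with 500-tree forests."""
        specs = {
            "logistic_regression": LearnerSpec("logistic_regression"),
            "random_forest": LearnerSpec("random_forest", {"n_trees": 500}),
        }
        defaults = dict(
            n_bootstrap=500, n_pseudo_samples=5, n_cv_splits=2, learner_specs=specs
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def effective_n_bootstrap(self) -> int:
        return max(1, round(self.n_bootstrap * self.scale_factor))

    @property
    def effective_n_pseudo(self) -> int:
        return max(1, round(self.n_pseudo_samples * self.scale_factor))


def _seed_int(master_seed: int, *coords: int) -> int:
    """Pure function of (master_seed, coordinates) -> 32-bit seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(coords))
    return int(ss.generate_state(1)[0])


def _stratified_split(
    arms: np.ndarray,
    outcomes: np.ndarray,
    source_ids: np.ndarray,
    train_fraction: float,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Train/evaluation indices, stratified by (arm, outcome) and grouped
    by source patient.

    The bootstrap and the pseudo-population both replicate patients, so a
    record-level split would place copies of one patient on both sides of
    the train/evaluation boundary and let a high-capacity learner score
    its own training patients.  All copies of a source patient therefore
    go to the same fold; within each (arm, outcome) stratum, whole
    patients are assigned until the train fold holds ~train_fraction of
    the stratum's records.
    """
    train, hold = [], []
    for a in (0, 1):
        for y in (0, 1):
            idx = np.flatnonzero((arms == a) & (outcomes == y))
            if len(idx) == 0:
                continue
            ids, counts = np.unique(source_ids[idx], return_counts=True)
            if len(ids) < 2:
                train.append(idx)
                continue
            order = rng.permutation(len(ids))
            cum = np.cumsum(counts[order])
            target = train_fraction * len(idx)
            k = int(np.searchsorted(cum, target) + 1)
            k = min(max(k, 1), len(ids) - 1)
            train_ids = ids[order[:k]]
            in_train = np.isin(source_ids[idx], train_ids)
            train.append(idx[in_train])
            hold.append(idx[~in_train])
    return np.concatenate(train), np.concatenate(hold)


@dataclass
class EvaluationReport:
    """Aggregated study results plus the full per-replicate records."""

    replicates: pd.DataFrame
    ate_replicates: pd.DataFrame
    summary: dict
    qini_curves: pd.DataFrame
    deciles: pd.DataFrame
    failures: list
    config: ExperimentConfig

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)
        with open(out / "replicates.jsonl", "w") as fh:
            for record in self.replicates.to_dict(orient="records"):
                fh.write(json.dumps(record, default=float) + "\n")
        self.ate_replicates.to_csv(out / "ate_replicates.csv", index=False)
        self.qini_curves.to_csv(out / "qini_curves.csv", index=False)
        self.deciles.to_csv(out / "deciles.csv", index=False)


def _mean_ci(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return {"mean": None, "ci_low": None, "ci_high": None}
    lo, hi = np.percentile(values, [2.5, 97.5])
    return {"mean": float(values.mean()), "ci_low": float(lo), "ci_high": float(hi)}


def run_experiment(cohort: Cohort, config: ExperimentConfig) -> EvaluationReport:
    """Execute the nested bootstrap x pseudo-sample x CV evaluation.

    A replicate that cannot be completed (e.g. a single-class arm in a
    fold) is skipped and recorded with its coordinates; the run aborts if
    more than ``max_failure_fraction`` of replicates fail.
    """
    n = len(cohort)
    feature_names = list(cohort.covariate_names)
    n_boot = config.effective_n_bootstrap
    n_pseudo = config.effective_n_pseudo
    rows: list[dict] = []
    ate_rows: list[dict] = []
    failures: list[dict] = []
    curve_acc: dict[str, list] = {}
    decile_acc: dict[str, list] = {}

    def record_failure(b, s, c, stage, exc):
        failures.append(
            {"bootstrap": b, "sample": s, "split": c, "stage": stage, "error": str(exc)}
        )

    for b in range(n_boot):
        rng_b = np.random.default_rng(_seed_int(config.master_seed, b))
        idx = rng_b.integers(0, n, size=n)
        boot = cohort.subset(idx)
        arms = dichotomize(boot.tifb, boot.ne, config.rule)
        try:
            prop = fit_propensity(
                boot, arms, config.adjustment_set, config.clip_epsilon
            )
            weights = iptw_weights(prop, arms)
        except ValueError as exc:
            record_failure(b, None, None, "propensity", exc)
            for s in range(n_pseudo):
                for c in range(config.n_cv_splits):
                    record_failure(b, s, c, "skipped", exc)
            continue
        ate_rows.append(
            {"bootstrap": b, "ate": hajek_ate(boot.outcomes, arms, weights)}
        )
        for s in range(n_pseudo):
            pseudo = build_and_sample_pseudo_population(
                boot,
                arms,
                weights,
                n_per_arm=n,
                multiplier=config.multiplier,
                seed=_seed_int(config.master_seed, b, s),
            )
            X = pseudo.features(feature_names)
            y = pseudo.outcomes
            p_arm = pseudo.arm
            # identity of the original-cohort patient behind each record,
            # so CV folds never split a patient's replicated copies
            src = idx[pseudo.indices]
            for c in range(config.n_cv_splits):
                seed_c = _seed_int(config.master_seed, b, s, c)
                rng_c = np.random.default_rng(seed_c)
                try:
                    row = _run_replicate(
                        X, p_arm, y, src, config, rng_c, seed_c, b, s, c,
                        curve_acc, decile_acc,
                    )
                except (ValueError, KeyError) as exc:
                    record_failure(b, s, c, "replicate", exc)
                    continue
                rows.append(row)

    total = n_boot * n_pseudo * config.n_cv_splits
    if len(failures) > config.max_failure_fraction * total:
        raise RuntimeError(
            f"{len(failures)} of {total} replicates failed "
            f"(> {config.max_failure_fraction:.0%}); first failure: {failures[0]}"
        )

    replicates = pd.DataFrame(rows)
    ate_replicates = pd.DataFrame(ate_rows)
    summary: dict = {
        "n_replicates": len(replicates),
        "n_failed": len(failures),
        "layout": {
            "n_bootstrap": n_boot,
            "n_pseudo_samples": n_pseudo,
            "n_cv_splits": config.n_cv_splits,
            "train_fraction": config.train_fraction,
            "multiplier": config.multiplier,
        },
        "metrics": {
            col: _mean_ci(replicates[col].to_numpy())
            for col in replicates.columns
            if col not in ("bootstrap", "sample", "split")
        },
        "ate": _mean_ci(ate_replicates["ate"].to_numpy()) if ate_rows else None,
    }

    grid = ev.default_grid()
    curve_frames = [
        pd.DataFrame(
            {"p": grid, "model": name, "q_norm": np.mean(np.stack(curves), axis=0)}
        )
        for name, curves in sorted(curve_acc.items())
    ]
    with warnings.catch_warnings():
        # deciles missing an arm in every replicate are legitimately all-NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        decile_frames = [
            pd.DataFrame(
                {
                    "decile": np.arange(1, 11),
                    "model": name,
                    "uplift": np.nanmean(np.stack(vals), axis=0),
                }
            )
            for name, vals in sorted(decile_acc.items())
        ]
    return EvaluationReport(
        replicates=replicates,
        ate_replicates=ate_replicates,
        summary=summary,
        qini_curves=pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["p", "model", "q_norm"]),
        deciles=pd.concat(decile_frames, ignore_index=True)
        if decile_frames
        else pd.DataFrame(columns=["decile", "model", "uplift"]),
        failures=failures,
        config=config,
    )


def _run_replicate(
    X, p_arm, y, src, config, rng_c, seed_c, b, s, c, curve_acc, decile_acc
) -> dict:
    train_idx, eval_idx = _stratified_split(
        p_arm, y, src, config.train_fraction, rng_c
    )
    X_tr, X_ev = X.iloc[train_idx], X.iloc[eval_idx]
    a_tr, a_ev = p_arm[train_idx], p_arm[eval_idx]
    y_tr, y_ev = y[train_idx], y[eval_idx]
    row = {"bootstrap": b, "sample": s, "split": c}

    def add_curve(name, scores):
        curve = ev.qini_curve(scores, a_ev, y_ev, tie_seed=seed_c)
        curve_acc.setdefault(name, []).append(curve.q_norm)
        dec = ev.uplift_by_decile(scores, a_ev, y_ev)
        decile_acc.setdefault(name, []).append(dec.table["uplift"].to_numpy())
        return ev.auqc(curve)

    for kind, spec in config.learner_specs.items():
        tag = _TAGS[kind]
        spec_r = spec.with_seed(seed_c % (2**31))
        umodel = fit_two_model(X_tr, a_tr, y_tr, spec_r)
        scores = predict_uplift(umodel, X_ev)
        row[f"auqc_uplift_{tag}"] = add_curve(f"uplift_{tag}", scores.uplift)
        for arm_value, arm_tag, p in (
            (1, "treat", scores.p_treat),
            (0, "control", scores.p_control),
        ):
            mask = a_ev == arm_value
            try:
                row[f"auroc_uplift_{tag}_{arm_tag}"] = ev.auroc(y_ev[mask], p[mask])
            except ValueError:
                row[f"auroc_uplift_{tag}_{arm_tag}"] = np.nan
        types = classify_response_type(scores)
        n_ev = len(eval_idx)
        for label, key in _RESPONSE_KEYS.items():
            row[f"frac_{key}_{tag}"] = float((types == label).sum() / n_ev)

        pmodel = fit_baseline_prediction(X_tr, y_tr, spec_r)
        p_hat = predict_beneficial(pmodel, X_ev)
        row[f"auqc_pred_{tag}"] = add_curve(f"pred_{tag}", p_hat)
        row[f"auroc_pred_{tag}"] = ev.auroc(y_ev, p_hat)

    row["auqc_random"] = ev.auqc(
        ev.qini_from_ordering(rng_c.permutation(len(eval_idx)), a_ev, y_ev)
    )
    row["auqc_optimal"] = ev.optimal_benchmark_auqc(a_ev, y_ev)
    return row


# ---------------------------------------------------------------------------
# cohort summary and sensitivity analysis
# ---------------------------------------------------------------------------

def summarize_cohort(cohort: Cohort, by: str = "outcome_beneficial") -> pd.DataFrame:
    """Baseline-table style summary stratified by a binary column.

    Categorical variables (<= 6 distinct values) are reported per level as
    ``count (percent)``; other numerics as ``median [q1;q3]``.  The first
    row carries the group sizes.
    """
    df = cohort.df
    strata = {f"{by}={v}": df[df[by] == v] for v in sorted(df[by].unique())}
    strata["overall"] = df
    rows = [
        {"variable": "N", "level": "", **{k: str(len(v)) for k, v in strata.items()}}
    ]
    for name in list(cohort.covariate_names) + ["tifb", "ne"]:
        values = df[name]
        if values.nunique() <= 6:
            for level in sorted(values.unique()):
                cells = {}
                for key, sub in strata.items():
                    count = int((sub[name] == level).sum())
                    cells[key] = f"{count} ({100 * count / len(sub):.1f}%)"
                rows.append({"variable": name, "level": str(level), **cells})
        else:
            cells = {}
            for key, sub in strata.items():
                q1, med, q3 = np.percentile(sub[name], [25, 50, 75])
                cells[key] = f"{med:.2f} [{q1:.2f};{q3:.2f}]"
            rows.append({"variable": name, "level": "", **cells})
    return pd.DataFrame(rows)


def sensitivity_over_offsets(
    cohort: Cohort,
    config: ExperimentConfig,
    n_boot: int = 100,
) -> pd.DataFrame:
    """Arm sizes, overlap and the IPTW ATE for every offset on the grid.

    Offsets that produce an empty arm (or an unfittable propensity model)
    are reported with a flag instead of aborting the analysis.
    """
    rows = []
    for i, offset in enumerate(config.rule.offset_grid):
        rule = config.rule.with_offset(offset)
        arms = dichotomize(cohort.tifb, cohort.ne, rule)
        row = {
            "offset": offset,
            "n_treat": int(arms.sum()),
            "n_control": int(len(arms) - arms.sum()),
            "ate": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "support_low": np.nan,
            "support_high": np.nan,
            "flag": "",
        }
        if row["n_treat"] == 0 or row["n_control"] == 0:
            row["flag"] = "empty_arm"
            rows.append(row)
            continue
        try:
            prop = fit_propensity(cohort, arms, config.adjustment_set,
                                  config.clip_epsilon)
            weights = iptw_weights(prop, arms)
            ate, lo, hi = estimate_ate(
                cohort,
                arms,
                weights,
                n_boot=n_boot,
                seed=_seed_int(config.master_seed, 10_000 + i),
                adjustment_set=config.adjustment_set,
                clip_epsilon=config.clip_epsilon,
            )
        except ValueError as exc:
            row["flag"] = f"propensity_failed: {exc}"
            rows.append(row)
            continue
        row.update(
            ate=ate,
            ci_low=lo,
            ci_high=hi,
            support_low=prop.overlap_summary["shared_support"][0],
            support_high=prop.overlap_summary["shared_support"][1],
        )
        rows.append(row)
    return pd.DataFrame(rows)


def config_to_dict(config: ExperimentConfig) -> dict:
    """JSON-serializable snapshot of an experiment configuration."""
    d = dataclasses.asdict(config)
    d["rule"] = dataclasses.asdict(config.rule)
    d["learner_specs"] = {
        k: dataclasses.asdict(v) for k, v in config.learner_specs.items()
    }
    return d
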