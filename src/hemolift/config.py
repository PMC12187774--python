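"""YAML configuration for the whole study.

One file with four blocks — ``synthetic``, ``treatment``, ``learners`` and
``experiment`` — is parsed into the dataclasses the library consumes.  Any
block may be omitted, in which case the packaged defaults apply.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiment import ExperimentConfig, default_learner_specs
from .synthetic import (
    DEFAULT_ADJUSTMENT_SET,
    CovariateSpec,
    SyntheticSpec,
    default_spec,
)
from .treatment import DichotomizationRule
from .uplift import LearnerSpec


def _parse_covariate(entry: dict) -> CovariateSpec:
    entry = dict(entry)
    kind = entry.pop("kind")
    if kind == "ordinal":
        entry["levels"] = tuple(entry["levels"])
        entry["probs"] = tuple(entry["probs"])
    return CovariateSpec(kind=kind, **entry)


def parse_synthetic(block: dict | None, seed: int = 0) -> SyntheticSpec:
    if not block:
        return default_spec(seed=seed)
    block = dict(block)
    covs = {k: _parse_covariate(v) for k, v in block.pop("covariate_spec").items()}
    rule = DichotomizationRule(**block.pop("rule")) if "rule" in block else (
        DichotomizationRule()
    )
    block.setdefault("seed", seed)
    return SyntheticSpec(covariate_spec=covs, rule=rule, **block)


def parse_treatment(block: dict | None) -> tuple[DichotomizationRule, list, int, float]:
    block = dict(block or {})
    rule = DichotomizationRule(
        slope=block.get("slope", 0.02),
        offset=block.get("offset", -0.04),
        offset_grid=tuple(block.get("offset_grid", (-0.12, -0.08, -0.04, 0.0, 0.04, 0.08))),
    )
    adjustment = list(block.get("adjustment_set", DEFAULT_ADJUSTMENT_SET))
    multiplier = int(block.get("multiplier", 10_000))
    clip = float(block.get("clip_epsilon", 0.01))
    return rule, adjustment, multiplier, clip


def parse_learners(block: dict | None) -> dict[str, LearnerSpec]:
    if not block:
        return default_learner_specs()
    return {
        kind: LearnerSpec(kind, dict(hp or {}))
        for kind, hp in block.items()
    }


def parse_experiment(
    block: dict | None,
    rule: DichotomizationRule,
    adjustment_set: list,
    multiplier: int,
    clip_epsilon: float,
    learner_specs: dict[str, LearnerSpec],
    master_seed: int = 0,
) -> ExperimentConfig:
    block = dict(block or {})
    block.setdefault("master_seed", master_seed)
    return ExperimentConfig(
        rule=rule,
        adjustment_set=adjustment_set,
        multiplier=multiplier,
        clip_epsilon=clip_epsilon,
        learner_specs=learner_specs,
        **block,
    )


def load_config(path, master_seed: int = 0) -> dict:
    """Parse the study YAML into ``{"synthetic": ..., "experiment": ...}``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    rule, adjustment, multiplier, clip = parse_treatment(raw.get("treatment"))
    learners = parse_learners(raw.get("learners"))
    experiment = parse_experiment(
        raw.get("experiment"), rule, adjustment, multiplier, clip, learners,
        master_seed,
    )
    return {
        "synthetic": parse_synthetic(raw.get("synthetic"), seed=master_seed),
        "experiment": experiment,
    }
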