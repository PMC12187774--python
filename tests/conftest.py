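import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from hemolift.synthetic import default_spec, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale heterogeneous-effect cohort (n = 1482)."""
    return generate_cohort(default_spec(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Same structure with zero treatment effect."""
    return generate_cohort(default_spec(seed=11, effect="null"))


@pytest.fixture(scope="session")
def large_confounded_cohort():
    """n = 5000 heterogeneous-effect cohort for recovery/balance checks."""
    spec = dataclasses.replace(default_spec(seed=7), n_patients=5000)
    return generate_cohort(spec)


@pytest.fixture
def worked_qini_set():
    """8-patient hand-checkable evaluation set.

    Sorted descending by score the sequence of (arm, outcome) is
    T1, T1, C0, C1 | T1, C1, T0, C0 so the p = 0.5 head holds treated
    outcomes {1,1} and control outcomes {0,1}, and the full set has
    Y_T = 3, Y_C = 2, N_T = N_C = 4.
    """
    scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2])
    arms = np.array([1, 1, 0, 0, 1, 0, 1, 0])
    outcomes = np.array([1, 1, 0, 1, 1, 1, 0, 0])
    return scores, arms, outcomes


def qini_oracle(ordering, arms, outcomes, grid):
    """Direct, loop-based evaluation of the incremental-uplift formula
    q(p) = Y_T(p) - Y_C(p) * N_T(p) / N_C(p) (independent of the library)."""
    n = len(arms)
    values = []
    for p in grid:
        head = list(ordering[: math.ceil(p * n)])
        yt = sum(int(outcomes[i]) for i in head if arms[i] == 1)
        yc = sum(int(outcomes[i]) for i in head if arms[i] == 0)
        nt = sum(1 for i in head if arms[i] == 1)
        nc = len(head) - nt
        values.append(yt - (yc * nt / nc if nc > 0 else 0.0))
    return np.array(values, dtype=float)


def auqc_oracle(grid, q_norm):
    """Trapezoid area with the origin prepended (independent arithmetic)."""
    p = np.concatenate(([0.0], np.asarray(grid, dtype=float)))
    q = np.concatenate(([0.0], np.asarray(q_norm, dtype=float)))
    total = 0.0
    for i in range(1, len(p)):
        total += 0.5 * (q[i] + q[i - 1]) * (p[i] - p[i - 1])
    return total
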