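"""Patient-level cohort container and CSV round-trip.

A cohort holds one row per patient: baseline covariates, the two continuous
exposures (total intraoperative fluid balance ``tifb`` in mL/kg/h and
norepinephrine rate ``ne`` in ug/kg/min) and the binary outcome
``outcome_beneficial`` coded 1 for an AKI-free recovery.  Synthetic cohorts
additionally carry the latent potential outcomes ``po_y0``/``po_y1`` and the
ground-truth per-patient effect ``true_uplift``.

Reading a CSV applies a complete-case rule: rows with any missing field are
dropped and the drop count is kept on the returned :class:`Cohort` (and
logged), mirroring standard practice for registry analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns every cohort must provide besides the covariates
MANDATORY_COLUMNS = ("tifb", "ne", "outcome_beneficial")

#: optional columns present only for synthetic cohorts with known ground truth
LATENT_COLUMNS = ("po_y0", "po_y1", "true_uplift")


@dataclass
class Cohort:
    """An ordered patient table plus the list of covariate column names."""

    df: pd.DataFrame
    covariate_names: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValueError("cohort is empty")
        for col in ("patient_id",) + MANDATORY_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"cohort is missing mandatory column {col!r}")
        for name in self.covariate_names:
            if name not in self.df.columns:
                raise ValueError(f"covariate {name!r} not found in cohort columns")
        pid = self.df["patient_id"]
        if pid.duplicated().any():
            raise ValueError("patient_id values are not unique")
        y = self.df["outcome_beneficial"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValueError("outcome_beneficial must be coded 0/1 (1 = beneficial)")
        if (self.df["ne"].to_numpy() < 0).any():
            raise ValueError("norepinephrine rate ne must be non-negative")
        self.df = self.df.reset_index(drop=True)

    # -- array views -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def tifb(self) -> np.ndarray:
        return self.df["tifb"].to_numpy(dtype=float)

    @property
    def ne(self) -> np.ndarray:
        return self.df["ne"].to_numpy(dtype=float)

    @property
    def outcomes(self) -> np.ndarray:
        return self.df["outcome_beneficial"].to_numpy(dtype=int)

    @property
    def has_ground_truth(self) -> bool:
        return all(c in self.df.columns for c in LATENT_COLUMNS)

    @property
    def true_uplift(self) -> np.ndarray:
        if not self.has_ground_truth:
            raise AttributeError("cohort carries no latent ground truth")
        return self.df["true_uplift"].to_numpy(dtype=float)

    def features(self, names: list[str] | None = None) -> pd.DataFrame:
        """Covariate sub-frame (defaults to all covariates, in order)."""
        names = list(self.covariate_names if names is None else names)
        unknown = [n for n in names if n not in self.df.columns]
        if unknown:
            raise KeyError(f"unknown covariate name(s): {unknown}")
        return self.df[names]

    def subset(self, indices: np.ndarray) -> "Cohort":
        """Row subset / resample; patient_id is re-issued to stay unique."""
        sub = self.df.iloc[np.asarray(indices)].reset_index(drop=True)
        sub = sub.assign(patient_id=np.arange(1, len(sub) + 1))
        return Cohort(sub, list(self.covariate_names))


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as a comma-separated UTF-8 CSV with a header row."""
    cohort.df.to_csv(path, index=False)


def read_cohort(path, covariate_names: list[str] | None = None) -> Cohort:
    """Read a cohort CSV, dropping incomplete rows (complete-case rule).

    Parameters
    ----------
    covariate_names
        Explicit covariate list; by default every column that is not
        ``patient_id``, a mandatory exposure/outcome column or a latent
        ground-truth column is treated as a covariate.

    Raises
    ------
    ValueError
        If a mandatory column (``tifb``, ``ne``, ``outcome_beneficial``) is
        absent, the error names the missing column.
    """
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file {path} lacks mandatory column {col!r}")
    if "patient_id" not in df.columns:
        df.insert(0, "patient_id", np.arange(1, len(df) + 1))
    n_raw = len(df)
    df = df.dropna(axis=0, how="any").reset_index(drop=True)
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info(
            "complete-case read: dropped %d of %d rows with missing fields",
            n_dropped,
            n_raw,
        )
    if covariate_names is None:
        reserved = {"patient_id", *MANDATORY_COLUMNS, *LATENT_COLUMNS}
        covariate_names = [c for c in df.columns if c not in reserved]
    return Cohort(df, list(covariate_names), n_dropped=n_dropped)
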