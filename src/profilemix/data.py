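"""Indicator matrices and preprocessing.

The unit of data throughout the package is a subjects × indicators numeric
table (e.g. standardized neuropsychological scores, or log-transformed EEG
band powers). Preprocessing steps — winsorization of individual outliers,
reverse coding, z-standardization — return new :class:`IndicatorMatrix`
objects and append to a provenance log so every derived matrix records how
it was produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorMatrix",
    "standardize",
    "winsorize_value",
    "reverse_code",
    "read_indicator_csv",
]


class DataError(ValueError):
    """Invalid indicator data (missing values, unknown labels, zero variance)."""


@dataclass
class IndicatorMatrix:
    """A complete-case subjects × indicators matrix with provenance.

    Parameters
    ----------
    values
        ``(n, J)`` float array. Missing values are rejected: the model is a
        complete-case procedure, and rows with missing indicators must be
        dropped by the caller explicitly.
    subject_ids, indicator_names
        Row and column labels.
    standardized
        True when each column is a within-sample z-score.
    raw_means, raw_sds
        Original-scale column moments, kept when standardizing so class
        profiles can be back-transformed for interpretation.
    log
        Provenance records (one dict per preprocessing step).
    """

    values: np.ndarray
    subject_ids: list
    indicator_names: list
    standardized: bool = False
    raw_means: np.ndarray | None = None
    raw_sds: np.ndarray | None = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-d subjects × indicators array")
        n, J = self.values.shape
        if len(self.subject_ids) != n:
            raise DataError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.indicator_names) != J:
            raise DataError(f"{len(self.indicator_names)} names for {J} columns")
        if not np.all(np.isfinite(self.values)):
            bad = [self.subject_ids[i] for i in
                   np.unique(np.nonzero(~np.isfinite(self.values))[0])]
            raise DataError(
                "missing or non-finite values for subjects "
                f"{bad}: complete cases are required — drop or impute these "
                "rows before constructing an IndicatorMatrix"
            )
        if self.standardized:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0, ddof=1)
            if not (np.all(np.abs(mu) < 1e-8) and np.all(np.abs(sd - 1) < 1e-8)):
                raise DataError("standardized flag set but columns are not z-scores")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    def column(self, indicator) -> np.ndarray:
        return self.values[:, self._col_index(indicator)]

    def _col_index(self, indicator) -> int:
        try:
            return self.indicator_names.index(indicator)
        except ValueError:
            raise DataError(
                f"unknown indicator {indicator!r}; available: {self.indicator_names}"
            ) from None

    def _row_index(self, subject) -> int:
        try:
            return self.subject_ids.index(subject)
        except ValueError:
            raise DataError(f"unknown subject {subject!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject"),
            columns=self.indicator_names,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "IndicatorMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=list(df.index),
            indicator_names=list(df.columns),
            **kwargs,
        )


def read_indicator_csv(path) -> IndicatorMatrix:
    """Read a CSV with a leading subject-ID column and indicator columns."""
    df = pd.read_csv(path, index_col=0)
    return IndicatorMatrix.from_dataframe(df)


def standardize(data: IndicatorMatrix) -> IndicatorMatrix:
    """Z-score each column using the within-sample mean and SD (ddof=1).

    The original-scale moments are stored on the result so fitted class
    means can later be mapped back to the raw metric.
    """
    if data.n < 2:
        raise DataError("standardization needs at least 2 subjects")
    mu = data.values.mean(axis=0)
    sd = data.values.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        names = [data.indicator_names[j] for j in zero]
        raise DataError(f"zero-variance indicator(s) {names}: cannot standardize")
    z = (data.values - mu) / sd
    entry = {"step": "standardize", "ddof": 1}
    return replace(
        data,
        values=z,
        standardized=True,
        raw_means=mu,
        raw_sds=sd,
        log=data.log + [entry],
    )


def winsorize_value(
    data: IndicatorMatrix, subject, indicator, new_value: float
) -> IndicatorMatrix:
    """Replace a single outlying cell, recording the old value in the log.

    Applied to raw (pre-standardization) data: winsorizing after
    z-scoring would leave the column moments stale.
    """
    if data.standardized:
        raise DataError("winsorize raw data before standardization")
    i = data._row_index(subject)
    j = data._col_index(indicator)
    old = data.values[i, j]
    values = data.values.copy()
    values[i, j] = float(new_value)
    entry = {
        "step": "winsorize", "subject": subject, "indicator": indicator,
        "old_value": float(old), "new_value": float(new_value),
    }
    return replace(data, values=values, log=data.log + [entry])


def reverse_code(data: IndicatorMatrix, indicators: Iterable) -> IndicatorMatrix:
    """Flip the direction of the named indicators.

    On z-scores the columns are negated; on raw scores they are reflected
    about the column mean, which preserves the mean and SD. Used so that
    higher always means better performance (e.g. reaction-time measures).
    """
    names = list(indicators)
    cols = [data._col_index(name) for name in names]
    values = data.values.copy()
    if data.standardized:
        values[:, cols] = -values[:, cols]
    else:
        mu = values[:, cols].mean(axis=0)
        values[:, cols] = 2 * mu - values[:, cols]
    entry = {"step": "reverse_code", "indicators": names,
             "mode": "negate" if data.standardized else "reflect"}
    return replace(data, values=values, log=data.log + [entry])
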