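"""Per-gene normalization and expression-change signals.

Genes in a time-course table may be reported on arbitrary scales
(log-ratio microarray summaries, RNA-seq abundances), so each gene is
first standardized to zero mean and unit variance across its own time
course.  All downstream steps operate on *changes* in expression per
hour rather than levels; dividing each interval's change by the
interval length keeps unevenly spaced sampling schemes comparable.  For
pattern alignment the change series of each gene is further rescaled by
its largest absolute change, so every gene's signal lives in [-1, 1]
with the dominant change at exactly +/-1.

The composition (standardize, differentiate, max-rescale) is invariant
to any per-gene affine transform a*g + b with a > 0 of the raw values,
which is what makes the pipeline agnostic to the upstream quantification
platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ConstantGeneError(ValueError):
    """Raised when genes have zero variance across the time course.

    The input is expected to be pre-filtered to differentially expressed
    genes, so a constant row indicates an input problem rather than a
    legitimate gene; callers may drop such rows explicitly via
    :func:`drop_constant_genes`.
    """

    def __init__(self, gene_ids):
        self.gene_ids = list(gene_ids)
        super().__init__(
            "zero-variance gene rows cannot be standardized: "
            + ", ".join(map(str, self.gene_ids))
        )


def _as_float_frame(x: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    values = x.to_numpy(dtype=float)
    times = np.asarray([float(c) for c in x.columns], dtype=float)
    if values.ndim != 2:
        raise ValueError("expression input must be a 2-D gene x time table")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time columns must be strictly increasing")
    return values, times


def zscore_normalize(x: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize every gene row to mean 0 and standard deviation 1.

    Parameters
    ----------
    x:
        Gene x time expression table; columns are sampling times in hours.
    ddof:
        Delta degrees of freedom for the standard deviation.  The default
        (population convention, divide by N) is arbitrary: the max-change
        rescaling applied later cancels any per-gene scale factor.

    Raises
    ------
    ConstantGeneError
        If any row has zero variance.
    """
    values, _ = _as_float_frame(x)
    mean = values.mean(axis=1, keepdims=True)
    std = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = np.isclose(std[:, 0], 0.0)
    if flat.any():
        raise ConstantGeneError(np.asarray(x.index)[flat])
    return pd.DataFrame((values - mean) / std, index=x.index, columns=x.columns)


def drop_constant_genes(x: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Return ``x`` without zero-variance rows plus the dropped gene ids."""
    values, _ = _as_float_frame(x)
    flat = np.isclose(values.std(axis=1), 0.0)
    dropped = list(np.asarray(x.index)[flat])
    return x.loc[~flat], dropped


@dataclass
class ChangeSeries:
    """Per-interval expression-change signals for a set of genes.

    Attributes
    ----------
    raw:
        Gene x interval table of changes per hour,
        ``(g(t_{k+1}) - g(t_k)) / (t_{k+1} - t_k)``.  Columns are the
        1-based interval indices ``1..N-1``.
    normalized:
        ``raw`` divided per gene by its maximum absolute change, so every
        row attains +/-1 at its dominant interval and lies in [-1, 1].
    times:
        The N sampling times (hours) the intervals are built from.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    times: np.ndarray

    @property
    def gene_ids(self) -> pd.Index:
        return self.raw.index

    @property
    def n_intervals(self) -> int:
        return self.raw.shape[1]

    @property
    def intervals(self) -> list[tuple[float, float]]:
        """Half-open sampling intervals ``(t_k, t_{k+1}]``."""
        return list(zip(self.times[:-1], self.times[1:]))

    @property
    def interval_starts(self) -> np.ndarray:
        return self.times[:-1]


def changes(x: pd.DataFrame) -> ChangeSeries:
    """Differentiate a (normalized) expression table into a ChangeSeries.

    ``x`` is a gene x time table, typically the output of
    :func:`zscore_normalize`.  Interval lengths are taken from the column
    labels, so uneven sampling is handled exactly.

    Raises
    ------
    ValueError
        If a gene has zero change over every interval; such a row cannot
        be max-rescaled.  This cannot happen for rows that passed
        standardization, but the guard protects direct callers.
    """
    values, times = _as_float_frame(x)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 time points to compute changes")
    dt = np.diff(times)
    raw = np.diff(values, axis=1) / dt
    peak = np.abs(raw).max(axis=1, keepdims=True)
    dead = np.isclose(peak[:, 0], 0.0)
    if dead.any():
        raise ValueError(
            "genes with no expression change cannot be max-rescaled: "
            + ", ".join(map(str, np.asarray(x.index)[dead]))
        )
    cols = pd.RangeIndex(1, values.shape[1])
    return ChangeSeries(
        raw=pd.DataFrame(raw, index=x.index, columns=cols),
        normalized=pd.DataFrame(raw / peak, index=x.index, columns=cols),
        times=times,
    )
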