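"""Partition a time course into Initiation / Response stages.

A transcriptional cascade shows up as waves of activity: a small set of
early regulators moves first, triggering a much larger response wave.
The boundary between the two is located at the sampling time preceding
the interval in which the largest number of genes exhibit their maximum
expression change.  Everything before that boundary is the Initiation
stage; the response window after it is split into a Primary Response
(the first ``c`` intervals) and a Secondary Response (the remainder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .preprocessing import ChangeSeries, changes, zscore_normalize

INITIATION = "Initiation"
PRIMARY_RESPONSE = "PrimaryResponse"
SECONDARY_RESPONSE = "SecondaryResponse"


@dataclass(frozen=True)
class Stage:
    """A named half-open stage window ``(start, end]`` in hours."""

    name: str
    start: float
    end: float

    def __contains__(self, t: float) -> bool:
        return self.start < t <= self.end

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class StagePartition:
    """Result of the stage-separation step.

    ``gene_sets`` maps the 1-based interval index ``n`` to the genes whose
    maximum change falls in interval ``(t_n, t_{n+1}]``; the sets partition
    the full gene list.  ``boundary_index`` is the modal interval ``b`` and
    ``boundary_time`` the preceding sampling time ``t_b``.
    """

    gene_sets: dict[int, frozenset]
    boundary_index: int
    boundary_time: float
    stages: list[Stage]
    n_primary_intervals: int
    times: np.ndarray = field(repr=False)

    @property
    def stage_names(self) -> list[str]:
        return [s.name for s in self.stages]

    def stage_of_time(self, t: float) -> str | None:
        for s in self.stages:
            if t in s:
                return s.name
        return None


def assign_gene_sets(ch: ChangeSeries, use_abs_max: bool = False) -> dict[int, set]:
    """Group genes by the interval of their maximum expression change.

    The maximum is taken over the *signed* per-hour change by default,
    matching the definition of the gene sets; ``use_abs_max`` switches to
    the magnitude instead.  Ties go to the earliest qualifying interval.
    """
    score = ch.raw.abs() if use_abs_max else ch.raw
    # np.argmax returns the first maximizer -> earliest interval on ties.
    winner = np.argmax(score.to_numpy(), axis=1) + 1
    sets: dict[int, set] = {n: set() for n in range(1, ch.n_intervals + 1)}
    for gene, n in zip(ch.gene_ids, winner):
        sets[int(n)].add(gene)
    return sets


def find_boundary(gene_sets: dict[int, set], times: np.ndarray) -> tuple[int, float]:
    """Locate the Initiation-Response boundary at the modal gene set.

    Returns the 1-based modal interval index ``b`` and the boundary time
    ``t_b`` (the sampling time preceding that interval).  A cardinality
    tie is resolved toward the *latest* interval, which maximizes the
    Initiation window and keeps upstream regulators separable.

    Raises
    ------
    ValueError
        If the modal interval is the first one: no sampling time precedes
        it, so there is no Initiation stage to draw regulators from.
    """
    if not gene_sets or all(len(s) == 0 for s in gene_sets.values()):
        raise ValueError("gene_sets is empty; nothing to stage")
    counts = {n: len(s) for n, s in gene_sets.items()}
    best = max(counts.values())
    ties = sorted(n for n, c in counts.items() if c == best)
    b = ties[-1]
    if len(ties) > 1:
        warnings.warn(
            f"gene-set cardinality tie at intervals {ties}; "
            f"using the latest (b={b}) to maximize the Initiation stage",
            stacklevel=2,
        )
    if b == 1:
        raise ValueError(
            "the modal change interval is the first sampling interval: "
            "Initiation stage empty; dataset cannot be staged"
        )
    return b, float(times[b - 1])


def define_stages(b: int, c: int, times: np.ndarray) -> list[Stage]:
    """Build the stage windows for boundary interval ``b`` and ``c`` primary intervals.

    Initiation covers ``(t_1, t_b]``, Primary Response the next ``c``
    sampling intervals ``(t_b, t_{b+c}]``, Secondary Response the rest.
    When ``b + c == N`` the Secondary Response window is empty and only
    two stages are returned.
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    if c < 1:
        raise ValueError("number of Primary Response intervals c must be >= 1")
    if not 2 <= b <= n - 1:
        raise ValueError(f"boundary interval b={b} out of range for {n} time points")
    if b + c > n:
        raise ValueError(
            f"b + c = {b + c} exceeds the number of time points N={n}"
        )
    t_b = float(times[b - 1])
    t_bc = float(times[b - 1 + c])
    stages = [
        Stage(INITIATION, float(times[0]), t_b),
        Stage(PRIMARY_RESPONSE, t_b, t_bc),
    ]
    if t_bc < times[-1]:
        stages.append(Stage(SECONDARY_RESPONSE, t_bc, float(times[-1])))
    return stages


def separate_stages(
    ch: ChangeSeries,
    c: int = 1,
    use_abs_max: bool = False,
    boundary_override: float | None = None,
) -> StagePartition:
    """Run the full stage-separation step on a change series."""
    gene_sets = assign_gene_sets(ch, use_abs_max=use_abs_max)
    if boundary_override is None:
        b, t_b = find_boundary(gene_sets, ch.times)
    else:
        matches = np.flatnonzero(np.isclose(ch.times, boundary_override))
        if len(matches) == 0:
            raise ValueError(
                f"boundary override {boundary_override} h is not a sampling time"
            )
        b = int(matches[0]) + 1
        t_b = float(ch.times[b - 1])
        warnings.warn(
            f"Initiation-Response boundary manually forced to t_b={t_b} h",
            stacklevel=2,
        )
    stages = define_stages(b, c, ch.times)
    return StagePartition(
        gene_sets={n: frozenset(s) for n, s in gene_sets.items()},
        boundary_index=b,
        boundary_time=t_b,
        stages=stages,
        n_primary_intervals=c,
        times=ch.times,
    )


class StageSeparator(BaseEstimator):
    """Estimator wrapper around the stage-separation step.

    Parameters
    ----------
    c:
        Number of sampling intervals assigned to the Primary Response.
    ddof:
        Degrees-of-freedom convention for the per-gene standardization.
    use_abs_max:
        Group genes by the interval of largest |change| instead of the
        largest signed change.
    boundary_override:
        Force the boundary to this sampling time (hours) instead of
        detecting it; recorded as manual.

    Attributes
    ----------
    partition_ : StagePartition
    gene_sets_ : dict[int, frozenset]
    boundary_index_ : int
    boundary_time_ : float
    stages_ : list[Stage]
    """

    def __init__(self, c=1, ddof=0, use_abs_max=False, boundary_override=None):
        self.c = c
        self.ddof = ddof
        self.use_abs_max = use_abs_max
        self.boundary_override = boundary_override

    def fit(self, X: pd.DataFrame, y=None):
        ch = changes(zscore_normalize(X, ddof=self.ddof))
        self.change_series_ = ch
        self.partition_ = separate_stages(
            ch,
            c=self.c,
            use_abs_max=self.use_abs_max,
            boundary_override=self.boundary_override,
        )
        self.gene_sets_ = self.partition_.gene_sets
        self.boundary_index_ = self.partition_.boundary_index
        self.boundary_time_ = self.partition_.boundary_time
        self.stages_ = self.partition_.stages
        return self
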