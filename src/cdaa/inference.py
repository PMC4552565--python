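"""Signed, delayed regulator-target inference by differential-pattern alignment.

The working assumption is that a regulator's change-in-expression
pattern reappears in its targets after some delay, possibly with the
sign inverted (repression).  Because sampling is sparse and uneven, each
gene's max-rescaled change series is extended to a piecewise-constant
step signal (zeroth-order hold over the half-open sampling intervals),
which can then be evaluated at arbitrary delayed times.

For a candidate pair the dissimilarity at delay m*dT is the mean
absolute difference between the regulator signal read on a dT grid over
its stage window and the target signal shifted by the delay, where dT is
the greatest common divisor of the sampling intervals and M delays
0..(M-1)*dT are scanned.  The same score computed with the regulator
negated detects repression; the smaller of the two is kept per delay
together with its orientation.  Candidates whose best alignment sits at
delay 0 are discarded as mere co-expression.  To absorb noise the whole
procedure is repeated on event-thresholded (ternarized) versions of the
signals, and only regulators that pass a dissimilarity cutoff under a
minimum number of threshold levels become edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .preprocessing import ChangeSeries, changes, zscore_normalize
from .stage_assignment import StageAssignment
from .stage_separation import INITIATION, Stage, StagePartition

_GCD_RESOLUTION = 1e-6  # hours; sampling grids finer than this are rejected

DIRECT = "direct"
INVERTED = "inverted"


def _float_gcd(values: np.ndarray, tol: float = _GCD_RESOLUTION) -> float:
    g = 0.0
    for v in np.abs(np.asarray(values, dtype=float)):
        a, b = g, v
        while b > tol:
            a, b = b, a % b
        g = a
    return g


@dataclass(frozen=True)
class DelayGrid:
    """Delay scan geometry for one regulator-stage / target-stage pair.

    ``delta_t`` is the gcd of all sampling-interval lengths, ``m`` the
    number of candidate delays ``0, dT, ..., (m-1)*dT``, and
    ``eval_points`` the dT grid over the regulator's stage window at
    which the regulator signal is read (``m`` points, so the score is a
    true mean).
    """

    delta_t: float
    m: int
    delays: tuple[float, ...]
    eval_points: tuple[float, ...]


def build_delay_grid(
    times: np.ndarray,
    regulator_stage_window: Stage | tuple[float, float],
    target_stage_window: Stage | tuple[float, float],
) -> DelayGrid:
    """Derive (dT, M, delays, evaluation grid) from the sampling scheme.

    dT is the greatest common divisor of the sampling-interval lengths;
    M is the number of dT steps that fit in the shorter of the two stage
    windows.
    """
    times = np.asarray(times, dtype=float)
    reg = (regulator_stage_window.start, regulator_stage_window.end) \
        if isinstance(regulator_stage_window, Stage) else tuple(regulator_stage_window)
    tgt = (target_stage_window.start, target_stage_window.end) \
        if isinstance(target_stage_window, Stage) else tuple(target_stage_window)
    intervals = np.diff(times)
    dt = _float_gcd(intervals)
    multiples = np.round(intervals / dt) if dt > _GCD_RESOLUTION else None
    if (
        dt <= _GCD_RESOLUTION
        or np.any(multiples < 1)
        or np.any(np.abs(intervals - multiples * dt) > _GCD_RESOLUTION)
    ):
        raise ValueError(
            "sampling times are non-commensurable: no common interval "
            f"divisor above the {_GCD_RESOLUTION} h resolution"
        )
    m = int(min((reg[1] - reg[0]) / dt + 1e-9, (tgt[1] - tgt[0]) / dt + 1e-9))
    if m < 1:
        raise ValueError("a stage window is shorter than one delay step")
    delays = tuple(i * dt for i in range(m))
    eval_points = tuple(reg[0] + (i + 1) * dt for i in range(m))
    return DelayGrid(delta_t=dt, m=m, delays=delays, eval_points=eval_points)


@dataclass
class StepSignal:
    """Piecewise-constant (zeroth-order hold) change signal of one gene.

    The value over ``(t_k, t_{k+1}]`` is the gene's max-rescaled change
    on that interval; with a threshold the values are ternarized to
    upregulation (+1), downregulation (-1) or no regulation (0).  The
    signal is defined on ``(t_1, t_N]`` only.
    """

    gene_id: object
    times: np.ndarray
    values: np.ndarray
    threshold: float | None = None

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.times[0], self.times[-1]
        if np.any(t_arr <= lo + 1e-12 * max(1.0, abs(lo))) or np.any(t_arr > hi + 1e-9):
            raise ValueError(
                f"step signal of {self.gene_id} evaluated outside its domain "
                f"({lo}, {hi}]"
            )
        idx = np.searchsorted(self.times, t_arr - 1e-9, side="left") - 1
        out = self.values[idx]
        return float(out) if np.isscalar(t) else out


def ternarize(values: np.ndarray, thr: float) -> np.ndarray:
    """Map changes to regulation events at threshold ``thr``.

    Strictly above ``thr`` -> +1, strictly below ``-thr`` -> -1,
    everything else (including values exactly at the threshold) -> 0,
    the conservative no-regulation call.
    """
    return np.where(values > thr, 1.0, np.where(values < -thr, -1.0, 0.0))


def step_signal(ch: ChangeSeries, gene_id, thr: float | None = None) -> StepSignal:
    """Build the (optionally ternarized) step signal of one gene."""
    if gene_id not in ch.normalized.index:
        raise KeyError(f"gene {gene_id!r} not present in the change series")
    values = ch.normalized.loc[gene_id].to_numpy(dtype=float)
    if thr is not None:
        values = ternarize(values, float(thr))
    return StepSignal(gene_id=gene_id, times=ch.times, values=values, threshold=thr)


def dissimilarity(
    reg: StepSignal, tgt: StepSignal, grid: DelayGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Score every candidate delay for one regulator-target pair.

    Returns ``(scores, orientations)`` aligned with ``grid.delays``.  For
    each delay the direct score d (mean |reg - shifted target|) and the
    inverted score d^ (regulator negated) are computed; the smaller one
    is kept and its orientation recorded (ties resolve to direct).
    Scores live in [0, 2] because both signals are bounded by 1.
    """
    pts = np.asarray(grid.eval_points)
    r = np.asarray([reg(t) for t in pts])
    scores = np.empty(grid.m)
    orientations = np.empty(grid.m, dtype=object)
    for j, delay in enumerate(grid.delays):
        try:
            s = np.asarray([tgt(t + delay) for t in pts])
        except ValueError as err:
            raise ValueError(
                f"delay {delay} h pushes evaluation outside the target "
                f"signal domain: {err}"
            ) from err
        d = float(np.mean(np.abs(r - s)))
        d_hat = float(np.mean(np.abs(-r - s)))
        if d <= d_hat:
            scores[j], orientations[j] = d, DIRECT
        else:
            scores[j], orientations[j] = d_hat, INVERTED
    return scores, orientations


@dataclass
class DissimilarityTable:
    """All candidate-regulator alignments against one target at one threshold.

    ``scores``/``orientations`` are candidate x delay tables.  ``kept``
    flags rows that survived zero-delay exclusion; ``best`` holds each
    surviving row's minimal score, the delay achieving it and the
    orientation there.
    """

    target: object
    threshold: float | None
    grid: DelayGrid
    scores: pd.DataFrame
    orientations: pd.DataFrame
    kept: pd.Series
    best: pd.DataFrame

    @property
    def surviving(self) -> pd.DataFrame:
        return self.best.loc[self.kept]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for regulator in self.scores.index:
            for delay in self.scores.columns:
                rows.append(
                    {
                        "target": self.target,
                        "threshold": "none" if self.threshold is None else self.threshold,
                        "regulator": regulator,
                        "delay_hours": delay,
                        "score": self.scores.at[regulator, delay],
                        "orientation": self.orientations.at[regulator, delay],
                        "kept": bool(self.kept[regulator]),
                    }
                )
        return pd.DataFrame(rows)


def build_dissimilarity_table(
    target,
    candidate_regulators,
    ch: ChangeSeries,
    grid: DelayGrid,
    thr: float | None = None,
    strict_zero_delay: bool = False,
) -> DissimilarityTable:
    """Score all candidates against one target and apply zero-delay exclusion.

    A row is discarded when delay 0 is the unique minimizer of its score
    -- such a candidate is indistinguishable from a co-expressed gene.
    When delay 0 ties with a positive delay the row is kept and the
    smallest positive minimizing delay reported; ``strict_zero_delay``
    discards on ties as well.
    """
    candidates = [c for c in candidate_regulators]
    if target in candidates:
        raise ValueError("the target cannot be its own candidate regulator")
    if not candidates:
        warnings.warn(f"no candidate regulators supplied for target {target!r}",
                      stacklevel=2)
    tgt_sig = step_signal(ch, target, thr)
    delays = list(grid.delays)
    score_rows, orient_rows, kept, best_rows = {}, {}, {}, {}
    for cand in candidates:
        reg_sig = step_signal(ch, cand, thr)
        scores, orients = dissimilarity(reg_sig, tgt_sig, grid)
        score_rows[cand] = scores
        orient_rows[cand] = orients
        row_min = scores.min()
        minimizers = [d for d, s in zip(delays, scores) if s <= row_min + 1e-12]
        positive = [d for d in minimizers if d > 0]
        if not positive or (strict_zero_delay and 0.0 in minimizers):
            kept[cand] = False
            best_delay = minimizers[0]
        else:
            kept[cand] = True
            best_delay = positive[0]
        j = delays.index(best_delay)
        best_rows[cand] = {
            "score": float(scores[j]),
            "delay_hours": best_delay,
            "orientation": orients[j],
        }
    index = pd.Index(candidates, name="regulator")
    return DissimilarityTable(
        target=target,
        threshold=thr,
        grid=grid,
        scores=pd.DataFrame(score_rows, index=delays).T.set_axis(index, axis=0),
        orientations=pd.DataFrame(orient_rows, index=delays).T.set_axis(index, axis=0),
        kept=pd.Series(kept, index=index, dtype=bool),
        best=pd.DataFrame(best_rows).T.set_axis(index, axis=0)
        if best_rows
        else pd.DataFrame(columns=["score", "delay_hours", "orientation"], index=index),
    )


@dataclass(frozen=True)
class Edge:
    """A consensus regulator -> target prediction."""

    regulator: object
    target: object
    sign: int  # +1 activation (direct), -1 repression (inverted)
    delay_hours: float
    min_dissimilarity: float
    n_supporting_thresholds: int


@dataclass
class PredictedNetwork:
    """Consensus edge set; nodes are the genes appearing in at least one edge."""

    edges: list[Edge] = field(default_factory=list)

    @property
    def nodes(self) -> list:
        seen: dict = {}
        for e in self.edges:
            seen.setdefault(e.regulator, None)
            seen.setdefault(e.target, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple]:
        return {(e.regulator, e.target) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "regulator": e.regulator,
                    "target": e.target,
                    "sign": e.sign,
                    "delay_hours": e.delay_hours,
                    "min_dissimilarity": e.min_dissimilarity,
                    "n_supporting_thresholds": e.n_supporting_thresholds,
                }
                for e in self.edges
            ],
            columns=[
                "regulator",
                "target",
                "sign",
                "delay_hours",
                "min_dissimilarity",
                "n_supporting_thresholds",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PredictedNetwork":
        edges = [
            Edge(
                regulator=row.regulator,
                target=row.target,
                sign=int(row.sign),
                delay_hours=float(row.delay_hours),
                min_dissimilarity=float(row.min_dissimilarity),
                n_supporting_thresholds=int(row.n_supporting_thresholds),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(edges=edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(
                e.regulator,
                e.target,
                sign=e.sign,
                delay_hours=e.delay_hours,
                min_dissimilarity=e.min_dissimilarity,
                n_supporting_thresholds=e.n_supporting_thresholds,
            )
        return g


def consensus_predict(
    target,
    tables: list[DissimilarityTable],
    cutoff: float = 0.4,
    min_support: int = 2,
) -> list[Edge]:
    """Combine per-threshold tables into consensus edges for one target.

    A regulator "appears" in a table when its row survived zero-delay
    exclusion and its minimal score is at most ``cutoff``; appearing in
    at least ``min_support`` tables makes it an edge.  Sign and delay
    are taken from the supporting table with the smallest row minimum
    (best evidence); +1 encodes a direct (activating) orientation, -1 an
    inverted (repressing) one.
    """
    support: dict = {}
    for table in tables:
        for regulator, row in table.surviving.iterrows():
            if row["score"] <= cutoff + 1e-12:
                support.setdefault(regulator, []).append(row)
    edges = []
    for regulator in sorted(support, key=str):
        rows = support[regulator]
        if len(rows) < min_support:
            continue
        best = min(rows, key=lambda r: r["score"])
        edges.append(
            Edge(
                regulator=regulator,
                target=target,
                sign=1 if best["orientation"] == DIRECT else -1,
                delay_hours=float(best["delay_hours"]),
                min_dissimilarity=float(best["score"]),
                n_supporting_thresholds=len(rows),
            )
        )
    return edges


def infer_network(
    x: pd.DataFrame,
    partition: StagePartition,
    targets,
    assignment: StageAssignment | None = None,
    regulator_pool="all-initiation",
    tf_ids=None,
    thresholds=(None, 0.2, 0.4),
    cutoff: float = 0.4,
    min_support: int = 2,
    ddof: int = 0,
    strict_zero_delay: bool = False,
    collect_tables: bool = False,
):
    """Run the full interaction-inference step for a list of targets.

    Parameters
    ----------
    x:
        Raw gene x time expression table (standardization happens here).
    partition:
        Stage windows from stage separation; regulators align over the
        first stage window, targets over the second.
    targets:
        Genes whose upstream regulators are sought.
    assignment:
        Stage labels from the clustering step.  Required when
        ``regulator_pool`` is ``"all-initiation"``; also used to warn
        about (and, for stage-derived pools, skip) targets that are not
        in the stage adjacent to the regulators'.
    regulator_pool:
        ``"all-initiation"`` (Initiation-stage genes, intersected with
        ``tf_ids`` when given) or an explicit list of candidate genes.
        With an explicit pool, non-adjacent targets are warned about but
        still processed, since the caller fixed both lists deliberately.
    thresholds:
        Event-threshold levels; ``None`` denotes the unthresholded signal.

    Returns
    -------
    PredictedNetwork, or ``(PredictedNetwork, tables)`` when
    ``collect_tables`` is true, where ``tables`` maps
    (target, threshold) -> DissimilarityTable.
    """
    if len(thresholds) < 2:
        raise ValueError("consensus needs at least 2 threshold levels")
    explicit_pool = not (
        isinstance(regulator_pool, str) and regulator_pool == "all-initiation"
    )
    if explicit_pool:
        pool = list(regulator_pool)
    else:
        if assignment is None:
            raise ValueError(
                "a stage assignment is required to draw regulators from the "
                "Initiation stage"
            )
        pool = assignment.genes_in_stage(INITIATION)
        if tf_ids is not None:
            tf_set = set(tf_ids)
            pool = [g for g in pool if g in tf_set]
    pool = [g for g in pool if g in x.index]
    ch = changes(zscore_normalize(x, ddof=ddof))
    grid = build_delay_grid(ch.times, partition.stages[0], partition.stages[1])
    target_stage = partition.stages[1].name
    edges: list[Edge] = []
    tables: dict = {}
    for target in targets:
        if target not in x.index:
            warnings.warn(f"target {target!r} absent from the expression table; "
                          "skipped", stacklevel=2)
            continue
        if assignment is not None and assignment.stages.get(target) != target_stage:
            msg = (
                f"target {target!r} is assigned to stage "
                f"{assignment.stages.get(target)!r}, not the {target_stage} "
                "stage adjacent to the regulator pool"
            )
            if explicit_pool:
                warnings.warn(msg + "; processing anyway (explicit pool)",
                              stacklevel=2)
            else:
                warnings.warn(msg + "; skipped", stacklevel=2)
                continue
        candidates = [g for g in pool if g != target]
        target_tables = [
            build_dissimilarity_table(
                target, candidates, ch, grid, thr,
                strict_zero_delay=strict_zero_delay,
            )
            for thr in thresholds
        ]
        if collect_tables:
            for thr, table in zip(thresholds, target_tables):
                tables[(target, thr)] = table
        edges.extend(
            consensus_predict(target, target_tables, cutoff=cutoff,
                              min_support=min_support)
        )
    network = PredictedNetwork(edges=edges)
    return (network, tables) if collect_tables else network


def threshold_diagnostics(
    ch: ChangeSeries,
    initiation_genes,
    thresholds,
    boundary_time: float,
) -> pd.Series:
    """Average number of early-window changes exceeding each threshold.

    For every threshold, the mean over ``initiation_genes`` of the count
    of intervals inside the Initiation window (those ending at or before
    ``boundary_time``) whose |max-rescaled change| strictly exceeds the
    threshold.  Plotting this against the threshold shows how many
    changes per gene a given noise level would write off.
    """
    genes = list(initiation_genes)
    inside = np.asarray(
        [end <= boundary_time + 1e-9 for _, end in ch.intervals], dtype=bool
    )
    if not inside.any():
        raise ValueError("the Initiation window contains no sampling interval")
    values = np.abs(ch.normalized.loc[genes].to_numpy(dtype=float))[:, inside]
    out = {
        float(thr): float((values > float(thr)).sum(axis=1).mean())
        for thr in thresholds
    }
    return pd.Series(out, name="mean_changes_above_threshold")
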