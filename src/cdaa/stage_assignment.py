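"""Incremental stage-windowed clustering of genes.

Genes are assigned to the earliest stage in which they show detectable
activity.  Clustering is run on expression values restricted to a
growing time window: first the Initiation window alone, then Initiation
plus Primary Response, and so on.  Before each round every remaining
gene is re-centered by its mean over the current window, so activity
outside the window cannot dominate the distance computations.  In each
round exactly one cluster -- the one with the flattest centroid -- is
treated as "inactive"; its members are carried into the next round,
while members of the active clusters are labeled with the current stage.
Whatever remains after the final round belongs to the last stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .stage_separation import StagePartition


@dataclass
class CenteredWindowMatrix:
    """Expression values over a window, each row shifted by its window mean."""

    values: pd.DataFrame  # genes x window time points, rows sum to ~0

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def times(self) -> np.ndarray:
        return np.asarray([float(c) for c in self.values.columns])


@dataclass
class StageAssignment:
    """Per-gene stage label plus the cluster id from every clustering round.

    ``clusters`` has one column per round (``round1``, ``round2``, ...);
    a gene labeled in round r holds NaN in later rounds because it never
    entered them.
    """

    stages: pd.Series
    clusters: pd.DataFrame

    def genes_in_stage(self, stage: str) -> list:
        return list(self.stages.index[self.stages == stage])

    def counts(self) -> pd.Series:
        return self.stages.value_counts()

    def to_frame(self) -> pd.DataFrame:
        out = self.clusters.copy()
        out.insert(0, "stage", self.stages)
        return out


def center_window(
    x: pd.DataFrame, gene_subset, window_end_index: int
) -> CenteredWindowMatrix:
    """Restrict to the first ``window_end_index`` time points and row-center.

    ``window_end_index`` counts time points (so the window is
    ``t_1..t_w``).  Centering is idempotent and makes genes that are flat
    inside the window exactly zero, regardless of later activity.
    """
    gene_subset = list(gene_subset)
    if len(gene_subset) == 0:
        raise ValueError("empty gene subset for window centering")
    w = int(window_end_index)
    if not 1 < w <= x.shape[1]:
        raise ValueError(f"window end index {w} out of range (need 1 < w <= N)")
    sub = x.loc[gene_subset].iloc[:, :w].astype(float)
    centered = sub.sub(sub.mean(axis=1), axis=0)
    return CenteredWindowMatrix(values=centered)


def cluster_window(
    cm: CenteredWindowMatrix, k: int, seed: int = 0, restarts: int = 50
) -> pd.Series:
    """k-means over the centered window; deterministic given (seed, restarts).

    The best of ``restarts`` initializations by within-cluster sum of
    squares is kept, which is what makes repeated runs reproducible in
    practice even though the objective is non-convex.
    """
    n_genes = cm.values.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters to separate activity")
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({n_genes})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(cm.values.to_numpy())
    return pd.Series(labels, index=cm.gene_ids, name="cluster")


def identify_inactive_cluster(
    cm: CenteredWindowMatrix,
    labels: pd.Series,
    criterion: str = "max_abs",
) -> int:
    """Pick the single cluster whose centroid is flattest over the window.

    criterion:
        ``max_abs``  -- smallest maximum |centroid| value (default);
        ``variance`` -- smallest centroid variance;
        ``range``    -- smallest mean per-gene range within the cluster.
    """
    amplitudes = {}
    for cl in sorted(labels.unique()):
        member = cm.values.loc[labels.index[labels == cl]]
        centroid = member.mean(axis=0).to_numpy()
        if criterion == "max_abs":
            amplitudes[cl] = float(np.abs(centroid).max())
        elif criterion == "variance":
            amplitudes[cl] = float(centroid.var())
        elif criterion == "range":
            rng = member.max(axis=1) - member.min(axis=1)
            amplitudes[cl] = float(rng.mean())
        else:
            raise ValueError(f"unknown inactive-cluster criterion {criterion!r}")
    inactive = min(amplitudes, key=lambda cl: (amplitudes[cl], cl))
    most_active = max(amplitudes.values())
    if most_active < 2 * amplitudes[inactive] + 1e-12:
        warnings.warn(
            "activity separation between clusters is weak; the flattest "
            "cluster was still selected as inactive",
            stacklevel=2,
        )
    return int(inactive)


def assign_stages(
    x: pd.DataFrame,
    partition: StagePartition,
    k1: int = 4,
    k2: int = 4,
    seed: int = 0,
    restarts: int = 50,
    inactive_criterion: str = "max_abs",
) -> StageAssignment:
    """Assign every gene to a stage by incremental windowed clustering.

    ``x`` is the standardized expression table.  One clustering round is
    run per stage except the last: round r clusters the genes still
    unassigned on the window ending at stage r's last time point, labels
    the active clusters' genes with stage r, and forwards the inactive
    cluster to round r+1.  ``k1`` applies to the first round, ``k2`` to
    every later round.
    """
    if len(partition.stages) < 2:
        raise ValueError("need at least 2 stages for stage assignment")
    times = np.asarray([float(c) for c in x.columns])
    stages = pd.Series(index=x.index, dtype=object, name="stage")
    cluster_cols: dict[str, pd.Series] = {}
    remaining = list(x.index)
    for r, stage in enumerate(partition.stages[:-1], start=1):
        w = int(np.sum(times <= stage.end + 1e-9))
        cm = center_window(x, remaining, w)
        k = k1 if r == 1 else k2
        labels = cluster_window(cm, k=k, seed=seed, restarts=restarts)
        cluster_cols[f"round{r}"] = labels
        inactive = identify_inactive_cluster(cm, labels, criterion=inactive_criterion)
        active_genes = labels.index[labels != inactive]
        stages.loc[active_genes] = stage.name
        remaining = list(labels.index[labels == inactive])
        if not remaining:
            warnings.warn(
                f"no genes left after round {r}; later stages are empty",
                stacklevel=2,
            )
            break
    stages.loc[remaining] = partition.stages[-1].name
    clusters = pd.DataFrame(cluster_cols, index=x.index)
    return StageAssignment(stages=stages, clusters=clusters)


class StageAssigner(BaseEstimator):
    """Estimator wrapper around incremental stage-windowed clustering.

    Expects standardized expression as ``X`` and the stage partition via
    the ``partition`` fit parameter.

    Attributes
    ----------
    assignment_ : StageAssignment
    labels_ : pd.Series mapping gene id -> stage name
    """

    def __init__(self, k1=4, k2=4, seed=0, restarts=50, inactive_criterion="max_abs"):
        self.k1 = k1
        self.k2 = k2
        self.seed = seed
        self.restarts = restarts
        self.inactive_criterion = inactive_criterion

    def fit(self, X: pd.DataFrame, y=None, *, partition: StagePartition):
        self.assignment_ = assign_stages(
            X,
            partition,
            k1=self.k1,
            k2=self.k2,
            seed=self.seed,
            restarts=self.restarts,
            inactive_criterion=self.inactive_criterion,
        )
        self.labels_ = self.assignment_.stages
        return self
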