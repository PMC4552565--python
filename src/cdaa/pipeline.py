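"""End-to-end pipeline: stage separation -> stage assignment -> inference.

`CDAA` is the scikit-learn-style front door: construct it with the
tunables, call :meth:`CDAA.fit` on a gene x time expression table, and
read the fitted attributes (``partition_``, ``assignment_``,
``network_``).  :func:`run_pipeline` adds the on-disk artifacts (network
TSV, stage CSV, dissimilarity tables, JSON manifest) used by the
command-line interface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import sklearn
from sklearn.base import BaseEstimator

from . import __version__
from .inference import build_delay_grid, infer_network, threshold_diagnostics
from .io import read_expression, read_gene_list, write_network
from .preprocessing import changes, drop_constant_genes, zscore_normalize
from .stage_assignment import assign_stages
from .stage_separation import separate_stages


class CDAA(BaseEstimator):
    """Stage-wise clustering and delayed differential-pattern alignment.

    Parameters
    ----------
    k1, k2:
        Cluster counts for the first and later stage-assignment rounds.
    c:
        Number of sampling intervals in the Primary Response stage.
    thresholds:
        Event-threshold levels for the consensus; ``None`` denotes the
        unthresholded signal.
    cutoff:
        Maximum admissible row-minimum dissimilarity.
    min_support:
        Number of threshold levels a regulator must pass.
    ddof:
        Degrees of freedom for the per-gene standardization.
    use_abs_max:
        Stage-separate on |change| instead of the signed change.
    drop_constant:
        Silently drop zero-variance genes (with a count) instead of
        raising.
    boundary_override:
        Force the Initiation-Response boundary to this time (hours).
    strict_zero_delay:
        Discard candidates whose best score ties between delay 0 and a
        positive delay (default keeps them at the positive delay).
    inactive_criterion:
        How the inactive cluster is recognized per round
        (``max_abs`` / ``variance`` / ``range``).
    restarts, random_state:
        k-means restarts and seed; fixed defaults keep runs reproducible.

    Attributes
    ----------
    normalized_, change_series_, partition_, assignment_, grid_,
    network_, tables_, dropped_genes_
    """

    def __init__(
        self,
        k1=4,
        k2=4,
        c=1,
        thresholds=(None, 0.2, 0.4),
        cutoff=0.4,
        min_support=2,
        ddof=0,
        use_abs_max=False,
        drop_constant=False,
        boundary_override=None,
        strict_zero_delay=False,
        inactive_criterion="max_abs",
        restarts=50,
        random_state=0,
    ):
        self.k1 = k1
        self.k2 = k2
        self.c = c
        self.thresholds = thresholds
        self.cutoff = cutoff
        self.min_support = min_support
        self.ddof = ddof
        self.use_abs_max = use_abs_max
        self.drop_constant = drop_constant
        self.boundary_override = boundary_override
        self.strict_zero_delay = strict_zero_delay
        self.inactive_criterion = inactive_criterion
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, *, targets=None,
            regulators="all-initiation", tf_ids=None):
        """Run the three pipeline steps on an expression table.

        ``targets`` lists the genes whose regulators are sought; when
        omitted, staging runs but no network is inferred (``network_``
        stays None).
        """
        if self.drop_constant:
            X, dropped = drop_constant_genes(X)
            self.dropped_genes_ = dropped
            if dropped:
                warnings.warn(
                    f"dropped {len(dropped)} zero-variance genes", stacklevel=2
                )
        else:
            self.dropped_genes_ = []
        self.normalized_ = zscore_normalize(X, ddof=self.ddof)
        self.change_series_ = changes(self.normalized_)
        self.partition_ = separate_stages(
            self.change_series_,
            c=self.c,
            use_abs_max=self.use_abs_max,
            boundary_override=self.boundary_override,
        )
        self.assignment_ = assign_stages(
            self.normalized_,
            self.partition_,
            k1=self.k1,
            k2=self.k2,
            seed=self.random_state,
            restarts=self.restarts,
            inactive_criterion=self.inactive_criterion,
        )
        self.grid_ = build_delay_grid(
            self.change_series_.times,
            self.partition_.stages[0],
            self.partition_.stages[1],
        )
        if targets is not None:
            self.network_, self.tables_ = infer_network(
                X,
                self.partition_,
                targets,
                assignment=self.assignment_,
                regulator_pool=regulators,
                tf_ids=tf_ids,
                thresholds=self.thresholds,
                cutoff=self.cutoff,
                min_support=self.min_support,
                ddof=self.ddof,
                strict_zero_delay=self.strict_zero_delay,
                collect_tables=True,
            )
        else:
            self.network_, self.tables_ = None, {}
        return self

    def threshold_diagnostics(self, thresholds) -> pd.Series:
        """Mean early-window change counts above each threshold (fitted data)."""
        genes = self.assignment_.genes_in_stage(self.partition_.stages[0].name)
        return threshold_diagnostics(
            self.change_series_, genes, thresholds, self.partition_.boundary_time
        )


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serializable)."""

    expression: str
    targets: str | None = None
    tf_list: str | None = None
    regulators: str | None = None  # file of explicit candidate ids
    out: str = "network.tsv"
    out_format: str = "tsv"
    assignments_out: str | None = None
    tables_dir: str | None = None
    manifest: str | None = None
    thresholds: tuple = (None, 0.2, 0.4)
    cutoff: float = 0.4
    min_support: int = 2
    k1: int = 4
    k2: int = 4
    c: int = 1
    seed: int = 0
    restarts: int = 50
    ddof: int = 0
    drop_constant: bool = False
    use_abs_max: bool = False
    strict_zero_delay: bool = False
    boundary_override: float | None = None
    inactive_criterion: str = "max_abs"

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["thresholds"] = ["none" if t is None else t for t in self.thresholds]
        return d


def run_pipeline(config: RunConfig):
    """Execute a configured run and write its artifacts.

    Returns the fitted :class:`CDAA` model.  Writes the network, the
    per-gene stage/cluster table, per-target per-threshold dissimilarity
    tables, and a JSON manifest with the resolved configuration, library
    versions and the boundary that was found.
    """
    x = read_expression(config.expression)
    targets = None
    if config.targets:
        targets = list(read_gene_list(config.targets).index)
    tf_ids = None
    if config.tf_list:
        tf_frame = read_gene_list(config.tf_list)
        tf_ids = list(tf_frame.index[tf_frame["is_tf"]])
    regulators = "all-initiation"
    if config.regulators:
        regulators = list(read_gene_list(config.regulators).index)

    model = CDAA(
        k1=config.k1,
        k2=config.k2,
        c=config.c,
        thresholds=tuple(config.thresholds),
        cutoff=config.cutoff,
        min_support=config.min_support,
        ddof=config.ddof,
        use_abs_max=config.use_abs_max,
        drop_constant=config.drop_constant,
        boundary_override=config.boundary_override,
        strict_zero_delay=config.strict_zero_delay,
        inactive_criterion=config.inactive_criterion,
        restarts=config.restarts,
        random_state=config.seed,
    )
    model.fit(x, targets=targets, regulators=regulators, tf_ids=tf_ids)

    if model.network_ is not None:
        write_network(model.network_, config.out, format=config.out_format)
    if config.assignments_out:
        model.assignment_.to_frame().to_csv(config.assignments_out)
    if config.tables_dir and model.tables_:
        tdir = Path(config.tables_dir)
        tdir.mkdir(parents=True, exist_ok=True)
        for (target, thr), table in model.tables_.items():
            tag = "none" if thr is None else str(thr)
            table.to_long_frame().to_csv(
                tdir / f"dissimilarity_{target}_thr_{tag}.csv", index=False
            )
    if config.manifest:
        manifest = {
            "config": config.to_jsonable(),
            "versions": {
                "cdaa": __version__,
                "scikit-learn": sklearn.__version__,
                "pandas": pd.__version__,
            },
            "boundary_time_hours": model.partition_.boundary_time,
            "boundary_index": model.partition_.boundary_index,
            "boundary_manual": config.boundary_override is not None,
            "stages": [
                {"name": s.name, "start": s.start, "end": s.end}
                for s in model.partition_.stages
            ],
            "delta_t_hours": model.grid_.delta_t,
            "n_delays": model.grid_.m,
            "n_dropped_genes": len(model.dropped_genes_),
            "n_edges": len(model.network_) if model.network_ is not None else None,
        }
        with open(config.manifest, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return model
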