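"""Synthetic regulatory cascades with known ground truth.

The generator emulates the statistical structure the inference pipeline
assumes rather than transcriptional kinetics: a small set of regulators
active only during an early (Initiation) window, targets whose
change-in-expression pattern is a delayed, possibly sign-inverted copy
of one regulator's pattern, a bulk wave of background responders whose
dominant change sits just after the stage boundary (these carry the
modal-interval boundary signal, exactly as the large response wave does
in real stress time courses), and inert genes that are constant up to
additive noise.

All signals are built as piecewise-constant change rates on the dT grid
(dT = gcd of the sampling intervals) and integrated to expression
values, so a target really is its regulator's step signal shifted by a
whole number of delay steps.  Expression rows are standardized to unit
variance before Gaussian noise of standard deviation ``noise_sd`` is
added; the noise level is therefore a fraction of signal amplitude.

Ground truth (edges, signs, delays, stage labels) is a deterministic
function of the spec alone; the seed only drives the noise, so two
seeds share the same truth and differ in noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import PredictedNetwork, _float_gcd
from .stage_separation import INITIATION, PRIMARY_RESPONSE, SECONDARY_RESPONSE

DEFAULT_TIMES = (0.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0)

# Change-rate templates on 4 equal cells spanning the Initiation window.
# Chosen to be (a) constant within the actual sampling intervals of the
# default grid, (b) mutually distinguishable under the alignment score
# across relative delays, sign inversion and event thresholding, so the
# planted edge structure is identifiable at all.
PATTERN_TEMPLATES = {
    "early_peak": (1.0, 0.6, 0.3, 0.3),
    "pulse": (0.0, 1.0, -0.3, -0.3),
    "oscillation": (-0.3, 0.3, -1.0, -1.0),
    "ramp": (0.6, 0.0, 1.0, 1.0),
    "transient": (0.6, 0.0, -1.0, -1.0),
}
DEFAULT_PATTERN_CYCLE = ("early_peak", "pulse", "oscillation", "ramp", "transient")

# Default edge plan: (regulator index, delay steps, sign, early level).
# Each regulator's targets use delays at which its pattern, as read on
# the delay-probe grid, stays identifiable against the other patterns.
# The early level is the target's change over the first sampling
# interval; it mimics baseline co-fluctuation preceding the true
# response and anchors unrelated regulators' best alignment at delay 0,
# where zero-delay exclusion removes them.
DEFAULT_EDGE_PLAN = (
    (0, 1, 1, 0.0),
    (1, 1, 1, 1.0),
    (2, 3, 1, -0.3),
    (3, 1, -1, -0.6),
    (4, 3, 1, 0.3),
    (0, 2, -1, 0.0),
    (1, 2, -1, -1.0),
    (2, 3, -1, 0.3),
    (3, 3, 1, 0.0),
    (4, 3, -1, -0.3),
)


@dataclass(frozen=True)
class CascadeSpec:
    """Parameters of one synthetic cascade.

    ``delay_steps``/``signs`` may be given per target; when None they are
    assigned deterministically (delays cycling through ``delay_choices``,
    signs alternating) so the ground truth does not depend on the seed.
    ``n_background`` genes form the dominant post-boundary response wave,
    split across the post-boundary sampling intervals according to
    ``background_weights``.
    """

    times: tuple = DEFAULT_TIMES
    n_regulators: int = 5
    n_targets: int = 10
    n_inert: int = 30
    n_background: int = 60
    initiation_end: float = 12.0
    delay_choices: tuple = (1, 2, 3)
    delay_steps: tuple | None = None
    signs: tuple | None = None
    early_levels: tuple | None = None
    noise_sd: float = 0.05
    seed: int = 0
    pattern_names: tuple = DEFAULT_PATTERN_CYCLE
    background_weights: tuple = (0.7, 0.2, 0.1)


@dataclass
class CascadeTruth:
    """Ground truth accompanying a generated expression matrix."""

    edges: pd.DataFrame  # regulator, target, sign, delay_steps, delay_hours
    stages: pd.Series  # gene id -> intended stage label
    boundary_time: float
    delta_t: float

    def edge_set(self) -> set[tuple]:
        return {(r.regulator, r.target) for r in self.edges.itertuples()}


def _pattern_cells(name: str, n_cells: int) -> np.ndarray:
    template = np.asarray(PATTERN_TEMPLATES[name], dtype=float)
    # zeroth-order resample of the 4-cell template onto n_cells cells
    idx = np.minimum((np.arange(n_cells) * len(template)) // n_cells,
                     len(template) - 1)
    return template[idx]


def _integrate(cells: np.ndarray, dt: float, sample_idx: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(cells) * dt])
    return cum[sample_idx]


def generate_cascade(spec: CascadeSpec) -> tuple[pd.DataFrame, CascadeTruth]:
    """Generate an expression matrix plus its ground truth.

    Returns ``(expression, truth)`` where expression is a gene x time
    DataFrame and truth carries the planted edges and stage labels.
    """
    times = np.asarray(spec.times, dtype=float)
    if len(times) < 4 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be >= 4 strictly increasing values")
    dt = _float_gcd(np.diff(times))
    n_cells = int(round((times[-1] - times[0]) / dt))
    sample_idx = np.round((times - times[0]) / dt).astype(int)
    if not np.allclose(times, times[0] + sample_idx * dt):
        raise ValueError("sampling times are not commensurable with their gcd")
    if spec.initiation_end not in times:
        raise ValueError("initiation_end must be one of the sampling times")
    init_cells = int(round((spec.initiation_end - times[0]) / dt))
    post_intervals = [
        (times[k], times[k + 1])
        for k in range(len(times) - 1)
        if times[k] >= spec.initiation_end - 1e-9
    ]
    if spec.n_background and not post_intervals:
        raise ValueError("no sampling interval after initiation_end for the "
                         "background wave")

    rng = np.random.default_rng(spec.seed)
    rows: dict = {}
    stages: dict = {}

    reg_ids = [f"reg_{i + 1}" for i in range(spec.n_regulators)]
    reg_cells: dict[str, np.ndarray] = {}
    for i, gene in enumerate(reg_ids):
        cells = np.zeros(n_cells)
        cells[:init_cells] = _pattern_cells(
            spec.pattern_names[i % len(spec.pattern_names)], init_cells
        )
        reg_cells[gene] = cells
        rows[gene] = _integrate(cells, dt, sample_idx)
        stages[gene] = INITIATION

    tgt_ids = [f"tgt_{j + 1}" for j in range(spec.n_targets)]
    edge_records = []
    if spec.n_targets and not spec.n_regulators:
        raise ValueError("targets require at least one regulator")
    dts = np.diff(times)
    for j, gene in enumerate(tgt_ids):
        plan = DEFAULT_EDGE_PLAN[j % len(DEFAULT_EDGE_PLAN)]
        reg_idx = plan[0] % len(reg_ids)
        d = (spec.delay_steps[j] if spec.delay_steps is not None
             else plan[1])
        sign = (spec.signs[j] if spec.signs is not None else plan[2])
        early = (spec.early_levels[j] if spec.early_levels is not None
                 else plan[3])
        reg = reg_ids[reg_idx]
        if d < 1:
            raise ValueError("planted delays must be >= 1 delay step")
        if spec.initiation_end + d * dt > times[-1] + 1e-9:
            raise ValueError(
                f"delay of {d} steps pushes target {gene} beyond the time range"
            )
        # regulator step signal (change per hour on its sampling intervals)
        reg_rates = np.array([
            reg_cells[reg][sample_idx[k]:sample_idx[k + 1]].mean()
            for k in range(len(times) - 1)
        ])
        # read the regulator on the delay-probe grid (the dT grid over the
        # Initiation window, shifted by the planted delay) and project the
        # delayed pattern onto the target's sampling intervals
        probes = times[0] + (np.arange(init_cells) + 1 + d) * dt
        acc = np.zeros(len(times) - 1)
        cnt = np.zeros(len(times) - 1)
        for t in probes:
            k = int(np.searchsorted(times, t - 1e-9, side="left")) - 1
            src = int(np.searchsorted(times, t - d * dt - 1e-9, side="left")) - 1
            acc[k] += sign * reg_rates[src]
            cnt[k] += 1
        rates = np.zeros(len(times) - 1)
        rates[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0]
        if cnt[0] == 0:
            rates[0] = early
        rows[gene] = np.concatenate([[0.0], np.cumsum(rates * dts)])
        stages[gene] = PRIMARY_RESPONSE
        edge_records.append(
            {"regulator": reg, "target": gene, "sign": int(sign),
             "delay_steps": int(d), "delay_hours": float(d * dt)}
        )

    weights = np.asarray(spec.background_weights, dtype=float)[: len(post_intervals)]
    weights = weights / weights.sum() if weights.sum() > 0 else weights
    counts = np.floor(weights * spec.n_background).astype(int)
    counts[0] += spec.n_background - counts.sum()
    bg_idx = 0
    for which, count in enumerate(counts):
        lo, hi = post_intervals[which]
        for _ in range(count):
            bg_idx += 1
            gene = f"bg_{bg_idx}"
            cells = np.zeros(n_cells)
            a = int(round((lo - times[0]) / dt))
            b = int(round((hi - times[0]) / dt))
            # transient surge with partial relaxation in the following
            # interval; induction dominates repression 3:1 as in typical
            # stress-response waves
            sign = -1.0 if bg_idx % 4 == 0 else 1.0
            cells[a:b] = sign
            if which + 1 < len(post_intervals):
                nlo, nhi = post_intervals[which + 1]
                na = int(round((nlo - times[0]) / dt))
                nb = int(round((nhi - times[0]) / dt))
                cells[na:nb] = -0.3 * sign
            rows[gene] = _integrate(cells, dt, sample_idx)
            stages[gene] = PRIMARY_RESPONSE if which == 0 else SECONDARY_RESPONSE

    for i in range(spec.n_inert):
        gene = f"inert_{i + 1}"
        rows[gene] = np.zeros(len(times))
        stages[gene] = SECONDARY_RESPONSE

    expr = pd.DataFrame.from_dict(rows, orient="index", columns=times)
    expr.index.name = "gene"
    # unit-variance scaling so noise_sd reads as a fraction of amplitude
    sd = expr.to_numpy().std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    expr = (expr - expr.to_numpy().mean(axis=1, keepdims=True)) / sd
    if spec.noise_sd > 0:
        expr = expr + rng.normal(0.0, spec.noise_sd, size=expr.shape)

    truth = CascadeTruth(
        edges=pd.DataFrame(
            edge_records,
            columns=["regulator", "target", "sign", "delay_steps", "delay_hours"],
        ),
        stages=pd.Series(stages, name="stage"),
        boundary_time=float(spec.initiation_end),
        delta_t=float(dt),
    )
    return expr, truth


def evaluate_recovery(truth: CascadeTruth, network: PredictedNetwork) -> dict:
    """Precision/recall of planted edges and sign accuracy on the recovered ones."""
    true_pairs = truth.edge_set()
    true_signs = {
        (r.regulator, r.target): int(r.sign) for r in truth.edges.itertuples()
    }
    predicted = network.edge_set()
    tp = predicted & true_pairs
    precision = len(tp) / len(predicted) if predicted else 1.0 if not true_pairs else 0.0
    recall = len(tp) / len(true_pairs) if true_pairs else 1.0
    signs_ok = sum(
        1 for e in network.edges
        if (e.regulator, e.target) in tp and e.sign == true_signs[(e.regulator, e.target)]
    )
    return {
        "precision": precision,
        "recall": recall,
        "sign_accuracy": signs_ok / len(tp) if tp else 1.0,
        "n_predicted": len(predicted),
        "n_true": len(true_pairs),
    }
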