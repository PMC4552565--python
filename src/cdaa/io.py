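"""Reading expression tables and gene lists; writing predicted networks.

Expression input is a CSV/TSV with one row per differentially expressed
gene: the first column carries the gene id, the remaining column headers
are sampling times in hours (a trailing unit token such as ``72hr`` is
tolerated).  Columns are reordered by time on read, so the caller never
depends on the file's column order.  Networks are written as TSV
(canonical, round-trippable), SIF or GraphML.
"""

from __future__ import annotations

import re
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .inference import PredictedNetwork

_TIME_LABEL = re.compile(r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*[a-zA-Z]*\s*$")

NETWORK_COLUMNS = [
    "regulator",
    "target",
    "sign",
    "delay_hours",
    "min_dissimilarity",
    "n_supporting_thresholds",
]


def parse_time_label(label) -> float:
    """Parse a column header like ``12``, ``12.0`` or ``72hr`` into hours."""
    m = _TIME_LABEL.match(str(label))
    if m is None:
        raise ValueError(f"cannot parse column header {label!r} as a time in hours")
    return float(m.group(1))


def validate_expression(x: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of an expression table.

    Gene ids unique, at least 2 genes, at least 4 strictly increasing
    time points (two stages of one interval each plus resolution for
    delays), no missing values.
    """
    if x.index.has_duplicates:
        dupes = sorted(set(x.index[x.index.duplicated()]))
        raise ValueError(f"duplicate gene ids: {', '.join(map(str, dupes))}")
    times = np.asarray([float(c) for c in x.columns])
    if len(times) < 4:
        raise ValueError(f"need at least 4 time points, got {len(times)}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sampling times must be strictly increasing and unique")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if x.isna().any().any():
        gene = x.index[x.isna().any(axis=1)][0]
        t = x.columns[x.isna().any(axis=0)][0]
        raise ValueError(f"missing value for gene {gene!r} at time {t}")
    return x


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if ";" in first and "," not in first:
        return ";"
    return ","


def read_expression(path, sep=None) -> pd.DataFrame:
    """Read a gene x time expression table.

    The first column is the gene id; the remaining headers are parsed as
    hours and the columns sorted by time.  Replicate columns sharing one
    time label are averaged with a warning, since the pipeline consumes
    a single value per gene per time point.
    """
    sep = sep or _sniff_sep(path)
    # header=None so pandas does not mangle replicate time labels
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                      skip_blank_lines=True)
    times = [parse_time_label(c) for c in raw.iloc[0, 1:]]
    body = raw.iloc[1:]
    values = body.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    non_numeric = values.isna() & body.iloc[:, 1:].notna()
    if non_numeric.any().any():
        raise ValueError(f"non-numeric expression values in {path}")
    frame = pd.DataFrame(
        values.to_numpy(dtype=float),
        index=pd.Index(body.iloc[:, 0].astype(str).str.strip(), name="gene"),
        columns=times,
    )
    if len(set(times)) < len(times):
        warnings.warn(
            "replicate columns share a time label; averaging them per time point",
            stacklevel=2,
        )
        frame = frame.T.groupby(level=0).mean().T
    frame = frame[sorted(frame.columns)]
    frame.columns = [float(c) for c in frame.columns]
    return validate_expression(frame)


def read_gene_list(path) -> pd.DataFrame:
    """Read a gene list: one id per line, or a CSV with id and is_tf columns.

    Returns a frame indexed by gene id with a boolean ``is_tf`` column
    (all True for a bare id list, which is the common case of a
    transcription-factor list).
    """
    sep = _sniff_sep(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([cell.strip() for cell in line.split(sep)])
    if not rows:
        raise ValueError(f"gene list {path} is empty")
    if rows[0][0].lower() in {"gene", "gene_id", "id"}:
        rows = rows[1:]
    ids = [r[0] for r in rows]
    seen, dupes = set(), []
    for g in ids:
        if g in seen:
            dupes.append(g)
        seen.add(g)
    if dupes:
        raise ValueError(
            f"duplicate gene ids in list: {', '.join(sorted(set(dupes)))}"
        )
    if all(len(r) >= 2 for r in rows) and rows:
        is_tf = [r[1].lower() in {"1", "true", "yes", "tf"} for r in rows]
    else:
        is_tf = [True] * len(rows)
    return pd.DataFrame({"is_tf": is_tf}, index=pd.Index(ids, name="gene"))


def write_network(network: PredictedNetwork, path, format: str = "tsv") -> None:
    """Serialize a predicted network as TSV (canonical), SIF or GraphML."""
    if format == "tsv":
        network.to_frame().to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for e in network.edges:
                verb = "activates" if e.sign > 0 else "represses"
                fh.write(f"{e.regulator}\t{verb}\t{e.target}\n")
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> PredictedNetwork:
    """Read a TSV network written by :func:`write_network`."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in NETWORK_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"network TSV lacks columns: {', '.join(missing)}")
    return PredictedNetwork.from_frame(frame)
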