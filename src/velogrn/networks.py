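"""Weight matrices, ranked edge lists, windowed and branch-aggregated GRNs.

A :class:`WeightMatrix` is the m x m signed edge-weight matrix an
inference method produces (entry (g1, g2) = strength of regulation
g1 -> g2), together with its per-interval decomposition so that dynamic,
per-window networks can be extracted.  The diagonal (self-loops) is
ignored by every consumer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "WeightMatrix",
    "threshold_edges",
    "window_grn",
    "aggregate_branches",
    "write_edge_list",
    "edge_list_to_graph",
]


@dataclass
class WeightMatrix:
    """Signed gene-gene edge weights with interval provenance.

    ``per_interval`` stores one summand per consecutive time interval
    (without any prefactor); ``intervals`` holds the (source, target) time
    labels.  For correlation-mode matrices the aggregate is the *mean* of
    the summands; for regression (Granger) mode it is their *sum*.
    """

    genes: list[str]
    matrix: np.ndarray
    method: Literal["corr", "granger"] = "corr"
    lag: int = 1
    per_interval: list[np.ndarray] | None = None
    intervals: list[tuple[float, float]] | None = None
    stimulus_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = len(self.genes)
        if self.matrix.shape != (m, m):
            raise ValueError(f"matrix must be {m}x{m}")
        if self.per_interval is not None:
            for A in self.per_interval:
                if A.shape != (m, m):
                    raise ValueError("per-interval matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.genes, columns=self.genes)


def _candidate_mask(W: WeightMatrix) -> np.ndarray:
    m = W.n_genes
    mask = ~np.eye(m, dtype=bool)
    if W.stimulus_flags is not None:
        mask &= ~W.stimulus_flags[None, :]  # no edges *into* stimulus genes
    return mask


def threshold_edges(
    W: WeightMatrix,
    threshold: float | None = None,
    top_fraction: float | None = None,
    top_k: int | None = None,
    window: str | None = None,
) -> pd.DataFrame:
    """Rank off-diagonal entries by |weight| into a signed edge list.

    Exactly one of ``threshold`` (keep |w| >= threshold > 0, or all
    nonzero when 0), ``top_fraction`` (keep the ceil(f * E) largest of the
    E candidate edges) or ``top_k`` may be given; with none given all
    nonzero edges are returned.  Ties in |weight| are broken
    lexicographically by (source, target) name so rankings are
    deterministic across platforms.
    """
    if sum(x is not None for x in (threshold, top_fraction, top_k)) > 1:
        raise ValueError("give at most one of threshold/top_fraction/top_k")
    mask = _candidate_mask(W)
    src, tgt = np.nonzero(mask)
    w = W.matrix[src, tgt]
    df = pd.DataFrame(
        {
            "source": [W.genes[i] for i in src],
            "target": [W.genes[j] for j in tgt],
            "weight": w,
        }
    )
    df["absw"] = df["weight"].abs()
    df = df.sort_values(
        ["absw", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)

    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
        keep = int(np.ceil(top_fraction * len(df)))
        df = df.iloc[:keep]
    elif top_k is not None:
        df = df.iloc[:top_k]
    tau = threshold if threshold is not None else 0.0
    df = df[(df["absw"] >= tau) & (df["absw"] > 0)]

    df = df.drop(columns="absw").reset_index(drop=True)
    df["sign"] = np.where(df["weight"] >= 0, "+", "-")
    df["rank"] = np.arange(1, len(df) + 1)
    if window is not None:
        df["window"] = window
    return df


def window_grn(W: WeightMatrix, t_start: float, t_end: float) -> WeightMatrix:
    """Restrict a weight matrix to intervals whose source time falls in
    the half-open window [t_start, t_end).

    Granger-mode windows sum the selected per-interval matrices; corr-mode
    windows average them (mirroring the aggregate's prefactor).  Two
    adjacent windows that partition the range therefore have granger sums
    adding exactly to the full-range sum.
    """
    if W.per_interval is None or W.intervals is None:
        raise ValueError("weight matrix has no per-interval decomposition")
    sel = [
        A
        for A, (src, _) in zip(W.per_interval, W.intervals)
        if t_start <= src < t_end
    ]
    if not sel:
        raise ValueError(f"window [{t_start}, {t_end}) overlaps no interval")
    agg = np.sum(sel, axis=0)
    if W.method == "corr":
        agg = agg / len(sel)
    return WeightMatrix(
        genes=list(W.genes),
        matrix=agg,
        method=W.method,
        lag=W.lag,
        per_interval=sel,
        intervals=[iv for iv in W.intervals if t_start <= iv[0] < t_end],
        stimulus_flags=W.stimulus_flags,
    )


def aggregate_branches(
    matrices: list[WeightMatrix], mode: Literal["sum", "maxabs"] = "sum"
) -> WeightMatrix:
    """Combine branch-specific weight matrices into one network.

    ``sum`` adds the matrices elementwise (the default for this method's
    own branch handling); ``maxabs`` keeps, per entry, the value of
    largest magnitude with its sign (the convention used to aggregate
    branch-specific graphs of other inference tools).
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    genes = matrices[0].genes
    for W in matrices[1:]:
        if W.genes != genes:
            raise ValueError("inconsistent gene sets across branches")
    stack = np.stack([W.matrix for W in matrices])
    if mode == "sum":
        agg = stack.sum(axis=0)
    elif mode == "maxabs":
        idx = np.abs(stack).argmax(axis=0)
        agg = np.take_along_axis(stack, idx[None, ...], axis=0)[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return WeightMatrix(
        genes=list(genes),
        matrix=agg,
        method=matrices[0].method,
        lag=matrices[0].lag,
        stimulus_flags=matrices[0].stimulus_flags,
    )


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def edge_list_to_graph(edges: pd.DataFrame):
    """Directed networkx graph with weight/sign attributes (for GraphML)."""
    import networkx as nx

    G = nx.DiGraph()
    for row in edges.itertuples(index=False):
        G.add_edge(row.source, row.target, weight=float(row.weight), sign=row.sign)
    return G
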