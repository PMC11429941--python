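"""Benchmarking inferred networks against a signed ground truth.

Predictions are the off-diagonal entries of a weight matrix ranked by
absolute value; the ground truth is a signed adjacency over the same
genes.  Reported metrics: AUPRC and AUROC (unsigned), their signed
variants (entries whose predicted sign contradicts the known sign are
zeroed before ranking), the AUPRC ratio (AUPRC over the random baseline,
i.e. the edge density), and early precision.

The PR curve is swept over every distinct score threshold with tied
scores grouped, and within a tie group predictions are included
*fractionally* (equivalently: the group's true and false positives
accrue proportionally, as under a randomised threshold).  The area is
the exact integral of precision over recall along this sweep.  Unlike
step-based or trapezoidal tie handling, this convention cannot reward
demoting a true edge into a tie group, so signed AUPRC <= unsigned
AUPRC holds; a constant score matrix scores exactly the ground-truth
density and a perfect ranking scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .networks import WeightMatrix

__all__ = [
    "GroundTruth",
    "auprc_auroc",
    "auprc_ratio",
    "early_precision",
    "evaluate_network",
]


@dataclass
class GroundTruth:
    """Signed adjacency over m genes: entries in {+1, -1, 0}, zero diagonal."""

    genes: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        m = len(self.genes)
        if self.adjacency.shape != (m, m):
            raise ValueError(f"adjacency must be {m}x{m}")
        if not np.isin(self.adjacency, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed in the ground truth")
        if not np.any(self.adjacency != 0):
            raise ValueError("ground truth has no edges")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    @property
    def density(self) -> float:
        m = len(self.genes)
        return self.n_edges / (m * (m - 1))

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame | str | Path, genes: list[str]) -> "GroundTruth":
        """Build from a table with columns source, target, sign (+1/-1)."""
        if isinstance(edges, (str, Path)):
            edges = pd.read_csv(edges, sep="\t")
        idx = {g: i for i, g in enumerate(genes)}
        adj = np.zeros((len(genes), len(genes)), dtype=int)
        for row in edges.itertuples(index=False):
            adj[idx[str(row.source)], idx[str(row.target)]] = int(np.sign(row.sign))
        return cls(genes=genes, adjacency=adj)

    def to_edge_list(self) -> pd.DataFrame:
        src, tgt = np.nonzero(self.adjacency)
        return pd.DataFrame(
            {
                "source": [self.genes[i] for i in src],
                "target": [self.genes[j] for j in tgt],
                "sign": self.adjacency[src, tgt],
            }
        )


# ---------------------------------------------------------------------------


def _pr_auc_tied(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUPRC with fractional (continuous-sweep) tie handling.

    Sweeping a fraction lam in [0, 1] through a tie group of g
    predictions containing t positives, entered with TP0 true and N0
    total predictions, traces precision (TP0 + lam t)/(N0 + lam g); its
    exact recall-integral over the group is
    t/g + (TP0 - (t/g) N0) log((N0 + g)/N0) / g.
    """
    order = np.argsort(scores)[::-1]
    s, y = scores[order], labels[order]
    P = y.sum()
    if P == 0:
        return float("nan")
    cut = np.nonzero(np.diff(s))[0]
    ends = np.append(cut, len(s) - 1)
    starts = np.concatenate([[0], ends[:-1] + 1])
    ap = 0.0
    TP0 = 0.0
    N0 = 0.0
    for a, b in zip(starts, ends):
        g = b - a + 1
        t = float(y[a : b + 1].sum())
        if t > 0:
            if N0 == 0:
                avg_precision = t / g
            else:
                avg_precision = t / g + (TP0 - t / g * N0) * np.log(
                    (N0 + g) / N0
                ) / g
            ap += (t / P) * avg_precision
        TP0 += t
        N0 += g
    return float(ap)


def _align(W: WeightMatrix, gt: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Restrict W to the ground-truth gene set (matching by name)."""
    if W.genes == gt.genes:
        return W.matrix.copy(), gt.adjacency
    idx = []
    pos = {g: i for i, g in enumerate(W.genes)}
    missing = [g for g in gt.genes if g not in pos]
    if missing:
        raise ValueError(f"ground-truth genes missing from weight matrix: {missing}")
    idx = np.array([pos[g] for g in gt.genes])
    return W.matrix[np.ix_(idx, idx)].copy(), gt.adjacency


def auprc_auroc(
    W: WeightMatrix, gt: GroundTruth, signed: bool = False
) -> dict[str, float]:
    """AUPRC/AUROC of the ranked off-diagonal weights against the truth.

    In signed mode, any entry whose sign contradicts a known interaction
    sign is zeroed before ranking (its |weight| no longer counts toward
    detecting that edge), so signed AUPRC <= unsigned AUPRC always.
    """
    M, adj = _align(W, gt)
    if signed:
        wrong = (adj != 0) & (np.sign(M) != adj) & (M != 0)
        M[wrong] = 0.0
    m = len(gt.genes)
    off = ~np.eye(m, dtype=bool)
    scores = np.abs(M[off])
    labels = (adj[off] != 0).astype(int)
    auprc = _pr_auc_tied(scores, labels)
    auroc = (
        float(roc_auc_score(labels, scores))
        if 0 < labels.sum() < len(labels)
        else float("nan")
    )
    return {"auprc": auprc, "auroc": auroc}


def auprc_ratio(auprc: float, gt: GroundTruth) -> float:
    """AUPRC over the random baseline (edge density); > 1 beats random."""
    return auprc / gt.density


def early_precision(W: WeightMatrix, gt: GroundTruth, k: int | None = None) -> float:
    """Precision of the top-k predicted edges (k = number of true edges by
    default); ties broken lexicographically by gene names."""
    from .networks import threshold_edges

    if k is None:
        k = gt.n_edges
    Wg = WeightMatrix(genes=gt.genes, matrix=_align(W, gt)[0])
    edges = threshold_edges(Wg, top_k=k)
    if len(edges) == 0:
        return 0.0
    idx = {g: i for i, g in enumerate(gt.genes)}
    hits = sum(
        gt.adjacency[idx[r.source], idx[r.target]] != 0
        for r in edges.itertuples(index=False)
    )
    return hits / len(edges)


def evaluate_network(W: WeightMatrix, gt: GroundTruth) -> dict[str, float]:
    """All benchmark metrics for one weight matrix: unsigned and signed
    AUPRC/AUROC, the corresponding AUPRC ratios, and early precision."""
    unsigned = auprc_auroc(W, gt, signed=False)
    signed = auprc_auroc(W, gt, signed=True)
    return {
        "auprc": unsigned["auprc"],
        "auroc": unsigned["auroc"],
        "auprc_signed": signed["auprc"],
        "auroc_signed": signed["auroc"],
        "auprc_ratio": auprc_ratio(unsigned["auprc"], gt),
        "auprc_ratio_signed": auprc_ratio(signed["auprc"], gt),
        "early_precision": early_precision(W, gt),
        "density": gt.density,
    }
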