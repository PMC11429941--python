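"""Time-stamped single-cell expression data model and preprocessing.

The central container is :class:`TimeSeriesDataset`: an ordered collection of
genes-by-cells expression matrices, one per observation time.  Matrices are
always oriented genes x cells (m x n(t)); readers transpose into this
orientation.  All downstream stages (optimal-transport coupling, velocity
estimation, network inference) consume this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesDataset",
    "load_dataset",
    "read_expression",
    "write_dataset",
    "read_dataset_dir",
    "log1p_transform",
    "normalize_total_counts",
    "top_variance_genes",
    "bin_pseudotime",
    "split_branches",
]


@dataclass
class TimeSeriesDataset:
    """Single-cell expression observed at N distinct time points.

    Parameters
    ----------
    gene_names : list of str
        m gene identifiers, shared (and identically ordered) across times.
    time_points : ndarray of float, shape (N,)
        Strictly increasing observation times, arbitrary units.
    expression : list of ndarray
        One m x n(t) matrix per time point (genes in rows, cells in columns).
    cell_ids : list of list of str
        Per time point, the n(t) cell identifiers (column labels).
    branch_labels : list of ndarray or None
        Optional per-cell categorical branch/lineage label, per time point.
    pseudotime : list of ndarray or None
        Optional per-cell pseudotime, per time point.
    stimulus_flags : ndarray of bool or None
        Optional per-gene flag marking artificial stimulus genes
        (predictor-only in network inference).
    transformed : bool
        True once log1p (or another variance-stabilising transform) has been
        applied; set by :func:`log1p_transform` and checked to prevent
        double transformation.
    """

    gene_names: list[str]
    time_points: np.ndarray
    expression: list[np.ndarray]
    cell_ids: list[list[str]]
    branch_labels: list[np.ndarray] | None = None
    pseudotime: list[np.ndarray] | None = None
    stimulus_flags: np.ndarray | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.expression = [np.asarray(X, dtype=float) for X in self.expression]
        m = len(self.gene_names)
        N = len(self.time_points)
        if N < 2:
            raise ValueError(f"need at least 2 time points, got {N}")
        if not (len(self.expression) == len(self.cell_ids) == N):
            raise ValueError("expression/cell_ids length must match time_points")
        if np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time_points must be strictly increasing")
        for k, (X, ids) in enumerate(zip(self.expression, self.cell_ids)):
            if X.ndim != 2 or X.shape[0] != m:
                raise ValueError(
                    f"expression[{k}] has shape {X.shape}, expected ({m}, n)"
                )
            if X.shape[1] < 1:
                raise ValueError(f"time point {k} has no cells")
            if X.shape[1] != len(ids):
                raise ValueError(f"cell_ids[{k}] length mismatch")
            if not np.all(np.isfinite(X)):
                raise ValueError(f"non-finite expression at time point {k}")
            if not self.transformed and np.any(X < 0):
                raise ValueError(f"negative counts at time point {k}")
        if self.stimulus_flags is not None:
            self.stimulus_flags = np.asarray(self.stimulus_flags, dtype=bool)
            if self.stimulus_flags.shape != (m,):
                raise ValueError("stimulus_flags must be per-gene")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    @property
    def n_cells(self) -> list[int]:
        return [X.shape[1] for X in self.expression]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TimeSeriesDataset(m={self.n_genes}, N={self.n_timepoints}, "
            f"n={self.n_cells}, transformed={self.transformed})"
        )


# ---------------------------------------------------------------------------
# loading


def read_expression(paths: Sequence[str | Path]) -> pd.DataFrame:
    """Read one or more genes x cells matrices and concatenate columns.

    Accepts delimited text (TSV/CSV, genes in rows, header row of cell ids)
    or MatrixMarket ``.mtx`` files accompanied by ``<stem>.rows.txt`` /
    ``<stem>.cols.txt`` name files.  All files must carry the same gene set;
    gene order is canonicalised to that of the first file.
    """
    frames = []
    for path in paths:
        path = Path(path)
        if path.suffix == ".mtx":
            from scipy.io import mmread

            M = mmread(path)
            if hasattr(M, "todense"):
                M = M.todense()
            genes = Path(str(path)[: -len(".mtx")] + ".rows.txt").read_text().split()
            cells = Path(str(path)[: -len(".mtx")] + ".cols.txt").read_text().split()
            df = pd.DataFrame(np.asarray(M), index=genes, columns=cells)
        else:
            sep = "," if path.suffix == ".csv" else "\t"
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
            df.index = df.index.astype(str)
            df.columns = df.columns.astype(str)
        frames.append(df)
    canonical = frames[0].index
    for i, df in enumerate(frames[1:], start=1):
        if set(df.index) != set(canonical):
            diff = sorted(set(df.index) ^ set(canonical))
            raise ValueError(
                f"inconsistent gene sets between {paths[0]} and {paths[i]}; "
                f"symmetric difference: {diff}"
            )
        frames[i] = df.loc[canonical]
    return pd.concat(frames, axis=1)


def _pivot_long(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format (gene, cell, count) table to genes x cells."""
    cols = {c.lower(): c for c in df.columns}
    for needed in ("gene", "cell", "count"):
        if needed not in cols:
            raise ValueError(f"long table must have a '{needed}' column")
    wide = df.pivot_table(
        index=cols["gene"], columns=cols["cell"], values=cols["count"],
        aggfunc="sum", fill_value=0.0,
    )
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    return wide


def load_dataset(
    source: pd.DataFrame | Sequence[str | Path] | str | Path,
    metadata: pd.DataFrame | str | Path,
) -> TimeSeriesDataset:
    """Assemble a :class:`TimeSeriesDataset` from expression + cell metadata.

    Parameters
    ----------
    source
        Either a genes x cells DataFrame, a path (or list of paths) to
        matrix files (TSV/CSV/MTX), or a long-format table with columns
        (gene, cell, count).
    metadata
        Table with columns ``cell_id``, ``time`` and optionally
        ``pseudotime`` and ``branch``.  Every matrix cell must appear here
        with a time label.

    Notes
    -----
    Cells are grouped by their time label and time points sorted ascending.
    Non-numeric time labels are replaced by their ranks 0..N-1 (downstream
    finite-difference weights need numeric gaps).
    """
    if isinstance(metadata, (str, Path)):
        p = Path(metadata)
        metadata = pd.read_csv(
            p, sep="," if p.suffix == ".csv" else "\t",
            float_precision="round_trip",
        )
    meta = metadata.copy()
    if "cell_id" not in meta.columns or "time" not in meta.columns:
        raise ValueError("metadata must have columns cell_id, time")
    meta["cell_id"] = meta["cell_id"].astype(str)
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell id in metadata: {dup!r}")
    if meta["time"].isna().any():
        bad = meta.loc[meta["time"].isna(), "cell_id"].iloc[0]
        raise ValueError(f"cell {bad!r} has no time label")

    if isinstance(source, (str, Path)):
        source = [source]
    if isinstance(source, pd.DataFrame):
        expr = source
        if {"gene", "cell", "count"} <= {c.lower() for c in expr.columns}:
            expr = _pivot_long(expr)
    else:
        expr = read_expression(source)

    matrix_cells = set(expr.columns)
    meta_cells = set(meta["cell_id"])
    missing_in_matrix = sorted(meta_cells - matrix_cells)
    if missing_in_matrix:
        raise ValueError(
            f"metadata cell {missing_in_matrix[0]!r} absent from expression matrix"
        )
    missing_label = sorted(matrix_cells - meta_cells)
    if missing_label:
        raise ValueError(f"cell {missing_label[0]!r} has no time label in metadata")

    # numeric times, or ranks for non-numeric labels
    try:
        times = pd.to_numeric(meta["time"])
    except (ValueError, TypeError):
        labels = pd.unique(meta["time"])
        rank = {lab: i for i, lab in enumerate(labels)}
        times = meta["time"].map(rank)
    meta = meta.assign(_t=np.asarray(times, dtype=float))

    time_values = np.sort(meta["_t"].unique())
    if len(time_values) < 2:
        raise ValueError(f"need at least 2 time points, got {len(time_values)}")

    expression, cell_ids, branches, pts = [], [], [], []
    has_branch = "branch" in meta.columns
    has_pt = "pseudotime" in meta.columns
    for t in time_values:
        sub = meta[meta["_t"] == t]
        ids = list(sub["cell_id"])
        expression.append(expr[ids].to_numpy(dtype=float))
        cell_ids.append(ids)
        if has_branch:
            branches.append(sub["branch"].to_numpy())
        if has_pt:
            pts.append(sub["pseudotime"].to_numpy(dtype=float))
    return TimeSeriesDataset(
        gene_names=[str(g) for g in expr.index],
        time_points=time_values,
        expression=expression,
        cell_ids=cell_ids,
        branch_labels=branches if has_branch else None,
        pseudotime=pts if has_pt else None,
    )


# ---------------------------------------------------------------------------
# writing


def write_dataset(ds: TimeSeriesDataset, outdir: str | Path) -> Path:
    """Write per-time TSV matrices, a metadata table and a JSON manifest.

    The written form round-trips bit-exactly through :func:`read_dataset_dir`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix_files = []
    for k in range(ds.n_timepoints):
        df = pd.DataFrame(
            ds.expression[k], index=ds.gene_names, columns=ds.cell_ids[k]
        )
        fname = f"expression_t{k}.tsv"
        df.to_csv(outdir / fname, sep="\t", float_format=None)
        matrix_files.append(fname)
    rows = []
    for k in range(ds.n_timepoints):
        for j, cid in enumerate(ds.cell_ids[k]):
            row = {"cell_id": cid, "time": repr(float(ds.time_points[k]))}
            if ds.pseudotime is not None:
                row["pseudotime"] = repr(float(ds.pseudotime[k][j]))
            if ds.branch_labels is not None:
                row["branch"] = ds.branch_labels[k][j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "metadata.csv", index=False)
    manifest = {
        "n_genes": ds.n_genes,
        "time_points": [float(t) for t in ds.time_points],
        "n_cells": ds.n_cells,
        "transformed": ds.transformed,
        "matrix_files": matrix_files,
        "stimulus_genes": (
            [g for g, f in zip(ds.gene_names, ds.stimulus_flags) if f]
            if ds.stimulus_flags is not None
            else []
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_dataset_dir(path: str | Path) -> TimeSeriesDataset:
    """Load a dataset written by :func:`write_dataset`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    ds = load_dataset(
        [path / f for f in manifest["matrix_files"]], path / "metadata.csv"
    )
    ds.transformed = manifest.get("transformed", False)
    stim = manifest.get("stimulus_genes", [])
    if stim:
        ds.stimulus_flags = np.array([g in stim for g in ds.gene_names])
    return ds


# ---------------------------------------------------------------------------
# preprocessing


def log1p_transform(ds: TimeSeriesDataset) -> TimeSeriesDataset:
    """Apply the conventional log(x+1) transform to every entry.

    Rejects data that is already transformed or contains negative entries.
    """
    if ds.transformed:
        raise ValueError("dataset is already log-transformed")
    for k, X in enumerate(ds.expression):
        if np.any(X < 0):
            raise ValueError(
                f"negative entry at time point {k}: data already transformed "
                "or corrupt"
            )
    return replace(
        ds, expression=[np.log1p(X) for X in ds.expression], transformed=True
    )


def normalize_total_counts(
    ds: TimeSeriesDataset, target_sum: float | None = None
) -> TimeSeriesDataset:
    """Scale each cell by its total count (optional, pre-log; default off
    in the pipeline).

    Each cell's counts are divided by the cell total and multiplied by
    ``target_sum`` (median total over all cells if None).
    """
    if ds.transformed:
        raise ValueError("normalize counts before log transformation")
    totals = np.concatenate([X.sum(axis=0) for X in ds.expression])
    if target_sum is None:
        target_sum = float(np.median(totals[totals > 0]))
    out = []
    for X in ds.expression:
        t = X.sum(axis=0)
        t[t == 0] = 1.0
        out.append(X / t * target_sum)
    return replace(ds, expression=out)


def top_variance_genes(ds: TimeSeriesDataset, k: int) -> TimeSeriesDataset:
    """Convenience filter: keep the k genes with highest pooled variance."""
    pooled = np.concatenate(ds.expression, axis=1)
    var = pooled.var(axis=1)
    keep = np.sort(np.argsort(var)[::-1][:k])
    return replace(
        ds,
        gene_names=[ds.gene_names[i] for i in keep],
        expression=[X[keep] for X in ds.expression],
        stimulus_flags=None if ds.stimulus_flags is None else ds.stimulus_flags[keep],
    )


# ---------------------------------------------------------------------------
# pseudotime binning and branches


def bin_pseudotime(ds: TimeSeriesDataset, n_bins: int) -> TimeSeriesDataset:
    """Re-time a dataset by quantile-binning its per-cell pseudotimes.

    Cells are pooled over the original time labels, assigned to ``n_bins``
    quantile bins of pseudotime, and the bin index (0..n_bins-1) becomes the
    new time stamp.  Ties exactly at a quantile edge go to the lower bin
    (left-closed convention).  Quantile binning of n*k uniformly spaced
    values into k bins yields exactly n cells per bin.
    """
    if ds.pseudotime is None:
        raise ValueError("dataset has no pseudotime annotations")
    pt = np.concatenate(ds.pseudotime)
    if not np.all(np.isfinite(pt)):
        raise ValueError("non-finite pseudotime")
    if len(np.unique(pt)) < n_bins:
        raise ValueError(
            f"fewer distinct pseudotime values ({len(np.unique(pt))}) than "
            f"bins ({n_bins})"
        )
    edges = np.quantile(pt, np.arange(1, n_bins) / n_bins)
    bins = np.searchsorted(edges, pt, side="left")

    X = np.concatenate(ds.expression, axis=1)
    ids = [c for sub in ds.cell_ids for c in sub]
    br = (
        np.concatenate(ds.branch_labels) if ds.branch_labels is not None else None
    )
    expression, cell_ids, branches, pts = [], [], [], []
    for b in range(n_bins):
        mask = bins == b
        expression.append(X[:, mask])
        cell_ids.append([i for i, m_ in zip(ids, mask) if m_])
        if br is not None:
            branches.append(br[mask])
        pts.append(pt[mask])
    return TimeSeriesDataset(
        gene_names=list(ds.gene_names),
        time_points=np.arange(n_bins, dtype=float),
        expression=expression,
        cell_ids=cell_ids,
        branch_labels=branches if br is not None else None,
        pseudotime=pts,
        stimulus_flags=ds.stimulus_flags,
        transformed=ds.transformed,
    )


def split_branches(ds: TimeSeriesDataset) -> dict[str, TimeSeriesDataset]:
    """Split a branch-labelled dataset into one dataset per branch.

    Time points with no cells of a branch are dropped for that branch; a
    branch observed at fewer than 2 time points is rejected.
    """
    if ds.branch_labels is None:
        raise ValueError("dataset has no branch labels")
    labels = sorted({str(b) for arr in ds.branch_labels for b in arr})
    out: dict[str, TimeSeriesDataset] = {}
    for lab in labels:
        expression, cell_ids, tps, pts = [], [], [], []
        for k in range(ds.n_timepoints):
            mask = np.asarray([str(b) == lab for b in ds.branch_labels[k]])
            if mask.sum() == 0:
                continue
            expression.append(ds.expression[k][:, mask])
            cell_ids.append([c for c, m_ in zip(ds.cell_ids[k], mask) if m_])
            tps.append(ds.time_points[k])
            if ds.pseudotime is not None:
                pts.append(ds.pseudotime[k][mask])
        if len(tps) < 2:
            raise ValueError(f"branch {lab!r} observed at fewer than 2 time points")
        out[lab] = TimeSeriesDataset(
            gene_names=list(ds.gene_names),
            time_points=np.asarray(tps),
            expression=expression,
            cell_ids=cell_ids,
            pseudotime=pts if ds.pseudotime is not None else None,
            stimulus_flags=ds.stimulus_flags,
            transformed=ds.transformed,
        )
    return out
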