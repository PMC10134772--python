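"""Snapshot datasets and population moments.

Cytometry is destructive, so single cells cannot be tracked between time
points; only population summaries are comparable across snapshots.  The
summaries used here are the per-species mean and the (biased, 1/N) sample
covariance

    mu_i(t) = (1/N) sum_a x_i^(a)(t)
    J_ij(t) = (1/N) sum_a (x_i^(a) - mu_i)(x_j^(a) - mu_j)

The 1/N normalization is deliberate: the fitting cost compares model
covariances against this estimator, and mixing 1/N with 1/(N-1)
conventions would bias the scale.

No arcsinh or other cytometry transform is applied by default — the model
is fit on raw abundances.  An optional ``transform`` hook on
:func:`read_snapshot` is available for users who want one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .kinetics import CellStateMatrix, SpeciesPanel, ValidationError

__all__ = ["SnapshotDataset", "MomentSummary", "read_snapshot", "compute_moments"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnapshotDataset:
    """Cells x species abundances at a single time stamp."""

    cells: CellStateMatrix
    panel: SpeciesPanel
    label: str = ""

    def __post_init__(self):
        if self.cells.x.shape[1] != self.panel.p:
            raise ValidationError(
                f"cell matrix has {self.cells.x.shape[1]} columns, "
                f"panel has {self.panel.p} species"
            )
        if not np.all(np.isfinite(self.cells.x)):
            raise ValidationError("snapshot contains non-finite values")

    @property
    def time(self) -> float:
        return self.cells.time

    @property
    def n_cells(self) -> int:
        return self.cells.n_cells

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.cells.x, columns=self.panel.names).to_csv(path, index=False)


@dataclass(frozen=True)
class MomentSummary:
    """Mean vector, 1/N covariance matrix, cell count and time stamp."""

    mu: np.ndarray
    J: np.ndarray
    n_cells: int
    time: float

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float).ravel()
        J = np.asarray(self.J, dtype=float)
        p = mu.shape[0]
        if J.shape != (p, p):
            raise ValidationError(f"J has shape {J.shape}, mu has length {p}")
        if not np.allclose(J, J.T, rtol=0.0, atol=1e-8 * max(1.0, float(np.abs(J).max(initial=0.0)))):
            raise ValidationError("covariance matrix is not symmetric")
        J = 0.5 * (J + J.T)
        if np.any(np.diag(J) < -1e-12 * max(1.0, float(np.abs(J).max(initial=0.0)))):
            raise ValidationError("covariance diagonal must be >= 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "J", J)

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    def to_csv(self, path: str | Path, panel: SpeciesPanel | None = None) -> None:
        """Export as CSV: one 'mean' row followed by the labeled J block."""
        names = list(panel.names) if panel is not None else [f"x{i}" for i in range(self.p)]
        rows = [["mean", *self.mu.tolist()]]
        for i, name in enumerate(names):
            rows.append([f"J:{name}", *self.J[i].tolist()])
        df = pd.DataFrame(rows, columns=["row", *names])
        df.to_csv(path, index=False)


def read_snapshot(
    path: str | Path,
    time: float,
    format: str | None = None,
    channel_map: Mapping[str, str] | None = None,
    label: str = "",
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SnapshotDataset:
    """Load one snapshot from a CSV or FCS file.

    Parameters
    ----------
    path:
        File to read.  CSV files have a header row of species names and one
        row per cell; FCS 3.0/3.1 list-mode files are read with the
        built-in parser.
    time:
        Acquisition time stamp in seconds (snapshot files carry no
        reliable time metadata).
    format:
        ``"csv"`` or ``"fcs"``; inferred from the suffix when omitted.
    channel_map:
        Optional ``{file_channel: panel_name}`` selection/rename map.  When
        given, only the mapped channels are kept, in the map's order.
    transform:
        Optional elementwise pre-transform (e.g. ``np.arcsinh``); off by
        default — the model fits raw abundances.

    Rows containing non-finite values are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"snapshot file not found: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError(f"empty snapshot file: {path}")
        df.columns = [str(c) for c in df.columns]
    elif format == "fcs":
        from .fcs import read_fcs

        df = read_fcs(path)
    else:
        raise ValidationError(f"unknown snapshot format {format!r}")

    if channel_map is not None:
        missing = [c for c in channel_map if c not in df.columns]
        if missing:
            raise ValidationError(
                f"channel(s) {missing} not present in {path.name}; "
                f"available channels: {list(df.columns)}"
            )
        df = df[list(channel_map)].rename(columns=dict(channel_map))

    x = df.to_numpy(dtype=float)
    finite = np.all(np.isfinite(x), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropped %d/%d rows with non-finite values from %s",
                    n_dropped, x.shape[0], path.name)
        x = x[finite]
    if x.shape[0] == 0:
        raise ValidationError(f"no valid rows left after filtering {path}")
    if transform is not None:
        x = np.asarray(transform(x), dtype=float)
    panel = SpeciesPanel(df.columns)
    return SnapshotDataset(CellStateMatrix(x, time=time), panel, label=label or path.name)


def compute_moments(ds: SnapshotDataset) -> MomentSummary:
    """Mean and 1/N covariance of a snapshot (requires >= 2 cells)."""
    x = ds.cells.x
    n = x.shape[0]
    if n < 2:
        raise ValidationError(f"need >= 2 cells to compute moments, got {n}")
    mu = x.mean(axis=0)
    d = x - mu
    J = (d.T @ d) / n
    J = 0.5 * (J + J.T)
    return MomentSummary(mu=mu, J=J, n_cells=n, time=ds.time)
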