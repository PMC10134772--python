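"""First-order reaction kinetics on a measured protein panel.

A signaling process over ``p`` measured species is approximated by linear
mass-action kinetics ``dx/dt = M x``, where the rate matrix ``M`` collects
directed first-order rates ``k_{i->j} >= 0`` (conversion of species i into
species j) off the diagonal and signed self-rates ``k_{i->i}`` (self
production from unmeasured species when positive, decay when negative) on
the diagonal:

    M[j, i] = k_{i->j}          (i != j)
    M[i, i] = k_{i->i} - sum_{j != i} k_{i->j}

With this convention every column of ``M`` sums to ``k_{i->i}``, so a model
with no self-rates conserves total abundance.  The linear system has the
closed form ``x(t2) = exp(M (t2 - t1)) x(t1)``, which is what makes fitting
snapshot moments tractable: means propagate as ``mu(t2) = E mu(t1)`` and
covariances as ``J(t2) = E J(t1) E^T`` with ``E = exp(M dt)``.

Matrix exponentials are evaluated with the scaling-and-squaring Pade
approximation (``scipy.linalg.expm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm as _pade_expm

__all__ = [
    "SpeciesPanel",
    "KineticRates",
    "RateMatrix",
    "CellStateMatrix",
    "build_rate_matrix",
    "matrix_exponential",
    "propagate_cells",
    "propagate_moments",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent panel / rate / architecture configuration."""


class ValidationError(ValueError):
    """Raised for numerically invalid inputs (negative rates, NaNs, shape)."""


@dataclass(frozen=True)
class SpeciesPanel:
    """Ordered panel of measured species; defines the dimension p everywhere."""

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        names = tuple(names)
        if len(names) == 0:
            raise ConfigurationError("panel must contain at least one species")
        if any(not n for n in names):
            raise ConfigurationError("species names must be non-empty")
        if len(set(names)) != len(names):
            raise ConfigurationError(f"species names must be unique, got {names}")
        object.__setattr__(self, "names", names)

    @property
    def p(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"unknown species {name!r}; panel is {list(self.names)}"
            ) from None

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class KineticRates:
    """Sparse first-order rates: directed k_{i->j} >= 0 and signed self-rates.

    Absent entries mean a rate of exactly zero.
    """

    off_diagonal: Mapping[tuple[str, str], float] = field(default_factory=dict)
    self_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for (i, j), k in self.off_diagonal.items():
            if i == j:
                raise ConfigurationError(
                    f"self-rate {i!r} must go in self_rates, not off_diagonal"
                )
            if k < 0:
                raise ValidationError(f"rate k[{i}->{j}] = {k} must be >= 0")


@dataclass(frozen=True)
class RateMatrix:
    """Dense p x p rate matrix M with its species panel (units 1/s)."""

    M: np.ndarray
    panel: SpeciesPanel

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.shape != (self.panel.p, self.panel.p):
            raise ValidationError(
                f"M has shape {M.shape}, panel has p = {self.panel.p}"
            )
        if not np.all(np.isfinite(M)):
            raise ValidationError("M contains non-finite entries")
        off = M[~np.eye(self.panel.p, dtype=bool)]
        if np.any(off < 0):
            raise ValidationError("off-diagonal entries of M must be >= 0")
        object.__setattr__(self, "M", M)

    @property
    def p(self) -> int:
        return self.panel.p

    def rate(self, source: str, target: str) -> float:
        """The directed rate k_{source->target} (or the self-rate if equal)."""
        i = self.panel.index(source)
        j = self.panel.index(target)
        if i == j:
            # column i sums to k_{i->i}: the diagonal absorbs minus the outflow
            return float(self.M[:, i].sum())
        return float(self.M[j, i])

    def column_sums(self) -> np.ndarray:
        return self.M.sum(axis=0)

    def to_rates(self) -> KineticRates:
        """Invert the M construction back to the sparse rate map (lossless)."""
        names = self.panel.names
        off: dict[tuple[str, str], float] = {}
        self_r: dict[str, float] = {}
        for i, src in enumerate(names):
            outflow = 0.0
            for j, tgt in enumerate(names):
                if i == j:
                    continue
                k = self.M[j, i]
                if k != 0.0:
                    off[(src, tgt)] = float(k)
                outflow += k
            kii = self.M[i, i] + outflow
            if kii != 0.0:
                self_r[src] = float(kii)
        return KineticRates(off_diagonal=off, self_rates=self_r)

    def to_csv(self, path: str | Path) -> None:
        """Write M as a labeled CSV grid (species names as header and index)."""
        pd.DataFrame(self.M, index=self.panel.names, columns=self.panel.names).to_csv(
            path, index_label="species"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RateMatrix":
        df = pd.read_csv(path, index_col=0)
        panel = SpeciesPanel(df.columns)
        if tuple(df.index) != panel.names:
            raise ValidationError(f"row/column labels disagree in {path}")
        return cls(df.to_numpy(dtype=float), panel)


@dataclass(frozen=True)
class CellStateMatrix:
    """Per-cell abundances (N_cells x p) at one time point (seconds)."""

    x: np.ndarray
    time: float

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValidationError(f"cell matrix must be 2-D with >= 1 row, got {x.shape}")
        object.__setattr__(self, "x", x)

    @property
    def n_cells(self) -> int:
        return self.x.shape[0]


def build_rate_matrix(rates: KineticRates, panel: SpeciesPanel) -> RateMatrix:
    """Assemble M from sparse directed rates.

    ``M[j, i] = k_{i->j}`` for i != j and
    ``M[i, i] = k_{i->i} - sum_{j != i} k_{i->j}``; the inverse mapping
    (:meth:`RateMatrix.to_rates`) recovers the input exactly.
    """
    p = panel.p
    M = np.zeros((p, p))
    for (src, tgt), k in rates.off_diagonal.items():
        i = panel.index(src)
        j = panel.index(tgt)
        M[j, i] += k
        M[i, i] -= k
    for name, kii in rates.self_rates.items():
        i = panel.index(name)
        M[i, i] += kii
    return RateMatrix(M, panel)


def matrix_exponential(M: RateMatrix | np.ndarray, dt: float) -> np.ndarray:
    """exp(M * dt) via scaling-and-squaring Pade approximation.

    ``dt`` is in seconds and must be >= 0.
    """
    A = M.M if isinstance(M, RateMatrix) else np.asarray(M, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValidationError("rate matrix contains non-finite entries")
    if dt < 0:
        raise ValidationError(f"dt must be >= 0, got {dt}")
    if dt == 0:
        return np.eye(A.shape[0])
    return _pade_expm(A * dt)


def propagate_cells(x1: CellStateMatrix, M: RateMatrix, dt: float) -> CellStateMatrix:
    """Propagate every cell's state vector forward by dt seconds.

    Row alpha of the output is exp(M dt) applied to row alpha of the input;
    cell identity is preserved.  No positivity clipping is applied — the
    linear model offers no positivity guarantee.
    """
    if x1.x.shape[1] != M.p:
        raise ValidationError(
            f"cells have {x1.x.shape[1]} species, rate matrix has {M.p}"
        )
    E = matrix_exponential(M, dt)
    return CellStateMatrix(x1.x @ E.T, time=x1.time + dt)


def propagate_moments(m1, M: RateMatrix, dt: float):
    """Propagate a moment summary (mean vector and covariance) by dt seconds.

    mu(t2) = E mu(t1) and J(t2) = E J(t1) E^T with E = exp(M dt).  The
    output covariance is symmetrized against floating-point drift, which
    preserves positive semidefiniteness.
    """
    from .moments import MomentSummary  # local import to avoid a cycle

    if m1.mu.shape[0] != M.p:
        raise ValidationError(f"moments have p = {m1.mu.shape[0]}, M has p = {M.p}")
    E = matrix_exponential(M, dt)
    mu2 = E @ m1.mu
    J2 = E @ m1.J @ E.T
    J2 = 0.5 * (J2 + J2.T)
    return MomentSummary(mu=mu2, J=J2, n_cells=m1.n_cells, time=m1.time + dt)
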