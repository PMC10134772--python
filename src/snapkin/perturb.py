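"""In silico perturbation experiments and candidate-model predictions.

A perturbation multiplies one species' initial abundance by a factor in
every cell (e.g. x2 or x1/2), mimicking drug or siRNA interventions.  The
readout is the net change in mean abundance over the fit window,

    dmu_X(t1, t2) = mu_X(t2) - mu_X(t1),

whose sign encodes net production (> 0) versus consumption (< 0).

The screening protocol mirrors how such fits are used: candidate models
are fit once on UNPERTURBED data, then the fixed best-fit matrix predicts
the perturbed outcome by propagating the perturbed t1 moments.  Scaling a
species' initial value by f in every cell multiplies its mean by f and
its row and column of the covariance by f, so the perturbed t1 moments
are exact, not resampled.  Ground-truth outcomes are resimulated from the
scaled initial cells.

A prediction counts as qualitatively accurate when its dmu falls in the
same sign class as the truth, where a dead zone |dmu| < 1% of mu(t1)
maps to the "~0" class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .kinetics import (
    CellStateMatrix,
    ConfigurationError,
    RateMatrix,
    SpeciesPanel,
    ValidationError,
    propagate_moments,
)
from .moments import MomentSummary, SnapshotDataset, compute_moments
from .simulate import LognormalSpec, MassActionModel, simulate_mass_action

__all__ = [
    "PerturbationSpec",
    "DeltaMuTable",
    "apply_perturbation",
    "delta_mu",
    "perturbation_study",
]

#: |dmu| below this fraction of mu(t1) is classified as "~0"
DEAD_ZONE_FRACTION = 0.01


@dataclass(frozen=True)
class PerturbationSpec:
    """Multiply one species' initial abundance by ``factor`` in every cell."""

    species: str
    factor: float

    def __post_init__(self):
        if self.factor <= 0:
            raise ValidationError(f"factor must be > 0, got {self.factor}")

    @property
    def label(self) -> str:
        return f"{self.species}x{self.factor:g}"


def apply_perturbation(
    x0: np.ndarray | CellStateMatrix,
    panel: SpeciesPanel,
    perturbation: PerturbationSpec,
) -> np.ndarray:
    """Scaled copy of the initial conditions; all other species untouched.

    ``panel`` must be the full simulator species set (perturbations may
    target species that are not in the measured panel).
    """
    x = x0.x if isinstance(x0, CellStateMatrix) else np.asarray(x0, dtype=float)
    j = panel.index(perturbation.species)  # raises ConfigurationError if unknown
    out = x.copy()
    out[:, j] *= perturbation.factor
    return out


def delta_mu(m1: MomentSummary, m2: MomentSummary) -> np.ndarray:
    """Elementwise mu(t2) - mu(t1), in panel order."""
    if m1.p != m2.p:
        raise ValidationError(f"moment dimensions differ: {m1.p} vs {m2.p}")
    return m2.mu - m1.mu


def _sign_class(dmu: float, mu_t1: float, dead_zone_frac: float) -> str:
    if abs(dmu) < dead_zone_frac * abs(mu_t1):
        return "0"
    return "+" if dmu > 0 else "-"


def _perturbed_moments(m1: MomentSummary, j: int | None, factor: float) -> MomentSummary:
    """Scale species j of the t1 moments by ``factor`` (exact per-cell scaling)."""
    if j is None or factor == 1.0:
        return m1
    mu = m1.mu.copy()
    J = m1.J.copy()
    mu[j] *= factor
    J[j, :] *= factor
    J[:, j] *= factor
    return MomentSummary(mu=mu, J=J, n_cells=m1.n_cells, time=m1.time)


@dataclass(frozen=True)
class DeltaMuTable:
    """Long-format perturbation results plus per-(condition, model) scores.

    ``table`` columns: condition, model, species, delta_mu, sign_class,
    sign_agrees, squared_distance (the squared distance between the
    candidate's and the truth's dmu vectors, repeated across the
    condition's rows; NaN for the truth rows).
    """

    table: pd.DataFrame
    dead_zone_frac: float = DEAD_ZONE_FRACTION

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def dmu(self, condition: str, model: str) -> pd.Series:
        sub = self.table[
            (self.table.condition == condition) & (self.table.model == model)
        ]
        return sub.set_index("species")["delta_mu"]

    def sign_agrees(self, condition: str, model: str, species: str) -> bool:
        sub = self.table[
            (self.table.condition == condition)
            & (self.table.model == model)
            & (self.table.species == species)
        ]
        return bool(sub["sign_agrees"].iloc[0])

    def squared_distance(self, condition: str, model: str) -> float:
        sub = self.table[
            (self.table.condition == condition) & (self.table.model == model)
        ]
        return float(sub["squared_distance"].iloc[0])

    def monotone_agrees(self, model: str, species: str, conditions: Sequence[str]) -> bool:
        """Does dmu_species move with the factor the same way as in truth?

        ``conditions`` must be ordered by increasing perturbation factor.
        """
        truth = [self.dmu(c, "truth")[species] for c in conditions]
        cand = [self.dmu(c, model)[species] for c in conditions]
        t = np.sign(np.diff(truth))
        c = np.sign(np.diff(cand))
        return bool(np.all(t == c))


def perturbation_study(
    truth: MassActionModel | RateMatrix,
    candidates: Mapping[str, FitResult],
    perturbations: Sequence[PerturbationSpec],
    times: Sequence[float] = (0.0, 30.0),
    n_cells: int = 250,
    lognormal: LognormalSpec | None = None,
    seed: int = 0,
    measured_panel: SpeciesPanel | None = None,
    dead_zone_frac: float = DEAD_ZONE_FRACTION,
) -> DeltaMuTable:
    """Compare ground-truth and candidate dmu predictions under perturbations.

    The candidates must have been fit on the unperturbed data; their fixed
    fitted matrices predict each perturbed outcome from the perturbed t1
    moments.  The ground truth is resimulated per condition from the
    scaled initial cells.
    """
    if len(times) != 2 or times[1] <= times[0]:
        raise ValidationError(f"times must be (t1, t2) with t2 > t1, got {times}")
    full_panel = truth.species if isinstance(truth, MassActionModel) else truth.panel
    if measured_panel is None:
        measured_panel = full_panel
    if lognormal is None:
        lognormal = LognormalSpec.uniform(full_panel.names)
    rng = np.random.default_rng(seed)
    x0 = lognormal.draw(full_panel, n_cells, rng)
    dt = float(times[1]) - float(times[0])
    meas_idx = [full_panel.index(n) for n in measured_panel.names]

    def truth_moments(x_init: np.ndarray) -> tuple[MomentSummary, MomentSummary]:
        if isinstance(truth, MassActionModel):
            run = simulate_mass_action(
                truth, n_cells=n_cells, times=times, seed=seed,
                measured_panel=measured_panel, initial_state=x_init,
                lognormal=lognormal,
            )
            return (
                compute_moments(run.snapshots[0]),
                compute_moments(run.snapshots[1]),
            )
        ds1 = SnapshotDataset(
            CellStateMatrix(x_init[:, meas_idx], time=float(times[0])), measured_panel
        )
        from .kinetics import propagate_cells

        ds2 = SnapshotDataset(
            propagate_cells(ds1.cells, truth, dt), measured_panel
        )
        return compute_moments(ds1), compute_moments(ds2)

    conditions: list[tuple[str, PerturbationSpec | None]] = [("baseline", None)]
    conditions += [(p.label, p) for p in perturbations]

    rows = []
    for label, pert in conditions:
        x_init = x0 if pert is None else apply_perturbation(x0, full_panel, pert)
        m1t, m2t = truth_moments(x_init)
        dmu_truth = delta_mu(m1t, m2t)
        truth_classes = [
            _sign_class(dmu_truth[k], m1t.mu[k], dead_zone_frac)
            for k in range(measured_panel.p)
        ]
        for k, sp in enumerate(measured_panel.names):
            rows.append(
                dict(condition=label, model="truth", species=sp,
                     delta_mu=dmu_truth[k], sign_class=truth_classes[k],
                     sign_agrees=True, squared_distance=np.nan)
            )
        # candidate prediction: perturbed t1 moments under the fixed fitted M
        pert_idx = None
        factor = 1.0
        if pert is not None and pert.species in measured_panel.names:
            pert_idx = measured_panel.index(pert.species)
            factor = pert.factor
        for name, fit_result in candidates.items():
            if fit_result.M.p != measured_panel.p:
                raise ConfigurationError(
                    f"candidate {name!r} was fit on a different panel"
                )
            m1c = _perturbed_moments(
                compute_moments(
                    SnapshotDataset(
                        CellStateMatrix(x0[:, meas_idx], time=float(times[0])),
                        measured_panel,
                    )
                ),
                pert_idx,
                factor,
            )
            m2c = propagate_moments(m1c, fit_result.M, dt)
            dmu_c = delta_mu(m1c, m2c)
            sq = float(np.sum((dmu_c - dmu_truth) ** 2))
            for k, sp in enumerate(measured_panel.names):
                cls = _sign_class(dmu_c[k], m1c.mu[k], dead_zone_frac)
                rows.append(
                    dict(condition=label, model=name, species=sp,
                         delta_mu=dmu_c[k], sign_class=cls,
                         sign_agrees=(cls == truth_classes[k]),
                         squared_distance=sq)
                )
    return DeltaMuTable(pd.DataFrame(rows), dead_zone_frac=dead_zone_frac)
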