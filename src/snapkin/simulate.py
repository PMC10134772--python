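"""Synthetic single-cell snapshot generators.

Two families of ground truth are provided:

* first-order chains ``X1 -> X2 -> ... -> Xp`` whose per-cell kinetics are
  propagated exactly with the closed-form matrix exponential, and
* nonlinear mass-action models (notably the second-order ground truths
  GT1: A + B -> C and GT2: A + B <-> C) integrated per cell as
  deterministic ODEs.

Cell-to-cell variation enters through lognormal initial abundances; rate
constants are shared across cells.  Snapshots keep cells in the same
order at every time point — the generator knows cell identity even though
a real destructive cytometry measurement would not — which is what makes
exact oracle checks (moment propagation vs explicit cell propagation)
possible.

Only the ``measured_panel`` columns are exported in snapshots, mimicking
experiments where most species of the underlying network are unmeasured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .architecture import NetworkArchitecture
from .kinetics import (
    CellStateMatrix,
    ConfigurationError,
    KineticRates,
    SpeciesPanel,
    ValidationError,
    build_rate_matrix,
    matrix_exponential,
)
from .moments import SnapshotDataset

__all__ = [
    "LognormalSpec",
    "MassActionModel",
    "Reaction",
    "SimulationRun",
    "simulate_chain",
    "simulate_mass_action",
    "builtin_models",
    "builtin_candidates",
]

#: default lognormal for fixture abundances: median 100, sdlog 0.5
DEFAULT_MEANLOG = float(np.log(100.0))
DEFAULT_SDLOG = 0.5
#: default second-order rate constant (per abundance-unit per second):
#: moderate, non-saturating conversion over a 30 s window at abundances ~100
DEFAULT_BIMOLECULAR_RATE = 1e-4


@dataclass(frozen=True)
class LognormalSpec:
    """Per-species (meanlog, sdlog) pairs, natural-log parameterization."""

    params: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for name, (m, s) in self.params.items():
            if s < 0:
                raise ValidationError(f"sdlog for {name!r} must be >= 0, got {s}")

    @classmethod
    def uniform(
        cls,
        names: Sequence[str],
        meanlog: float = DEFAULT_MEANLOG,
        sdlog: float = DEFAULT_SDLOG,
    ) -> "LognormalSpec":
        return cls({n: (meanlog, sdlog) for n in names})

    def draw(
        self, panel: SpeciesPanel, n_cells: int, rng: np.random.Generator
    ) -> np.ndarray:
        x = np.empty((n_cells, panel.p))
        for j, name in enumerate(panel.names):
            if name not in self.params:
                raise ConfigurationError(
                    f"no lognormal parameters for species {name!r}"
                )
            m, s = self.params[name]
            x[:, j] = rng.lognormal(mean=m, sigma=s, size=n_cells)
        return x


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction with integer stoichiometry."""

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: float
    reverse_rate: float | None = None  # set for reversible reactions

    def __post_init__(self):
        for side in (self.reactants, self.products):
            for sp, nu in side.items():
                if nu < 0 or int(nu) != nu:
                    raise ValidationError(
                        f"stoichiometry for {sp!r} must be a non-negative integer"
                    )
        if self.rate < 0:
            raise ValidationError(f"rate must be >= 0, got {self.rate}")
        if self.reverse_rate is not None and self.reverse_rate < 0:
            raise ValidationError("reverse rate must be >= 0")

    @property
    def reversible(self) -> bool:
        return self.reverse_rate is not None


@dataclass(frozen=True)
class MassActionModel:
    """A deterministic mass-action reaction network over named species."""

    species: SpeciesPanel
    reactions: tuple[Reaction, ...]
    name: str = ""

    def __post_init__(self):
        if len(self.reactions) == 0:
            raise ValidationError("model needs at least one reaction")
        for r in self.reactions:
            for sp in (*r.reactants, *r.products):
                self.species.index(sp)  # raises on unknown species
        object.__setattr__(self, "reactions", tuple(self.reactions))

    def _elementary(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        """Expand reversible reactions; returns (nu_react, nu_net, rate)."""
        p = self.species.p
        out = []
        for r in self.reactions:
            nu_r = np.zeros(p)
            nu_p = np.zeros(p)
            for sp, nu in r.reactants.items():
                nu_r[self.species.index(sp)] = nu
            for sp, nu in r.products.items():
                nu_p[self.species.index(sp)] = nu
            out.append((nu_r, nu_p - nu_r, r.rate))
            if r.reversible:
                out.append((nu_p, nu_r - nu_p, float(r.reverse_rate)))
        return out

    def stoichiometric_matrix(self) -> np.ndarray:
        """Species x elementary-reactions net stoichiometry."""
        return np.column_stack([net for _, net, _ in self._elementary()])

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """dx/dt at state x: sum of rate * prod(x^nu) fluxes."""
        dx = np.zeros_like(x)
        for nu_r, net, rate in self._elementary():
            flux = rate * np.prod(np.power(np.maximum(x, 0.0), nu_r))
            dx += net * flux
        return dx

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "species": list(self.species.names),
            "reactions": [
                {
                    "reactants": dict(r.reactants),
                    "products": dict(r.products),
                    "rate": r.rate,
                    **({"reverse_rate": r.reverse_rate} if r.reversible else {}),
                }
                for r in self.reactions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MassActionModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            species=SpeciesPanel(payload["species"]),
            reactions=tuple(
                Reaction(
                    reactants=r["reactants"],
                    products=r["products"],
                    rate=r["rate"],
                    reverse_rate=r.get("reverse_rate"),
                )
                for r in payload["reactions"]
            ),
            name=payload.get("name", ""),
        )


@dataclass(frozen=True)
class SimulationRun:
    """Snapshots at the requested times plus provenance (model, seed)."""

    snapshots: tuple[SnapshotDataset, ...]
    description: str
    seed: int
    measured_panel: SpeciesPanel
    initial_full_state: np.ndarray | None = None  # all species, pre-restriction

    def __post_init__(self):
        n = {s.n_cells for s in self.snapshots}
        if len(n) > 1:
            raise ValidationError(f"snapshots disagree on cell count: {n}")

    def snapshot_at(self, time: float) -> SnapshotDataset:
        for s in self.snapshots:
            if s.time == time:
                return s
        raise KeyError(f"no snapshot at t = {time}")

    def write(self, out_dir: str | Path) -> list[Path]:
        """One CSV per time point plus a JSON manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for s in self.snapshots:
            path = out_dir / f"snapshot_t{s.time:g}.csv"
            s.to_csv(path)
            paths.append(path)
        manifest = {
            "description": self.description,
            "seed": self.seed,
            "times": [s.time for s in self.snapshots],
            "n_cells": self.snapshots[0].n_cells if self.snapshots else 0,
            "species": list(self.measured_panel.names),
            "files": [p.name for p in paths],
        }
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2) + "\n")
        return paths + [mpath]


def chain_rates(p: int, rng: np.random.Generator) -> KineticRates:
    """Chain rates k_{i->i+1} ~ U(0, 1) on the standard X1..Xp panel."""
    names = [f"X{i + 1}" for i in range(p)]
    return KineticRates(
        off_diagonal={
            (names[i], names[i + 1]): float(rng.uniform(0.0, 1.0))
            for i in range(p - 1)
        }
    )


def chain_architecture(p: int) -> NetworkArchitecture:
    """Ground-truth mask of the linear chain X1 -> X2 -> ... -> Xp."""
    panel = SpeciesPanel([f"X{i + 1}" for i in range(p)])
    return NetworkArchitecture.from_reactions(
        panel, [(f"X{i + 1}", f"X{i + 2}") for i in range(p - 1)]
    )


def simulate_chain(
    p: int,
    n_cells: int = 2500,
    rates: KineticRates | None = None,
    lognormal: LognormalSpec | None = None,
    times: Sequence[float] = (0.0, 30.0),
    seed: int = 0,
) -> SimulationRun:
    """Simulate the first-order chain X1 -> X2 -> ... -> Xp per cell.

    Initial abundances are drawn per species from lognormal distributions
    (default median 100, sdlog 0.5); every later snapshot is the exact
    closed-form propagation of the t = times[0] cells.  When ``rates`` is
    omitted the chain rates are drawn ~ U(0, 1) under ``seed``.
    """
    if p < 2:
        raise ValidationError(f"chain needs p >= 2, got {p}")
    if n_cells < 2:
        raise ValidationError(f"need n_cells >= 2, got {n_cells}")
    if len(times) < 1:
        raise ValidationError("need at least one snapshot time")
    panel = SpeciesPanel([f"X{i + 1}" for i in range(p)])
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = chain_rates(p, rng)
    M = build_rate_matrix(rates, panel)
    if lognormal is None:
        lognormal = LognormalSpec.uniform(panel.names)
    x0 = lognormal.draw(panel, n_cells, rng)
    t0 = float(times[0])
    snaps = []
    for t in times:
        x_t = x0 if t == t0 else x0 @ matrix_exponential(M, float(t) - t0).T
        snaps.append(
            SnapshotDataset(
                CellStateMatrix(x_t, time=float(t)), panel, label=f"chain p={p} t={t:g}"
            )
        )
    return SimulationRun(
        snapshots=tuple(snaps),
        description=f"first-order chain p={p}",
        seed=seed,
        measured_panel=panel,
        initial_full_state=x0,
    )


def simulate_mass_action(
    model: MassActionModel,
    n_cells: int = 250,
    lognormal: LognormalSpec | None = None,
    times: Sequence[float] = (0.0, 30.0),
    seed: int = 0,
    measured_panel: SpeciesPanel | None = None,
    initial_state: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> SimulationRun:
    """Integrate the mass-action ODEs deterministically for each cell.

    Each cell's initial state is drawn from the lognormal spec (or taken
    from ``initial_state``, cells x all-species, e.g. a perturbed draw);
    trajectories use a stiff-safe implicit integrator (LSODA) at relative
    tolerance 1e-8.  Snapshots report only the ``measured_panel`` columns.
    """
    if measured_panel is None:
        measured_panel = model.species
    idx = [model.species.index(n) for n in measured_panel.names]
    if lognormal is None:
        lognormal = LognormalSpec.uniform(model.species.names)
    rng = np.random.default_rng(seed)
    if initial_state is None:
        x0 = lognormal.draw(model.species, n_cells, rng)
    else:
        x0 = np.asarray(initial_state, dtype=float)
        if x0.shape != (n_cells, model.species.p):
            raise ValidationError(
                f"initial_state has shape {x0.shape}, expected {(n_cells, model.species.p)}"
            )
    t0 = float(times[0])
    t_end = float(max(times))
    traj = np.empty((len(times), n_cells, model.species.p))
    for alpha in range(n_cells):
        if t_end == t0:
            traj[:, alpha, :] = x0[alpha]
            continue
        sol = solve_ivp(
            lambda t, x: model.rhs(x),
            (t0, t_end),
            x0[alpha],
            t_eval=[float(t) for t in times],
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"mass-action integration failed for cell {alpha}: {sol.message}"
            )
        traj[:, alpha, :] = sol.y.T
    snaps = []
    for k, t in enumerate(times):
        snaps.append(
            SnapshotDataset(
                CellStateMatrix(traj[k][:, idx], time=float(t)),
                measured_panel,
                label=f"{model.name or 'mass-action'} t={t:g}",
            )
        )
    return SimulationRun(
        snapshots=tuple(snaps),
        description=model.name or "mass-action model",
        seed=seed,
        measured_panel=measured_panel,
        initial_full_state=x0,
    )


def _abc_panel() -> SpeciesPanel:
    return SpeciesPanel(["A", "B", "C"])


def builtin_models() -> dict[str, MassActionModel]:
    """Catalog of the built-in nonlinear ground truths.

    ``GT1`` is the irreversible second-order reaction A + B -> C; ``GT2``
    is its reversible counterpart A + B <-> C.  The reverse rate of GT2 is
    chosen so that equal abundances (~100) sit near equilibrium, which
    makes the three directional regimes (see :func:`gt2_regimes`) behave
    as intended.
    """
    panel = _abc_panel()
    return {
        "GT1": MassActionModel(
            species=panel,
            reactions=(
                Reaction({"A": 1, "B": 1}, {"C": 1}, rate=DEFAULT_BIMOLECULAR_RATE),
            ),
            name="GT1",
        ),
        "GT2": MassActionModel(
            species=panel,
            reactions=(
                Reaction(
                    {"A": 1, "B": 1},
                    {"C": 1},
                    rate=DEFAULT_BIMOLECULAR_RATE,
                    reverse_rate=DEFAULT_BIMOLECULAR_RATE * 100.0,
                ),
            ),
            name="GT2",
        ),
    }


def get_model(name: str) -> MassActionModel:
    catalog = builtin_models()
    if name not in catalog:
        raise ConfigurationError(
            f"unknown model {name!r}; catalog: {sorted(catalog)} "
            f"plus candidate masks {sorted(builtin_candidates())}"
        )
    return catalog[name]


def gt1_lognormal() -> LognormalSpec:
    """GT1 fixture initials: reactants at median 100, product at median 10."""
    return LognormalSpec(
        {
            "A": (DEFAULT_MEANLOG, DEFAULT_SDLOG),
            "B": (DEFAULT_MEANLOG, DEFAULT_SDLOG),
            "C": (float(np.log(10.0)), DEFAULT_SDLOG),
        }
    )


def gt2_regimes() -> dict[str, LognormalSpec]:
    """Initial-condition presets steering GT2's net direction.

    ``forward``: reactants 10x more abundant than product (net production
    of C); ``reverse``: product 10x more abundant (net dissociation);
    ``balanced``: all species at the same median, near equilibrium.
    """
    hi, lo = DEFAULT_MEANLOG, float(np.log(10.0))
    s = DEFAULT_SDLOG
    return {
        "forward": LognormalSpec({"A": (hi, s), "B": (hi, s), "C": (lo, s)}),
        "reverse": LognormalSpec({"A": (lo, s), "B": (lo, s), "C": (hi, s)}),
        "balanced": LognormalSpec({"A": (hi, s), "B": (hi, s), "C": (hi, s)}),
    }


def builtin_candidates() -> dict[str, NetworkArchitecture]:
    """The seven first-order candidate masks for the A/B/C ground truths.

    C1-C5 include the forward directionality of A + B -> C (some with a
    reverse edge as well); C6 and C7 point the wrong way and lack it.
    """
    panel = _abc_panel()
    mk = NetworkArchitecture.from_reactions
    return {
        "C1": mk(panel, [("B", "C")]),
        "C2": mk(panel, [("A", "C"), ("B", "C")]),
        "C3": mk(panel, [("B", "C"), ("C", "B")]),
        "C4": mk(panel, [("A", "C"), ("C", "A"), ("B", "C")]),
        "C5": mk(panel, [("A", "C"), ("C", "A"), ("B", "C"), ("C", "B")]),
        "C6": mk(panel, [("C", "B")]),
        "C7": mk(panel, [("C", "A"), ("C", "B")]),
    }


#: candidates whose reactions include the true forward directionality
CANDIDATE_DIRECTIONALITY = {
    "C1": True, "C2": True, "C3": True, "C4": True, "C5": True,
    "C6": False, "C7": False,
}
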