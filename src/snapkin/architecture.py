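"""Boolean network architectures over directed first-order rate slots.

A candidate model is a Boolean mask over the p(p-1) directed off-diagonal
rate slots plus a per-species flag for self-rates.  Following the rate
matrix convention, ``allowed[i, j]`` (i != j) marks the reaction j -> i
(i.e. the slot for ``M[i, j]``) as free.  Architectures are the unit of
model selection: each mask is fit independently and ranked by cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .kinetics import ConfigurationError, SpeciesPanel, ValidationError

__all__ = [
    "NetworkArchitecture",
    "enumerate_architectures",
    "n_true_connections",
    "slot_order",
]

#: guard against accidental full enumeration of huge mask spaces
DEFAULT_SLOT_CAP = 20


@dataclass(frozen=True)
class NetworkArchitecture:
    """Boolean mask over rate slots: ``allowed[i, j]`` frees reaction j->i."""

    allowed: np.ndarray
    self_allowed: np.ndarray
    panel: SpeciesPanel

    def __post_init__(self):
        allowed = np.asarray(self.allowed, dtype=bool).copy()
        self_allowed = np.asarray(self.self_allowed, dtype=bool).copy()
        p = self.panel.p
        if allowed.shape != (p, p):
            raise ValidationError(f"allowed has shape {allowed.shape}, expected {(p, p)}")
        if self_allowed.shape != (p,):
            raise ValidationError(
                f"self_allowed has shape {self_allowed.shape}, expected {(p,)}"
            )
        np.fill_diagonal(allowed, False)  # diagonal of `allowed` is unused
        allowed.setflags(write=False)
        self_allowed.setflags(write=False)
        object.__setattr__(self, "allowed", allowed)
        object.__setattr__(self, "self_allowed", self_allowed)

    @classmethod
    def from_reactions(
        cls,
        panel: SpeciesPanel,
        reactions: list[tuple[str, str]],
        self_species: list[str] | None = None,
    ) -> "NetworkArchitecture":
        """Build a mask from directed (source, target) reaction pairs."""
        p = panel.p
        allowed = np.zeros((p, p), dtype=bool)
        self_allowed = np.zeros(p, dtype=bool)
        for src, tgt in reactions:
            i, j = panel.index(src), panel.index(tgt)
            if i == j:
                self_allowed[i] = True
            else:
                allowed[j, i] = True
        for name in self_species or []:
            self_allowed[panel.index(name)] = True
        return cls(allowed, self_allowed, panel)

    @classmethod
    def fully_connected(
        cls, panel: SpeciesPanel, include_self: bool = False
    ) -> "NetworkArchitecture":
        p = panel.p
        return cls(
            ~np.eye(p, dtype=bool),
            np.full(p, include_self, dtype=bool),
            panel,
        )

    @property
    def p(self) -> int:
        return self.panel.p

    @property
    def n_free(self) -> int:
        return int(self.allowed.sum() + self.self_allowed.sum())

    def reactions(self) -> list[tuple[str, str]]:
        """Directed (source, target) pairs of the allowed off-diagonal slots."""
        names = self.panel.names
        out = []
        for i, j in zip(*np.nonzero(self.allowed)):
            out.append((names[j], names[i]))  # allowed[i, j] is reaction j -> i
        return sorted(out)

    def bitstring(self) -> str:
        """Mask over off-diagonal slots in row-major (i->j) slot order."""
        return "".join(
            "1" if self.allowed[j, i] else "0" for i, j in slot_order(self.p)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": list(self.panel.names),
            "edges": [[s, t] for s, t in self.reactions()],
            "self": [
                n for n, f in zip(self.panel.names, self.self_allowed) if f
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkArchitecture":
        payload = json.loads(Path(path).read_text())
        panel = SpeciesPanel(payload["species"])
        return cls.from_reactions(
            panel,
            [tuple(e) for e in payload.get("edges", [])],
            payload.get("self", []),
        )


def slot_order(p: int) -> list[tuple[int, int]]:
    """Row-major ordering of the p(p-1) directed slots (i -> j), i != j."""
    return [(i, j) for i in range(p) for j in range(p) if i != j]


def enumerate_architectures(
    p: int,
    include_self: bool = False,
    panel: SpeciesPanel | None = None,
    slot_cap: int = DEFAULT_SLOT_CAP,
) -> Iterator[NetworkArchitecture]:
    """Lazily yield all 2^{p(p-1)} off-diagonal masks (x 2^p with self flags).

    The slot count p(p-1) must stay at or below ``slot_cap`` (default 20);
    above that, enumerate an explicit subset instead.
    """
    if p < 2:
        raise ConfigurationError(f"enumeration needs p >= 2, got {p}")
    n_slots = p * (p - 1)
    if n_slots > slot_cap:
        raise ConfigurationError(
            f"p = {p} has {n_slots} rate slots, above the cap of {slot_cap}; "
            "enumerate a sampled subset of masks instead"
        )
    if panel is None:
        panel = SpeciesPanel([f"X{i + 1}" for i in range(p)])
    slots = slot_order(p)
    n_self_codes = (1 << p) if include_self else 1
    for code in range(1 << n_slots):
        allowed = np.zeros((p, p), dtype=bool)
        for bit, (i, j) in enumerate(slots):
            if (code >> bit) & 1:
                allowed[j, i] = True  # slot (i -> j) lives at M[j, i]
        for self_code in range(n_self_codes):
            self_allowed = np.array(
                [(self_code >> i) & 1 == 1 for i in range(p)], dtype=bool
            )
            yield NetworkArchitecture(allowed, self_allowed, panel)


def n_true_connections(
    truth: NetworkArchitecture, candidate: NetworkArchitecture
) -> int:
    """Number of ground-truth off-diagonal slots present in the candidate.

    Elementwise AND of the two Boolean reaction matrices, summed.
    """
    if truth.p != candidate.p:
        raise ValidationError(
            f"architecture dimensions differ: {truth.p} vs {candidate.p}"
        )
    return int(np.sum(truth.allowed & candidate.allowed))
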