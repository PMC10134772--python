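"""Per-edge flux report for a fitted network.

The reporting quantity attached to a directed edge i -> j is the flux
``k_{i->j} * mu_i(t1)``: the initial rate of conversion of i into j at
the observed t1 abundances.  Sorting edges by flux is how a fitted
fully-connected network is read as a candidate wiring diagram.
"""

from __future__ import annotations


import pandas as pd

from .architecture import NetworkArchitecture
from .kinetics import RateMatrix, ValidationError
from .moments import MomentSummary

__all__ = ["flux_report"]


def flux_report(
    M: RateMatrix,
    m1: MomentSummary,
    architecture: NetworkArchitecture | None = None,
) -> pd.DataFrame:
    """Flux table for every allowed directed edge, sorted descending.

    With no architecture, all p(p-1) directed edges are listed (zero
    rates give zero flux but stay listed).
    """
    if m1.p != M.p:
        raise ValidationError(f"moments have p = {m1.p}, M has p = {M.p}")
    names = M.panel.names
    rows = []
    for i, src in enumerate(names):
        for j, tgt in enumerate(names):
            if i == j:
                continue
            if architecture is not None and not architecture.allowed[j, i]:
                continue
            rate = float(M.M[j, i])  # k_{i->j}
            rows.append(
                dict(source=src, target=tgt, rate=rate,
                     flux=rate * float(m1.mu[i]))
            )
    df = pd.DataFrame(rows, columns=["source", "target", "rate", "flux"])
    return df.sort_values("flux", ascending=False, kind="stable").reset_index(drop=True)
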