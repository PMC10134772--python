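"""Rank candidate wirings by goodness of fit.

Fits a handful of Boolean architecture masks to the same chain data and
shows that masks containing all true connections reach cost ~0 while
masks missing a true connection cannot.
"""

import numpy as np

import snapkin as sk

run = sk.simulate_chain(p=4, n_cells=2500, seed=1)
m1 = sk.compute_moments(run.snapshots[0])
m2 = sk.compute_moments(run.snapshots[1])
truth = sk.chain_architecture(4)
panel = truth.panel

candidates = {
    "truth (X1>X2>X3>X4)": truth,
    "truth + extra edge": sk.NetworkArchitecture.from_reactions(
        panel, truth.reactions() + [("X2", "X1")]
    ),
    "missing X2->X3": sk.NetworkArchitecture.from_reactions(
        panel, [("X1", "X2"), ("X3", "X4")]
    ),
    "reversed chain": sk.NetworkArchitecture.from_reactions(
        panel, [("X4", "X3"), ("X3", "X2"), ("X2", "X1")]
    ),
    "fully connected": sk.NetworkArchitecture.fully_connected(panel),
}
schedule = sk.AnnealingSchedule(
    n_cooling_steps=500, cooling_rate=0.955, mc_trials_per_step=20,
    n_cycles=2, proposal_width_final=0.02, rate_bound=1.0, seed=11,
)
scores = sk.screen(m1, m2, list(candidates.values()), schedule, truth=truth)

print(f"{'architecture':24s} {'n_true':>6s} {'cost':>10s}")
for name, score in zip(candidates, scores):
    print(f"{name:24s} {score.n_true:6d} {score.chi2:10.3g}")
print("\n(n_true = 3 means the mask contains the full ground-truth wiring; "
      "only those masks can drive the cost to ~0.  Masks missing a true "
      "edge are stuck ~14 orders of magnitude higher.  The fully "
      "connected mask also contains the truth, but with 12 free slots "
      "this short schedule only gets it part of the way down)")
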