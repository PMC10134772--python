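"""Fit chain rates by simulated annealing when the wiring is known.

The two-snapshot moments determine the rate matrix through the closed
form mu(t2) = E mu(t1), J(t2) = E J(t1) E^T with E = exp(M dt); the fit
minimizes the three-term relative-error cost over the rates allowed by
the (here: true) architecture mask.
"""

import numpy as np

import snapkin as sk

run = sk.simulate_chain(p=4, n_cells=2500, seed=1)
m1 = sk.compute_moments(run.snapshots[0])
m2 = sk.compute_moments(run.snapshots[1])
truth = sk.chain_rates(4, np.random.default_rng(1)).off_diagonal

schedule = sk.AnnealingSchedule(
    n_cooling_steps=400, cooling_rate=0.955, mc_trials_per_step=25, seed=3
)
result = sk.fit(m1, m2, sk.chain_architecture(4), schedule)

print(f"best cost: {result.cost.total:.3g}")
print(f"  mean term {result.cost.mean_term:.3g}, "
      f"covariance term {result.cost.covariance_term:.3g}, "
      f"conservation term {result.cost.conservation_term:.3g}")
print("\nrate        true     fitted   rel.err")
for slot, k_true in truth.items():
    k_fit = result.M.to_rates().off_diagonal.get(slot, 0.0)
    print(f"{slot[0]}->{slot[1]}    {k_true:.4f}   {k_fit:.4f}   "
          f"{abs(k_fit - k_true) / k_true:.2%}")
print("\n(a cost ~0 and sub-percent errors mean the two snapshots pin the "
      "rates down essentially exactly for first-order data)")
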