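"""Profile-sampling confidence intervals on fitted rates.

After fitting, every element of M is jointly scaled by b^a (a ~ U(-1,1),
b = 2) in many samples; binning the cost excess d along one element's a
traces an approximate profile, and the d >= 2.71 crossing marks the
bound in each direction.
"""

import numpy as np

import snapkin as sk
from snapkin.kinetics import propagate_moments

run = sk.simulate_chain(p=4, n_cells=2500, seed=1)
m1 = sk.compute_moments(run.snapshots[0])
truth = sk.chain_rates(4, np.random.default_rng(1))
M_true = sk.build_rate_matrix(truth, run.measured_panel)
m2 = propagate_moments(m1, M_true, 30.0)  # exact closed-form t2 moments

result = sk.fit(
    m1, m2, sk.chain_architecture(4),
    sk.AnnealingSchedule(n_cooling_steps=400, cooling_rate=0.955,
                         mc_trials_per_step=25, seed=3),
)
intervals = sk.estimate_intervals(
    result, m1, m2, sk.CISettings(n_samples=20_000, seed=5)
)

print("slot        true     point    [lower, upper]        flags")
for iv in intervals:
    k_true = truth.off_diagonal[iv.slot]
    flags = "open" if iv.non_identifiable else ""
    inside = iv.lower <= k_true <= iv.upper
    print(f"{iv.slot[0]}->{iv.slot[1]}    {k_true:.4f}   {iv.point:.4f}   "
          f"[{iv.lower:.4f}, {iv.upper:.4f}]   {flags} "
          f"{'(covers truth)' if inside else '(misses truth)'}")
print("\n(bounds are multiplicative, within a factor of 2 of the point "
      "estimate; an interval covering the true rate is the expected outcome)")
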