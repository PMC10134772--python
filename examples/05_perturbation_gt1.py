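"""Predict perturbation outcomes of a nonlinear ground truth.

GT1 (A + B -> C, a second-order reaction) is simulated per cell; the
first-order candidate models C1 (B -> C) and C6 (C -> B, wrong
direction) are fit to the unperturbed snapshots; the fitted matrices
then predict what doubling or halving B at t1 does to the mean changes
dmu_X = mu_X(t2) - mu_X(t1).
"""

import snapkin as sk

gt1 = sk.builtin_models()["GT1"]
log = sk.gt1_lognormal()
run = sk.simulate_mass_action(gt1, n_cells=250, lognormal=log, seed=1)
m1 = sk.compute_moments(run.snapshots[0])
m2 = sk.compute_moments(run.snapshots[1])

candidates = sk.builtin_candidates()
schedule = lambda i: sk.AnnealingSchedule(  # noqa: E731
    n_cooling_steps=800, cooling_rate=0.975, mc_trials_per_step=25,
    n_cycles=2, seed=100 + i,
)
fits = {name: sk.fit(m1, m2, candidates[name], schedule(i))
        for i, name in enumerate(["C1", "C6"])}

table = sk.perturbation_study(
    gt1, fits,
    [sk.PerturbationSpec("B", 2.0), sk.PerturbationSpec("B", 0.5)],
    n_cells=250, lognormal=log, seed=1,
)

for cond in ("baseline", "Bx2", "Bx0.5"):
    print(f"\ncondition {cond}:")
    for model in ("truth", "C1", "C6"):
        d = table.dmu(cond, model)
        print(f"  {model:6s} dmu_A={d['A']:+8.1f}  dmu_B={d['B']:+8.1f}  "
              f"dmu_C={d['C']:+8.1f}")
print("\n(C1 shares the true B->C directionality and tracks the sign and "
      "trend of dmu_B/dmu_C; C6 points the wrong way and predicts ~0. "
      "No first-order model can track dmu_A's response to B — consumption "
      "of A depends on B only through the second-order propensity)")
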