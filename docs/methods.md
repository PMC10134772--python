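# Methods

## Model

`snapkin` approximates single-cell signaling kinetics between two
time-stamped cytometry snapshots as a network of first-order reactions
among the p measured species.  Per cell α, abundances follow the linear
ODE dx^(α)/dt = M x^(α), where the rate matrix M collects directed
conversion rates k_{i→j} ≥ 0 (units 1/s) off the diagonal
(M[j,i] = k_{i→j}) and signed self-rates k_{i→i} on the diagonal
(M[i,i] = k_{i→i} − Σ_{j≠i} k_{i→j}).  Positive self-rates model
production from unmeasured species, negative ones decay; every column of
M sums to k_{i→i}, so a model with no self-rates conserves total
abundance.

Because mass cytometry is destructive, individual cells cannot be
tracked between snapshots; only population summaries can.  The linear
model propagates them in closed form:

    μ(t2) = E μ(t1),   J(t2) = E J(t1) Eᵀ,   E = exp(M·(t2−t1)),

with μ the mean vector and J the biased (1/N) sample covariance.  The
1/N convention is deliberate: the fit compares model covariances to this
estimator and mixing conventions would bias the scale.  Matrix
exponentials use scaling-and-squaring Padé approximation
(`scipy.linalg.expm`); an explicit eigendecomposition solution exists in
the test suite as an independent oracle only, because it fails for
defective matrices.

No arcsinh or other cytometry transform is applied by default; the model
is fit on raw abundances.  A pre-transform hook exists on
`read_snapshot` for users who want one.  Propagated abundances are not
clipped at zero — the linear model offers no positivity guarantee and
clipping would break the closed form.

## Cost function

Fitting minimizes a dimensionless three-term cost,

    χ² = Σ_i (1 − μ_pred,i/μ_obs,i)²
       + Σ_{i,j} (1 − J_pred,ij/J_obs,ij)²
       + λ Σ_j (Σ_i M_ij)²,

with predictions propagated from the observed t1 moments.  The
covariance sum runs over all ordered pairs, so off-diagonal residuals
count twice (a flag restricts to the upper triangle).  The conservation
prefactor is λ = ((t2−t1)/a)² with the scale `a` exposed and defaulting
to t2−t1, i.e. λ = 1; the term penalizes nonzero column sums, hence
nonzero self-rates.  Ratio terms whose observed denominator is below
1e−12 times the largest observed moment are skipped and counted.  If the
data are generated by a mass-conserving first-order model and the
generating M is evaluated, χ² is exactly zero; the implementation keeps
this identity exact in floating point (true division, and the same
symmetrization applied to predicted and generated covariances).

## Simulated annealing

The cost is minimized over the slots freed by a Boolean architecture
mask with Metropolis sampling under geometric cooling.  Defaults:

- initialization: all free rates ~ U(0,1);
- proposal: pick one free slot uniformly; multiply its value by exp(u),
  u ~ U(−s, s), s = 0.5; a zero rate is replaced by a small positive
  draw; self-rate proposals flip sign with probability 0.1 (self-decay
  would otherwise be unreachable from the positive initialization);
- swap moves: with probability 0.1 two off-diagonal slots exchange
  values.  Cascades have near-degenerate local minima with adjacent
  rates swapped (the classic flip-flop ambiguity); single-site
  multiplicative moves cannot cross them, a swap can;
- acceptance: uphill moves accepted with probability exp(−Δχ²/T);
- cooling: T ← 0.99·T per cooling step, 50 proposals per step, 2,000
  steps by default (presets: 2,000 for chain fits, 3,000 for
  dimension-scaling runs, 5,000 for fits to nonlinear ground truths);
- starting temperature: 1.0.  The cost is a sum of squared relative
  errors, so T ≈ 1 accepts order-one relative fluctuations early on.  A
  probe-based start is available (`t_initial=None` uses the median cost
  of 20 random draws; the `initial_temperature` helper implements the
  max-over-probes rule).  The median, not the max, is the probe default
  because the ratio-form cost has an extremely heavy upper tail — random
  draws can exceed observed covariances by many orders of magnitude, and
  a tail-dominated start cannot cool into the basin within thousands of
  steps;
- reheating: `n_cycles > 1` splits the schedule into anneal cycles, each
  re-melted from the best state found so far.  Four cycles at cooling
  rate 0.965 is the configuration used for the full-scale recovery runs;
  repeated anneal/quench passes are what reliably escape the swap
  minima for longer chains (p ≥ 8);
- the best state ever visited is tracked separately from the chain and
  is what the fit returns, which makes the best-cost trace
  non-increasing by construction.

Fits are bitwise reproducible for a fixed seed.  Screening a sequence of
architectures derives per-architecture seeds as base + index, so a
screen is reproducible and embarrassingly parallel.

## Uncertainty

Confidence intervals use multiplicative profile sampling around the best
fit: M*_ij = M_ij · b^{a_ij} with a_ij ~ U(−1,1) drawn independently for
every element and b = 2 (structural zeros stay zero).  For each free
slot, the samples' a values are binned over [−1,1] (40 bins, so ~2,500
expected samples per bin at the full n = 100,000); the smallest cost
excess d = χ²(M*) − χ²(M) per bin approximates the profile, and scanning
outward from the two central bins, the first bin whose minimum d reaches
the threshold (2.71 by default) sets the bound at that bin's center.
Directions that never cross are reported open-ended; zero-valued slots
get degenerate multiplicative intervals and are flagged.  The scheme
suffers the curse of dimensionality — all free elements are perturbed
jointly, so per-bin minima sit above the true profile when the sample
budget is thin relative to the number of slots; a warning is emitted
below ~1,000 samples per slot.  The test suite uses n = 20,000.

## Synthetic data

Two generator families reproduce the in silico study designs:

- **First-order chains** X1→X2→…→Xp with rates ~ U(0,1) (1/s), 2,500
  cells, lognormal initial abundances, snapshots at t = 0 and 30 s.
  Later snapshots are produced by the exact closed-form propagation, so
  moment-propagation identities hold to floating-point accuracy by
  construction.  Note that with rates up to 1/s and a 30 s window the
  upstream species drain essentially completely; tiny observed t2 means
  are what makes the ratio-form cost landscape heavy-tailed.
- **Nonlinear mass-action ground truths**, integrated per cell as
  deterministic ODEs (LSODA, rtol 1e−8): GT1 (A + B → C, irreversible)
  and GT2 (A + B ↔ C).  Defaults chosen once on physical grounds, since
  no canonical values exist for these toy systems: bimolecular rate
  1e−4 per abundance-unit per second (a moderate, non-saturating ~25%
  conversion over 30 s at abundances ~100), GT2 reverse rate 1e−2/s so
  that equal abundances sit near equilibrium.  Initial abundances are
  lognormal with meanlog log(100) and sdlog 0.5; GT1 starts its product
  at median 10, and GT2 ships three regime presets (forward, reverse,
  balanced) scaling reactants versus product by 10× either way.  250
  cells by default.

What the generators deliberately do not emulate: measurement noise,
spillover, acquisition-time drift, gating artifacts, or cell-cycle
structure.  Passing tests therefore demonstrate correctness of the
estimator on data that satisfy (chains) or controllably violate
(GT1/GT2) the first-order assumption — not robustness to real CyTOF
noise sources.

## Perturbation protocol

A perturbation multiplies one species' initial abundance by a factor in
every cell.  Candidates are fit once on unperturbed data; their fixed
fitted matrices then predict perturbed outcomes by propagating the
perturbed t1 moments (scaling species s by f multiplies μ_s by f and
row/column s of J by f — exact for deterministic per-cell scaling).  The
ground truth is resimulated from the scaled cells.  The readout is
Δμ_X = μ_X(t2) − μ_X(t1); "qualitatively accurate" is operationalized as
sign agreement with the truth, with |Δμ| below 1% of μ(t1) mapped to a
"≈0" class.  Squared distances between candidate and truth Δμ vectors
quantify the comparison.

## Known limitations and deliberately open behavior

- The first-order approximation cannot represent reactant co-dependence:
  under GT1, no first-order candidate responds in Δμ_A when B is
  perturbed, because A's dynamics are linear in A alone.  This failure
  mode is pinned by a test as a documented property.
- The qualitative distinction between candidates with and without a
  reverse edge (B↔C versus B→C) is not reproduced under the default GT1
  regime: the fitted reverse rates converge to zero, making the
  reversible candidates collapse onto their irreversible counterparts.
  Whether a reverse edge survives fitting depends on the ground truth's
  rate constants and initial conditions, for which no canonical values
  exist; the corresponding acceptance check is expected to fail in part
  and is kept failing rather than tuned around.
- Chain identifiability: two-snapshot data pin down chain rates
  remarkably well, but the cost landscape contains deep rate-swap minima
  whose basins grow with p; the shipped annealing defaults (swap moves +
  reheating) recover p = 13 chains to sub-percent accuracy for most
  seeds, not all.
- Non-monotonic kinetics cannot be captured within one fit window; fit
  piecewise-monotonic intervals separately.
- Problem sizes in the test suite are scaled down where noted (256
  sampled masks instead of the full 4,096; annealing schedules of
  350–800 cooling steps for screening and nonlinear fits; 20,000 profile
  samples), chosen to keep the suite fast while leaving each claim's
  margin intact; the full-scale settings are the library defaults.
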