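# Methods

## The model

`triosc` implements a five-variable ODE model of autophagy induction built
around the regulatory triangle of mTORC1 (growth master regulator), AMPK
(energy-stress sensor) and ULK1 (autophagy-initiation kinase), plus a
delayed intermediate PROT ("extra protein") that carries AMPK's slow
positive effect on ULK1, and AUTOPHAGY as a pure readout of successful
induction.  Activities are dimensionless pool fractions in arbitrary units
(a.u.); each species `X` with pool total `X_T` obeys a Michaelis–Menten
activation/inactivation pair

    dX/dt = a(X) (X_T − X)/(J_act + X_T − X) − i(X) X/(J_inact + X)

where the activation rate `a` is a basal rate plus one mass-action term
`k_e · source` per positive incoming edge, and the inactivation rate `i`
symmetrically collects the negative edges.  Rate constants `k` have
dimension (time unit)⁻¹; Michaelis constants `J` are dimensionless.  The
prefactors vanish at the pool boundaries, so the state box is forward
invariant for any nonnegative rates — asserted as a property test on 1,000
random boundary states.

The wiring (all mandatory):

* loop 1 — AMPK ⊣ mTORC1 and mTORC1 ⊣ AMPK (double negative);
* loop 2 — ULK1 ⊣ mTORC1 and mTORC1 ⊣ ULK1 (mutual antagonism);
* loop 3 — AMPK → PROT → ULK1 ⊣ AMPK (delayed negative feedback);
* readout — AMPK·ULK1 → AUTOPHAGY (product: both inducers are required)
  and mTORC1 ⊣ AUTOPHAGY.

Three optional edges define the topology variants: AMPK ⊣ ULK1 (the
"amplifying" double-negative arm; variant A = reference), AMPK → ULK1
(counter-operating loop; variant C), ULK1 → AMPK (variant D).  B is A
without the amplifying arm; E and F add both positive edges, F with the
AMPK → ULK1 weight overridden to 0.1× (F_weak) or 10× (F_strong) the
ULK1 ⊣ AMPK weight.  Variant E appears in the source nomenclature without
a quantitative characterization and is deliberately excluded from the
ordering assertions.

Two dimensionless stress inputs act additively on rate sums: `stress` on
AMPK's activation, `stress1` on mTORC1's inactivation.  The points of
action are configurable (`stress_points` in the config); these defaults
are a declared modeling choice, since only the input magnitudes of the
study scenarios (stress = 0.75, stress1 = 0.25) are prescribed.
Rapamycin treatment is modelled purely as lowering the mTORC1 pool total
(`mTORC1T = 0.4`), with no separate drug species.

## The reference parameterization

The original equations and constants for this system live in a
supplementary file that is not redistributed here, so the shipped
`reference_model.yaml` was calibrated by randomized hill-climbing under
the rate-law template above until the model reproduces every qualitative
claim of the underlying analysis simultaneously:

1. without stress, a unique stable steady state with mTORC1 > 0.5·mTORC1T
   and AUTOPHAGY at ~10⁻⁶ of its stressed maximum;
2. under stress (0.75/0.25) and under rapamycin (mTORC1T = 0.4), sustained
   relaxation oscillations of AMPK, ULK1 and AUTOPHAGY (period CV < 1%,
   amplitude stationary to < 0.01%);
3. a unique, unstable fixed point in both the full system and the reduced
   (AMPK, ULK1) plane under stress, surrounded by a limit cycle;
4. the variant amplitude ordering amp(B) < amp(A), amp(C) < amp(A),
   amp(D) maximal, amp(F_strong) < 0.5·amp(F_weak), with "amplitude"
   meaning ULK1 peak-to-trough.

The calibration was frozen before the test suite was written and the
configuration is never adjusted afterwards; the orderings are acceptance
properties of this reference set, not universal theorems.

Mechanistically the oscillator works as a relaxation clock: ULK1 is the
slow variable (its rate constants are ~20× smaller than the others),
PROT is fast and tracks AMPK, and AMPK gains effective self-activation
through the graded mTORC1 switch (J_mTORC1 = 0.04 versus 0.01 for the
sharp AMPK/ULK1 switches).  AMPK fires, mTORC1 collapses, PROT charges
and slowly lifts ULK1; once ULK1 crosses the ULK1 ⊣ AMPK threshold it
shuts AMPK down, PROT drains, ULK1 decays, and AMPK refires.  The graded
mTORC1 response is what carries the instability into the two-variable
reduction: with razor-sharp mTORC1 kinetics the reduced fixed point is a
weakly damped focus and the oscillation would live only in the eliminated
variables' lag.

## Numerical choices

* **Integration** — LSODA with rtol 1e-8, atol 1e-10, output step 0.1,
  default horizon 400–500 time units; halving tolerances moves periods
  and amplitudes by < 1e-3 relative (asserted).
* **Oscillation metrics** — peaks by prominence (default 1e-3 a.u.) on the
  second half of the run; period = mean inter-peak interval; amplitude =
  mean peak-to-following-trough; "oscillatory" requires ≥ 3 cycles,
  period CV < 10% and amplitude > 0.01 a.u.; a flat tail (< 0.01 total
  variation) is "steady", anything else "irregular".
* **Steady states** — multistart hybrid root finding (64 seeded uniform
  starts plus a long-integration endpoint), residual < 1e-10, duplicates
  merged at 1e-6; stability from the finite-difference Jacobian (central,
  relative step 1e-6, floor 1e-8).
* **QSS reduction** — no species regulates itself, so each eliminated
  species' balance is quadratic in its own activity and solved in closed
  form (the Goldbeter–Koshland root, verified against bisection to
  1e-12); eliminated species are re-solved iteratively in case a custom
  wiring couples them (the shipped wiring does not).  Inner residuals are
  asserted < 1e-10 at every evaluation.
* **Nullclines** — 201-point grid scan per axis with vectorized
  evaluation, sign-change bracketing and bisection to 1e-12; every stored
  point re-checks |d(variable)/dt| < 1e-8.
* **Transition location** — bisection on the simulation-based
  classification; deterministic, cold-started probes.
* **Parameter recovery** — log-space trust-region least squares on the
  summed squared residual of all five species at 200 equispaced
  observation times over 40 time units (about two cycles).  Multistarts
  perturb the stored values log-normally (sd 0.4, roughly ±50%); distant
  cold starts are deliberately avoided because the residual surface of an
  oscillatory fit is multimodal in the period, and a long horizon
  amplifies phase aliasing (a 100-time-unit window reproducibly trapped
  the optimizer in period-aliased minima).
* **Default free parameters** — the ULK1 ⊣ AMPK and PROT → ULK1 weights,
  the two most debated edges of the wiring.

## What the synthetic data emulate — and what they do not

`generate_observations` produces clean model trajectories at equispaced
times plus independent Gaussian noise clipped to [0, total]; the
generator records its seed and the generating parameter fingerprint, and
is bit-reproducible.  `generate_synthetic_network` emulates a layered,
signed interaction export (core/direct/additional) with planted true
"extra protein" candidates and near-miss decoys (single qualifying edge,
wrong sign, reversed direction, random noise edges).

Real data differ in ways these generators do not model: measurement noise
in immunoblot/reporter time courses is neither Gaussian nor independent
across time points, sampling is sparse and irregular, cell populations
desynchronize (damping apparent oscillations), and curated interaction
databases contain redundant, conflicting and unsigned records with
identifier ambiguity.  Passing the recovery and filter tests therefore
demonstrates correctness of the algorithms under their stated model, not
robustness to real experimental artifacts.

## Known limitations

* Activities only: no synthesis/degradation layer, fixed pool totals,
  no stochasticity, no spatial structure, no explicit delay terms (the
  delay is the PROT intermediate).
* The amplitude orderings are statements about the shipped reference
  configuration; robustness over parameter space can be explored with
  `response_curves.sweep` but is not claimed.
* The candidate filter uses direct single-edge criteria; pathway-mediated
  ("indirect") qualification is intentionally out of scope, as is any
  live database access or identifier mapping beyond user aliases.
* The decaying-amplitude/cell-death hypothesis sometimes attached to this
  system is not modelled; the simulated oscillations are sustained.
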