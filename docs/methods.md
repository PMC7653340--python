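# Methods

This note documents the models and numerical choices behind `ties-kit`:
what each component computes, which knobs matter, and what the synthetic
data used in testing does and does not emulate.

## The estimand

For two congeneric ligands L1 and L2 binding the same receptor, the
relative binding free energy is obtained from a thermodynamic cycle,

    ΔΔG = ΔG₁ − ΔG₂ = ΔG_alch(aqueous) − ΔG_alch(bound),

where each leg is an alchemical transformation of L1 into L2 carried out in
one environment.  The transformation is parameterized by λ ∈ [0, 1] through
the hybrid potential

    V(λ, x) = (1 − λ) V₁(λ, x) + λ V₂(λ, x),

and each leg's free energy is the thermodynamic-integration integral

    ΔG_alch = ∫₀¹ ⟨∂V/∂λ⟩_λ dλ.

`ties-kit` implements everything around the molecular-dynamics engine: the
dual-topology hybrid, the λ-coupling schedule, the ensemble task plan, and
the statistical estimation of the integral from per-window ensembles.  It
runs no MD and evaluates no molecular force field; the `ToyAlchemicalSystem`
evaluator exists solely to exercise the estimator on closed-form potentials.

## Dual-topology hybrid construction

The hybrid ligand is a shared core plus a "disappearing" region (atoms
unique to L1) and an "appearing" region (atoms unique to L2).

1. **Core search.** A maximum connected common substructure of the two
   molecular graphs, matching atoms on element symbol (hydrogens included —
   their charges matter for the tolerance rule below) and requiring the
   mapped subgraphs to be induced: a bond is present between two mapped
   atoms of L1 exactly when it is present between their images.  The search
   is an exact branch-and-bound over connected pair extensions with an
   exclude-after-explore rule so each candidate mapping is enumerated once,
   and a per-element availability bound for pruning.  Maximum common
   subgraph is NP-hard, so the worst case is exponential; on
   element-labelled ligand-sized graphs it is fast in practice.
   *Tie-break:* among equally large mappings the lexicographically smallest
   pair sequence is chosen, evaluated with the ligands in a canonical order
   (a deterministic key on atom count, elements, bonds, charges, name) and
   mirrored back if the caller's order differed.  Breaking ties in a fixed
   orientation is what makes the result independent of argument order; a
   naive per-direction lex rule is not symmetric when distinct tied maxima
   exist.  Bond orders are not part of the ligand model; the
   `match_bond_order` flag is accepted for interface stability.
2. **Ring completeness.**  Rings are the minimum cycle basis of each
   ligand's graph (the usual smallest-set-of-smallest-rings notion).  A
   mapped atom belonging to a ring that is not mapped in its entirety is
   removed, iterated to a fixed point, so no ring straddles the
   core/alchemical boundary.
3. **Charge tolerance.**  Mapped pairs whose partial charges differ by more
   than a tolerance (default 0.1 e) are removed, together with every ring
   containing such an atom, after which ring completeness is re-applied.
   Tightening the tolerance can only remove more pairs, so the core size is
   non-increasing as the tolerance decreases.
4. **Charge assignment.**  Core atoms take the arithmetic mean of their two
   endpoint charges.  Averaging shifts each end state's net charge by half
   the core charge difference; with `charge_correction=True` (default) the
   residual is spread equally over that end state's alchemical-region atoms
   (over the core if that region is empty), restoring both endpoint net
   charges exactly.  The correction is a flag because the ordering of
   averaging and correction is a genuine free choice; for the neutral
   congeneric series this tool targets the residuals are small.

The result is serialized as a versioned JSON document (schema
`ties-kit/hybrid-topology` v1) listing core/appearing/disappearing atoms
with charges and a provenance record naming every pruned pair and the stage
and reason for its removal.

## λ schedule and coupling rules

The default grid is 13 windows — 0.0, 0.05, 0.1, 0.2, …, 0.8, 0.9, 0.95,
1.0 — denser near the endpoints where the integrand changes fastest.  Van
der Waals interactions of alchemical atoms scale linearly over the whole
range (appearing: λ; disappearing: 1 − λ) through a separation-shifted
soft-core form

    U(r; λs) = 4 ε λs (ρ⁻⁶ − ρ⁻³),   ρ = (r/σ)² + α(1 − λs),

with α = 0.5 by default: finite at r → 0 for λs < 1, plain Lennard-Jones at
λs = 1, zero at λs = 0.  Electrostatics use partial windows: disappearing
charges ramp 1 → 0 over λ ∈ [0, 0.55] and stay off beyond; appearing
charges stay off until λ = 0.45 and ramp 0 → 1 over [0.45, 1].  All four
factors are piecewise-linear and confined to [0, 1]; λ = 0 is pure L1 and
λ = 1 pure L2.

## Ensemble planning

Each λ window runs an ensemble of replicas (default 5) that share starting
coordinates and differ only in initial velocities — encoded as one
deterministic velocity seed per task, derived from the master seed via
`numpy.random.SeedSequence` spawn keys (unique and < 2³¹).  With 13 windows
and 5 replicas that is 65 tasks per environment per ligand pair.  The
absolute-protocol planner (`plan_esmacs`) produces a flat ensemble,
25 replicas × 4 ns by default.

The per-task protocol template: 1000 minimization steps; heat 50 → 300 K
over 60 ps; 2 ns NPT equilibration at 300 K / 1 bar (Langevin damping
5 ps⁻¹; Berendsen-style barostat, compressibility 4.57 × 10⁻⁵ bar⁻¹,
relaxation 100 fs) during which heavy-atom restraints step down
4 → 2 → 1 → 0 kcal/mol/Å² in four equal sub-stages (the release schedule is
a free choice; monotone-to-zero in equal steps is the simplest defensible
default and is configurable); then 4 ns production.  Config stubs are
keyword/value text in a dialect this project versions and owns
(`ties-kit/config-stub v1`); byte-identical re-emission from the same plan
is tested, engine-native compatibility is not promised.  A manifest with
per-file size and SHA-256 supports the post-generation sanity check (no
missing or zero-length files), which exits non-zero on any defect.

## The stochastic TI estimator

Per window, each replica is reduced to the time-mean of its (post-discard)
samples; the window mean is the average of replica means and its standard
error their standard deviation over √n.  Replica means — not pooled
samples — are the unit of error: replicas are independent by construction,
so within-series autocorrelation inflates within-replica variance but
cannot bias the inter-replica standard error.  The equilibration-discard
fraction defaults to 0 (callers are expected to pass production data).

The integral is trapezoidal quadrature over the λ grid, ΔG = Σ wᵢ mᵢ with
the usual composite weights, treated as a stochastic integral: the window
means are independent random variables, so

    σ²(ΔG) = Σ wᵢ² sᵢ².

A seeded bootstrap alternative resamples replica means per window (default
B = 1000) and reports the resample standard deviation; per-window
deviations are rescaled by √(n/(n−1)) to undo the plug-in bootstrap's
small-ensemble bias, which is ~10% at n = 5 and would otherwise be a
systematic disagreement with the propagated route.  Duplicate λ entries are
rejected rather than merged; missing windows are a coverage error.

Both routes are exposed through the `ThermodynamicIntegration` model /
`TIEstimatorResults` front end (statsmodels-style: `fit()`, `summary()`,
`conf_int()`), and the results object feeds `ddg_cycle`, which combines the
two legs' independent uncertainties in quadrature.

Uncertainty caveat: the reported σ is estimated from few replicas, so a
ΔG ± 1.96σ interval is slightly anticonservative.  With 5 replicas over the
13 weighted windows the effective degrees of freedom are ≈ 39
(Welch–Satterthwaite), giving true coverage near 94% rather than 95% — the
calibration test's tolerance band accounts for this.

## Synthetic data

`SyntheticSpec` draws replica series whose window mean follows a polynomial
m(λ) (default cubic, 2 − λ + 3λ² − 2λ³, chosen so the truth
∫₀¹ m dλ = Σ cₖ/(k+1) = 2.0 kcal/mol is closed-form) with stationary
Gaussian AR(1) noise per replica: marginal sd `noise_sd` (default
2 kcal/mol), lag-1 coefficient `ar1_coefficient` (default 0.5), initialized
from the stationary marginal.  Defaults mirror the production protocol:
5 replicas × 13 windows × 400 samples (a 4 ns production sampled every
10 ps).  The benchmark generator mirrors a 17-pair congeneric study:
experimental ΔΔG uniform on ±3 kcal/mol, calculated = experimental +
Gaussian noise (default sd 1 kcal/mol, the scale of typical alchemical
accuracy).

What passing tests show: the estimator is unbiased and near-nominally
calibrated when the integrand really is a smooth mean plus stationary
autocorrelated Gaussian noise with exchangeable replicas.  What they do not
show: robustness to slow conformational transitions (non-stationarity),
replica-dependent drift, fat-tailed ∂V/∂λ distributions near endpoint
windows, or force-field error — none of which the generator emulates.

## Benchmark statistics

`benchmark` matches calculated and experimental ΔΔG one-to-one by pair
label (orphans are an error) and reports Pearson r, Spearman r_s, MSE,
RMSE and the least-squares line of calculated on experimental.  MSE is
reported in kcal²/mol² — the dimensionally consistent choice; RMSE² = MSE
by construction — with a units label that can be switched for reports that
quote MSE in kcal/mol.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic/toy
inputs: MCS oracle comparisons on random graphs of ≤ 6 atoms (exhaustive
enumeration is exact there), calibration over 500 ensembles at the default
5 × 13 × 400 size, quadrature oracles on 10⁶-point fine grids, and 17-pair
benchmarks, sizes chosen to make every check exact or statistically sharp
while completing in seconds.
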