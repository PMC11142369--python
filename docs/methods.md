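# Methods

This note records the models implemented in `phagehab`, the assumptions they
make, the defaults and why, and what the tests do and do not establish.

## Device geometry

The published device description fixes the etch depths (10 μm chambers and
corridors, 100 nm nanoslits), the total etched chamber area (~40 mm²), the
medium volume that follows from them (~0.4 μl), and the inlet-well volume
(4×10⁻² μl).  It does not publish the number of hexagons, their side length,
or corridor dimensions.  The `reference_layout()` preset is therefore an
explicit reconstruction:

* 6 rows × 75 columns of regular hexagons, sized so the total chamber area
  is exactly 40 mm² (hex side ≈ 0.185 mm);
* corridors 5 μm wide × 80 μm long × 10 μm deep;
* nanoslits 300 μm wide × 5 μm long × 100 nm deep, one per boundary-row
  chamber, coupling row 0 to the phage-feed channel and the last row to the
  plain-feed channel;
* the chamber nearest the array centroid is the inlet (row 3 of 0–5), with
  the 0.04 μl well volume kept as a property of the inlet, separate from
  chamber volume.

The corridor cross-section was chosen on physical grounds, once: with
conductance g = D·A/L the inter-chamber diffusive hop time for virions
(V/g ≈ 9 h) makes the 20 h pre-run produce a *steep, still-evolving*
gradient spanning several decades across the array — the regime the original
experiment reports (an established but explicitly non-steady gradient,
rendered on a log color scale).  A wider/shorter corridor choice would relax
the array toward a linear steady profile within the pre-run, which
contradicts that description.  All dimensions are constructor parameters, so
other reconstructions are one call away.

Chamber adjacency is a rectangular grid (row and column neighbors) with
honeycomb-offset centroid positions.  True honeycomb 3-coordination is not
modelled; downstream physics consumes only the row structure, conductances
and positions.

## Virion transport

Chambers are treated as well mixed and conduits as quasi-1-D diffusive
resistors, giving the compartmental system Vᵢ dcᵢ/dt = Σⱼ gᵢⱼ(cⱼ − cᵢ) with
gᵢⱼ = D·A/L per conduit.  The two flow channels are Dirichlet reservoirs
(c₀ = 2×10⁹ virions/ml and 0) because the 5 μl/h flow continuously
replenishes them; advection inside channels is not modelled, nor is phage
decay, nor lysis-driven local release in the default model (the
eco-evolutionary module can couple it back explicitly).

Integration is backward Euler (default step 10 s).  The scheme is
unconditionally stable, positivity-preserving, satisfies the discrete
maximum principle, relaxes monotonically from an empty device, and — for a
closed network — conserves total virion number to solver round-off; all four
properties are asserted in the test suite.  `steady_state_field` solves the
Dirichlet balance directly and is cross-checked against a dense brute-force
solve on a small layout.

This compartmental model replaces the original full-3-D finite-element
computation.  Since that mesh and its boundary conditions are unpublished,
agreement is asserted at the property level (monotone row ordering,
multi-decade span, boundedness by the feed titer), never at field-value
level.

## Mutation arithmetic

One mutation law is used throughout the package: a *dividing sensitive cell*
yields one resistant and one sensitive daughter with probability
p = m·Θ_D + Θ_L·[exposed]; resistant lineages breed true and never
back-mutate.  Expected-value consequences:

* resistant count after G generations of unstressed doubling:
  N_r = m·G·Θ_D·N₀·2^(G−1), valid while m·G·Θ_D ≪ 1 (the implementation
  flags results when m·G·Θ_D > 0.01, where neglecting sensitive-pool
  depletion becomes visible);
* resistant fraction F = m·G·Θ_D, normalized by N₀·2^(G−1) — the same
  normalization is used when the branching simulator is compared against it;
* stress-induced estimator Θ_L ≈ k/(g·N₀) for k observed resistance events
  after g exposure generations of a roughly constant pool N₀; with k = 0 the
  k = 1 value is returned flagged as an upper bound;
* the Composite expectation adds an induced term; with the default doubling
  population each exposed generation contributes Θ_L·N₀·2^(G−1) resistant
  descendants, while an explicit (e.g. constant) population trajectory
  counts mutation events only, making the estimator exactly invertible.

"Order of magnitude" is defined as 10 raised to the exponent rounded half
away from zero, which maps 1/(30×10⁴) = 3.3×10⁻⁶ to 10⁻⁵ and
1/(140×10⁴) = 7.1×10⁻⁷ to 10⁻⁶ — both printed device estimates.  The
defaults use Θ_D = 2.0×10⁻⁹/generation; the round value 10⁻⁹ used in the
arithmetic examples is available via `MutationParams.with_round_rate()`.
Whether the "30 generations" in the estimator counts exposure or total
growth generations is ambiguous in the source; it is implemented as exposure
generations g, matching the estimator's own form.  The exposed population in
that estimator is taken as N₀ per generation at face value.

## Branching simulator

The per-generation update is an aggregated draw — mutants ~ Binomial(S, p),
then S ← 2S − mutants, R ← 2R + mutants — which follows the exact same law
as a per-cell simulation at any population size up to ~10¹².  Replicate
seeds are derived deterministically from a root seed through numpy's
`SeedSequence`, and are recorded per replicate.

Fluctuation summaries report mean, unbiased variance, Fano factor
(variance/mean; undefined at zero mean), the zero-mutant fraction p₀, and
the p₀ rate estimator −ln p₀ / D with D = N₀(2^G − 1) divisions per culture.
The Ma–Sandri–Sarkar maximum-likelihood estimator is intentionally out of
scope; p₀ and mean-based estimators suffice for the package's claims.

The central cross-validation runs both routes at the device operating point
(N₀ = 10⁴, G = 24, Θ_D = 10⁻⁹): the stochastic mean must match the closed
form within three standard errors at 10⁴ replicates.  Because the jackpot
distribution is extremely heavy-tailed, the standard error is taken from the
sample itself.

## Spatial eco-evolutionary simulation

A synchronous tau-leap scheme (default Δt = 0.01 h; 0.001 h on the full
device preset, where the bottom-row infection probability otherwise exceeds
the 0.5 per-step cap and the simulator refuses to run) updates per chamber:

* **growth** — division probability μ(n)Δt with Monod μ(n) = μ_max·n/(K_s+n);
  each division consumes one nutrient unit, so "nutrient" is denominated in
  divisions;
* **mutation** — per division, probability m·Θ_D + Θ_L·[c_local > c*];
  the stress-induction mechanism is unknown in the source system, so it is
  modelled phenomenologically as an exposure-gated elevated rate with
  threshold c* = 10⁶ virions/ml (configurable);
* **infection** — each sensitive cell is adsorbed with probability
  1 − exp(−k_a·c_local·Δt), the exact exponential survival form.  The step
  size is validated against the externally imposed field; the self-generated
  free-phage pool (when lysis coupling is on) may saturate this probability
  toward 1, which is the physically correct overwhelming-phage limit rather
  than a discretization error.  Resistant cells are never infected
  (receptor loss);
* **lysis** — infected cells are age-structured and lyse exactly one latent
  period τ after adsorption; bursts feed the local free-phage pool only when
  coupling is enabled (off by default, mirroring the imposed-gradient
  approximation of the transport model);
* **migration** — each free S or R cell crosses an incident corridor with
  probability λΔt; the destination among neighbors is drawn with weight
  ∝ exp(β·Δn/K_s) (Δn measured in units of K_s to keep β dimensionless and
  the exponent bounded; clipped at ±50).  The multinomial split is realized
  as an exact chain of conditional binomials, vectorized over chambers.
  Nanoslits never pass cells;
* **nutrient** — slit-bearing chambers relax toward a saturation level
  (default 5×10⁴ divisions; supply cannot exceed the feed medium's carrying
  level, which prevents unbounded accumulation in chambers sterilized by
  phage), plus optional inter-chamber exchange using the corridor
  conductances scaled by a small-molecule/virion diffusivity ratio
  (default 50).

T4r kinetic parameters are not given in the source; defaults are
literature-typical: latent period τ = 0.5 h, burst size b = 50, adsorption
constant k_a = 1.4×10⁻⁷ ml/h (≈2.4×10⁻⁹ ml/min, the classic T4 value).  At
that k_a the MOI = 1000 challenge fully excludes ancestor growth in the
well-mixed limit, as observed; a much smaller k_a would not.  Corridor
crossing λ = 0.2 /h and bias β = 1 make chambers weakly coupled communities;
none of the package's quantitative claims depend on these placeholders'
exact values, and all are configurable.

Resistance is treated as heritable from the mutation event onward.  Whether
the earliest observed insensitive cells in the real system are genetic from
the outset or initially phenotypic (transient biofilm protection) is
unresolved; biofilm mechanics, membrane lifting, lysis inhibition, CRISPR
dynamics and phage co-evolution are deliberately not modelled.

### What the preset run shows

With the reconstruction preset, seed 11, Θ_L = 10⁻⁵ and a 30 h experiment
after the 20 h pre-run, the simulation reproduces the experiment's anatomy:
sensitive cells bloom toward the plain-feed rows (the gradient refuge),
stress-induced mutants arise in the band where exposure exceeds c* but
adsorption does not yet outpace growth (row concentrations ~10⁶–10⁷
virions/ml), and the first chamber whose resistant count passes 100 lies in
that band — below the array's median concentration — within the first day.
Resistant cells subsequently colonize even the high-titer rows.  Across
seeds the hot spot's chamber varies and occasionally its first crossing
lands one row higher; the seeded run is the documented reference, and the
claim defended is the qualitative localization, not a chamber identity.

## Synthetic data

Generators default to the published operating point: N₀ = 10⁴ founders,
~30 exposure generations, Θ_L of order 10⁻⁵.  The first-detection generator
holds the exposed pool constant at N₀ (phage pressure cancels net growth),
giving a geometric waiting time with per-generation success probability
1 − (1 − p)^N₀ ≈ 0.095 at the defaults (median ≈ 7 generations).  Ground
truth lives in a JSON sidecar next to each table, never inside it; recovery
tests read truth only from the sidecar.  The miniature spatial fixture
plants a resistant clone in a known chamber of a 3×3 array for
detector unit tests.

A green recovery test establishes that the estimators invert the generating
model at the stated operating point.  It does not establish that real
detection-time data follow a geometric law, that the exposed pool in the
device is constant, or anything about mutation identities — the synthetic
world contains none of the biology (biofilms, motility structure, receptor
genetics) that distinguishes the real habitat.

## Numerical choices

* Backward Euler everywhere in transport; sparse LU factorized once per run.
* Steady-state detection is by direct linear solve, not iteration.
* Integer cell counts throughout the stochastic modules (int64); binomial
  draws on aggregated counts; no floating-point cell bookkeeping.
* Per-step probability above 0.5 for division, migration, or external-field
  infection raises an error instructing a smaller step — never silently
  clipped.
* Nutrient can be overdrawn by at most one step's births before clamping at
  zero; the plateau error this introduces is bounded by one batch of
  divisions and is covered by test tolerances.
* Hot-spot crossing times are resolved to the recording interval (default
  0.1 h on the preset); ties break by chamber id.
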