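# Methods

## Model

The package implements a two-lesion-class kinetic model of photon cell
killing.  The nucleus is partitioned into `n_domains` = 3000 chromatin
giant-loop domains (6000 Mbp genome at ~2 Mbp per loop, treated as equally
sized closed targets).  DSBs are induced linearly in dose with yield
`dsb_yield` = 30 /Gy/cell and are Poisson-distributed over domains, so an
acute dose D gives λ = dsb_yield·D/n_domains breaks per domain.  One
unprocessed DSB in a domain is an *isolated* DSB; two or more coexisting
unprocessed DSBs form a *clustered* DSB.  Each class carries a per-domain
lethal-event probability (ε_i, ε_c) and a first-order processing rate
k_x = ln 2/HLT_x split into viable repair r_x = (1−ε_x)k_x and lethal
misrepair m_x = ε_x·k_x.  Survival is the Poisson zero class of lethal
events over the whole nucleus.

Key assumptions, and what they exclude:

* domains are closed: lethality depends only on the DSB multiplicity
  inside one loop (inter-domain interactions are absorbed into the mean
  lethalities);
* a constant mean loop size — no loop-size distribution;
* constant radiosensitivity over the cell cycle;
* a clustered DSB never reverts to isolated (no fc → fi transition), and
  lethal levels are absorbing;
* DSB yield is dose-rate independent.

## Kinetics and numerics

The five level occupations (f0, fi, fc, li, lc) obey a *linear* ODE system
with piecewise-constant coefficients (induction rate d′ = dsb_yield·Ḋ/
n_domains during a segment).  Instead of an adaptive stiff integrator, each
constant-rate segment is propagated **exactly** with the matrix exponential
of the 5×5 generator (`scipy.linalg.expm`), vectorized over stacks of
(dose, dose-rate) pairs.  This removes solver tolerance as an error source
(important for the finite-difference Taylor coefficients below), is immune
to the stiffness that appears at high induction rates, and is fast enough
to sit inside a global fit; a Radau `solve_ivp` cross-check at
rtol 1e−10/atol 1e−12 is kept in the test suite as an independent route.

Instantaneous pulses are applied as an exact Poisson redistribution of the
non-lethal levels (f0 splits with weights p0/p1/p≥2; fi stays isolated
with probability p0, otherwise clusters; fc and the lethal levels are
unchanged).  Domains already lethal are excluded from the pool a later
fraction can repopulate.  After the last segment no integration to large
times is needed: the closure li(∞) = li(T) + ε_i·fi(T), lc(∞) = lc(T) +
ε_c·fc(T) is exact because the post-exposure system is autonomous.

The low-dose-rate limit drops the clustered pathway entirely (no two DSBs
ever coexist) and propagates the reduced (f0, fi, li) system the same way.
Its −ln S has first-order coefficient ε_i·dsb_yield and a small *negative*
second-order coefficient: a second lethal event in an already-lethal
domain causes no further harm, bending survival curves slightly upward.

Units are fixed throughout: hours, Gy, Gy/h; conversions are the caller's
responsibility.

## Split-dose closed form

For two acute fractions separated by a gap t1, the domain bookkeeping
(Poisson loading, single-exponential decay of each class during the gap
with lethal share ε_x, Poisson reloading of the non-lethal pool) gives a
closed form that the test suite pins against two exact identities: at
t1 = 0 it equals the acute survival of the summed dose (algebraic identity
of the Poisson weights), and at t1 → ∞ it satisfies −ln S = 2L1 − L1²/N_L
(full sublethal recovery; the quadratic term is the overlap of lethal
domains).  The closed form agrees with the two-pulse kinetic route to
<1e−8 on −ln S across all fixture parameter sets.

Two fine points surfaced by exact propagation: recovery S(d, t1) is not
perfectly monotone in t1 — parameter sets with large ε_c show dips of
order 1e−6 from slow-phase bookkeeping — and the distance to the
infinite-gap plateau at t1 = 10·HLT_i is governed by the *fast* phase's
amplitude n_i⁺·Δℓ·2⁻¹⁰ (Δℓ the per-domain lethality gap between an
unprocessed and a processed isolated DSB) plus an exactly computable
slow-phase term n_c⁺·e^(−k_c·t1)·(1−ε_c)·(ε_i p1 + ε_c p_m).  Both are
asserted quantitatively in the tests.

## LQ correspondence

The Lea-Catcheside factor uses the standard constant-rate form
G = 2(rT − 1 + e^(−rT))/(rT)², with the restitution rate identified with
the total processing rate of isolated DSBs, r = k_i = ln 2/HLT_i (isolated
DSBs carry the linear term, and only the linear-term lesions enter G).
The kinetic model's equivalent is g_equiv = c2/β: the second-order Taylor
coefficient of −ln S in dose at D = 0 for fixed protraction time T,
normalized by the static β, so g_equiv(T→0) = 1 by construction.

c2 (and a consistency check on c1) are extracted by one-sided finite
differences on the dose grid {h, 2h} with Richardson extrapolation between
h = 0.05 Gy and h/2; with exact propagation the c1 identity
c1 = ε_i·dsb_yield holds to ~1e−8 relative, and any violation beyond 1e−4
raises rather than returning a silently degraded coefficient.  On the
self-consistent hypothetical parameter sets (α/β = 1 and 14.4 Gy) the two
factors agree within 1.2% wherever G ≥ 0.05; the relative deviation grows
without bound at long protraction because the kinetic model keeps a finite
second moment while G → 0.

## Deterministic effects

The empirical inverse-dose-rate law D50(Ḋ) = d50_acute + slope/Ḋ is
implemented with the published endpoint constants (pneumonitis 10 Gy,
30 Gy²/h; bone marrow syndrome 3 Gy, 0.07 Gy²/h).  The mechanistic
counterpart solves constant_rate_survival(D, Ḋ) = acute_survival(D_ref)
by Brent root finding on the strictly decreasing −ln S, with the bracket
grown geometrically from D_ref and an absolute dose tolerance of 1e−4 Gy.
Endpoint lethalities come from the α/β ratio via the inverse LQ mapping
(the dose-rate effect depends only on ε_i/ε_c, not the absolute values,
which the tests verify by joint rescaling).  HLT_i defaults to 0.5 h, the
median of the fixture calibrations; the pneumonitis prediction tracks the
empirical law within 7.4% over 3–100 Gy/h and deviates below ~3 Gy/h,
where the empirical law diverges but the isoeffective dose converges to
the finite low-dose-rate root.  With the same machinery the bone-marrow
shift at 1 Gy/h is +19.7% of the 3 Gy reference — confirmed independently
by an LQ + Lea-Catcheside calculation — i.e. several-fold weaker than
pneumonitis's at the same rate.

## Fitting

Calibration minimizes Σ(ln S_model − ln S_obs)² over (ε_i, ε_c, HLT_i)
with `scipy.optimize.differential_evolution` (popsize 15, maxiter 150,
tol 1e−8, deferred updating, L-BFGS-B polish), deterministic for a given
seed.  The search box is ε ∈ [0, 1] and HLT_i ∈ [0.01, 24] h — wide
enough to contain every fixture value with margin — and boundary hits are
reported in the result.  HLT_c is fixed at 5 h by default (profiling it
over 2–10 h moves the normalized SSR by <5%); n_domains and dsb_yield are
structural constants.  Model survival inside the objective is dispatched
by schedule type: static closed form for acute, two-fraction closed form
for splits, batched matrix-exponential propagation for constant-rate
exposures.  Non-finite candidate survivals return a large penalty (1e12)
rather than raising, so the global search can traverse pathological
corners of the box.

## Synthetic data

The generator emulates clonogenic-assay designs: a dose grid measured at
each of several constant dose rates, or a two-fraction design over a grid
of gaps.  Noise is additive Gaussian on ln S (multiplicative lognormal on
the surviving fraction) with default σ_lnS = 0.15, ~16% CV, typical of
clonogenic scatter, and matches the fitter's least-squares-on-ln S error
model by construction.  Draws are seeded and reproducible; survivals
pushed above 1 by noise at near-zero dose are clipped to 1.

Default study designs used by the tests and the acceptance script:
noise-free recovery uses 3 dose rates × 6 doses (90, 4.56, 0.96 Gy/h ×
1–10 Gy); the noisy study uses 4 dose rates × 10 doses (adding
0.29 Gy/h), n = 40, σ_lnS = 0.15, 20 replicates.  Rates span the range of
the published experiments (0.06–90 Gy/h) and bracket the fast-repair
half-life, which is what makes HLT_i identifiable.

What the generator does *not* emulate: plating-efficiency and
colony-counting error structure, cell-cycle redistribution during long
exposures, inter-experiment calibration offsets, and dose-measurement
uncertainty.  Passing recovery tests therefore demonstrate internal
consistency of model + objective under the assumed error model, not
robustness to the full error structure of real clonogenic data.

## Fixture tables

The published calibrations for 17 cell lines (dose-rate experiments) and
5 cell lines (split-dose experiments) ship as fixtures, along with repair
half-lives from exponential-recovery fits and from the Incomplete Repair
and Lethal Potentially Lethal models for cross-model comparison.  Summary
statistics computed from them: median HLT_i = 0.485 h for the dose-rate
fits (excluding the two outliers HX32 and CHO 10B2, whose 5.7/6.1 h are
outside the biphasic-repair range) and 0.458 h for the split-dose fits.
These tables are inputs, not outputs: the underlying experimental survival
data are not bundled, so the original fits are not re-derived here.

## Known limitations

* Piecewise-constant dose-rate profiles only; continuously varying
  profiles must be discretized by the caller.
* No per-cell stochastic simulation — all quantities are population
  averages.
* No confidence intervals on fitted parameters.
* Cell lines with a dose-rate effect despite linear acute survival curves
  (dose-rate-dependent initial slopes) are outside the model's structure:
  the linear component is protraction-independent by construction.
* High-LET radiation and explicit nm-scale damage complexity are out of
  scope; ε_i is an effective lethality averaging over DSB complexity.
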