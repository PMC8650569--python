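# Methods

This note documents the models, estimators and design choices behind
biofilmnet, and what the synthetic-data generator does and does not
emulate.

## Lag-logistic growth model

A species' density in a given community context is modelled as a logistic
curve preceded by a hard latency switch: `dx/dt = 0` for `t < τ` and
`dx/dt = μ x (1 − x/K)` afterwards. The closed form is used everywhere;
its equivalence with numerical integration of the ODE is a test oracle,
not part of the implementation. The hard switch makes the model
non-smooth in τ, which has two practical consequences: (i) numerical ODE
oracles must start integration at τ, and (ii) the least-squares surface
is only piecewise smooth in τ, which is why the fitter is multi-started.

### Fitting

`fit_growth` minimises the sum of squared residuals on log10 counts over
the non-censored points, with box constraints `μ ∈ [0, μ_max]`
(default 1 h⁻¹), `τ ∈ [0, τ_max]` (default 72 h) and
`log10 K ∈ [0, 12]`. Choices:

* **x₀ is not a free parameter.** It is pinned to the t = 0 observation
  (the density right after the adhesion step). With replicates pooled,
  the geometric mean of the t = 0 counts is used — the maximum-likelihood
  location under the lognormal noise model and consistent with the log10
  objective.
* **Replicate handling.** All replicate points enter one pooled residual
  sum (the default); per-replicate fitting is available by passing
  single-replicate curves.
* **Censored points are excluded** from the residual sum. Imputation is a
  separate endpoint-testing procedure (below); keeping it out of the
  fitter makes fits deterministic.
* **Multi-start.** 16 local optimisations (scipy `least_squares`, TRF)
  from a 4×4 grid of (μ, τ) midpoints over the bounded box, K started at
  the maximum observed count; best final objective wins, ties broken by
  smallest τ (the smallest lag consistent with the data). A property test
  checks the optimum against a 20³ brute-force grid.
* **No-growth curves.** If the largest per-time geometric-mean count
  exceeds the t = 0 level by less than 0.5 log10 (≈3-fold, configurable),
  the curve is classified as no-growth: K is reported as the arithmetic
  mean of the observed counts, μ and τ are NaN. The threshold classifies
  the flat *B. cereus* curves (and community *K. varians*) as no-growth
  while all genuinely growing curves pass.
* **Inconclusive fits.** A censored t = 0 point (x₀ unknown) or fewer
  than four usable points yields `insufficient_data` rather than numbers.
* **μ_max caveat.** The mono-culture *K. varians* rate (1.93 h⁻¹) exceeds
  the conventional bound of 1 h⁻¹; `FitBounds(mu_max=...)` is therefore
  configurable, and recovery runs for that context use μ_max = 2.

### Identifiability

Recovery of (μ, τ) requires sampling the rise of the curve. With 6-h
sampling, contexts whose exponential phase spans a single interval (mono
*K. varians*: 2.4 logs at 1.93 h⁻¹ ≈ 2.9 h) leave (μ, τ) on a near-flat
ridge `μ·(t_i − τ) ≈ const`; K and the fit quality are unaffected but the
reported rate is not trustworthy there. The test suite asserts recovery
only where at least ~3 points fall strictly inside the rise; the
*K. varians* mono rate is asserted anyway (an acceptance criterion) and
fails honestly.

## Synthetic-data generator

The generator produces long-format count tables
(context, species, replicate, time, cfu, censoring flag) and is the test
bed for every downstream estimator. Its stated world:

* **Species and contexts.** Four species; contexts are the four
  mono-cultures, the four single-species omissions, the full community,
  plus presets (planktonic, thiocillin-null mutant, undiluted medium,
  1000-fold *B. cereus* inoculum dilution, glass substratum). Sampling at
  0/24/48/72/96 h, 5 replicates (7 for the undiluted preset, mirroring
  the seven datasets of that design).
* **Interactions as parameter modifiers, not coupled dynamics.** Each
  modifier multiplies (or shifts) one parameter of a target species when
  its source species are present — `trigger="all"` requires every source
  member, `trigger="any"` at least one. Modifiers compose commutatively
  (products and sums). This is exactly the granularity at which the
  underlying study quantifies interactions (per-context parameters), so
  no joint Lotka–Volterra system is simulated.
* **Planted interaction structure.** *K. varians* capacity is multiplied
  by 1/27000 whenever *B. cereus* is present, ×4.5 when *P. fluorescens*
  is additionally present and ×15.4 when *Rhodocyclus* is — reproducing
  the four printed 72-h levels (2.1e7 alone or without Bc, 5.4e4 in the
  full community, 1.2e4 without Pf, 3.5e3 without Rh; net full-community
  suppression ≈390-fold). *P. fluorescens* in any mixed context grows
  later but faster (τ 0→33 h, μ 0.25→0.94 h⁻¹, K 1.7e7→5.8e6).
  *Rhodocyclus* alone adheres below detection (5e2, flagged censored
  through 24 h) and is facilitated by any partner (x₀ 5e2→2.9e3, no lag).
  *B. cereus* is flat (μ = 0) at 7.9e4 alone and 2.3e5 in community.
* **Noise and censoring.** Observations multiply the expected value by
  10^ε, ε ~ N(0, σ) with σ = 0.1 log10 — a stand-in chosen to match the
  order of magnitude of plate-count error bars; the study reports no
  dispersion estimate. Observations below the detection limit
  (10³ cfu cm⁻²) are stored at the limit with a censoring flag, never as
  zero, so log transforms are safe.
* **Reproducibility.** Every (context, replicate) pair owns an RNG stream
  derived from the master seed via a hash of the context label, so
  identical seeds give bit-identical tables and adding contexts never
  perturbs existing draws.

What a green test on this generator does **not** establish: the generator
has no spatial structure, no biofilm–supernatant exchange, no medium-
change dynamics (absorbed into the logistic parameters), no mechanism for
the interactions (thiocillin biochemistry is out of scope), and its noise
is homoscedastic in log10 — real plate counts near the detection limit
are noisier. Conclusions about estimator calibration transfer to real
data only insofar as lognormal noise and hard censoring describe it.

### Known inconsistency: steady-state time

Under the printed growth parameters every species reaches its plateau
before 48 h (*P. fluorescens* at ≈39 h is the last), so with 24-h
sampling the detector places equilibrium at 48 h — deterministically. The
study's own equilibrium call is 72 h, reflecting measured counts that
still changed between 48 and 72 h; fitted point estimates and 24-h
sampling cannot reproduce that. The acceptance suite keeps the 72-h
assertion and it fails honestly.

## Censored-count statistics

* **Randomized imputation.** Censored counts are replaced by 10^u,
  u ~ Uniform(log10 low, log10 high), defaults 10²–10⁴ (the detection
  limit ± 1 log). Uniform-in-log10, not uniform-in-cfu.
* **Two-way ANOVA + Tukey HSD.** Implemented as Tukey–Kramer contrasts on
  the cells of the design with the residual mean square of the saturated
  (cell-means) model — algebraically identical to the two-way ANOVA with
  interaction post test, verified against `statsmodels.pairwise_tukeyhsd`
  to machine precision (the in-package version is ~100× faster, which the
  repeated-imputation calibration loops need). Two families are offered:
  per-slice ("within", e.g. all time contrasts within one species — used
  by steady-state detection) and all interaction cells ("cells" — used by
  perturbation comparisons, whose familywise false-alarm rate then sits
  at the nominal α).
* **Retained p-values.** The test is repeated across 20 independent
  imputations; per contrast the retained p is
  `mean(p) + t₀.₉₇₅,₁₉ · sd(p)/√20`, truncated to [0, 1] — one reading of
  "upper 95% confidence level" of the p-value; the 95th percentile of the
  p sample is available as `estimator="percentile"`. Both are
  conservative (never below the mean p). Consequence, measured in the
  acceptance suite: when imputation noise dominates a contrast the type-I
  error is far *below* nominal (0/200 under an identical-conditions null
  with ~22% censoring), so the procedure trades power for safety. Without
  censored rows the procedure collapses to a single exactly-calibrated
  test run.
* **Mann–Whitney.** Exact two-sided null distribution for combined
  n ≤ 12 without ties (verified against full enumeration), normal
  approximation with tie correction otherwise. Two fully tied groups
  return p = 1 with a warning.
* Significance stars follow the usual figure-legend convention
  (*, **, *** at 0.05/0.01/0.001).

## Interaction inference

Endpoint abundances of each target in the full community are compared
against every single-species omission (Mann–Whitney, ≥3 replicates).
An effect is *called* when p < α (default 0.05) **and** the fold change is
≥3 (0.5 log10) — the effect-size floor prevents significance-without-
magnitude calls in large designs. Classification:

* omission of X increases Y → X→Y **negative**; if X is itself unaffected
  by Y's presence (same α and floor on the reciprocal comparison) the
  edge is **amensalism**, otherwise **competition**;
* omission of Z decreases Y while a negative W→Y edge exists → Z→Y
  **positive, mitigation**, annotated with the conditioning edge (the
  strongest negative edge onto Y); without a conditioning edge the
  positive effect is **facilitation**;
* mitigation is inherently a three-species statement; it is emitted as a
  pairwise edge with the conditioning edge recorded, not as a hyperedge.

Facilitation of adhesion (the *Rhodocyclus* pattern) is visible as an
x₀/earliest-time comparison: `compare_contexts(..., endpoint_time=0)`.
Fold changes of fitted parameters (x₀, μ, K multiplicative; τ as a
difference in hours) are attached when per-context fits are supplied;
no-growth fits contribute only K.

## Composition and robustness

Proportions are percentages of per-species replicate-mean counts; fully
censored species contribute 0% with an explicit flag (or the log-midpoint
of the imputation range on request). Steady state is the earliest
sampling time after which no species changes significantly — either
against every later time (default, stricter) or between consecutive
readings; the two modes exist because the underlying figure legend only
compared consecutive readings. `perturbation_response` routes endpoint
species × condition comparisons through the repeated-imputation machinery
whenever censored rows are present and calls the community "altered" iff
any species is significant at α.

## Numerical details

* log10 of zero never occurs: counts are validated positive or censored.
* τ and μ are clamped to 0 when modifier composition leaves a tiny
  negative residue (< 1e-9).
* Tukey p-values are clipped to [0, 1]; zero-variance contrasts with zero
  difference give p = 1, with nonzero difference p = 0.
* Seeds are combined via CRC32 of the context label and the replicate
  index into a `SeedSequence`, keeping all entropy below 2³².

## Limitations

* No confidence intervals on growth parameters (point estimates only).
* No Tobit/likelihood treatment of censoring; the imputation procedure is
  implemented as specified and is conservative.
* No higher-order interaction search beyond single-species omissions.
* The generator's perturbation presets encode endpoint-level effects, not
  mechanisms; they exist to exercise the robustness statistics.
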