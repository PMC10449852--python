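# Methods

## Model

The package describes a single-substrate, single-product enzyme by the
two-step scheme E + S ⇌ ES → E + P (optionally ES ⇌ E + P for the
reversible variant).  Its thermodynamic state is the pair (ΔG₁, ΔG_T): the
free energy of complex formation and of the overall reaction, with
ΔG₂ = ΔG_T − ΔG₁ enforced by construction.  Kinetics follow from two
empirical ingredients:

1. **BEP relation** — each elementary step's activation barrier is linear
   in its driving force, E_a = E_a⁰ + α·ΔG, with sensitivity α ∈ (0, 1).
   The reverse barrier sensitivity is 1 − α, so each step individually
   satisfies detailed balance.
2. **Arrhenius law** — barriers map to rate constants; the pre-exponential
   factor and the equilibrium barrier are folded into a single reference
   constant k⁰ ≡ A·exp(−E_a⁰/RT), which is why neither A nor E_a⁰ appears
   anywhere in the API.

The resulting rate constants (see `enzact.thermo`) automatically satisfy
the Haldane identity k₁k₂/(k₁ᵣk₂ᵣ) = exp(−ΔG_T/RT); this is asserted
property-style over randomized landscapes rather than imposed.

Key consequences implemented and tested:

* K_m = g₁(1+K) with K = k₂⁰g₁^(α₁+α₂−1)/(k₁⁰g_T^(α₂)); identical to the
  kinetic definition (k₁ᵣ+k₂)/k₁.
* Activity v = k₂[S][E_T]/(K_m+[S]) is single-peaked along ΔG₁; for
  α₁+α₂ = 1 the maximizer satisfies [S] = g₁((1−α₂)/α₂ + (α₁/α₂)K), i.e.
  K_m = (α₂/(1−α₂))[S], and K_m = [S] when α₁ = α₂ = 0.5.
* log k₂ = α₂ log K_m + const along any ΔG₁ sweep with α₁+α₂ = 1: turnover
  and affinity cannot be improved independently.

## Parameters, units, defaults

| parameter | meaning | default | why |
|---|---|---|---|
| ΔG₁, ΔG_T | binding / total free energy, kJ/mol | — | decision variables |
| α₁, α₂ | BEP sensitivities | 0.5 | unbiased forward/backward sensitivity; typical experimental range 0.3–0.7 |
| k₁⁰ | reference binding rate, 1/(µM·s) | 1 | reference simulation convention |
| k₂⁰ | reference turnover, 1/s | 1 | idem |
| T | temperature, K | 298.15 | conventional biochemical reference; R = 8.314×10⁻³ kJ/(mol·K) |
| [E_T] | enzyme concentration, µM | 0.01 | small relative to [S] so [S] is quasi-constant |
| γ | degree of inhibition [I]/K_i | 10 in robustness scans | upper range of experimentally common values (~80% of observed γ are below 10) |
| grid | ΔG₁ ∈ [−60, 20], ΔG_T ∈ [−80, 0], 400×400 | — | typical biochemical driving forces span −80…+40 kJ/mol; forward reactions need ΔG_T < 0 |

Concentrations are µM throughout; a change of concentration unit is a shift
of ΔG₁ by RT·ln c (the binding standard state is folded into g₁), under
which K_m/[S] and v/(k₂E_T) are invariant (tested).

## Numerical choices

* Exponentials are assembled in log space; landscapes with |ΔG/RT| > 500
  are rejected with a range error rather than silently saturating.
* `optimize_numeric` is a derivative-free bounded scalar search on ΔG₁ over
  [ΔG_T − 60, +60] kJ/mol (Brent-style bounded minimization followed by a
  golden-section polish to 10⁻¹⁰ kJ/mol).  Derivative-free bracketing was
  chosen because the rate is smooth and single-peaked in every supported
  regime, including mechanisms with no closed-form optimum.  Results at a
  bracket edge are flagged `boundary=True` and warned about, not hidden.
* The closed-form optimum is exposed only for α₁ + α₂ = 1.  Outside that
  regime K itself depends on g₁, the stationarity condition is implicit,
  and the numeric path is authoritative (closed form and numeric agree to
  <10⁻⁶ kJ/mol whenever both apply; tested).
* Ridge extraction on activity grids takes the per-ΔG_T argmax over ΔG₁,
  ties broken toward the more negative ΔG₁ (deterministic output).
* The reversible net rate uses the unique steady-state solution of
  E+S ⇌ ES ⇌ E+P, v = E_T(k₁k₂[S] − k₁ᵣk₂ᵣ[P])/(k₁[S] + k₂ᵣ[P] + k₁ᵣ + k₂).
  Cells with v ≤ 0 in grids (net reverse reaction) are flagged, never
  masked with fabricated values.
* Histogram Gaussian fits: fixed bin width (default 0.25 log₁₀ units,
  configurable), bins aligned to multiples of the width, unweighted
  least-squares of A·exp(−(x−µ)²/2σ²) against bin counts
  (`scipy.optimize.curve_fit`, initialised at the sample moments).  Sample
  mean/SD are always reported alongside the fit.  Degenerate inputs (n <
  10, or all values identical) raise instead of returning a sham fit.

## Robustness metric (the "57%" convention)

For inhibition scans the package reports the **symmetric relative
difference** |v_opt − v_rule| / mean(v_opt, v_rule) between the activity at
the true optimal K_m and at K_m = [S].  For competitive inhibition at
α = 0.5 this has the closed form 2(1−r)/(1+r) with r = 2√(1+γ)/(2+γ),
independent of ΔG_T — about 57.6% at γ = 10 even though the two K_m values
sit a factor 1+γ = 11 apart.  Alternative conventions (shortfall relative
to the optimum: 44.7%; excess relative to the rule: 80.9%) are trivially
recoverable from the scan's `v_rule`/`v_opt` arrays; the symmetric one is
the package's reporting convention.

## Synthetic data: what it emulates, what it does not

`generate_km_dataset` emulates the statistical structure of the reference
wild-type K_m vs in-vivo concentration compilation (1703 entries: 980
major-metabolite entries with log₁₀(K_m/[S]) ~ N(−0.18, 1.3²) spread over
40 substrates of ≤ 50 entries each; 410 cofactor entries at −0.43 over 5
substrates; 313 single-substrate "ATP" entries at −1.64).  The cofactor and
ATP spreads (σ = 1.1 and 0.9) are the package's own choices of realistic
widths; only the centers carry reference values.  In-vivo concentrations
are log-uniform over 10⁻²–10⁴ µM, matching the ~6 decades real metabolome
data span; only the ratio statistics are scientifically meaningful.
Occurrence counts are split as evenly as possible within each category,
which guarantees the class thresholds; real occurrence distributions are
heavy-tailed, so tests passing on synthetic tables validate the pipeline's
bookkeeping and estimators, not any biological claim.  The generator also
does not emulate enzyme-class or organism covariance, measurement error
structure, or correlated K_m–[S] errors.  Randomness: one
`numpy.random.default_rng(seed)` stream per call, consumed per category as
(ratios, concentrations); fixed seeds give byte-identical CSV output.

`generate_landscapes` draws landscape/condition fixtures uniformly over
safe ranges (|ΔG| ≤ 100 kJ/mol, α ∈ [0.05, 0.95] by default) for the
property suites; `complementary_alphas=True` restricts to α₂ = 1 − α₁.

## Dataset pipeline conventions

* Units must be declared per concentration column (BRENDA K_m are
  conventionally mM; metabolome [S] are often µM; silent mixups are the
  main corruption risk).  Everything is converted to µM on load.
* log₁₀(K_m/[S]) is always recomputed from the loaded concentrations, never
  trusted from a file column.
* Occurrence classes: ≤ 50 → major metabolite, 51–299 → cofactor,
  ≥ 300 → ATP-like.  The published class labels use strict inequalities
  without boundary cases; the boundary convention here assigns 50 down and
  300 up.
* Duplicate (enzyme, substrate) rows are retained — the statistics count
  entries, not unique pairs.
* Rows with missing or non-positive concentrations are dropped and counted
  per reason in the load report.

## Problem sizes

The test suite runs grids up to 400×400 (the default panel resolution),
dense 1-D scans up to 2×10⁵ points as brute-force oracles for the
optimizer, 10⁴ random landscapes for the Haldane property suite, and 10⁵
draws for Gaussian-recovery checks; the whole suite completes in a few
seconds on one core.  `scripts/acceptance.py` uses an 81-point ΔG_T scan
for the robustness maximum (the quantity is analytically constant along
ΔG_T at α = 0.5, so resolution is uncritical).

## Known limitations

* Steady-state rate laws only; no time-course ODE integration, and no
  treatment of regimes where the Michaelis–Menten steady-state assumption
  itself fails (e.g. diffusion-limited enzymes, substrate depletion).
* The BEP relation is empirical; systems that break it (3-D active-site
  preorganisation, Marcus-inverted redox chemistry) are outside the model.
* Substrate inhibition and allosteric/Hill mechanisms are not implemented.
* The closed-form inhibited optima K_m* = [S]/(1+γ) (competitive) and
  [S](1+γ) (uncompetitive) are validated against the numeric optimizer at
  α = 0.5 rather than assumed; for general α only the numeric route is
  offered.
* The concordance analysis is only as good as its input table; no live
  BRENDA/Sabio-RK querying and no organism-level stratification beyond the
  organism column carried through.
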