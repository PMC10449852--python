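# enzact — thermodynamic optimality of enzyme kinetics

`enzact` is a Python package for asking a deceptively simple question: given
a fixed free-energy budget, how should an enzyme distribute driving force
between substrate binding (E + S → ES) and product release (ES → E + P) to
maximize its activity?  It is aimed at enzyme engineers and systems
biologists who want a quantitative handle on the trade-off between turnover
(k₂ = k_cat) and binding affinity (K_m).

## The model

The Michaelis–Menten rate

    v = k₂ [S] [E_T] / (K_m + [S]),      K_m ≡ (k₁ᵣ + k₂)/k₁

is coupled to the free-energy landscape through the
Brønsted–Evans–Polanyi (BEP) relation, E_a = E_a⁰ + α·ΔG, and the Arrhenius
law.  Writing g₁ = exp(ΔG₁/RT), g_T = exp(ΔG_T/RT):

    k₁  = k₁⁰ g₁^(−α₁)        k₁ᵣ = k₁⁰ g₁^(1−α₁)
    k₂  = k₂⁰ (g₁/g_T)^(α₂)   k₂ᵣ = k₂⁰ (g_T/g₁)^(1−α₂)
    K_m = g₁ (1 + K),         K ≡ k₂⁰ g₁^(α₁+α₂−1) / (k₁⁰ g_T^(α₂))

These satisfy the Haldane identity k₁k₂/(k₁ᵣk₂ᵣ) = exp(−ΔG_T/RT) by
construction.  Because ΔG₁ + ΔG₂ = ΔG_T is fixed, activity is single-peaked
along ΔG₁, and for α₁ = α₂ = 0.5 the peak sits exactly at

    K_m = [S]

— the enzyme is fastest when its Michaelis constant matches the substrate
concentration it operates at.  For α₁ + α₂ = 1 the optimum generalises to
K_m = (α₂/(1−α₂))·[S]; for arbitrary α's the package finds it numerically.
The same machinery quantifies how robust the rule is under reverse
reactions and competitive/uncompetitive inhibition, and the companion
dataset pipeline checks the rule against wild-type enzymes by comparing
BRENDA K_m values with measured in-vivo metabolite concentrations via the
log-ratio log₁₀(K_m/[S]).

Units throughout: kJ/mol for energies, µM for concentrations, seconds for
time, T = 298.15 K by default.

## Worked example

Find the activity-maximizing landscape at [S] = 10 µM with a typical
driving force ΔG_T = −40 kJ/mol:

```
$ enzact optimize --S 10 --dGT -40
{
  "dG1_star": -14.293084621925871,
  "Km_star": 9.999999821866602,
  "v_star": 0.8931484922431268,
  "method": "numeric",
  "denominator_f_value": 357.3713252954424,
  "boundary": false
}
```

The optimizer puts −14.3 kJ/mol of driving force into binding, which makes
K_m equal the substrate concentration (10 µM) — the K_m = [S] rule — and
the rate at the optimum, 0.89 µM/s, is exactly half of k₂[E_T]
(half-saturation is a signature of the apex).  The same applies from
Python:

```python
from enzact import ThermoLandscape, AssayCondition, optimize_numeric

template = ThermoLandscape(dG1=0.0, dGT=-40.0)   # alpha = 0.5, k0 = 1
result = optimize_numeric(template, AssayCondition(S=10.0, ET=0.01))
print(result.Km_star)   # 9.999999821866602
```

The dataset side: generate a synthetic K_m–[S] table with the reference
structure (1703 entries over three occurrence classes) and run the
concordance analysis:

```python
from enzact import generate_km_dataset, KmConcordance

df = generate_km_dataset(seed=42)
res = KmConcordance.from_dataframe(df.drop(columns="category"),
                                   units={"Km": "uM", "S": "uM"}).fit()
print(res.summary())
```

```
Km vs in-vivo [S] concordance
==================================================================
entries: 1703   histogram bin width: 0.25 log10 units
overall fraction log10(Km/[S]) > 3: 0.0035 (6 entries)
------------------------------------------------------------------
category               n      mu   sigma  |r|<=1    Km<S     r>3
major_metabolite     980   -0.21    1.25    0.57    0.56    0.01
cofactor             410   -0.37    0.95    0.64    0.66    0.00
ATP                  313   -1.62    0.90    0.27    0.95    0.00
------------------------------------------------------------------
mu, sigma: Gaussian fitted to the log10(Km/[S]) histogram
```

The per-category Gaussian centers (µ ≈ −0.2 for rarely shared metabolites,
strongly negative for ATP, whose effective concentration is lowered by
enzyme competition) recover the generator's ground truth, validating the
load → categorize → histogram-fit pipeline end to end.  Point
`KmConcordance.from_csv` at a real table (declaring the units, e.g.
`{"Km": "mM", "S": "uM"}`) to analyze experimental data.

Other entry points: `enzact grid` (activity over the (ΔG₁, ΔG_T) plane plus
its ridge), `enzact volcano` (v vs K_m curves), `enzact scaling` (the
log k₂–log K_m scaling law with slope α₂), `enzact mechanism-grid`
(reverse-reaction and inhibition variants with the K_m = [S] line and the
true-optimum line), `enzact simulate-dataset` / `enzact analyze-dataset`.

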