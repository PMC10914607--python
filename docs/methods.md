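# Methods

## Model structure and assumptions

The community model is a deterministic, well-mixed batch adaptation of a
chemostat cross-feeding framework.  State variables: glucose *G* (g l⁻¹),
exchanged metabolites *xᵢ* (mg l⁻¹), strain biomasses *yᵢ* (OD₇₀₀ units),
plus intermediate and product concentrations (µM) when the
division-of-labour pathway is enabled.  Assumptions:

- **Monod uptake** for glucose and every exchanged metabolite; no
  competition terms beyond shared substrate pools.
- **Proportional leak**: a strain diverts a fixed fraction ϕ of its
  instantaneous glucose uptake flux to overproduction of its donated
  metabolite (`J_leak = ϕ·δ·J_upt,G`, stoichiometry δ = 1 by default).  ϕ is
  the model's proxy for promoter-tunable enzyme expression.
- **Liebig growth**: `J_grow = min(γ_G(1−Σϕ)·J_upt,G, min_j γ_j·J_upt,j)` —
  growth runs at the rate allowed by the scarcest requirement.  The min() is
  integrated as-is with a stiff solver rather than smoothed; a log-sum-exp
  soft-min variant is available behind `SimulationConfig.smooth_min` for
  solver-robustness comparisons only.
- **First-order death** η, applied to biomass independently of nutrition.
- Dead biomass neither consumes nor releases anything; no lysis recycling,
  no spatial structure, no stochastic birth–death, no genome-scale
  metabolism.

Optional extensions, both off by default:

- **Toxicity**: growth is multiplied by a Hill inhibition factor
  `Π 1/(1+(xᵢ/θᵢ)^n)` (default n = 2) for metabolites with configured
  thresholds θ.  The functional form is this package's assumption; only the
  qualitative property (monotone attenuation above a threshold) is
  constrained by the phenomenon being modelled.
- **Division-of-labour pathway**: the upstream strain diverts an additional
  fraction `phi_upstream` of glucose flux to an intermediate
  (p-coumaric-acid-like); the downstream strain converts intermediate to an
  inert product by Monod kinetics scaled by its biomass.  This is the
  minimal two-stage structure consistent with an upstream-synthesis /
  downstream-conversion split; intermediate export/import is treated as
  passive and lossless.

## Units and nominal parameterisation

Biomass is kept in OD₇₀₀ units, glucose in g l⁻¹, metabolites in mg l⁻¹ —
the units of the biological parameter ranges used for sensitivity analysis —
with the yields carrying the conversions (γ_G in OD per g l⁻¹, γ_j in OD per
mg l⁻¹).

The nominal set (`syntroph.scenarios.NOMINAL`) is calibrated to the growth
physiology these engineered communities display in plate-reader batch
culture, not fitted to any dataset:

| parameter | value | rationale |
|---|---|---|
| G₀ | 20 g l⁻¹ | standard 2% glucose medium |
| N₀ | 0.1 OD₇₀₀ | centre of the experimental inoculum catalogue |
| γ_G | 0.05 OD per g l⁻¹ | 20 g l⁻¹ glucose yields ≈1.0 OD₇₀₀ |
| V_max,G | 1.33 g h⁻¹ OD⁻¹ | with γ_G and k_M,G gives μ_max ≈ 0.055 h⁻¹, so a prototroph exhausts G₀ in ≈2 days and a ϕ = 0.5 producer just inside the 72 h window |
| k_M,G | 2 g l⁻¹ | weak glucose saturation effect over most of the batch |
| V_max,j | 60 mg h⁻¹ OD⁻¹ | mid-range of the biological interval [1, 120] |
| k_M,j | 100 mg l⁻¹ | low-mg/l amino-acid uptake affinity; with γ_j below, a nominal 1:1 mutualistic pair reaches the "strong" growth class (OD₇₀₀ ≥ 0.5) within 72 h |
| γ_j | 0.5 OD per mg l⁻¹ | trace-requirement yield; same calibration as k_M,j |
| η | 0.01 h⁻¹ | slow decay, an order below μ_max |
| ϕ | 0.25 | mid leak fraction of the engineerable range [0.01, 0.5] |

The slow μ_max is deliberate: these auxotroph/overproducer communities grow
far below wild-type yeast rates, and the 72 h assay window is an integral
part of the reported behaviours (the ϕ-productivity peak at 0.5 emerges
precisely because high-ϕ producers cannot finish their batch within the
window).

## Metrics

- **Batch culture time**: first time G(t) ≤ ε_G·G₀ (ε_G = 10⁻³), linearly
  interpolated between grid points and capped at t_end.  A
  population-plateau definition would also be defensible; the
  glucose-exhaustion definition is robust to metabolite-limited stalls and
  is configurable via ε_G.
- Maxima (growth rate, uptake, production, metabolite concentration) are
  taken on the dense output grid; the refinement-stability test bounds the
  discretisation error (<0.1% when halving the step).  Rates are specific
  (per unit biomass): growth in h⁻¹, uptake/production fluxes in substrate
  units h⁻¹ OD⁻¹.
- **Degenerate composition**: if total biomass is ~0 throughout, final
  ratios are reported as the inoculum ratios with a flag, keeping
  sensitivity-analysis outputs finite.
- **Productivity** = product(t_end)/t_end; **yield ratio** =
  product(t_end)/glucose consumed.  Reported as absent (None), not zero,
  when no pathway is configured.

## eFAST implementation

Classical eFAST construction: for each *focus* parameter, all k parameters
move along `x = low + range·(½ + arcsin(sin(ω s + φ))/π)` over
s ∈ (−π, π) at Ns points; the focus parameter carries
ω = ⌊(Ns−1)/(2M)⌋ and the k−1 complementary parameters carry distinct
frequencies ≤ ω/(2M) (M = 4 harmonics retained; Ns must be odd and
≥ 4M²+1).  First-order index: variance at ω and its first M harmonics over
total variance.  Total-order index: 1 − (variance in the complementary band,
frequencies ≤ ω/2)/total.  Each of the NR resamplings redraws all phases φ;
indices are reported as mean ± s.d. over resamplings.  Reference sizes are
Ns = 1285, NR = 100; desk-scale analyses in the tests use Ns = 129–257,
NR = 5–25.

- **Ratio simplex**: initial-ratio parameters are sampled independently on
  [0.01, 1] and renormalised per sample so the inoculum composition sums to
  one; this generalises the two-strain constraint r₀,₁ + r₀,₂ = 1 to any
  community size.
- **Dummy parameter**: varied, never applied.  Each parameter's Sᵢ and S_T
  distributions over resamplings are compared with the dummy's by a Welch
  two-sample t-test (pooled-variance variant configurable); a parameter is
  flagged significant when either index is larger than the dummy's and
  p < α/n_k with α = 0.01 and n_k the number of parameters varied in the
  analysis.
- **Failure policy**: a failed simulation row is replaced by linear
  interpolation along the search curve and counted; the analysis aborts if
  more than 1% of a curve's rows fail.  Rows are independent, so results do
  not depend on evaluation order.
- The default varied set for the two-member analyses is the headline set
  (ϕᵢ, x₀ᵢ, r₀ᵢ, each strain's glucose and metabolite V_max, dummy;
  n_k = 11), with K_M's and yields held at nominal;
  `pair_gsa_parameters(variant="full")` also varies N₀, the K_M's and the
  yields over their biological ranges.

Correctness is anchored to closed-form oracles (additive linear model;
Ishigami function, including its interaction-only total-order index) at
Ns = 1285, M = 4, within 0.05 absolute.

## Synthetic plate-reader generator

Emulates a kinetic microplate assay of one well: total OD₇₀₀ = Σyᵢ·(1+ε)
and per-channel fluorescence = (gain_c·y_c + background_c)·(1+ε), ε ~
N(0, σ²) i.i.d. per reading (multiplicative noise — plate-reader OD error
grows with signal), fully seeded, ground truth retained.  It does **not**
emulate lag phases, evaporation/condensation drift, spectral bleed-through
between channels, or flow-cytometry event data, so passing recovery tests
demonstrates the estimator pipeline's correctness under the stated noise
model, not robustness to every artefact of real plate data.

- **Subpopulation estimation** (channel-estimated OD traces): linear
  unmixing `ŷ_c = (F_c − background_c)/gain_c`, clipped at zero, then
  rescaled so channel estimates sum to the observed total OD.  Gains and
  backgrounds come from calibration constants (monoculture wells, in
  practice).
- **Parameter fitting**: trust-region-reflective least squares of simulated
  vs observed total OD with 5 seeded multi-starts (the Liebig kink creates
  local optima); free-parameter subset of {γ_G, V_max,G, k_M,G, η, ϕ} with
  broad positivity bounds.

## Numerical choices

- Integration: LSODA (automatic stiff switching) via `scipy`, rtol 10⁻⁸ /
  atol 10⁻¹⁰ by default; sensitivity sweeps use rtol 10⁻⁶ / atol 10⁻⁹ and a
  1 h output grid, which the refinement-stability bound shows is ample for
  the metrics.  The right-hand side is JIT-compiled with numba when
  available (a pure-Python fallback is part of the package).
- Flux evaluation clips state components at zero so tiny negative solver
  excursions cannot feed back into the dynamics; trajectories satisfy
  non-negativity to within 10× the absolute tolerance.
- Desk-scale problem sizes used by the test suite: eFAST at Ns = 257/NR = 25
  for the two-member growth-rate analysis, Ns = 129/NR = 5 with a
  3-seed majority vote for ordinal sensitivity rankings, an 11×11 (ϕ₁, ϕ₂)
  grid for the exchange-strength landscape, and 20 noise replicates for
  parameter recovery.  These sizes were chosen as the smallest at which the
  checked properties are stable across seeds.

## Known limitations

- The original nominal parameter set behind the reference analyses is not
  redistributable, so `NOMINAL` is a calibrated stand-in (see table above).
  Quantities that depend on the *ratio* of glucose-limited to
  metabolite-limited growth across the sampled space — e.g. the exact share
  of growth-rate sensitivity carried by a strain's own glucose V_max — are
  sensitive to that choice: under this parameterisation the own-V_max,G
  total-order share measures ≈0.6 of the summed index mass (dominant, but
  above the ≈0.5 reported for the original parameterisation), because the
  glucose branch of the Liebig min binds over most of the sampled space at
  mid-range metabolite-uptake nominals.  Ordinal results (which parameter
  ranks first) are stable across seeds and parameterisations we examined.
- eFAST total-order indices are biased upward by resampling noise (the
  dummy's S_T is ≈0.02–0.05 at desk scale); comparisons against the dummy,
  not against zero, are the supported significance statement.
- The pathway extension is a minimal two-stage structure; enzyme burden,
  intermediate toxicity and transport saturation are not modelled.
- Promoter ranks map to leak fractions through a configurable geometric
  series — ordinal fidelity, not measured promoter strengths.
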