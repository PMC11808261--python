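# Methods

## Kinetic model

Pyruvoyl-dependent L-aspartate-α-decarboxylase loses activity through a side
branch of its own catalytic cycle: misprotonation of the imine intermediate
converts the pyruvoyl cofactor into an inactive alanyl group.  The model
therefore couples inactivation to ES occupancy,

    dS/dt = −v,  dP/dt = +v,  v = k_cat·E_a·S/(K_M+S)
    dE_a/dt = −k_inact·E_a·S/(K_M+S),

rather than to wall-clock time.  A plain first-order alternative
(dE_a/dt = −k_inact·E_a) is available behind `coupling="time"` for comparison
with the common "time-dependent first-order" description; the two coincide
exactly at saturation (S ≫ K_M) and diverge at low substrate, where the
turnover-coupled enzyme is protected because it is not cycling.

Shared saturation factors give two exact linear invariants — substrate
conservation S+P=S₀ and E_a = E₀ − (k_inact/k_cat)·P — used as oracles for
every simulation: explicit Runge–Kutta methods preserve linear invariants
exactly, so any violation beyond round-off indicates a coding error, not an
integration error.

Assumptions: a single well-mixed compartment, no product inhibition or
reactivation, no tetramer cooperativity, temperature and pH constant
(annotations only).  The system is non-stiff at realistic parameter scales,
so the integrator is SciPy's adaptive RK45 at rtol 1e-8 / atol 1e-12.

### Units

I/O uses minutes and mM; rate constants are per second; enzyme is µM
(substrate/product mM).  All conversions live in `bsadc.units`, including
enzyme molarity from a mass loading (25 µg/mL of a ~14 kDa monomer ≈ 1.7 µM)
with a sequence-derived or user-supplied molar mass.

### Key parameters

| parameter | units | typical value | meaning |
|---|---|---|---|
| K_M | mM | 3–4 | Michaelis constant for L-aspartate |
| k_cat | 1/s | 4–8 | turnover number |
| k_inact | 1/s | 1e-4–1e-3 | inactivation per unit occupancy |
| E₀ | µM | 0.2–2 | active enzyme at t=0 |
| S₀ | mM | 40 | initial substrate |

Derived: partition ratio r = k_cat/k_inact (model-side total turnover
number); product plateau min(S₀, r·E₀); effective activity-decay constant
λ = k_inact·S₀/(K_M+S₀) and catalytic half-life ln 2/λ.

## Stability pipeline

`analyze_stability` mirrors the assay-side procedure: a zero-intercept
polynomial (default cubic, configurable 2–5) is least-squares fitted to
product vs. time; its analytic derivative is the instantaneous activity; the
derivative normalized to its t=0 value (defined as 100 %) is the residual
activity; 100·exp(−λt) fitted to that series gives λ and t½ = ln 2/λ.

Numerical choices:

- the intercept is pinned to zero because no product exists before the
  reaction starts, which also makes the t=0 derivative well defined;
- initial activity is the fitted derivative at t=0, not a separately
  measured early rate, keeping the 100 % normalization internally consistent;
- negative fitted derivatives (cubic edge artifacts) are clipped to 0 with a
  warning; the exponential fit trims such points rather than failing;
- extrapolation beyond the fitted time range is refused;
- half-life is read off the fitted exponential, not by inverse interpolation
  of the raw points;
- the empirical TTN uses the raw curve's plateau (last two points within 2 %
  relative, configurable) divided by the enzyme amount.

A cubic tracks a single exponential well only over about two half-lives: at a
36-min window the wild-type-like decay (t½ ≈ 18 min) is recovered to ~2 %
noiselessly, while a 60-min window (3.3 half-lives) biases λ low by ~6 %.
The closed-loop analyses therefore sample each variant over 2·t½ with 13
points; this window is also where residual activity stays meaningfully above
the noise floor.

A second bias source is physical, not numerical: the pipeline measures
*apparent* activity decay, and when the plateau r·E₀ approaches S₀ the
substrate itself depletes within the assay window, shortening the apparent
half-life relative to ln 2/λ.  The closed-loop driver uses 0.2 µM enzyme so
substrate stays saturating for all three variants; at the assay-scale 1.7 µM
loading the stabilized variants show exactly this depletion bias, which is a
property of the experiment design, not an estimator defect.

## Michaelis–Menten estimation

Initial rates are endpoint rates (product/duration over a 5-min simulated or
measured assay).  Two fitters: the unweighted double-reciprocal line of 1/v
on 1/S (K_M = slope/intercept, V_max = 1/intercept; standard errors by the
delta method), and direct nonlinear least squares on v = V_max·S/(K_M+S)
initialized from the reciprocal fit (tolerances 1e-14 so noiseless round
trips are exact to 1e-8 and better).  On noiseless data the two agree to
machine precision; under constant-absolute noise the nonlinear fit is
markedly better because reciprocals of small rates amplify noise, and the
suite asserts exactly that.  Under constant-CV (multiplicative) noise the
two are comparable on the default grid — the often-quoted inferiority of the
reciprocal fit is a constant-absolute-noise phenomenon, so no superiority
claim is made there.

Endpoint rates equal initial rates only while substrate depletion during the
assay is negligible; the round-trip analyses use a low loading (0.002 µM) for
that reason, while the generator's default conditions remain assay-scale.
k_cat = V_max/E₀ after unit conversion; catalytic efficiency k_cat/K_M is
always derived, never stored.

## Hydropathy

Kyte–Doolittle constants (from biopython's canonical table) averaged over a
uniform sliding window, no edge padding, so the first and last (w−1)/2
residues are unscored.  Window 9 with uniform weights reproduces all three
published Lys9 scores (−0.378 template, −0.678 after S7N, −0.433 after S7Y)
exactly, which fixes the convention; residues are "hydrophilic" when the
windowed score is strictly below −0.5.  Mutation strings are 1-based on the
unprocessed pro-protein; `*` truncates at the named residue (I126* leaves
125 residues of a 127-residue chain).  Non-standard residues are rejected
rather than scored 0.

The bundled pro-protein is a SYNTHETIC stand-in: the full sequence is not
distributed with the package, so `bsadc.datasets.synthetic_proprotein`
anchors every residue whose identity is pinned by published numbering
(M1, Y2, R3, the 5–13 = MMSGKLHRA stretch, G24/S25, Y58, K63, V68, I88,
S94/D95, A99, P103, S104/L108, N109, K113, M117, I126) and fills the rest
arbitrarily.  Lys9 window scores are exact because their windows lie wholly
inside the anchored stretch; profile values elsewhere are fixture-dependent
and are used only for relative, same-fixture comparisons.

## Recombination screen

Candidate combinations are the cross product of per-site residue menus
(S7:N/C/Y, A99:V/E/T, K113:R/E → 18 strings) merged with the fixed
K63N/I88M/I126* background, canonicalized (sites ascending, truncation last)
and ordered lexicographically.  ΔΔG_fold values are consumed as data and
ranked ascending with strict ddG < threshold (default 0) selection —
more-negative = non-destabilizing under the sign convention of the supplied
table.  A full relative-fitness recombination rule would need per-variant
fitness measurements, which are not part of the data model; the implemented
rule is the ΔΔG screen alone.

## Synthetic data

The generator emulates HPLC-style concentration readouts with additive
Gaussian noise, sd = σ_abs + σ_rel·value, truncated at 0 (defaults σ_rel 1 %,
σ_abs 0 — the simplest model consistent with a chromatographic readout; the
true assay noise is unknown).  Screening plates sample per-well kinetics from
a log-normal k_cat spread (σ=0.3 on the log scale) with a 5 % "beneficial"
tail (2× k_cat, ½ k_inact — a fixture convention, not an empirical claim) and
record signals proportional to product at the sampled times; the fluorescence
chemistry, plate-reader optics and mutational spectra are not modeled.  All
randomness flows through one explicit seeded generator; identical seeds give
bitwise-identical outputs.

What passing closed-loop tests show: the pipeline recovers parameters under
the generator's idealized noise.  Real assays add systematic components the
generator omits (derivatization efficiency, pipetting structure, plate edge
effects, correlated drift), so recovery there can only be worse.

## Published-value handling

The per-variant characterization table is internally inconsistent under any
single first-order reading: for the wild type, k_cat/k_inact with the printed
inactivation rate gives ≈3864 turnovers vs. the printed TTN 830.56, and
ln 2/k_inact gives ≈10.5 min vs. the printed 17.91-min half-life.  The
package therefore never forces agreement: model-based quantities
(partition ratio, ln 2/λ) and empirical ones (plateau-product TTN, fitted
half-life) are computed and reported side by side.  Fold-change checks
(TTN 2.01×/2.03×, half-life 3.37×) are made against the printed ratios at
printed precision.  The 67.3 %/89.11 % residual-activity improvements are
not reproduced: whether they are ratios of residual percentages or of
instantaneous activities is ambiguous and the raw assay data are
unavailable.

## Problem sizes

Simulations and replicate counts throughout (100-replicate closed loops,
200–500-replicate estimator comparisons, 2000-clone screening libraries,
13-point curves) are chosen so each analysis is statistically stable at
desk scale; all drivers and the full test suite run in well under a minute
each on one core.

## Known limitations

- No substrate/product inhibition, no global progress-curve fitting of K_M.
- No thermal stability: "stability" is exclusively catalytic (mechanistic).
- ΔΔG values are inputs; no structure or folding computation.
- The first-order residual-activity fit is misspecified when substrate
  depletes within the assay window (see above) — by design, since that is
  what the laboratory procedure measures.
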