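# Methods

This note records the models implemented in `pinnicomp`, the
assumptions and defaults behind them, and the design choices made where
the underlying field methods leave room for interpretation.

## Cones geometry

A seal on land is modeled as a stack of conical frusta between eight
landmark sites ordered ankles → pelvis → umbilicus → mid → sternum →
axilla → neck → ears, with an elliptical cross-section at each site
(horizontal semi-axis a = width/2, vertical semi-axis b = height/2).
The frustum volume is the exact integral of π·a(t)·b(t) along the axis
with both semi-axes linear in t; the circular variant sets
a = b = girth/(2π). Straight segment lengths come from taped
curvilinear lengths via Lₛ = √(L_c² − Δr²), treating the tape as the
hypotenuse over the radial offset between sites. Two choices here are
deliberate:

- **The radial offset uses the vertical semi-axes.** The tape runs
  along the dorsum, so the height profile, not the width profile, sets
  how much longer the surface path is than the axis.
- **Axial lengths are a property of the body, not of a surface.** The
  straight lengths are computed once from the *outer* surface and
  reused for the nested skin and muscle surfaces. Recomputing them from
  the shrunken semi-axes would make the shells of a known nested body
  non-recoverable.

Partitioning subtracts a constant skin depth from both semi-axes to
form the skin boundary, and the ultrasound sculp depths (dorsal reading
from b, lateral reading from a — matching probe placement) to form the
muscle boundary. At the ankles and ears, where no ultrasound image is
taken, the sculp depth is set equal to the skin depth so blubber tapers
to zero at the extremities; the full-body extent adds end cones (all
core) beyond them. Because every shell is a difference of stacked
frusta over identical axial lengths, additivity
V_skin + V_blubber + V_core = V_total holds to machine precision by
construction. Negative inner semi-axes (possible under extreme Monte
Carlo draws) are clamped to zero with a warning rather than raised, so
propagation runs survive; the clamp is flagged on the result.

The traditional configuration subtracts the *mean* of the dorsal and
lateral depths from both radii — the method's historical single-depth
usage — and spans pelvis to neck only, with no skin surface.

## Tissue conversion

Volumes (cm³ ≡ mL) convert to masses (kg) via densities (g/mL) and to
fat via mass fractions. Defaults ship as a YAML config
(`src/pinnicomp/data/tissue_properties.yaml`) for adult female northern
elephant seals: blubber 0.89 ± 0.03 g/mL with fat fraction
0.853 ± 0.026 (early molt) / 0.823 ± 0.031 (late molt); skin
1.17 ± 0.13 g/mL, depth 1.32 ± 0.16 cm, fat fraction 0.161 ± 0.007.
The traditional route instead uses sculp density 0.94 g/mL and fat
fraction 0.903 ± 0.003 and never touches skin properties. "Proportion
adipose" from the cones methods counts blubber only — skin is not
adipose tissue — while the dilution method sees whole-body adipose;
both are reported so the comparison is explicit. Skin density can also
be inferred from a blubber+skin core sample via
ρ_D = ρ_T + (ρ_T − ρ_B)·(d_T − d_D)/d_D.

## Labeled water

TBW (mL) = CPM_inj / (CPM·mL⁻¹_eq − CPM·mL⁻¹_bg). The injected
activity is the syringe mass (g) times the stock specific activity
(CPM/mL), taking the saline at 1 g/mL — the conversion the weighing
procedure implies but never states. Stock activity is back-computed
from standard dilutions (net activity × (diluent + aliquot)/aliquot)
and summarized as a normal distribution over all pooled replicates.

Three water-to-fat conversions are implemented:

- **Heteroscedastic logit**: logit(P_fat) = α₀ + α₁·x + x·ε with
  x = P_H2O/(1−P_H2O) and ε ~ N(0, σ²). The residual SD grows with the
  water ratio, and the inverse logit confines output to (0,1). The
  shipped point calibration (α₀ = 0.86, α₁ = −1.6) is the
  decreasing-in-water fit: proportion fat falls as proportion water
  rises and asymptotes to zero at high water, tracking the linear rule
  closely in the 0.45–0.66 range and departing above it. The sign
  convention is determined by fitting, not assumed; the fit routine is
  generic in (α₀, α₁).
- **Linear (gray-seal) rule**: P_fat = 1 − 1.37·P_H2O. Negative
  outputs above P_H2O = 1/1.37 ≈ 0.73 are *flagged, not clamped*, so
  the divergence between the rules is visible.
- **Hydration constants**: P_adipose = (w_lean − P_adj)/(w_lean −
  w_adipose), P_fat = P_adipose·f_adipose, with
  P_adj = 0.967·P_H2O correcting the tracer's high bias relative to
  carcass desiccation. Defaults w_lean = 0.732, w_adipose = 0.151,
  f_adipose = 0.854 are representative mammalian values shipped as
  config (`data/water_fat.yaml`); the operation is generic in its beta
  parameters and any alternative source values can be swapped in.

## Bayesian calibrations

Three regression shapes share one Gaussian likelihood core: simple
(Y = β₀ + β₁X + ε), shared slope with per-site intercepts
(Y = β_U·X + β_i + ε, used for the with-image vs without-image
ultrasound cross-calibration), and the heteroscedastic logit above
(dividing through by x makes it an ordinary weighted regression).
Priors are uniform on all coefficients (data-scaled boxes spanning
±100× the scale of the least-squares estimate — effectively flat) and
uniform (> 0) on the inverse variance τ.

The sampler is one-parameter-at-a-time Gaussian random-walk Metropolis
("Metropolis within Gibbs") with step sizes adapted during burn-in to
a 0.3–0.5 acceptance rate. Two numerical choices matter:

- **Orthogonalized updates.** Coefficients are updated in the frame
  θ = Rβ from the QR decomposition X = QR. Given τ the components of θ
  are a-posteriori independent, so componentwise proposals mix well
  even when the slope/intercept posterior correlation approaches −1
  (as it does for these calibrations); reported draws are mapped back
  through R⁻¹, and the prior box is enforced on the original β.
  Likelihood evaluations use the sufficient statistics, O(p) per
  proposal regardless of n.
- **Precision on the log scale.** τ is proposed as a random walk in
  log τ with the Jacobian term in the acceptance ratio (the prior
  remains uniform in τ), so chains traverse orders of magnitude in
  residual variance — including the near-zero-noise limit, where the
  posterior piles against the upper precision bound.

Defaults: 3 chains, 2000 kept iterations after 1000 burn-in, explicit
seeds everywhere. Diagnostics report lag-1 autocorrelation per
parameter per chain (threshold 0.9) and the spread of per-chain
posterior means in pooled-SD units (threshold 0.5).

A property of the flat-on-precision prior worth knowing: the marginal
posterior of a coefficient is a t distribution with n − p + 2 degrees
of freedom and correspondingly deflated scale, so 95% credible
intervals are slightly *shorter* than the frequentist t-interval and
their repeated-sampling coverage sits near 91–94% at small n rather
than 95%. The calibration tests therefore use sample sizes (n = 20 for
the simple shape, 9 points for the logit, 6 points per site for the
shared slope) at which the exact posterior itself covers ≥ 90/100 on
the test's seed set; at sparser designs the shortfall is a property of
the prior, not of the sampler.

## Monte Carlo uncertainty and sensitivity

Inputs are named distributions: normal for tape/pole measurements and
densities, lognormal (fit to log replicates) for ultrasound depth
readings, beta (moment-matched) for proportions, fixed for constants.
The three observer replicates are treated as independent draws —
deliberately flattening the observer/measurement hierarchy, which is
not estimable at triplicate sample sizes. `propagate` pushes N joint
draws (default 15,000) through an estimator; draws that fail
geometrically (e.g. a curvilinear draw shorter than its radial offset)
return NaN, are excluded, and are reported as a failure fraction, with
a hard abort above 1%. `sensitivity_oat` varies one input at a time
with the rest pinned at their means — a ranking of where measurement
effort buys the most precision, not a variance decomposition (inputs
interact multiplicatively through volumes, so one-at-a-time variances
do not sum exactly to the total).

For the labeled-water pipeline the water-to-fat calibration enters as
two standard-normal inputs mapped through the Cholesky factor of the
(α₀, α₁) posterior covariance, preserving their strong negative
correlation instead of treating the parameters as independent.

## Synthetic data

The generator produces truth bodies that are piecewise elliptical
frusta with nested skin and blubber surfaces — *inside* the
estimator's model class — so zero-noise recovery is exact by
construction and any discrepancy is a defect, not discretization. The
default truth is a magnitude-realistic adult female (~2.4 m, ~330 kg,
~19% adipose by mass, elliptical sections wider than tall); girth is
the true ellipse perimeter, so the circular-shape assumption is
genuinely misspecified for elliptical bodies, just as for real seals —
this is what drives the traditional/modified differences in the
simulated study. Measurement noise defaults: 1.0 cm SD for girth and
curvilinear lengths, 0.5 cm for heights and widths, 5% multiplicative
(lognormal) for ultrasound readings, 5% CV for scintillation counts,
three observers. True TBW derives from tissue hydration fractions
(adipose 0.151, lean 0.732) applied to the true tissue masses.

What passing tests on these bodies do **not** show: real seals are not
piecewise-conical (smooth curvature between landmarks biases frustum
sums), skin thickness varies over the body, fat slumping deforms
sections on land, and the observer hierarchy is real. Closure results
bound pipeline correctness, not field accuracy.

## Known limitations

- No girth↔ellipse-perimeter inversion: elliptical mode requires
  measured heights and widths.
- No fat-slumping correction and no within-body skin-thickness
  variation.
- The hydration-constant conversion's beta parameters are config
  values; users with species-specific carcass data should replace
  them.
- One-at-a-time sensitivity ignores input interactions by design; no
  global (Sobol-type) indices are provided.
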