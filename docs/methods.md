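# Methods

## Model

Transcription of each XlnR target gene *i* is driven by the product of
two Hill factors: activation by the XlnR·D-xylose complex `X` and
repression by CreA (`x_CreA`):

```
dX/dt      = K_on · x_xlnR · u(t) − K_off · X
dx_CreA/dt = k1 · u(t) − k2 · x_CreA
dx_i/dt    = k_is · ψ_Xyl(X) · ψ_CreA(x_CreA) − k_id · x_i

ψ_Xyl(X)       = X^h1 / (K_i1^h1 + X^h1)
ψ_CreA(x_CreA) = K_i2^h2 / (K_i2^h2 + x_CreA^h2)
```

Assumptions: *xlnR* is constitutively transcribed, so its level enters
as a constant input `x_xlnR` (default 1.0 normalized units, overridable
with a measured value); translation delay is negligible; basal
transcription is negligible next to induced levels; mRNA decay is
first-order and unregulated; occupation of a single CreA site suffices
to repress. `X` and `x_CreA` are in arbitrary concentration units whose
scale is absorbed by the thresholds `K_i1`/`K_i2`. Time is in hours;
expression in reference-gene-normalized units.

The CreA partial loss-of-function mutant is represented by strain-
specific `(k_is, K_i2)`: a larger `K_i2,Mt` (less effective repression)
and `k_is,Mt = λ·k_is,Wt` with λ the de-repression fold-change. A full
knockout (`x_CreA ≡ 0`, `ψ_CreA ≡ 1`) is available as a flag. The legacy
single-regulator model (dynamic *xlnR* state; repression a direct Hill
function of `u`) is retained for comparison only.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `K_on` | complex association rate | h⁻¹·mM⁻¹ (effective) | 14.957 |
| `K_off` | complex dissociation rate | h⁻¹ | 75.541 |
| `k1` | CreA synthesis coefficient | conc·h⁻¹·mM⁻¹ | 21.455 |
| `k2` | CreA decay rate | h⁻¹ | 20.065 |
| `k_is` | maximal transcription rate (per strain) | expr·h⁻¹ | 10 |
| `K_i1` | activation half-saturation | complex units | 0.1 |
| `K_i2` | repression half-saturation (per strain) | CreA units | 25 |
| `k_id` | mRNA decay rate | h⁻¹ | 1 |
| `h1` | activation Hill coefficient | – | 2 |
| `h2` | repression Hill coefficient | – | 4 |

The shared-block defaults are the consolidated wild-type averages used
throughout as literature-scale anchors. `h2 = 4` is used everywhere;
`h1` defaults to 2 (cooperative binding) and may be freed or set by
config. The threshold defaults follow from the shared block: with
`x_xlnR = 1`, `X` peaks near 0.16 at 1 mM induction (so `K_i1 ≈ 0.1`
half-saturates inside the observed sweep) and `x_CreA` peaks near 0.9
at 1 mM but ≈ 53 at 50 mM (so `K_i2 ≈ 25` leaves 1 mM induction
essentially unrepressed while repression engages strongly at 50 mM —
the regime the data display, and the model's explanation of why 1 mM
induction yields *higher* expression than 50 mM).

## Xylose input

`u(t)` is not measured continuously; three forms are supported:
constant, piecewise-linear through measured knots, and (default)
exponential decay calibrated to the bioreactor observations — a 50 mM
pulse falls to 38 mM by 5 h (ρ = ln(50/38)/5 ≈ 0.0549 h⁻¹, ≈ 76 % of
the pulse left), and a 1 mM pulse is nearly exhausted
(ρ = ln(25)/5 ≈ 0.644 h⁻¹, 0.04 mM at 5 h).

## Simulation and the estimation predictor

`kinetics.simulate` integrates with LSODA at rtol 1e-8 / atol 1e-10
(configurable); values within atol of zero are clipped to zero so
nonnegativity survives round-off. Inside the optimizer a much faster
predictor is used: `(X, x_CreA)` are linear and solved in closed form
for constant/exponential inputs, and the transcript equation — linear in
`x_i` given those — is advanced by an exact-propagator trapezoidal
update (`x⁺ = e^{−k_id·dt} x + dt/2 (e^{−k_id·dt} a_n + a_{n+1})`) on a
3000-step grid, with half the steps packed into the first 0.25 h where
`X` and CreA equilibrate. Agreement with the reference integrator is
≤ ~2·10⁻⁵ absolute on study-like trajectories and is asserted in tests;
interpolated inputs fall back to the reference integrator. Initial
conditions default to `X(0) = x_CreA(0) = 0` (pre-growth on sorbitol, a
non-inducing/non-repressing carbon source) and `x_i(0)` = first measured
value.

## Fitting

Per gene, the goal `J_comb = J_1 + J_50` (unweighted sums of squared
residuals over both induction conditions; an inverse-SD weighting option
exists but is off by default) is minimized in **log-parameter space**
(positivity by construction) with scipy's bounded trust-region
least-squares solver. Multi-start: the supplied initialization plus
seeded log-uniform draws within box bounds (default 20 restarts for
stand-alone fits; the protocol uses fewer because it warm-starts).
Bounds default to (1e-3, 1e3) × initialization. Ties on the goal break
to the smaller parameter-vector norm. The coefficient of variation of
each free parameter is the SD/estimate over the ensemble of local
optima within 1 % of the best goal — a multi-start dispersion measure,
not an asymptotic standard error. A failed fit is returned flagged, not
raised.

### Two-stage protocol and identifiability

Stage 1a fits each wild-type gene; stage 1b consolidates the shared
block θ₁ = (K_on, K_off, k1, k2) across genes by **geometric mean**
(positive rates with multiplicative scatter; the geometric mean
commutes with the identifiable ratios K_on/K_off and k1/k2), fixes it,
and re-estimates the gene block θ₂ = (k_is, K_i1, K_i2, k_id). Stage 2
fits each mutant gene with θ₁ and the gene's wild-type (K_i1, k_id)
held, estimating only (k_is,Mt, K_i2,Mt) — optionally also k_id.

The shared block deserves care. Two of its directions are **exactly**
degenerate: rescaling `K_on` together with every `K_i1`, or `k1` with
every `K_i2`, changes no trajectory (the observables depend only on
`X/K_i1` and `x_CreA/K_i2`). The only other signal — the equilibration
transients of `X` (1/K_off ≈ 48 s) and CreA (1/k2 ≈ 3 min) — is far
below the 20-minute sampling resolution and realistic noise floors
(≈ 0.3 % trajectory effect vs ≈ 3 % per-point noise). Unrestrained
per-gene "refinement" of the block therefore chases noise along flat
valleys to wherever the bounds stop it, and cross-gene averages of such
fits inherit arbitrary window-scale error — verified here on synthetic
data (noiseless recovery is exact; at 5 % noise per-gene estimates pin
at any window's edges). The protocol consequently **anchors θ₁ at its
initialization by default** (`theta1_bounds_scale = (1.0, 1.0)`;
stage 1a then estimates θ₂ against the fixed convention) and exposes the
window for designs that genuinely resolve the transients. Consequence:
`K_i1` and `K_i2` estimates are defined *relative to the θ₁ scale
convention*; this is intrinsic to the model class, not to the
implementation. A finite-difference sensitivity ranking is provided for
audit, with the caveat that one-at-a-time perturbations understate the
directional (correlated) nature of the weakness.

### Hypothesis test for CreA repression

Whether repression is needed at all is tested per gene by nested least
squares: the reduced model clamps `ψ_CreA ≡ 1` and drops `K_i2`; the
full model is additionally started from the reduced optimum (with
`K_i2` at its upper bound) so `J_full ≤ J_reduced` holds numerically.
Significance is the extra-sum-of-squares F statistic
`((J_red − J_full)/1) / (J_full/(N − p_full))` at α = 0.05 by default.
Because the null places `K_i2` on the boundary, the test is
conservative; simulation shows full power against strong repression and
a false-rejection rate at or below the nominal level at the study's
noise scale.

## Profile classification

Series are smoothed with a 3-point moving median; a peak or trough is
*prominent* if it stands out by at least `max(replicate noise SD, 10 %
of the series range)`. Rules: **C1** if nondecreasing within tolerance
(no cumulative drop beyond the prominence floor); **C4** if two or more
prominent interior maxima are separated by a prominent trough; **C3**
if a single maximum is followed by a decrease and a renewed rise of at
least the prominence floor that persists to the final point; **C2** if a
single maximum ends at least the floor below its peak; anything else is
UNCLASSIFIED. The observation window splits into W1/W2 at the first
detected trough (2.5 h if none). The thresholds are relative to the
series range and replicate SDs, making labels invariant to positive
rescaling of the expression axis; single-sample spikes are treated as
noise by the median filter, so real bimodality must persist for more
than one sampling interval. `pattern_generability` sweeps a fixed
81-parameter × 3-input grid, classifies each noiseless trajectory and
reports per-class reachability with a witness parameter set; on the
default grid the model produces C1 and C2 but no C3/C4 witness,
consistent with the de-repression shapes requiring mechanisms beyond
this model (e.g. renewed activation after repression wanes faster than
xylose).

## DTW clustering

Classical dynamic time warping with the symmetric step pattern
(match/insert/delete), squared local cost, no warping window, and — by
default — per-series z-normalization so shape rather than magnitude
drives the distance (a constant series z-normalizes to zeros). The
implementation is validated against brute-force enumeration of all
warping paths on short series. Distances feed scipy average-linkage
agglomerative clustering; flat clusters come from an explicit count
`k`, a distance threshold, or the largest gap in the merge heights.
Dendrograms export as Newick with merge heights as node depths; gene
order does not affect the partition. All of step pattern, cost,
normalization and linkage are configurable and recorded in output
metadata.

## Synthetic data generator

Emulates the study design: wild type, 23 genes, sampled every 20 min
for 5 h (16 points); mutant, 8 genes, hourly (6 points); induction at
1 and 50 mM with the calibrated depletion profiles; 3 biological
replicates; a near-constant "xlnR-like" series at ~1.5 normalized units
and an optional xylose-indifferent decoy gene. Noise is multiplicative
lognormal (qPCR-typical), mean-corrected so replicate means are
unbiased, with SD fraction 0.1 by default; replicate means and SDs are
emitted in the tidy CSV schema together with a complete ground-truth
JSON. Gene-block truths are drawn log-uniform from K_i1 ∈ (0.05, 0.15),
K_i2 ∈ (15, 60), k_is ∈ (4, 40), k_id ∈ (0.5, 4) — ranges chosen so the
panels reproduce the study's qualitative regime (strong 1 mM responses,
repressed-but-visible 50 mM responses, ψ_CreA ≈ 1 throughout at 1 mM).
`generate_study` draws one truth per gene and emits paired wild-type and
mutant datasets (mutant via λ·k_is and an enlarged K_i2, factor 3 each
by default).

What the generator does **not** emulate: correlated replicate errors,
amplification-efficiency artifacts or reference-gene instability,
gene-specific input lags, regulation mechanisms outside the model class
(so C3/C4-shaped courses never occur in generated data), and biological
parameter correlations across genes. Passing recovery tests on this
generator therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to
model misspecification.

## Problem sizes and numerical choices in tests

The acceptance checks run the recovery experiment at the full study
design (23 + 8 genes, 5 % noise, λ = 3) with 4 optimizer restarts per
gene; hypothesis-test calibration uses 100 simulated replicates per
regime with 2 restarts per fit; the DTW oracle enumerates all
{0,1,2}-valued series of lengths 2–3 exhaustively plus 150 random
integer series up to length 6; class generability scans the default
243-cell grid. Integration tolerances: reference rtol 1e-8/atol 1e-10;
optimizer ftol/xtol 1e-10.

## Known limitations

- Absolute scales of `K_i1`/`K_i2` (and hence of `X`, `x_CreA`) are
  conventions tied to the anchored shared block, not measurable
  quantities.
- The CV is a multi-start dispersion, not a confidence interval; no
  bootstrap or profile likelihood is provided.
- No CreA-feedback-on-*xlnR* variant, no translation/protein states,
  no stochastic simulation.
- The W1/W2 window split and the C3-vs-C4 boundary are heuristic and
  configurable; different conventions will relabel borderline courses.
- The F test's nominal level relies on approximately Gaussian,
  homoscedastic residuals; with strongly heteroscedastic noise use the
  weighted-residual option.
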