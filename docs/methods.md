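# Methods

`goitroscan` reimplements, as a reusable library and CLI, the analysis
behind automated goitrogen screens with thyroid-reporter zebrafish
embryos: transgenic embryos carrying an mCherry reporter under the
thyroglobulin promoter are exposed to a concentration series, imaged,
and the gland's fluorescence quantified; because the
hypothalamus–pituitary–thyroid (HPT) feedback loop compensates for
inhibited thyroid-hormone synthesis by upregulating thyroglobulin,
goitrogens produce a concentration-dependent *increase* in reporter
fluorescence. This note records the models, the tunable constants, the
numerical choices, and what the synthetic data do and do not emulate.

## Image quantification

Each embryo contributes one fluorescence image (or a Z-stack from which
one plane is chosen). The readout chain is:

1. **Rolling-ball background subtraction** (`ball_radius`, default
   50 px). The background is the grayscale morphological opening of the
   intensity landscape with a ball structuring element — the surface a
   ball of that radius traces when rolled under the image. Structures
   narrower than the ball diameter (the gland, pigment spots) survive;
   illumination gradients do not. We compute the exact opening with two
   passes of scikit-image's ball-kernel minimum filter:
   `restoration.rolling_ball` alone returns the ball-*apex* envelope
   (the erosion, offset by the radius), and a second pass on the
   inverted erosion supplies the dilation, since dilation is the
   negation-conjugate of erosion for a symmetric structuring element.
   Tests verify agreement with an independent `scipy.ndimage`
   grey-opening oracle to machine precision.
2. **Focal-plane selection.** The instrument's autofocus plane is used
   when it yields a non-empty segmentation; otherwise the plane
   maximizing the variance of a discrete Laplacian inside the ROI is
   taken. This automates what an operator does when autofocus locks
   onto a pigment cell.
3. **Threshold segmentation** (`threshold`, default 20 grey levels on
   the 8-bit background-subtracted image) restricted to a rectangular
   region of interest. The ROI replaces the manual rectangle an
   operator would draw to exclude pigment-cell autofluorescence; it is
   supplied per embryo in the layout table, plate-wide, or by a
   brightest-component fallback (`auto_roi`). Images are treated as
   8-bit; for 16-bit inputs the threshold is rescaled proportionally.
   Connected components are 8-connected.
4. **Label cleanup**: components smaller than `min_spot_area`
   (default 10 px) are discarded — except the largest, so a faint gland
   is never deleted — and the surviving label is dilated with a disc of
   `dilation_radius` (default 2 px, clipped to the ROI) to recapture
   the dim gland rim lost to thresholding. The dilation radius and the
   spot-size threshold are conventions of this implementation; both are
   configurable.
5. **Pixel sum**: the sum of grey values over the final label on the
   background-subtracted image — a proxy that reflects both gland area
   and intensity. An empty label flags the embryo ("no gland
   detected", e.g. non-expressing fish); flagged embryos are excluded
   from statistics and logged in the run manifest.

Coordinates are 0-based and ROIs are half-open rectangles
`[x0, x0+w) × [y0, y0+h)`, which keeps area arithmetic exact.

## Concentration-response model

Per replicate, the mean pixel sum at each concentration is divided by
the mean control pixel sum, so the control fold induction is exactly 1.
Fold inductions are fitted with the Hill (log-logistic) model

    y(x) = Min + (Max − Min) / (1 + (x / EC50)^(−p))

with **Min fixed at 1** (the normalized control level); `Max` (maximum
fold induction), `EC50` (μM) and the slope `p` are estimated by
unweighted least squares on the replicate-level per-concentration
means, pooled across replicates (replicates may use different
concentration ranges; pooled points are fitted jointly without a
replicate term). `EC50` is parameterized as `log10 EC50` during
optimization; at `x = 0` the model evaluates to `Min`, its limit for
`p > 0`. Starting values: `Max` from the largest observed fold, `EC50`
from the geometric mean of the tested nonzero concentrations, `p = 1`,
with a multi-start over `p ∈ {0.5, 1, 2, 4}` on failure. The EC50
standard error comes from the asymptotic covariance by the delta
method; confidence intervals are formed on the log scale with a
Student-t quantile at `n_points − 3` degrees of freedom.

A fitted amplitude of at most `Min + 0.05` is reported as **no
induction** (EC50 undefined) — the expected outcome for a
non-goitrogenic compound, including ones that repress the reporter.
If the response at the highest tested concentration falls more than
`decline_margin` (default 10% relative) below the next-highest —
cytotoxic interference with the reporter — that one concentration is
excluded before fitting and the exclusion logged.

**Benchmark dose.** BMD20 is the concentration at which the fitted
curve reaches 1.2 (a 20% increase over controls), from the closed-form
inversion `x = EC50·((Max−Min)/(y−Min) − 1)^(−1/p)`. A target at or
outside the asymptotes is an explicit error. The half-max target is
special-cased to return `EC50` itself so the identity holds exactly
rather than to an ulp. Tests check the closed form against numeric
root-finding to a relative error below 1e-9.

**Mortality.** Death counts follow a two-parameter log-logistic with
asymptotes 0 and 1, which on the log-concentration scale is exactly a
binomial GLM with logit link; the fit is delegated to statsmodels and
`LC50 = exp(−intercept/slope)` with a delta-method SE. All-or-nothing
tables yield a geometric-mean interval estimate of the bracketing
concentrations; tables with no deaths censor the LC50 at the highest
tested concentration.

**Potency metrics.** TDI = LC50/EC50 (displayed rounded half-up to the
integer; full precision kept internally). When the LC50 is censored
and baseline-toxicity QSAR coefficients are configured, the TDI falls
back to the predicted baseline LC50. The baseline model is
`log10 LC50_baseline[μM] = slope·logD + intercept` with user-supplied
coefficients; the toxic ratio (baseline/observed LC50) is annotated
"baseline-like" strictly below 10. Rankings are ascending in
EC50/BMD20 and descending in TDI, undefined values last, ties broken
by name.

## Synthetic data

The generator exists so that every stage is testable against exact
ground truth without microscope data.

* **Scenes**: a linear background plane (uneven illumination), a
  flat-top elliptical gland with a 1-px cosine edge roll-off (keeps the
  true pixel sum analytic while avoiding aliasing), optional small
  bright pigment discs placed outside — or, for the hard case,
  adjacent to — the gland, and additive Gaussian noise, quantized to
  8 bits. The ground truth (`true_pixel_sum`) is the noiseless gland
  component summed over its mask, independent of background, pigment
  and noise. Noise is drawn before pigment placement so scenes
  differing only in pigment share a noise realization.
* **Z-stacks** blur the scene with a Gaussian whose width grows by
  `blur_step` per plane of distance from the focal plane.
* **Response datasets** draw per-embryo pixel sums as
  `control_mean × Hill(c) × LN(1, cv)` with a lognormal of mean 1 —
  fluorescence is positive and right-skewed. The paper-scale default
  is `embryo_cv = 0.15`, a typical per-animal reporter variability;
  the published study reports no per-embryo variance, so this is an
  implementation default. Simulation studies prescribed at `cv = 0.1`
  use 0.1.
* **Mortality tables** draw binomial deaths from the log-logistic
  survival curve.

What the generator does **not** emulate: embryo morphology and
orientation errors, bright-field content, spatially correlated noise,
photobleaching, or gland-shape variability. Passing tests therefore
demonstrate the correctness of the measurement and modelling chain
under controlled conditions, not robustness to every real-image
artifact — the ROI-and-cleanup stages are exercised against the
pigment-spot confounder, which is the dominant artifact this assay
design targets.

## Study designs used in simulations

* Induction series: 5 log-spaced concentrations between the doses at
  which the curve reaches 5% and 95% of its span (shallow slopes get
  automatically wider ranges, as screeners do between replicates),
  plus a control; 24 embryos per concentration for tabular studies, 10
  for rendered-image campaigns (the assay's minimum-images design
  rule), 2 replicates.
* Mortality series: 6 log-spaced concentrations bracketing the
  expected LC50 within a factor of 4 (range-finding practice), 25
  embryos per concentration.
* The demo panel's generating parameters (EC50, slope, maximum fold,
  LC50, log D) are literature-scale values for seven reference
  goitrogens plus a non-inducing negative control.
* Rendered campaigns use 96×96-px scenes; image sizes only need to
  hold the gland with margin for the 50-px ball, and the pixel sum is
  size-invariant.

## Known limitations

* The nonlinear least-squares EC50 has a small positive finite-sample
  bias (≈0.5% at cv 0.1, n 24, 5 concentrations) that Box's curvature
  term explains only partly — the remainder traces to the skewed noise
  of lognormal means propagated through the fit's nonlinearity. It is
  well inside the Monte-Carlo noise of the recovery studies and is not
  corrected.
* Confidence intervals are asymptotic (t on the log scale); bootstrap
  intervals are not implemented.
* Printed report values round EC50/BMD to 3 significant figures and
  TDI to the integer; downstream arithmetic always uses full
  precision.
* The mortality model fixes the asymptotes at 0 and 1; control
  mortality is assumed absent and zero-concentration rows carry no
  information.
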