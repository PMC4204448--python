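# Methods

This note documents the models, the synthetic stimuli, the decision stage,
the numerical choices, and the places where the design was genuinely open.

## Stimuli

All stimuli are rendered programmatically as two-level luminance maps
(background 0, foreground 1) on a 512×512 frame at 1 px per arc min, bright
elements on a dark background. The vernier target is 84 arc min tall in
total (two segments separated by a 4 arc min gap, 2 arc min line width),
with a 2 arc min horizontal offset of the lower segment; offsets are placed
at whole pixels (no anti-aliasing). Flanker columns sit at multiples of the
14 arc min element spacing on both sides of the target. Two batteries are
provided:

* **manassi_fig2a** — eleven flanked conditions at 3.88° eccentricity
  (metadata only; no acuity falloff is modelled): lines, lines with a
  superimposed X, rectangles, and rectangles with X, each at 2 and 16
  flankers, plus three length variants of plain lines. The exact
  composition of the original eleven conditions was published graphically,
  so this table is an approximate reconstruction and is marked as such in
  the source.
* **malania_fig2b** — foveal battery crossing flanker length
  {short = 0.5×, equal = 1×, long = 2× the vernier height} with flanker
  count {2, 16}, plus the unflanked baseline. The length multipliers encode
  the verbal "shorter/longer than the vernier".

Rectangles reuse the flanking-line positions as their vertical sides
(consecutive line pairs become one rectangle; an unpaired line gets a
rectangle extending one spacing outward), so the very same lines become
part of a larger structure. X variants draw both diagonals of each flanker
region. Flanker ink is rendered on the right side and mirrored, which makes
the mirror property (left-offset image = horizontal mirror of the
right-offset image) exact by construction; the test suite asserts it
bit-exactly for every condition.

What the generator does *not* emulate: luminance calibration and display
gamma, temporal presentation, eye movements, peripheral acuity loss, and
trial-to-trial noise. Passing tests therefore show that the *models*
behave as described on idealized geometry, not that they fit real
psychophysical data.

## Fourier observer

Forward FFT of the stimulus frame (no zero padding — the frame is the
analysis window, with the periodic boundary the transform implies),
multiplication with a radially symmetric binary mask in cycles/degree,
inverse FFT, real part. Low-pass passes f ≤ cutoff, high-pass f ≥ cutoff,
band-pass |f − center| ≤ bandwidth/2; the DC bin follows the same radial
rules (passed by low-pass and by a band-pass whose lower edge reaches 0,
blocked by a high-pass with positive cutoff). Mask edges are hard by
default, matching the binary pass/stop masks the approach is usually drawn
with; a raised-cosine taper of configurable width is available for
robustness experiments. Hard masks make filtering idempotent, and radial
symmetry makes it mirror-equivariant, which guarantees zero
discriminability for zero-offset stimuli downstream.

## Wilson–Cowan field

The input is first convolved with a balanced difference of Gaussians
(center σ 1 arc min, surround σ 3 arc min, equal integrals, reflective
boundaries), so uniform luminance is rejected and edges/line elements are
transduced. The resulting drive A feeds two fields integrated with explicit
Euler (dt = 1 ms ≤ min(τ)/5 stability guard, duration 150 ms, τ_E = 10 ms,
τ_I = 20 ms, half-wave rectifying transfer; a logistic transfer is
available and keeps activity in (0, 1)):

```
E ← E + (dt/τ_E) (−E + f( G(σ_E)*A − w_IE (G(σ_I)*I) ))
I ← I + (dt/τ_I) (−I + f( G(σ_I)*A + w_EI (G(σ_E)*E) ))
```

The readout is the terminal excitatory field (a time-averaged readout is
available by flag). Defaults: σ_E = 3 arc min, σ_I = 120 arc min,
w_EI = 1.0, w_IE = 4.0.

The coupling architecture is fixed but its numbers are not published with
it, so the defaults are this package's own calibration, chosen so the
field operates in its characteristic regime — local excitatory spread with
long-range inhibitory pooling. In that regime the inhibition a unit
receives grows with the number of elements across a ~2° neighbourhood:
one flanker pair adds little, eight pairs attenuate the target
substantially, and the attenuation depends only weakly on flanker shape.
This is what produces the model's documented signature on these batteries
(near-flat predictions across the peripheral conditions, two flankers
≈ unflanked, thresholds growing with flanker count) — and it is exactly
the signature by which the model *fails* to reproduce the human patterns
(rectangle release from crowding; count effects that reverse with flanker
length). With short-range inhibition (e.g. σ_I ≈ 9 arc min) those
signatures disappear; the calibration is part of the package's definition
of the model, not a fit to data.

Numerics: Gaussian couplings with σ ≤ 12 px use separable spatial
convolution with reflective boundaries; wider couplings are applied
spectrally (multiplication with the analytic Gaussian transfer function),
which is O(n log n) instead of O(n·σ). The implied periodic boundary is
immaterial here because activity decays to ~0 well inside the frame.
Non-finite activity is detected after every step and reported with the
step index.

## Decision stage

Templates are the rendered left/right verniers (no flankers), restricted
to a window whose width is 5× the element spacing centred on the target
(the template-matching convention for these stimuli), mean-subtracted
within the window; the template offset equals the stimulus offset. The
match statistic is a cross-correlation at the fixed target location — the
observer knows where the target is, so there is no spatial search. Two
dialects exist:

* **normalized** (default for the Fourier observer): correlation divided
  by the operand norms, invariant to affine rescaling of the response;
  this isolates pattern distortion from pass-band energy changes.
* **raw** (default for the Wilson–Cowan observer): the plain
  mean-subtracted dot product. This choice is forced by the physics of the
  model: its crowding mechanism is inhibitory *attenuation* of the target
  signal, which a scale-invariant statistic provably cannot see.

Discriminability is the correct-minus-incorrect match difference averaged
over the left- and right-offset renditions. Predictions are
`a + b·(−score)` with (a, b) from least squares against the reference
vector and b clamped to ≥ 0; identical scores are flagged degenerate and
fall back to the reference mean. The normal-equations solution is verified
against a hand-solved three-condition oracle in the tests.

## Search and fragility

Exhaustive grid evaluation (no gradient or stochastic optimization — the
brute force is the point), scaling re-fit per grid point, ties broken
toward lower center/cutoff then lower bandwidth so results are a pure
function of the inputs. Library default grids: cutoff 0.5–30 c/deg step
0.5; band-pass center 0.5–20 × bandwidth 0.5–10, step 0.5, invalid
combinations (lower edge < 0) skipped. The acceptance script and tests use
these same default grids (a full three-family search plus the
recurrent-field runs completes in minutes on one core); the grid spec
always travels with the reported optimum. The fragility probe
re-evaluates the optimum ± each delta (default ±1 and ±2 grid steps) on
both axes, reports per-condition prediction ranges across neighbours and
counts rank-order inversions against the optimum's prediction ordering;
invalid neighbours are skipped and listed.

## Reference data and pattern checks

No numeric human thresholds ship with the package — the source data exist
only as figures, and digitizing them would fabricate precision. The
canonical reference is qualitative: ordering/shape predicates
(`greater`, `not_increasing`, `approx_equal`, `increasing`, `flat`), each
carrying a provenance string naming the study and finding it encodes.
"Virtually no difference" is operationalized as relative spread
(max − min)/|mean| ≤ 0.05 and "essentially no change" as relative
difference ≤ 0.05; both tolerances are explicit parameters, and these
operationalizations are a design choice, not a published criterion. Where
the SSR machinery needs numbers, a bundled *synthetic* vector satisfying
the qualitative rules is used and labelled as such; users can supply their
own numeric vectors by CSV (validated against the battery's condition
labels).

The Wilson–Cowan expected-pattern rules resolve one internal tension in
the verbal record: thresholds cannot both equal the unflanked level at two
flankers and rise strictly from zero to two flankers, so the rules assert
equality at two flankers and strict growth from two to sixteen.

## Known limitations

* The eleven-condition peripheral battery is a reconstruction; different
  plausible compositions would change the flatness statistic somewhat.
* The Fourier model's supplementary-level details (mask edge softness, DC
  handling, template width) are reconstructions with documented defaults.
* Figure-level quantitative bar heights of the original studies cannot be
  targeted by design (no numeric data exist in the record used here);
  all quantitative claims in this package are about its own computations.
* The laminar cortical grouping model discussed alongside these two
  observers is out of scope; only its 5×-spacing template-window
  convention is reused.
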