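# Methods

This note records the models, parameter choices, and numerical decisions
behind `vinespec`, in the order the pipeline runs them.

## Synthetic campaigns

No public on-the-go vineyard NIR dataset with matched stem-water-potential
(Ψs) references exists, so the package ships a generator whose output has the
statistical structure every downstream stage assumes. Its defaults define the
study conditions the tests and the acceptance script run under.

**Field design.** A randomized-block layout of 12 blocks (4 replicates × 3
irrigation treatments T0 full / T1 moderate / T2 none), each block three rows
of 15 vines at 1.20 m vine and 2.60 m row spacing; only the middle row is
monitored to avoid edge effects, and its 15 vines form three 5-vine groups,
each carrying one Ψs reference per date. Six dates spanning a season give
6 × 12 × 3 = 216 reference samples. A 9-block (3-replicate) variant with 27
references per date is available through `default_layout(n_replicates=3)`.

**Water status.** Per-date population means follow a drying trend from
−1.13 to −1.82 MPa, with treatment offsets of ±0.12 MPa (T0 wetter, T2
drier) and a group-level SD of 0.10 MPa; draws are clamped to
[−2.5, −0.05] MPa. Combined, the per-date spread is ≈0.14 MPa, a realistic
single-plot range for a Mediterranean season. Leaf water content links to Ψs
linearly, W = w0 + w1·Ψs with (w0, w1) = (0.9, 0.25), so W spans roughly
0.3–0.9 over the Ψs range; the link is a modelling convenience, not a
calibrated relation.

**Leaf optics.** Reflectance is a smooth baseline attenuated by Gaussian
absorption bands, R(λ) = B(λ)·exp(−Σ_k A_k·G(λ; μ_k, σ_k)): water bands at
978, 1454 and 1935 nm (σ = 35, 45, 55 nm) plus fixed dry-matter bands at
1720 and 2100 nm. Water-band amplitudes respond as A_k = amp_k·W^e_k with
(amp, e) = (0.80, 0.9), (0.85, 1.3), (1.60, 2.0): the weak second overtone is
near-linear in water content while the strong combination band saturates, as
Beer–Lambert behaviour of deep bands suggests. This keeps every band strictly
monotone in Ψs while preventing the bands from being perfectly collinear —
with identical exponents their common variation is exactly the kind of
per-spectrum scaling SNV removes, which would leave the model leaning on
incidental structure instead of the water bands. Multiplicative/additive
scatter (a ~ U[0.9, 1.1], b ~ U[−0.02, 0.02]) and i.i.d. Gaussian channel
noise (sd 0.005 reflectance units) are applied after absorption; SNV and the
derivative are expected to remove them. This is deliberately not a
radiative-transfer model (no PROSPECT-style leaf structure): the pipeline
needs a monotone, band-localized Ψs signal plus scatter artifacts, nothing
more.

**Scene mix and interference.** Each stream frame views leaf with
probability 0.7, otherwise one of five stylized non-leaf materials (canopy
gap, wood, wire, irrigation pipe, grape berry) with equal weights. Templates
are validated at generation: a candidate must have cosine similarity < 0.985
to the reference leaf signature, re-jittered up to five times, else
generation fails loudly. With defaults, leaf-vs-signature cosines stay above
0.991 and interference below 0.978 on both sensor grids, so the two
populations genuinely straddle the 0.985 operating threshold rather than
being trivially separable.

**Kinematics.** The vehicle moves at 3 km/h; each 18 m row yields
row_length/speed·rate frames (270 at 12.5 Hz), with an 8 s headland gap
between rows; GPS runs at 20 Hz along the monitored row. Raw counts are
reconstructed from reflectance via the dark/white lamp model so the
acquisition stage has something real to calibrate.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: canopy 3-D structure and view-angle effects,
illumination drift within a pass, temperature-dependent band shifts,
spatially autocorrelated soil/irrigation patterns beyond the block design,
and reference-method operator error. Model skill on synthetic campaigns
(R²cv ≈ 0.9) is accordingly higher than field studies report (≈0.7); the
tests assert the qualitative regime, not field-level difficulty.

## Acquisition and filtering

Reflectance is the two-point calibration R = (S−D)/(W−D); channels where
W = D abort with the offending wavelengths listed. The workflow order
(dark → white → signature → measure) is enforced; each step writes its own
file plus a final filtered table. GPS pairing takes the nearest fix within
0.5 s (sensor at 12.5–14 Hz vs GPS at 20 Hz makes this unambiguous); frames
beyond tolerance are kept but flagged unlocated. Negative or >1 reflectance
at calibration edges is kept, not clipped — SNV is scale-invariant, clipping
would only distort. Filtering operates on calibrated reflectance spectra,
before any preprocessing; a frame exactly at the threshold is accepted.
Block allocation is point-in-polygon (boundary-inclusive) in the layout's
local metric frame; the block-mean spectrum of a date is paired with each of
the block's three group references, so one date contributes three samples
per block sharing a spectrum but not a response.

## Preprocessing

SNV uses the sample (n−1) standard deviation; zero-variance spectra are an
error. The Savitzky–Golay derivative is scaled by the channel spacing so
units are per-nm, and edges are handled by fitting the polynomial on the
truncated terminal window, keeping the output length and the channel grid
stable for VIP indexing. Defaults: window 7, polyorder 2, first derivative
for the 118-channel grid (a ~57 nm neighbourhood); window 15 suits the
501-channel grid. Default order is SNV then derivative; both orders are
configurable and the config is serialized into the model so train and
predict share one code path.

## PLS, cross-validation, VIP

PLS1 is fitted by the NIPALS recursion with internal centering; the
regression vector is b = W(P'W)⁻¹q. If deflation makes the residual
orthogonal to y the fit stops early and returns a reduced model with a
warning flag instead of failing. Venetian-blind folds assign sample i to
fold i mod 10 in stored (date-major, block-minor) order. Centering is
refitted inside each training fold; SNV and the derivative are per-spectrum
operations, so they carry no cross-fold statistics by construction. The
latent-variable count is the first local minimum of RMSECV — the smallest A
with RMSECV(A) < RMSECV(A+1), ties treated as still decreasing, monotone
curves selecting a_max (default 20). R² is the coefficient of determination
1 − SSE/SST, not squared Pearson correlation. VIP follows the
explained-sum-of-squares definition; mean(VIP²) = 1 is asserted to 1e−8 on
every fitted model.

External validation draws 7 samples per date into the hold-out after
excluding every sample tying that date's maximum or minimum Ψs (outlier
shielding); with 6 × 36 samples that is 42 (19.4%, the "20%" convention).
The split is a seeded permutation, reproducible by construction.

## Mapping

Point Ψs values are interpolated with a thin-plate spline
(`scipy.interpolate.RBFInterpolator`, degree-1 polynomial tail), which
reproduces constants and planes exactly and interpolates the data when the
smoothing penalty λ is 0. The module defaults are exact interpolation and
per-grid classification into at most five ordered zones (quantile or
equal-interval breaks; class 0 = most stressed). Grid cells default to 2 m,
below the 2.60 m row spacing; cells outside the convex hull of the points
buffered by one row spacing are masked. Inputs in lon/lat are projected to a
local tangent plane before distance computation (an equirectangular
approximation, sub-centimetre at plot scale).

The end-to-end demo comparison makes three deliberate choices on top of
those defaults. Predicted and reference maps are classified with a *shared*
legend (breaks from the pooled cells of both surfaces) because class
agreement against per-surface breaks is meaningless. The demo uses three
zones — the low/medium/high framing irrigation decisions actually use, and
models at this skill level resolve three zones reliably, whereas five
quantile zones have widths comparable to the surface RMSD. And the demo
smoothing is λ = 300, sized so the surface's RMS residual at the data points
(≈0.09 MPa) matches the reference method's ≈0.1 MPa group-level sampling
noise; exactly interpolating known noise would transfer it into the class
boundaries.

## Problem sizes and determinism

The default campaign (six dates, 12 blocks, ~19 400 frames of 118 channels,
216 samples) runs end-to-end in well under a minute on one CPU; the test
suite and the acceptance script use it as-is. Every stochastic step draws
from a `numpy` Generator seeded from the run seed (per-date child seeds via
`SeedSequence`, kept below 2³¹), and campaigns are verified bit-identical
under seed reuse via a SHA-256 checksum over all frames and references.

## Known limitations

- The leaf model's Ψs→spectrum link is stylized; absolute RMSECV values are
  not comparable to field instruments.
- The thin-plate spline approximates the regularized-spline interpolators of
  commercial GIS tools; their exact weighting is proprietary and no attempt
  is made to match it.
- PLS2 (multivariate response), variable-selection PLS variants, kriging,
  and machine-learning baselines are out of scope.
- The acquisition module replays recorded or simulated streams; it does not
  talk to instruments.
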