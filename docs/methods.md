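# Methods

## The measurement problem

The membrane-associated periodic skeleton (MPS) organizes actin rings
along axons at a ~190 nm pitch, and many axonal membrane proteins follow
that lattice — either in phase with the rings or in the spectrin gaps
between them.  Demonstrating such periodicity from super-resolution
(STED/STORM) images by drawing a line profile through a hand-picked region
is irreproducible and biased.  `ringcorr` instead analyzes *every* part of
a masked structure on a fixed grid and reduces each grid to two scalars —
an autocorrelation amplitude (how periodic) and a frequency (at what
period) — plus, for two-channel images, a cross-correlation shift that
classifies the two labels as overlapping or alternating.

## Pipeline

1. **Masking.**  The region of interest is a binary mask: thresholding of
   one user-chosen channel after an optional mean filter (radius `r`,
   window `2r+1`; radius 0 disables smoothing), optionally edited by
   add/erase coordinate sets, with erase taking precedence.  Everything
   outside the mask is background and never contributes to any mean.

2. **Grid partition.**  The image is tiled from the top-left in row-major
   order into grids of user-defined height and width (defaults: 1 µm
   height, width equal to the image width).  Tiles whose mask region is
   empty are dropped; a trailing partial tile at the bottom/right edge is
   kept when it contains mask pixels, so no foreground is silently
   discarded.  The 1 µm default height matches the ~190–200 nm MPS pitch
   (≈5 periods per grid) while tolerating axon curvature.

3. **Oriented profiles.**  For each angle θ in the sweep (default −20° to
   +20° in 1° steps; 0° points along the column axis, positive is
   counter-clockwise), every pixel is assigned to one of a family of
   parallel digital (Bresenham) lines perpendicular to the profile
   direction.  Consecutive lines are one pixel apart *along the profile
   direction*, so lag k of any correlogram corresponds to
   `k / pixels_per_um` µm at every angle; the closed form of this
   nearest-line assignment is `label = round(c·cosθ − r·sinθ)`.  The mean
   masked intensity per label is the profile.  Labels empty of mask pixels
   are trimmed at the profile ends and linearly interpolated in the
   interior; masked-out pixels are excluded from the means rather than
   contributing zeros, because zeros at mask edges would fabricate
   periodic dips.  Two-channel images share the identical label layer per
   angle, which is what makes the per-angle cross-correlation meaningful.

4. **Correlation.**  Profiles are centred by subtracting their mean.  With
   σ the population (divide-by-N) standard deviation,

       A(k)      = Σ_{i=1..N−k} n'_i n'_{i+k},   k = 0 … N−1
       A_norm(k) = A(k) / (N σ²)

   The population σ is forced by the requirement `A_norm(0) = 1`; no
   per-lag length correction is applied, so the correlogram tapers toward
   large lags — deliberate, since amplitudes are compared between
   profiles, not interpreted as spectra.  The cross-correlogram
   `C_norm(k) = C(k)/(N σ₁ σ₂)` is two-sided, the negative branch defined
   by swapping channel roles (`C(−k) = Σ n'_{2,i} n'_{1,i+k}`); the sign
   convention (positive lag = channel 2 leads) is immaterial after
   folding.

5. **Feature extraction.**  Extrema are sign changes of the first
   difference; a plateau reports its centre lag rounded down; endpoints
   are never extrema.  Counting the forced lag-0 maximum as the first
   maximum, the *frequency* is the lag of the second maximum (converted to
   nm) and the *amplitude* is the correlation difference between the
   second maximum and the first minimum.  A correlogram without both
   degrades to NaN frequency and amplitude 0.  The cross-correlation
   *shift* S is the lag of the larger of the two local maxima closest to
   lag zero (nearest non-positive and nearest non-negative candidates;
   ties to the smaller |lag|, then the non-negative lag).  Correlograms
   are not smoothed before extrema detection; robustness comes from the
   frequency filter below.

6. **Post-processing.**  Per grid, entries outside the angle range or the
   frequency window (default 170–230 nm; undefined frequencies always
   fail an active window) are discarded.  For single-channel reporting the
   surviving entry with the highest amplitude is kept (ties: angle nearest
   0°, then the smaller signed angle); a grid with no survivor reports
   amplitude 0 and NaN frequency.  For two channels, one angle is retained
   per grid — the one maximizing the mean autocorrelation amplitude of
   both channels, among angles where *both* channels pass the filters and
   a cross-correlogram exists — and every reported value of that row
   (amplitudes, frequencies, shift) comes from that single data point.
   The shift is folded into half a period,

       L  = (F₁ + F₂) / 4
       S' = L − |(S mod 2L) − L|        (floored modulo)

   and classified Overlapping if `S' < L/2`, Alternating if `S' ≥ L/2`
   (the boundary is Alternating).  An optional amplitude threshold
   (reference value 0.6) removes grids whose smaller channel amplitude at
   the selected angle falls below it.

## Simulator

The generator reproduces the validation design used to characterize the
method, entirely from code:

* **Masks.**  `synthetic_axon_mask` draws a band of configurable width
  (default 0.6 µm) following a smoothly drifting centerline whose slope is
  set by `curvature` (default 0.2, local orientations within the ±20°
  sweep).  The drift is monotone, so each 1 µm grid band contains one
  contiguous crossing; a 20 µm mask yields ≈5 analyzable grids.  Real
  masks are supported through the same skeleton path.
* **Backbone.**  Lee's 3-D-capable thinning restricted to 2-D, then the
  longest geodesic path between skeleton endpoints (two breadth-first
  searches).  The pixel polyline is low-pass filtered (Gaussian, σ 3 px)
  before arc-length measurements: the raw staircase path is ~5–8% longer
  than the underlying curve, which would otherwise compress the simulated
  ring period by the same factor.
* **Zones.**  Anchor points every 200 nm of arc length along the backbone
  (the simulated ring spacing); at each anchor a Bresenham line
  perpendicular to the local tangent — estimated from up to three anchor
  neighbors on each side — is drawn, dilated by a 2 px half-width disk
  (≈50 nm ring footprint at 100 px/µm) and clipped to the mask: the
  on-line zone.  The rest of the mask is off-line.  The alternating zone
  map advances every anchor by half a period (100 nm) along the backbone.
* **Points.**  With point density D (default 100 points/µm²), pixel
  density PPM², zone areas A and periodic localization percentage F
  (PLP ∈ [50, 100]):

      P_total = round(D (A_on + A_off) / PPM²)
      P_on    = round(P_total · A_on F / (A_on F + A_off (100 − F)))
      P_off   = P_total − P_on            (conservation by subtraction)

  PLP 50 therefore scatters points uniformly over the mask; PLP 100 puts
  all of them on the rings.  Rounding is half-up.
* **Rendering.**  Points are sampled without replacement within each zone
  and valued 1 ("constant") or uniform in [0.3, 1] ("uniform" signal
  variance), convolved with a unit-peak isotropic Gaussian kernel
  truncated at 3σ (RED 60 nm FWHM, ORANGE 90 nm — parametric stand-ins
  for the two STED fluorophore spot sizes; any pair with RED < ORANGE
  preserves the qualitative behavior), and overlaid with zero-mean
  Gaussian noise of standard deviation `noise_pct`/100 of the kernel peak
  over the whole image, unclipped.  Sub-1e-9 FFT residues are zeroed so
  untouched background is exactly 0.
* **Two channels.**  Overlapping pairs re-spawn points independently in
  the same zone map; alternating pairs spawn channel 2 from the
  half-period-shifted map.

Defaults (RED, no noise, 100 px/µm, D = 100, constant variance) are the
reference condition of the validation study; one-factor-at-a-time sweeps
vary a single parameter against it.

## Validation experiments and problem sizes

`ringcorr.validate` reruns the simulation study at desk scale.  Per-grid
amplitudes across PLP levels are compared with two-sided Mann-Whitney U
tests, reported raw (no multiplicity correction).  Classification accuracy
is the fraction of classified grids whose Overlapping/Alternating call
matches the generated pattern; cells with fewer grids than the
minimum-data-point criterion (10) are flagged.  The suite and the
acceptance script use 20 µm masks and 8–48 masks per condition (roughly
150–450 grids per level — comparable to the 195 grids per level of the
original study), sizes chosen to keep full runs in the minutes range on a
single core.  Key observed behaviors: median detected period exactly
200 nm at PLP 100; mean amplitude strictly ordered in PLP over 50–100;
classification accuracy ≈80% per pattern at 65/65 PLP unthresholded, 100%
at 100/100; chance-level (~50%) at 50/50.

## What the synthetic data does and does not show

The generator emulates ring spacing, point statistics, kernel blur, image
noise and two-channel phase relations.  It does not emulate out-of-focus
neurites, labeling stoichiometry, deconvolution artifacts, photophysics
(blinking, bleaching), 3-D geometry, or empirically shaped point-spread
functions.  Passing tests therefore certify the estimator chain and its
statistical behavior under controlled periodicity, not performance on any
particular microscope's data.

One deliberate divergence from intuition deserves a note: *image noise
barely moves the amplitude at low PLP in this generator.*  Because
profiles average each label over all mask pixels of a line (~60 px for a
0.6 µm band at 100 px/µm), added pixel noise is suppressed ~8-fold and
contributes only a few percent of profile variance, which is invisible
next to point-sampling fluctuations (measured: means 0.117 vs 0.116,
p ≈ 0.2 at ~225 grids per level for 0% vs 30% noise at PLP 50).  A
pipeline whose profile extraction averaged fewer pixels per label — or
included background pixels — would be more noise-sensitive.  The
corresponding acceptance test is intentionally left failing rather than
weakened, as a documented property of this design.

## Numerical choices and degenerate inputs

* Population (divide-by-N) σ in the normalizations, so `A_norm(0) = 1`
  exactly; the sample estimator would give N/(N−1).
* Constant profiles (zero variance) and profiles with fewer than two
  occupied labels skip that grid × angle combination; a cross-correlogram
  with no local maxima excludes the grid from cross analysis.
* Floored modulo in the shift fold, making S and −S, and S and S + 2L,
  equivalent.
* Plateau extrema report the centre rounded down — deterministic and
  symmetric under profile reversal up to one lag.
* All randomness flows through `numpy.random.default_rng` seeds; every
  experiment is reproducible bit for bit from its seed, and identical
  inputs yield byte-identical CSV outputs (floats printed at 6 significant
  digits).

## Known limitations

* Angles approaching ±90° are outside the label-layer domain (the line
  family would parallel the profile direction); sweeps are intended for
  structures roughly aligned with the image x axis, as captured axons are.
* The frequency grid is quantized at the lag resolution
  (10 nm at 100 px/µm), so detected periods are multiples of it.
* Interior mask gaps are linearly interpolated; profiles crossing long
  gaps dilute periodicity rather than splitting the grid.
* The amplitude is not bounded by 1 (it is a difference of two correlogram
  values) and depends on point density; comparisons are only meaningful
  within matched acquisition and labeling conditions.
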