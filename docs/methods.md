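# Methods

## Problem and signal model

Regional lung ventilation modulates the luminance of chest fluoroscopy: in an
anteroposterior projection, the X-ray signal at a point reflects the
anterior–posterior thickness of aerated lung, which oscillates with breathing.
The luminance time series of a small lung region is modeled as a sum of a
static component (ribs, mediastinum, baseline lung thickness), a respiratory
wave at the breathing fundamental f_r (≈0.1–0.5 Hz at rest), a cardiac-band
component (≈0.8–2 Hz) and broadband noise.  Because resting breathing is
approximately periodic and the respiratory and cardiac bands are disjoint,
the respiratory component can be isolated by retaining only the discrete
Fourier bin at f_r (plus, optionally, its immediate neighbours) in each
region's time series and inverting the transform.

The pipeline has five stages.

### 1. Respiratory phase from the diaphragm

One designated control point (default: point 5 of the left lung, the
costophrenic region) provides a per-frame y-coordinate y5_t, either supplied
in the annotation file or tracked from the images.  The normalized phase is

    r_t = (y5_t − y5_min) / (y5_max − y5_min),

exactly 1 at the maximal-inspiration frame and 0 at maximal expiration
(image origin top-left, y increasing downward, so y5 increases on
inspiration).  r_t is applied without smoothing or clipping; ties for the
extrema resolve to the earliest frame.  A single global r_t drives both
lungs.

The tracker (used only when no trace is supplied) smooths the column
intensity profile through the seed's x with a 1-D Gaussian (σ = 2 px), takes
the row of maximum absolute vertical gradient inside a search window centered
on the previous frame's estimate, and refines it with a parabolic fit through
the gradient peak.  On phantoms at SNR 10 with a 10 px excursion this
recovers the excursion amplitude to well under 5% (≈0.3 px rms).  Sub-pixel
accuracy degrades for very small excursions (a 6 px excursion can carry
≈0.5 px quantization at the extremes), which is why the designated point
should sit on a high-contrast diaphragm edge.

### 2. Contour interpolation

Each lung field is a closed chain of quadratic Beziers over 12 (left) or 10
(right) control points; odd indices are on-curve anchors at anatomical
landmarks, even indices are the off-curve auxiliaries.  Given the annotated
inspiration (IP) and expiration (EP) control points, every frame's contour is

    P_{i,t} = (1 − r_t) · EP_i + r_t · IP_i,

an affine blend that reproduces IP exactly at r = 1 and EP at r = 0.  Each
frame's boundary is validated for simplicity on a 32-samples-per-segment
polygonal approximation (required by the tiling stage).

### 3. Block grid

Division counts are fixed once from the maximal-expiration contour (the
smallest lung field) and reused for every frame, so block (m, n) is a
deforming region following roughly the same tissue:

* The two apex-to-base boundary chains (left lung: medial chain P1→P11→P9→P7
  and lateral chain P3→P5; right lung: lateral P1→P9 and medial P3→P5→P7)
  are sampled at 256 points per segment; the shorter one is divided into
  4-pixel arc lengths, M = max(1, round(L/4)).  `round` keeps the mean cell
  edge closest to 4 px.
* M + 1 quadratic band curves are drawn.  Curve k runs between the
  equal-arc-length fraction k/M points of the two side chains, with its
  control point at fraction k/M along the straight segment joining the apex
  segment's control point to the base segment's control point (left: P2–P6;
  right: P2–P8).  Curve 0 therefore coincides with the apex boundary segment
  and curve M with the base segment — the construction tiles the entire
  field with no gaps at the poles.
* Band m's shorter bounding curve sets N_m the same way; both curves are
  split into N_m equal-arc pieces and corresponding split points joined by
  straight lines.  Cells are stored as sampled polygons (8 samples per
  curved edge).

Equal-arc positioning uses cumulative-length inversion on the dense
polylines (tolerance well under 0.05 px at 256 samples/segment).  On
phantom contours the cells are interior-disjoint and tile the lung polygon
within 1% area.

### 4. Block signals

value(b, t) is the arithmetic mean of pixels whose centers (integer
coordinates) fall inside cell b's polygon at frame t.  Cells are ≈4×4 px, so
center membership is an adequate substitute for partial-area weighting.  A
cell that captures no pixel center takes the frame value bilinearly
interpolated at its centroid, keeping the block count constant.  The default
analysis signal is the adjacent-frame difference, which removes static
per-block offsets exactly and matches the "respiratory differential wave"
interpretation of the output; the raw series is a configuration switch.

### 5. Spectral filtering

The respiratory fundamental is the maximum-magnitude in-band bin
(default band 0.05–1.0 Hz) of the linearly detrended r_t spectrum; the
resolution is frame_rate/N and an override parameter is available.  Each
block series is mean-removed, transformed, all bins zeroed except the
fundamental bin ± half_width_bins (default 1, absorbing slight breathing-rate
drift; 0 gives the strict single-bin filter), and inverse transformed.
Amplitude and phase come from the fundamental coefficient in the sine
convention (x ≈ A sin(2π f t + φ)).

Detrending is mean-only by default.  Removing a fitted linear trend is *not*
neutral for short records: for a k-cycle on-bin sinusoid the fitted slope is
O(A/kN) and its removal biases the fundamental amplitude by ≈ 6/(π²k²) —
about 7% at the 3 cycles a 12 s acquisition contains.  Mean removal is exact
for any record-periodic signal; `linear` remains available for drifting
baselines, and differencing already suppresses drift.  The rectangular
window is the default (exact for on-bin components); a Hann option with
coherent-gain correction is provided for strongly off-bin breathing.

When the differenced series was analyzed, amplitude/phase maps are converted
to raw luminance units using the closed-form gain 2·sin(πf/fs) and phase
advance πf/fs + π/2 of first differencing.

### Rendering

Cells are filled with a diverging colormap (blue–white–red) of the per-frame
reconstruction, alpha-blended (default 0.5) over the grayscale frame; the
scale is fixed across frames at ±(99th percentile of |recon|) so temporal
oscillation and phase reversals remain visible.  Amplitude and phase still
maps are available separately.  PNG-stack export is lossless and
deterministic; MP4 export requires an ffmpeg-enabled imageio backend.

## Synthetic phantom

The phantom emulates exactly the structure the method assumes, with known
ground truth:

* **Geometry.** Two lung-shaped 12/10-point templates; breathing is a
  vertical stretch about a horizontal apex line with factor 1 + e·r(t),
  r(t) = (1 + sin 2π f_r t)/2, where e is set by the configured diaphragm
  excursion.  Since quadratic Beziers are affine-invariant, the stretched
  template *is* the interpolated contour, so the annotation (exact IP/EP
  templates, exact diaphragm trace) is perfectly consistent with the images.
* **Luminance.** Fields are material (defined in expiration coordinates and
  advected with the stretch): baseline + apex-to-base ramp, respiratory
  amplitude map A(x, y) with phase map φ(x, y), a global cardiac sinusoid
  inside the lung fields, and per-pixel Gaussian noise (Poisson statistics
  are not modeled; the pipeline is linear, so the noise family is
  secondary).  Lesions multiply A and shift φ inside a polygon, emulating
  the patchy "mosaic" amplitude loss and locally phase-reversed respiratory
  signal of obstructive disease.
* **Ground truth.** Per cell of the expiration grid, the exact amplitude and
  phase of the block's respiratory wave are |mean_cell(A e^{iφ})| and its
  angle, plus the lesion-area fraction.

Defaults mirror the target acquisition: 1024×1024 at 12.5 fps for 250 frames
(20 s), 4096 gray levels, 40 px excursion, f_r = 0.25 Hz, cardiac 1.2 Hz at
10 counts, respiratory amplitude 30 counts, noise σ 3 (SNR 10).  The *fast
profile* used throughout the test suite is 256×256, 101 frames (≈8 s),
10 px excursion, cardiac 1.25 Hz.  The frame counts are chosen so the
fundamental is on-bin: 101 frames make the differenced record (100 samples)
an integer number of 0.25 Hz cycles, and 1.25 Hz (75 bpm) keeps the cardiac
tone on-bin as well — with a rectangular window an off-bin cardiac tone
leaks ≈3% into the fundamental, which is a windowing artifact rather than a
property of the band-pass.

What passing phantom tests do **not** show about real data: the phantom has
no ribs or other moving overlying structure, no scatter, no dose
nonlinearity, its deformation is exactly the affine model the analysis
assumes (so grid-tracking error is near its best case), and its breathing is
strictly periodic.  Rate drift, irregular breathing and rib artifacts in
real sequences will degrade the single-bin filter in ways these tests do not
measure.

## Numerical choices and degenerate inputs

* Arc lengths: 256-point polyline sampling per Bezier segment; simplicity
  checks at 32 points/segment via polygon validity.
* Division counts: max(1, round(L/4)); a zero-length side chain is an error.
* r_t requires y5_max > y5_min; a flat trace is an error, not a NaN.
* Band-pass refuses a fundamental on the DC or Nyquist bin.
* Empty grid cells fall back to centroid interpolation; a cell fully outside
  the image is an error.
* Frame-rate precedence: explicit override > DICOM cine-rate metadata
  (CineRate, then FrameTime, then RecommendedDisplayFrameRate) > error.
  Image stacks always need an explicit rate.

## Known limitations

* Landmarks are inputs: there is no automatic IP/EP detection.
* One global phase drives both lungs; per-lung phase is out of scope.
* The anchor/auxiliary (odd/even) convention and the identity of the
  vertical side chains are conventions of this implementation; the
  right-lung construction mirrors the left one.
* Single-bin filtering assumes stable breathing over the acquisition;
  half_width_bins = 1 tolerates mild drift only.
* Grid cells follow the affine contour interpolation, not true tissue
  motion; near the hilum and diaphragm the correspondence is approximate.
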