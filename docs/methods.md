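# Methods

## Scope and data model

The package analyzes stimulus-evoked calcium signals recorded from
the mouse inferior colliculus (dorsal cortex imaged from above;
lateral cortex imaged from the side via microprism) during auditory,
somatosensory, and bimodal stimulation. It begins after motion
correction: inputs are motion-corrected multi-page TIFF stacks
(typically 512×512 px at 29.9 Hz) plus manually drawn ROI masks
(ImageJ archives or label images), or pre-extracted per-ROI traces.
Surgery, hardware control, audio synthesis, speaker calibration, and
motion correction itself (e.g. NoRMCorre) are out of scope; group
level hypothesis testing uses standard statistics libraries directly.

## Stimulus protocol

Grids follow the published protocol: pure tones at 5–40 kHz in
half-octave steps (7 carriers) × 40–80 dB SPL in 10 dB steps
(5 levels) = 35 combinations; 100% AM white noise at modulation rates
0, 2, 4, 8, 16, 32, 64, 128, 256 Hz × the same 5 levels = 45
combinations (0 Hz denotes unmodulated noise). Stimuli last 500 ms
with a 600 ms inter-stimulus interval, so one repeat of the tone grid
spans 38.5 s (fitting a 40 s movie) and one AM repeat 49.5 s (fitting
52 s). Schedules are a single seeded uniform permutation of all
combo × repeat slots — no block structure — with onsets strictly
periodic at 1.1 s. The top of the carrier range is included when the
geometric step lands within 0.1% of it, guarding against
floating-point shortfall at 40 kHz. Somatosensory and bimodal blocks
are single-combination schedules, five presentations by default.

## Signal extraction

Processing order is filter → extract → neuropil-correct → normalize.

* **Filtering.** Separable Gaussian smoothing: spatial σ of 1 px for
  surface fields of view and 2 px for microprism views, then a
  temporal σ of 2 frames; reflection padding at the ends (the edge
  rule is our choice; any sensible padding changes only the outermost
  ~4 frames). When the pipeline starts from traces rather than
  pixels, the same temporal filter is applied to the traces so both
  paths see identical smoothing.
* **Extraction.** Soma signal = mean over ROI pixels per frame.
  Neuropil signal = mean over an annulus grown by iterative binary
  dilation from the ROI until its area reaches 4× the ROI area,
  excluding every cell's pixels.
* **Neuropil correction.** corrected = soma − 0.4 × neuropil. The 0.4
  coefficient is the conventional contamination factor for somatic
  GECI recordings and is exposed as a parameter.
* **ΔF/f.** (F − F₀)/F₀ with F₀(t) a fitted photobleaching trend. The
  trend model is deliberately simple: a straight line fit to the
  running 10th-percentile envelope (10 s window), which tracks slow
  bleaching while ignoring transients. A plain linear detrend of the
  raw trace is available as `baseline_method="linear_trend"`. Both are
  recorded in the output. Correction is applied before normalization.

## Responsiveness and tuning

ΔF/f is segmented into windows [onset − pre, onset + 500 ms + post].
The default response window is onset to onset + 1.1 s (post = 600 ms,
i.e. through the ISI) so that offset responses are captured; pre = 0
except for timing classification, which needs a baseline. Repeats of
the same combination are pooled across runs by combo identity.

A cell × combination is **responsive** when the mean Pearson
correlation over all unordered repeat pairs is strictly above 0.6
(0.4 for the somatosensory/bimodal comparison). Pairs involving a
zero-variance trial contribute r = 0 (undefined Pearson), logged.
Response magnitude is the trapezoidal AUC of the trial-averaged ΔF/f
over the window with negative-going segments clipped to zero
(excitatory responses only); the signed integral is available.

BTF/BMF = frequency of the flagged combination with maximal AUC over
all levels (a per-level best is used inside the level-resolved
indices); exact ties break toward the lower frequency, logged. RFS
counts flagged combinations per level and in total. SMI/TMI are
computed per sound level, pairing the level's best tone (or AM)
response with the unmodulated-noise (0 Hz AM) response at the same
level; the unmodulated response enters as 0 when not flagged. RI
requires a positive auditory-alone response; RI exactly 1 is
classified "unchanged" (logged; with continuous data it is a measure-
zero event). Timing classes compare the peak ΔF/f in the stimulus
window and in a 600 ms post-offset window against k·SD (k = 3) of the
pre-stimulus baseline — this rule is our operationalization of
onset/offset labels, with k and the windows exposed.

## Tonotopy

Distances from an axis origin are binned half-open at 50 µm; the
geometric means of BTF and of distance are taken per bin (a zero
distance enters as the bin's lower edge + 1 µm); linear and quadratic
ordinary least squares are compared by R². Because geometric
averaging implies multiplicative structure, fits are on log₂(BTF) by
default, with a raw-Hz option.

Two distance conventions are provided. The straight-line Euclidean
distance from the origin matches the classical formula but is
identical for every axis direction sharing an origin, so it cannot
distinguish candidate axes; the scalar projection onto the axis
direction can, and is what the axis-comparison workflows (pipeline,
validation) use. The two coincide for cells lying on the axis line.
Cells projecting behind the origin are excluded with a log entry.

## Spontaneous events

Stimulus-free traces are detrended with a least-squares polynomial
(default order 2; the fitted constant term is added back so the
baseline level is preserved), then scored causally: for each frame
after the first second, z = (x − mean)/SD over the trailing 1 s
window (29 frames at 29.9 Hz; a global-SD variant is provided since
the window-vs-global choice is open). Frames with z strictly above 3
mark events; consecutive supra-threshold frames merge into one event.

A consequence worth stating plainly: for a frame-wise z > 3 rule on
Gaussian noise, the false-alarm probability is ≈0.13% per scored
frame (~1800 frames/min), so the detector has an irreducible floor of
a few false events per minute on pure-noise traces (we measure ≈6/min
at these settings). On real recordings the rule is serviceable
because genuine transients dwarf noise excursions in amplitude and
duration; users needing a low false-alarm regime should raise the
threshold or screen events by duration downstream. We keep the rule
as stated rather than silently hardening it.

## Synthetic experiments

The generator emulates exactly the structure the analysis assumes:

* **Kinetics.** Transients are a difference of exponentials, 50 ms
  rise and 700 ms decay, resembling red-GECI dynamics; peak
  normalized to 1 and scaled by the cell's evoked amplitude.
* **Tuning.** Evoked peak ΔF/f follows a Gaussian in log₂ frequency
  centered on the cell's true BTF (tones) or BMF (AM rates), SD
  0.7 octaves by default; broadband/unmodulated stimuli drive
  responsive cells at 0.6 of their preferred amplitude; amplitude
  grows linearly with level from a per-cell threshold (settable per
  compartment) to the loudest level presented.
* **Trace model.** recorded = bleach(t) · F₀ · (1 + Σ transients) +
  0.4 · neuropil(t) + noise, with F₀ = 100 a.u., single-exponential
  bleaching (τ = 600 s by default), a shared slowly wandering
  neuropil background at 0.5 F₀, and i.i.d. Gaussian noise of SD 5
  a.u. (5% of baseline — evoked responses at the default amplitude of
  0.6 ΔF/f are ≈12× the noise SD, comfortably above the ≈3× regime
  where flagging begins to degrade). Offset-timing cells emit
  transients at stimulus offset; bimodal presentations multiply the
  auditory amplitude by the cell's bimodal gain. Spontaneous
  transients can be injected as a Poisson process (0.05 Hz default).
* **Layouts.** Cells are uniform in a 500 µm field; `gradient`
  implants log₂(BTF) increasing linearly along a chosen axis over 3
  octaves with 0.25-octave per-cell jitter; `random` draws BTFs from
  the 7-carrier grid. Module/matrix compartments come from seeded
  contiguous disks with a target area fraction. `render_movie` paints
  disks carrying each cell's trace over the neuropil background and
  returns matching masks, for exercising the pixel path.

What the generator does **not** model: optics (PSF, depth, scatter),
motion artifacts, correlated network noise, overlapping somata,
inhibitory (suppressed-ΔF/f) responses, and run-to-run nonstationarity.
Recovery results on synthetic data therefore certify the pipeline's
correctness and statistical behavior under its own assumptions, not
performance on arbitrary real recordings.

## Validation problem sizes

The self-check benchmarks (`colliscope.validation`, also run by
`scripts/acceptance.py`) use 10 independent seeds per quantity:
30 random-layout cells × 5 repeats of the 35-combo tone grid for
flagging and BTF recovery; 200-cell gradients for tonotopy; 40
noise-free cells for the bimodal sign; 2-minute traces with six
injected 5·SD transients for event detection. These sizes give
binomial standard errors of a few percent on the reported fractions
while keeping a full run around ten seconds.

## Known limitations

* The baseline ("slope") model is linear; strongly nonexponential
  bleaching over long recordings would call for the polynomial
  detrender or a spline.
* Pearson-correlation flagging assumes repeat-stable response shapes;
  cells with reliable amplitude but jittered latency score lower.
* The AUC magnitude ignores suppressed responses by construction.
* No spike inference: all magnitudes are ΔF/f-domain quantities.
* The spontaneous detector's false-alarm floor on Gaussian noise,
  discussed above.
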