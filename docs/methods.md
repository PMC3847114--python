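# Methods

This note documents the models, numerical choices and limitations behind
`rtnf`. The package implements a streaming (real-time) fMRI neurofeedback
stack: volume ingestion, preprocessing, motion quality control, a
functional-localizer GLM, and three feedback engines, validated against
offline batch recomputation on synthetic sessions.

## Streaming model

The scanner side is modelled as a folder into which one reconstructed 3D
NIfTI volume per repetition appears (`vol_<index>.nii`, zero-padded,
0-based; the pattern is configurable). The watcher delivers volumes in
encoded-index order regardless of filesystem listing or mtime order, and
treats a file as complete when its size is non-zero and stable across two
polls ≥ 50 ms apart — a deliberately conservative contract, since export
tools differ in whether they write atomically. A gap that persists beyond
the configured timeout raises a stall error naming the last delivered
index. 4D files are rejected: the streaming model is strictly one file
per acquisition.

## Preprocessing

**Motion correction.** Each volume is realigned to the reference
functional image (RFI) by maximising normalised correlation over the six
rigid parameters (three rotations about the RFI intensity centre of mass,
three translations), then resampled with trilinear interpolation;
out-of-field voxels are zero. The optimiser is Nelder–Mead on a scaled
parameter vector (0.01 rad ≙ 1 mm per simplex step), warm-started from
the previous volume's fit during streaming.

Two estimation details matter at sub-voxel scale and are worth recording.
First, parameters are estimated on copies of both images smoothed by a
1-voxel Gaussian: without this, trilinear resampling's incidental noise
averaging *rewards* small spurious transforms on noisy data and biases
the fit away from the identity. Second, both sides of the cost are
resampled through a constant half-voxel offset (the candidate transform
composed with the offset on the moving side, the offset alone on the
fixed side, cubic-spline interpolation): every candidate, including the
identity, then pays the same interpolation penalty. Without the offset
the exactly grid-aligned identity is artificially favoured and small true
motions are missed. The final corrected volume is produced from the *raw*
input with trilinear interpolation, as stated in the pipeline contract;
the cubic path exists only inside the cost function.

**RFI→RAI registration.** A single 12-parameter affine fit (rotations,
translations, log-scales, shears; rigid-first two-stage optimisation)
maps the RFI to the anatomical reference for display overlay only — all
feedback computation stays in RFI space. A fit whose final correlation is
below a configurable floor (default 0.2) raises an error carrying the
best correlation seen, so structureless input is flagged rather than
silently accepted.

**Smoothing.** Separable Gaussian with per-axis sigma
`(FWHM / voxel_size) / (2√(2 ln 2))`; FWHM 0 is an exact no-op. Smoothing
follows motion correction; the pipeline order is fixed and documented
here because streaming engines cannot reorder retroactively.

## Motion quality control

Each fitted transform is summarised as its RMS displacement over a
uniform solid sphere of radius 80 mm (the conventional brain-sized
sphere): with the homogeneous matrix written in the frame of the rotation
centre and `M = T − I = [[A, b], [0, 0]]`,

    RMS² = (1/5) R² · trace(AᵀA) + bᵀb.

The `1/5 R²` factor is the second moment of the uniform *ball*; the unit
tests verify the closed form against a Monte-Carlo average over the ball
to 2%. A volume is flagged when its RMS deviates from the mean of the
previous `n` values (default 40; partial mean during warm-up; the first
volume is always kept) by strictly more than 0.4 mm. Flagged volumes
freeze the displayed level at its previous value and are excluded from
every estimator: baseline means, ROI sliding means, correlation buffers,
and decoder averaging windows. RMS is computed relative to the RFI, not
the previous volume, so the deviation-from-mean rule is meaningful across
a whole session.

## Baseline normalisation

All engines normalise against the most recently *completed* baseline
block: its per-voxel mean (over kept volumes only) is frozen at the
moment the design leaves the baseline condition and replaced only when
the next baseline block completes. This interleaved renormalisation is
what makes slow scanner drift tolerable without explicit detrending. A
baseline block whose volumes were all discarded leaves the previous state
in force and records a warning. Baseline normalisation is the ratio
`(x − b) / b` voxelwise (for SVM patterns and activation maps) or on ROI
means (for the ROI engine); the ratio form makes patterns comparable
across sessions with different raw intensity scales.

## Feedback engines

**ROI engine.** `raw = (m − b)/b` with `m` the sliding mean of the last
`n_avg` kept ROI means (default 1). Display level is
`clip(raw / r_max, 0, 1) · 100` with full-scale `r_max = 0.02` (2% signal
change) — the numeric mapping of ratio to thermometer is not fixed by the
published pipeline descriptions, so `r_max` is an explicit configuration
knob. A voxelwise activation-ratio map over the mean of the last three
kept volumes is available for display overlay, with zero-baseline voxels
masked.

**Connectivity engine.** On each kept volume the ROI-mean pair is pushed
into a ring buffer; once `L` kept pairs exist (default `L = 10`,
recommended range 10–15 for stability), ρ is the Pearson correlation of
the last `L` pairs, evaluated by the direct sum formula (the offline
replay uses `np.corrcoef`, giving a genuinely independent dual route that
agrees to 1e-12). The published formula indexes the window as
`t−1 … t−L`; we push first and then correlate, i.e. the window includes
the current volume — the same statistic under a one-step index shift,
chosen so feedback reflects the newest data. The thermometer midline is a
recency-weighted mean of the last `N` ρ values (default 10) with logistic
weights `w_j = 1/(1 + exp(j − N/2))`, `j = 0` newest — a sigmoid
discounting with unit slope; bounds are `midline ∓ k·sd` of the last `L`
ρ values (`k = 1`). Degenerate scales (constant ρ history) hold the
previous bounds. Before the buffer fills — and during the initial
five-volume discard prefix applied by every engine — samples are emitted
frozen at the midline level, keeping the display contract total.

**SVM engine.** Training examples are sliding-window averages (default 3
volumes) of kept volumes sharing one non-baseline label; windows
straddling a label change or a discarded volume are skipped, and each
averaged pattern is baseline-normalised and masked before entering the
solver. The solver is the libSVM-backed linear `SVC` (C default 1.0,
deterministic given data order); the hyperplane `(w, b)` is extracted
into voxel space so the weight map can be exported as NIfTI and the
streaming projection `x·w + b` is computed by the package itself. The
display full-scale `d_max` is the 95th percentile of |decision| over
training examples, and the signed distance toward the *cued* class is
binned uniformly onto `2 × n_bins` figure bins (default 5 per class):
bin 0 is the most distorted figure (confidently the wrong class), the top
bin the smoothest. The cue selects the figure family and the decision
value the distortion; cumulative accuracy over scored scans is tracked
per volume.

## Functional localizer GLM

The design file (one condition token per line, `#` comments) yields one
boxcar per non-baseline condition, convolved with the canonical
double-gamma HRF (positive lobe Gamma(6, 1) s, undershoot Gamma(16, 1)
scaled by 1/6, unit peak) sampled at the TR, plus an intercept and
optionally the six motion parameters. The baseline is implicit in the
intercept. The fit is voxelwise OLS with classical t statistics
(`t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c)`, dof = n − rank); no autocorrelation
correction is applied — the localizer is a feature-selection step, not an
inference step, so plain OLS is stated and tested (against the
normal-equation closed form and against `statsmodels`). Pairwise
contrasts among conditions (including each task vs implicit baseline) are
pooled by union for `|t| > τ` selection (default τ = 5.5); top-percent
selection takes the `⌈q·m⌉` highest-|t| voxels within a required ROI,
ties broken by ascending voxel index. Both selection modes are supported
because published usage is ambiguous about whole-brain vs within-ROI
thresholding; the caller must be explicit.

## Synthetic scanner

The generator emulates the statistical structure the engines assume, on a
default 16×16×12 grid at 3.75×3.75×5 mm (the classic 64×64 EPI matrix
scaled down ~4× in-plane for speed) with TR 2 s:

    s_t(v) = base(v) · (1 + Σ_c a_c(v)·m_c(t) + drift·t) + ε,
    ε ~ N(0, sd·1000)

where `base` is an ellipsoidal head phantom at 1000 arbitrary units with
smooth internal gradients plus a fine band-passed random texture (fixed
internal seed — real EPI has high-frequency structure, and without it
sub-voxel rotations are not identifiable); `m_c` is the condition boxcar,
HRF-convolved unless disabled and normalised to unit plateau so a
sustained block reaches the configured amplitude exactly; amplitudes are
fractions of the local baseline (0.02 = 2% signal change). Defaults
follow the protocols used throughout: 1% noise, 2% amplitudes, 15/22/35
volume blocks depending on protocol. Motion events apply a rigid
transform (cubic resampling) to the finished volume. Identical configs
(including seed) are bit-identical; the manifest records every injected
quantity so recovery tests are self-verifying.

What the generator does *not* model: physiological noise (cardiac,
respiratory), spatially correlated noise, susceptibility distortion,
spin-history effects of motion, and slice timing. Passing tests therefore
demonstrate correctness of the *computation* under the stated noise
model, not robustness to every artifact of real scanner data.

## Validation strategy

The primary check mirrors how real-time pipelines are validated in
practice: run the streaming pipeline end to end, then recompute the
feedback series offline in one batch pass (`batch_replay`) and correlate
the two series over time. The replay path is deliberately independent at
two levels: motion correction is re-fit cold-start per volume (the
streaming path warm-starts from the previous fit), and the engine
arithmetic is re-implemented in vectorised form sharing no state
machinery with the streaming engines. At study scale (300/296/360-volume
protocols) the streamed and replayed series correlate at r > 0.999 for
all three engines; `scripts/acceptance.py` recomputes this from scratch.
Engine-level equivalence on identical preprocessed inputs is additionally
asserted to 1e-10 in the unit tests, with and without QC discards.

Registration accuracy is assessed on a finer 32×32×20 phantom (3×3×3.5 mm)
because sub-voxel rotation recovery is resolution-limited on the small
streaming grid: there, known transforms up to 5 mm / 0.05 rad are
recovered within 0.004 rad and 0.2 mm (typically 10× better). Motion
spikes of ±2 mm / 0.02 rad produce RMS ≈ 2 mm and are always flagged at
the 0.4 mm deviation threshold; spike-free 1%-noise runs produce no false
flags on the 24×24×16 grid used for that check.

## Design choices on open points

- **Freeze semantics.** Warm-up periods (no completed baseline,
  correlation buffer not yet full) emit frozen samples at a neutral level
  rather than emitting nothing, so there is exactly one feedback row per
  volume after the discard prefix.
- **Strict threshold.** The motion flag fires on deviation *strictly
  greater than* 0.4 mm, fixed for testability.
- **Sham feedback.** A non-contingent control mode either replays a
  stored level series or emits seeded uniform-random levels; neither is
  claimed to reproduce any particular published control arm.
- **Per-volume wall time** is logged but never asserted: it is
  hardware-dependent.
- **Problem sizes.** Tests and the acceptance script use the block
  structures of the three protocols at their full session lengths
  (300/296/360 volumes) on the default grid, and scaled-down sessions
  (40–120 volumes) for unit-level checks; these sizes are the package's
  test design, chosen to exercise every contract with reasonable runtime.

## Known limitations

- The rigid/affine optimiser is a local method with a single
  (translation-seeded) basin search; motions far beyond ~10 mm / 0.1 rad
  on a structure-poor image can converge to a wrong basin. Real-time
  motion is small and incremental, which is the regime the warm-started
  streaming fit targets.
- Slice-timing correction, nonlinear registration and B0 unwarping are
  out of scope.
- The SVM engine is strictly two-class; the connectivity engine is
  strictly two-ROI (whole-brain connectivity is not a real-time
  operation in this design).
- Feedback rendering (thermometer/figure bitmaps) is the caller's
  concern; the engines emit levels and bin indices.
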