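# Methods

`beamadv` studies the adversarial robustness of seizure-detection networks
that consume brain electrical activity maps (BEAMs). This note documents the
models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does not
establish.

## From EEG to BEAMs

A trial is a tensor of T = 5 one-second slices x C = 22 electrodes x S = 256
samples (256 Hz). Each slice/electrode signal is decomposed with a full
wavelet-packet tree (db1, 8 levels, orthonormal filters, periodization), whose
256 leaves tile 0–128 Hz in 0.5 Hz bins. Leaves are re-ordered from the
tree's natural order to frequency order with the Gray-code permutation
`natural = f ^ (f >> 1)`; band selection is only meaningful in frequency
order. A rhythm band (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz,
half-open intervals) keeps the leaves whose nominal bin intersects it; the DC
leaf belongs to no band. Inverting the filtered tree gives the time-domain
rhythm, its unnormalized DFT the frequency-domain rhythm, and the mean
absolute value of that spectrum the rhythm power `P(t, b, c)`.

A caveat worth stating plainly: db1 (Haar) leaves have strong spectral
sidelobes. For a pure sinusoid the matching band always carries the largest
energy share, but that share is 0.4–0.8, not ~1 (with a longer filter such as
db16 the same leaf bookkeeping concentrates >= 99%). The transform is kept at
db1 because the attack pipeline is defined in terms of it; the wavelet is a
parameter for users who want sharper bands.

Powers are spread over the scalp per (slice, band): electrodes sit at
idealized 10-20/10-10 angles on a 0.095 m sphere, flattened by an equidistant
azimuthal projection about the vertex (planar radius = great-circle distance
from Cz, azimuth preserved). The minimum bounding rectangle of the projected
positions is meshed into H x W = 22 x 22 cells; scattered interpolation is
Clough–Tocher (piecewise cubic, C1, exact at electrodes), with grid points
outside the electrode convex hull filled from the nearest inside grid point.
The full rectangle (no head mask) is what victim models see.

Sampling a BEAM-space image back at the electrodes (needed to turn a BEAM
perturbation into a rhythm-power perturbation) uses bicubic interpolation on
the regular grid. This resampling is lossy: most of the 22 electrodes are
vertices of the convex hull, where the nearest-filled exterior biases the
bicubic stencil (median relative error ~1% at interior electrodes, worst-case
tens of percent at hull corners). That loss is intrinsic to the dense attack's
design and is precisely what the sparse attack avoids by perturbing the power
array directly.

## Victim models

Two families share one training interface and differ in input: BEAM-related
models consume (T, 4, 22, 22) map stacks; EEG-related models consume
(T, 1, 22, 256) raw slices. A shared per-slice conv stack (4x [3x3x32 conv +
ReLU] + 2x2 maxpool; the EEG stack continues with 2x [3x3x64] + pool +
3x3x128 + pool) feeds one of four temporal heads over the T per-slice feature
vectors: element-wise max, 1-D temporal convolution (kernel 3, 64 filters),
an LSTM (hidden 128), or the concatenation of the last two — then a
512-wide fully connected layer and a 2-class softmax. Training is Adam
(lr 1e-3, betas 0.9/0.999) on cross-entropy, batch 32, with early stopping on
a 15% validation split (patience 3, at most 30 epochs by default); dropout
0.5 + L2 1e-4 are enabled by default only for the EEG mixed head, the one
combination prone to overfitting. Runs are bit-reproducible given the seed.

The networks, backpropagation (including the input gradients the white-box
attacks require) and Adam are implemented directly in vectorized numpy;
gradients are verified against central finite differences in the test suite.
Convolutions are computed as one GEMM per kernel offset, which keeps memory
proportional to activations and makes single-CPU training of the desk-scale
experiments take minutes.

## The dense attack

1. Build BEAMs from the raw sample.
2. Generate a BEAM-space perturbation against the victim — FGSM
   (`eps * sign(input gradient)`) by default; I-FGSM, MI-FGSM and PGD are
   available with per-step projection to the eps ball and step eps/iterations.
3. Resample the perturbation image at the electrodes to get eta_P (T, B, C).
4. Impose eta_P on the frequency-domain rhythms: per spectral bin, the
   magnitudes of the real and imaginary components absorb
   `sign(eta) * eta^2`, split in proportion to their squared magnitudes,
   clamped at zero, with the original component signs restored afterwards.
   This magnitude reading is the unique one that makes eta = 0 the exact
   identity; bins with both components zero are skipped. Note the imposed
   power change scales as eta^2, so BEAM-space budgets translate
   quadratically into power space — at eps = 0.3 the realized rhythm-power
   shift is ~0.09.
5. Inverse-DFT each perturbed rhythm, wavelet-packet decompose it, splice its
   in-band leaves into the raw signal's decomposition, and invert. Out-of-band
   content is untouched, and the chain with eta = 0 reproduces the input to
   1e-6.

Success is judged by re-deriving BEAMs from the reconstructed EEG and asking
the victim again; distortion is reported both in BEAM space (DL_B, RMSE of
the BEAM perturbation) and EEG space (DL_E, RMSE of the signal change).

The modified dual-target variant first makes a plain EEG-space FGSM
adversarial sample against an EEG-input victim (budget eps_E) and uses it as
the carrier in step 5, while eta_P is still computed from the raw sample's
BEAMs (a flag recomputes it on the carrier instead). Matching eps_E to the
dense attack's measured DL_E keeps the total distortion unchanged while
making the output aggressive to both families.

## The sparse attack

Differential evolution (DE/rand/1/bin) searches over individuals of N genes;
a gene `(t, c, v_1..v_B)` perturbs the B rhythm powers of one slice/electrode
by `v / r` with integer `v` in `[-round(eps * r * delta), round(eps * r *
delta)]` (r = 100; delta = C with perturbation overflow, else 1). Mutation is
`X_r1 + F (X_r2 - X_r3)` (F = 0.5) rounded to integers, with out-of-range
entries redrawn uniformly; crossover rate CR = 0.6 (no forced-crossover
index, so CR = 0 is deliberately a no-op); greedy selection on fitness
`1 - max-class probability` of the victim on BEAMs built from P + eta.
Evolution stops once any individual flips the prediction away from the true
label, or after max_generations (50 by default). Population NP = 40 by
default; these DE constants follow standard DE practice and are surfaced in
`DEConfig`.

Perturbation overflow computes the total excess `sum(|eta'| - eps)+` over all
slices, bands and electrodes, adds `excess / C` to every electrode with the
sign pattern of the dense attack's eta_P on the same sample, and clips to the
eps ball. The excess is deliberately global — summed once over the whole
array and applied to every (t, b) row — which couples slices; a consequence
is that a single wide-range gene can already saturate the dense spread, so
the flip rate depends only weakly on the gene count N. Whether fitness
evaluates the overflow-adjusted perturbation (default) or the raw sparse one
is a flag.
Duplicate genes on the same (t, c) overwrite earlier ones.

## Evaluation

SR = flips / samples (against the true label; the clean-prediction-relative
count is recorded alongside, since either convention appears in published
tables). Acc = correct / samples. DL is the mean per-sample RMSE. The noise
baseline adds N(0, 0.5) to the BEAMs and reports its empirical DL_B rather
than assuming it equals sigma. Transfer evaluation feeds the adversarial EEG
to each target through that target's own input pipeline (BEAM conversion for
BEAM-input targets, the raw signal for EEG-input targets).

## Synthetic benchmark

The generator emulates the structure of seizure-annotated scalp EEG: 22
channels at 256 Hz in 5 x 1 s trials. Background is 1/f noise plus a 10 Hz
alpha rhythm (lognormal trial amplitude, sigma 0.3). The seizure class adds
(a) a focal 3 Hz spike-wave complex (fundamental + 3 decaying harmonics) on a
left-temporal electrode subset (F7, T7, P7, FT9), with lognormal
trial-to-trial amplitude (median 1.1 x background, sigma 0.45) and
per-channel weight jitter — the strong clinical feature whose weak-amplitude
tail keeps a well-trained classifier below ceiling; and (b) a diffuse
scalp-wide delta-band elevation (amplitude 0.35, per-channel jitter),
mimicking generalized slowing — many weak distributed correlates, so the
learned decision aggregates small spectral shifts across electrodes the way
models trained on real EEG do. Every sample is z-scored per channel, so the
classes differ in spectral topography, not gross amplitude. These amplitudes
were fixed so that the default BEAM-input victim lands in the accuracy
regime reported for comparable seizure-detection CNNs (~0.92-0.97) rather
than saturating; they are study conditions, not free dials.

What the synthetic task does not emulate: real electrode artefacts, patient
heterogeneity, non-stationary background, seizure evolution within a trial,
and realistic inter-channel correlation structure. Passing the benchmark
shows the pipeline's algebra and the relative behaviour of the attacks
(gradient > noise at matched distortion; overflow > no overflow; poor
transfer from BEAM-space to EEG-space models) — it does not certify absolute
success rates on clinical data.

Desk-scale problem sizes used by the bundled experiments: 400/400 training
and 100/100 test trials for the BEAM victim; attacks evaluated on up to the
full test set for the dense method and on 15–20-trial subsets across three
seeds for DE (population 20, <= 20 generations); the EEG victim for transfer
experiments trains on a 150/150 subset. These sizes keep a full run on one
CPU in minutes while leaving the compared rates enough resolution to order.

A limitation worth stating plainly: at these sizes the raw-EEG victim does
not reach the accuracy of comparable raw-EEG seizure classifiers trained on
real data. The deep EEG-input stack needs far
more trials and optimizer steps than the BEAM-input one (its per-slice input
is ~25x larger), and at 150/150 trials it hovers between chance and ~0.6
test accuracy depending on the seed. In the transfer and dual-target
experiments it therefore serves primarily as a white-box gradient source and
a family-of-its-own prediction pipeline, not as a competent diagnostician;
conclusions about EEG-family accuracy under attack should be drawn only
after training it at realistic dataset sizes.

## Segmentation and EDF input

For continuous recordings, seizure windows of 5 s start every 3 s inside
annotated seizure intervals (consecutive windows share 2 s); background
windows tile the complement non-overlapping; the background class is
subsampled to the seizure count. A simple artefact screen (flatline std <
1e-7, |x| > 15 after unit normalization) is available but off by default,
since no principled bad-data rule is prescribed. The optional EDF reader
(via `mne`) enforces 256 Hz, maps dataset channel names to 10-20 labels
through an editable TSV (the packaged default assigns the 22 distinct CHB-MIT
bipolar channels to 22 scalp positions by convention), and unit-normalizes
per channel.

## Numerical conventions and edge cases

- Orthonormal wavelet filters: energy conservation is exact to rounding.
- FFT: unnormalized forward, 1/S inverse, fixed package-wide.
- Canonical axis order is (T, B, C) for power arrays; inputs in other axis
  conventions must be transposed by the caller.
- The imposition guards zero bins and clamps magnitudes at zero so a large
  negative eta cannot flip component signs.
- The antipode of the projection apex has no defined azimuth and is rejected;
  points off the sphere beyond 1e-6 relative are rejected.
- Grid cells are exactly square only when the bounding rectangle's aspect
  matches W/H; spacing is constant along each axis by construction.
- DE integer repair rounds first and redraws uniformly only the entries that
  leave their range.
- Ties in max-pool argmax are broken by first index (numpy argmax), which
  keeps runs deterministic.

## Known limitations

- db1 band leakage (above): rhythm "powers" mix neighbouring bands.
- The dense attack's electrode resampling and eta^2 imposition attenuate the
  BEAM-space budget substantially before it reaches the signal; the sparse
  attack with overflow is therefore the stronger method at matched eps, which
  is the central comparative finding the package reproduces.
- Victim conv stacks are fixed by design; the fully connected and recurrent
  widths (512/128) are this package's defaults.
- Whether the dual-target variant should recompute eta_P on the
  EEG-adversarial carrier is genuinely open; both behaviours are implemented,
  defaulting to raw-sample BEAMs.
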