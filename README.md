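# beamadv

Adversarial robustness of EEG seizure-detection models that work on **brain
electrical activity maps** (BEAMs) — per-rhythm topographic power images of
the scalp. The package is for researchers who want to probe, or defend,
deep-learning pipelines for epilepsy screening: it implements the full
EEG↔BEAM transform chain, the victim-model families, two white-box attacks
that perturb the maps rather than the signal, and the evaluation harness that
compares them.

## What it computes

A trial `E ∈ R^{T×C×S}` (T=5 one-second slices, C=22 electrodes, S=256
samples at 256 Hz) is decomposed per slice/electrode with a full
wavelet-packet tree (db1, 8 levels, frequency-ordered leaves). Zeroing the
leaves outside a rhythm band b ∈ {δ, θ, α, β} and inverting gives the rhythm
`Rhy_c^b`; its DFT `F_c^b` yields the rhythm power

    P_c^b = (1/S) Σ_i |F_c^b(i)|.

The C powers are interpolated (Clough–Tocher, exact at electrodes) on a
22×22 grid over the projected electrode positions (equidistant azimuthal
projection about Cz on a 0.095 m spherical head), giving the BEAM tensor
`BEAM ∈ R^{T×B×H×W}`.

**Dense attack (GPBEAM).** A gradient perturbation of the maps,
`η_BEAM = ε·sign(∇_BEAM J(θ, BEAM, y))` (FGSM; I-FGSM/MI-FGSM/PGD available),
is resampled at the electrodes to `η_P`, imposed on the frequency-domain
rhythms (each bin's real/imaginary magnitudes absorb `sign(η)·η²` split by
their squared shares), and spliced back into the raw signal's wavelet
decomposition — an adversarial EEG trial whose out-of-band content is
untouched.

**Sparse attack (GPBEAM-DE).** Differential evolution over N genes
`(t, c, v_1..v_B)` perturbs the rhythm-power array directly; fitness is
`1 − max-class probability` of the victim on the rebuilt maps. *Perturbation
overflow* redistributes the excess above ε across all electrodes with the
dense attack's sign pattern, clipped to the ε-ball.

**Victims.** Two families (BEAM-input 4×22×22 slices; EEG-input 1×22×256
slices) × four heads (max-pool, temporal conv, LSTM, mixed), trained with
Adam on cross-entropy; implemented in vectorized numpy with exact input
gradients, as scikit-learn-style estimators.

Metrics: attack success rate SR = R/S, accuracy Acc = A/S, distortion DL =
mean per-sample RMSE (on maps, DL_B, and on signals, DL_E), a Gaussian-noise
baseline, and a transferability harness.

## Worked example

```python
import beamadv as ba

montage = ba.build_montage()                 # 22 electrodes, 10-20 positions
grid = ba.build_grid(montage, 22, 22)
X, y = ba.generate_dataset(ba.SyntheticConfig(n_per_class=250, seed=11))
Xt, yt = ba.generate_dataset(ba.SyntheticConfig(n_per_class=60, seed=12))

beams = ba.BeamTransformer(montage, grid).transform(X)
victim = ba.VictimClassifier(architecture="maxpool", input_kind="beam",
                             epochs=12, seed=1)
victim.fit(beams, y)
print("clean accuracy:",
      victim.score(ba.BeamTransformer(montage, grid).transform(Xt), yt))

atk = ba.GPBEAMAttack(victim, montage, grid, ba.PerturbationConfig(epsilon=0.3))
report = ba.evaluate_results(atk.attack_many(Xt[:60], yt[:60]))
print(f"SR={report.sr:.2f}  Acc={report.acc:.2f} "
      f"DL_B={report.dl_b:.3f}  DL_E={report.dl_e:.4f}")
```

prints (seeds as above):

```
clean accuracy: 0.967
SR=0.05  Acc=0.95  DL_B=0.300  DL_E=0.0491
```

Read: the trained victim classifies 96.7% of clean synthetic trials
correctly; the dense attack at ε=0.3 flips 5% of predictions (10% at ε=0.5)
with a BEAM-space distortion exactly ε (FGSM sign pattern) and a time-domain
distortion of ~0.05 standard deviations — invisible on a plotted trace. The
same victim under N(0, 0.5) map noise (`ba.gaussian_baseline`) loses 4% at
five times the dense attack's map distortion: the gradient direction buys a
consistent edge per unit distortion. The sparse DE attack
(`ba.GPBEAMDEAttack`, N=5 genes, overflow on) is far stronger — SR=0.50 at
the same ε with a *smaller* map distortion (DL_B=0.239) — and switching
perturbation overflow off collapses it to SR=0.03, the package's central
comparative finding.

The same experiments are scriptable from the shell:

```
beamadv synth-data --n-per-class 250 --seed 11 --out run/data.npz
beamadv train-victim --data run/data.npz --architecture maxpool --out run/victim
beamadv attack gpbeam --data run/data.npz --victim run/victim --epsilon 0.3 --out run/atk
beamadv transfer --results run/atk.npz --victims run/victim --out run/transfer.csv
beamadv inspect --results run/atk.npz --electrode T7 --out run/plots
```

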