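# ictalnet

Personalized detection of electrographic seizure (ictal) patterns in
RNS-style intracranial EEG epochs, built around a patient-conditioned
residual 1-D convolutional network with a joint detection + onset-regression
loss. The package also ships the surrounding machinery: device-faithful
EDF+CSV epoch I/O, a synthetic multi-patient cohort generator with known
onsets and detector-pitfall confounds, label-preserving training-time
augmentation, the SGD training protocol with a cyclical learning rate, and
seed-based leave-one-patient-out evaluation (AUPRC, onset MAE, ±5 s
tolerance, implant-site subgroup statistics).

The network is implemented in pure NumPy (with optional numba-accelerated
inner loops) — no deep-learning framework is required: an initial strided
convolution, 11 pre-activation residual blocks of two kernel-16
convolutions (23 main-path convolutional layers in total), filter widths
growing linearly 16 → 116, one-hot patient conditioning concatenated before
the final block, and a two-output head (ictal probability, onset seconds).
The loss is `crossentropy + 0.1 · huber` with a 1-second Huber branch
point; training is plain SGD, batch 128, 20 epochs, learning rate cycling
0.1 → 0.025 every 4 epochs and held at 0.025 for the final two.

Because the clinical recordings behind the reference protocol are private,
all end-to-end behaviour is exercised on a synthetic cohort whose epochs
match the device conventions: 90 s, 4 channels, 250 Hz, 4–125 Hz band,
10-bit amplitude quantization. A packaged per-patient metadata table (22
patients) drives the protocol-level computations (inclusion filter,
demographic summaries).

## CLI

```bash
ictalnet simulate --config config.yaml --out cohort/           # synthetic cohort (EDF + CSV tree)
ictalnet train    --config config.yaml --cohort cohort/ --out ckpt.npz
ictalnet evaluate --config config.yaml --cohort cohort/ --out results/
ictalnet report   --results results/
```

A single `master_seed` (config key or `--seed`) fans out deterministically
to every module, so one flag reproduces a whole experiment. The YAML config
has `cohort`, `augment`, `network`, `train` and `eval` sections mirroring
the module configuration dataclasses; any omitted section uses defaults.

Example config:

```yaml
master_seed: 7
cohort: {n_patients: 6, epochs_per_patient: 60, ictal_fraction: 0.4}
network: {first_filters: 16, penultimate_filters: 116}
train: {n_epochs: 20, batch_size: 128}
eval: {scenario: random, seed_sizes: [0, 5, 10, 15, 20, 25, 30]}
```

## Layout

- `src/ictalnet/io.py` — epoch/annotation types, 10-bit ADC quantization, EDF+CSV round trip, metadata table
- `src/ictalnet/synthetic.py` — patient profiles, background/ictal/confound generators, cohort assembly and summaries
- `src/ictalnet/augment.py` — zero-pad + random crop, amplitude rescale
- `src/ictalnet/network.py` — network spec, construction, forward, structural traversal
- `src/ictalnet/_nn.py`, `_kernels.py` — NumPy layers with manual backprop; numba inner loops
- `src/ictalnet/training.py` — losses, cyclical LR, SGD loop
- `src/ictalnet/evaluation.py` — AUPRC, onset metrics, seed selection, leave-one-patient-out protocol, Kruskal–Wallis
- `src/ictalnet/cli.py` — `ictalnet` entry points
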