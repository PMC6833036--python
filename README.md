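# ecgstress

End-to-end stress detection from **raw ECG** with an 8-stage dual-branch
1-D convolutional network, three training regimes (including transfer
learning with a frozen prefix), subject-wise cross-validation, and a
synthetic stress-modulated ECG simulator so the whole pipeline runs and
is tested fully offline.

The network consumes fixed windows (10/30/60 s at 256 Hz) of z-scored
ECG. Each stage applies a width-16 convolution, then two parallel
stride-2 subsampling branches (strided convolution + max pooling) whose
outputs are concatenated along channels, batch-normalized, rectified and
dropped out; after stage 8 a flatten + linear + softmax head yields
rest/stress probabilities. Stage *N* features have width `w / 2^N` and
`8·2^⌈N/2⌉−1` channels. The neural-network core (conv / pool / batch
norm / dropout / dense, backprop, Adam, He initialization) is implemented
directly on numpy — no deep-learning framework required.

## Layout

| module | contents |
| --- | --- |
| `ecgstress.synthetic` | RR-interval model (Gaussian + respiratory sinusoid), sum-of-Gaussians P-QRS-T synthesis, protocol specs, cohort generation |
| `ecgstress.io` | record container, minimal waveform-database + text formats with marker sidecars, polyphase resampling, per-stressor z-score normalization |
| `ecgstress.dataset` | non-overlapping window slicing, labels, subject ids, (de)serialization |
| `ecgstress.nn` | numpy layer primitives with explicit forward/backward, Adam |
| `ecgstress.model` | architecture, shape contract, He init, checkpoints |
| `ecgstress.training` | cross-entropy, lr schedule, regimes I/II/III, transfer freezing |
| `ecgstress.evaluation` | subject-wise k-fold plans, metrics, ROC/PR, ANOVA+Tukey, conventional baselines, stage-feature extraction + 2-D embedding |
| `ecgstress.cli` | `simulate` / `preprocess` / `train` / `evaluate` commands with manifests |

## CLI pipeline

```sh
ecgstress simulate --protocol ma --subjects 17 --seed 1 --out records/
ecgstress preprocess --records records/ --window 10 --out ds.npz
ecgstress train --data ds.npz --regime II --k 10 --seed 1 --out model.npz
ecgstress evaluate --data ds.npz --model model.npz --k 10 --seed 1 --report report/
```

Transfer learning (regime III) fine-tunes only stage 8 + softmax head of
a regime-I checkpoint at a 10× lower learning rate:

```sh
ecgstress simulate --protocol driving --subjects 14 --seed 2 --out drive/
ecgstress preprocess --records drive/ --window 10 --out drive.npz
ecgstress train --data drive.npz --regime I  --seed 2 --out pretrained.npz
ecgstress train --data ds.npz    --regime III --pretrained pretrained.npz --out finetuned.npz
```

Every command writes a `manifest.json` (config, seeds, content hash) next
to its artifact. Real corpora can be ingested from waveform-database
records (`.hea`/`.dat` + `<name>.markers.csv`) or plain text
(`.txt` + `.meta.json` + markers).

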