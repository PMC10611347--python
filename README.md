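# tla-unet

A hybrid CNN–Transformer UNet for 2D medical image segmentation, built
around a **Three-Level Attention (TLA)** decoder module. The package is
aimed at researchers who want a fully tested, desk-scale implementation of
this architecture family — attention-gated UNet++ decoders with a
Transformer bottleneck — that trains and evaluates end to end on a single
CPU, using synthetic multi-organ phantoms instead of clinical datasets.

## The model

The network is an encoder–decoder with four architectural ingredients, each
individually switchable for ablation studies:

- **Hybrid encoder.** A CNN contracting path (double conv + batch norm,
  2× max pooling, channels doubling per stage) feeds its bottleneck plane
  into a ViT-style Transformer: patch embedding, learned position
  embeddings, and *L* pre-norm multi-head self-attention layers computing
  softmax(QKᵀ/√d_k)V per head. At the reference geometry (224×224 input,
  patch 16) the sequence length is 196.
- **UNet++ dense decoder.** Decoder nodes X(i,j) aggregate all same-level
  predecessors X(i,0..j−1) plus the upsampled deeper node X(i+1,j−1),
  narrowing the semantic gap between encoder and decoder features.
- **Three-Level Attention.** Each outermost decoder node chains
  (1) an additive **Attention Gate**
  f_ag = σ(φ(ReLU(Θ_x x + Θ_z z))) ⊗ x over the skip features x with the
  deeper feature z as gating signal; (2) **channel attention**
  f_ca = σ(MLP(AvgPool F) + MLP(MaxPool F)) ⊗ F over the concatenation;
  (3) a double convolution ending in batch norm, multiplied elementwise by
  a **spatial coefficient map** W_s ∈ [0,1]^{1×H×W} distilled from the
  Transformer's final self-attention (mean attention received per token,
  min–max normalised, bilinearly upsampled).
- **SE skips and deep supervision.** Squeeze-and-Excitation recalibrates
  each encoder skip; 1×1 side heads on every outermost decoder node and
  aux heads on intermediate top-row nodes are supervised during training
  only.

Training minimises the compound objective
ℓ = λ₁·ℓ_Dice + λ₂·ℓ_CE (λ₁ = λ₂ = 0.5) averaged over all supervised
outputs, with SGD (lr 0.005, momentum 0.9, weight decay 1e-4), polynomial
learning-rate decay lr·(1−t/T)^0.9, and flip/rotation augmentation.
Evaluation reports per-structure Dice (%) and exact boundary Hausdorff
distance; k-fold cross-validation splits by patient identifier.

The tensor backend is a small, fully tested NumPy reverse-mode autograd
engine (`tla_unet.autograd` / `tla_unet.nn`) — the package has no deep
learning framework dependency and is deterministic end to end.

## Worked example

Train the desk-scale model on 64 synthetic three-structure phantoms
(the package's standard learning benchmark; ~2 minutes on one CPU):

```python
import tla_unet as t

spec, model_cfg, train_cfg = t.smoke_benchmark(seed=0)
data = t.generate_phantom_dataset(spec)

model = t.SegmentationModel(model_cfg)
results = model.fit(data, train_cfg)
print(results.summary())
```

```
Segmentation model fit
==========================================================
classes: 4   input: 64px   depth: 2   base width: 24
transformer: hidden 64, 2 layers, 4 heads, 256 tokens
switches: unetpp=True side=True tla=True se=True
parameters: 245,692
optimizer: sgd (lr 0.005, momentum 0.9, wd 0.0001)
samples: 56 train / 8 validation
----------------------------------------------------------
epochs run: 10
final train loss: 0.3069
best val DSC: 82.09% (epoch 8)
==========================================================
```

The summary says the best checkpoint (saved at epoch 8, selected on the
held-out validation split) segments the three phantom structures with a
mean foreground Dice of 82%. Evaluating that checkpoint on a few samples
gives the per-case metric table (Dice in percent, Hausdorff in pixels):

```python
report = results.evaluate(data[-4:])
print(report[report["structure"] == "mean"].round(2).to_string(index=False))
```

```
     case_id structure  dsc_pct    hd  n_slices  n_hd_undefined
phantom_0060      mean    96.63  8.22         1               0
phantom_0061      mean    93.68  9.67         1               0
phantom_0062      mean    94.55  2.82         1               0
phantom_0063      mean    84.93 15.21         1               0
         ALL      mean    92.45  8.98         1               0
```

The same workflow is available from the shell:

```bash
tla-unet generate-data --spec spec.yaml --out data/
tla-unet train --config cfg.yaml --data data/ --out run/
tla-unet cross-validate --config cfg.yaml --data data/ --k 10 --report cv.csv
tla-unet evaluate --checkpoint run/checkpoint.npz --data data/ --report out.csv
```

Real data can be supplied as PNG/TIFF image+mask pairs
(`image_<id>.png` / `mask_<id>.png`) or NIfTI volumes.

## Documentation

`docs/methods.md` describes the model and training protocol in detail:
the W_s derivation, the synthetic phantom generator and what it does and
does not emulate, numerical choices (smoothing constants, tie-breaks,
initialisation), and known limitations.
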