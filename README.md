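# sparsect

Sparse-view CT study toolkit: simulate sparse-view acquisition from
synthetic thorax phantoms, correct streak artifacts with a residual
dual-frame U-Net, and evaluate both image quality and diagnostic
performance with multireader-study analytics.

The package is a self-contained re-implementation of a sparse-view
lung-CT study pipeline on synthetic data:

- **`sparsect.synthetic`** — thorax phantom generator (two lung fields,
  vessel-like structures, optional 1–2 cm nodule with exact ground-truth
  mask) and a statistical reader simulator (logistic detection model,
  ordinal quality/confidence/artifact scores, jittered segmentations).
- **`sparsect.projection`** — parallel-beam forward projection to
  2,048-view sinograms, uniform angular subsampling (16–512 views), and
  ramp-filtered backprojection (scikit-image Radon backend).
- **`sparsect.preprocessing`** — lung-window normalization (width 1,700,
  level −600 HU → [0, 1]), pure-artifact residual labels
  (`sparse − full`), residual correction, subject-level splits.
- **`sparsect.model`** — the dual-frame U-Net in pure NumPy (explicit
  forward/backward passes; no deep-learning framework required). The
  paper configuration (encoder 64/128/256/512, bottleneck 512→1024→512,
  mirrored decoder with channel-halving second convs, parameter-free
  additive dual-frame bridges, final 1×1 conv) has exactly
  **21,971,584** parameters.
- **`sparsect.training`** — MSE loss, Adam, exponential LR decay
  (`lr_n = lr_0·e^{−0.1n}`), early stopping, best-validation checkpoint;
  one independent model per view count.
- **`sparsect.image_quality`** — MSE/SSIM with mean and 95 % t-interval
  aggregation.
- **`sparsect.reader_study`** — Dice with the empty/no-overlap zero rule,
  TP/FP/FN/TN detection classification, sensitivity/specificity/F1/NPV,
  and the clustered Wilcoxon signed-rank test (Rosner–Glynn–Lee
  construction; reduces exactly to the classical test for singleton
  clusters).
- **`sparsect.orchestration`** — the two experiments end-to-end behind
  seeded, manifest-logged configs (`desk` CPU profile and the
  paper-scale profile).

## CLI

```bash
sparsect model-summary                      # architecture + parameter count
sparsect synth cohort --n 19 --diseased 12 --seed 1 --out cohort/
sparsect synth annotate --cohort cohort/ --readers 3 --seed 1 --out ann.csv
sparsect project --in cohort/S000.tif --views 16,64,256,2048 --out recon/
sparsect evaluate --profile desk --seed 0 --out eval/
sparsect readerstudy --seed 0 --out study/
sparsect run-all --seed 0 --out out/
```

## Notes

- The residual sign convention is `residual = sparse − full` (the pure
  artifact), so the corrected image is `sparse − prediction`.
- Residual pairs are snapped to a 2⁻²⁴ fixed-point lattice so the
  reconstruction identity holds bit-exactly in IEEE arithmetic.
- The parameter-count convention matches the published total: convolution
  kernels only (bias-free convs, non-affine batch norm); batch-norm
  running statistics are non-trainable state.
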