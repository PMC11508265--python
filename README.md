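# t2adc

Unpaired translation of T2-weighted prostate MRI into ADC-like maps, built
around a patch-contrastive (NCE) objective, a least-squares adversarial
loss, a pixel-level self-regularization term, and a ResNet-9
encoder-decoder generator with a channel+spatial attention block. A
synthetic prostate phantom makes every stage runnable and testable without
any clinical data.

Everything runs on CPU with NumPy: the package ships its own small
reverse-mode autodiff engine (`t2adc.nn`) with 2-D convolution, transposed
convolution, instance normalization, and an Adam optimizer, so no deep
learning framework is required.

## Modules

| module | purpose |
| --- | --- |
| `t2adc.phantom` | synthetic T2W/ADC/mask volumes with prostate zones, lesions (hypointense in both domains), and reproducible artifact corruptions (motion ghost, distortion field, aliasing, noise) |
| `t2adc.preprocess` | NIfTI ingestion, resampling to target spacing, z-score normalization, mask-guided cropping, axial slice extraction to [-1, 1], and inverse slice reinsertion |
| `t2adc.networks` | ResNet-9 generator with configurable channel/spatial attention, 70×70 patch discriminator, per-layer projection heads, patch-feature sampling |
| `t2adc.objectives` | InfoNCE, patch-wise NCE, self-regularization, least-squares adversarial terms, composite loss |
| `t2adc.train` | seeded unpaired training loop (alternating D / G+H updates), CSV loss log, checkpointing, volume inference |
| `t2adc.metrics` | PSNR, SSIM (with luminance/contrast/structure decomposition), Fréchet distance over Gaussian feature moments, Dice, dataset evaluation reports |

The default generator has 11,379,254 trainable parameters (11.379 M);
disabling the attention block gives 11,378,179 (11.378 M).

## CLI

```bash
t2adc phantom --n-subjects 20 --seed 1 --out data/           # synthetic cohort
t2adc preprocess --t2 t2.nii.gz --mask mask.nii.gz \
      --spacing 0.5,0.5,3.0 --margin-mm 5 --out prep/
t2adc train --x-dir data --y-dir data --config train.yaml --out run/
t2adc infer --checkpoint run/checkpoint.npz --t2 t2.nii.gz \
      --mask mask.nii.gz --out adc_generated.nii.gz
t2adc evaluate --pred pred/ --truth truth/ --out report.csv
```

Training defaults: 5 epochs, batch size 4, Adam (lr 0.0002, betas 0.5/0.999),
Glorot initialization, temperature 0.07. A CPU-minutes test profile
(`t2adc.train.TEST_PROFILE`: width-16 generator, 64×64 crops, 200
iterations) is used by the test suite.

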