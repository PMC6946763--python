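# nervequant

Automated quantification of the corneal sub-basal nerve plexus in corneal
confocal microscopy (CCM) images: patch-based U-Net segmentation (single
network or a 5-member bootstrap ensemble fused by pixel-wise majority
voting), skeleton morphometry of the segmented nerves, and the
method-agreement and diagnostic statistics used to validate automated nerve
analysis against manual annotation.

CCM images the cornea's sub-basal nerve plexus non-invasively; loss of
corneal nerve fibre (CNF) length is an early biomarker of diabetic
peripheral neuropathy and other small-fibre neuropathies. Quantifying it
requires tracing thin (1–4 px) curvilinear fibres on noisy, unevenly
illuminated images — this package is aimed at researchers building or
validating that kind of pipeline.

## What it computes

For a greyscale CCM frame (standardised to 1.04 µm/px, 384×384 px) the
pipeline produces the per-image clinical variables:

* **total CNF length** (µm) — geodesic length of the segmented centrelines;
* **branch points** (skeleton nodes with ≥ 3 neighbours) and **tail
  points** (endpoints);
* **nerve segments** (maximal node-free skeleton paths), with mean and SD
  segment length;
* **fractal number** — box-counting dimension of the skeleton, from the
  least-squares slope of log N(ε) vs log(1/ε).

Segmentation: frames are tiled into 128×128 patches anchored every 32 px
(81 patches per standard frame), the U-Net maps each patch to foreground
probabilities through a sigmoid head (trained with the Dice loss 1 − DSC,
DSC = (2Σpt + s)/(Σp + Σt + s)), and patch outputs are stitched by
per-pixel majority vote. The ensemble trains five networks on image-level
bootstrap resamples and fuses their masks pixel-wise (foreground iff ≥ 3 of
5 agree).

Validation statistics: per-variable RMSE and SD of the method−manual error,
ICC(2,1) absolute agreement with the conventional reliability bands,
Bland–Altman limits of agreement (mean ± 1.96 SD, with 95% CIs), and ROC
analysis with the Youden-index optimal cut-point (J = sens + spec − 1).

A seeded phantom generator produces CCM-like images — branching persistent
random walks entering at the field border, Gaussian fibre cross-sections on
a noisy illumination-gradient background — with exact polyline ground
truth, so every stage is testable against known answers. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import dataclasses
import numpy as np
from nervequant import (PhantomSpec, generate_phantom, EnsembleSegmenter,
                        quantify, dice_coefficient)

spec = PhantomSpec(image_size=192)           # CCM-like phantom, 192 px
train = [generate_phantom(dataclasses.replace(spec, seed=100 + k))
         for k in range(12)]
test_img, test_truth = generate_phantom(dataclasses.replace(spec, seed=900))

est = EnsembleSegmenter(n_members=5, depth=2, base_channels=8,
                        patch_px=64, stride_px=32, epochs=6, random_state=0)
est.fit([im.pixels for im, _ in train], [t.mask for _, t in train])

mask = est.predict([test_img.pixels])[0]
print("Dice vs truth:", round(dice_coefficient(mask, test_truth.mask), 3))
rec = quantify(mask, spec.pixel_size_um)
print("total length (um):", round(rec.total_length_um, 1),
      " true:", round(test_truth.true_total_length_um, 1))
print("branch/tail/segments:", rec.n_branch, rec.n_tail, rec.n_segments)
```

Output from a run of the above:

```
Dice vs truth: 0.95
total length (um): 465.4  true: 474.2
branch/tail/segments: 0 8 4
```

The Dice of 0.95 says the ensemble reproduces the ground-truth mask almost
pixel-for-pixel; the quantified total nerve length lands within ≈ 2% of the
generator's polyline truth (this phantom drew four unbranched fibres, hence
8 tails, 4 segments and no branch points).

The same workflow is available from the shell:

```bash
nervequant simulate --out cohort/ --n-per-group 10 --seed 1
nervequant split    --manifest cohort/manifest.csv --fraction 0.9 --seed 1 --out split.json
nervequant train    --manifest cohort/manifest.csv --split-plan split.json --ensemble 5 --out model/
nervequant quantify --model model/ --images img.png --out results/
nervequant validate --pred results/morphometry.csv --manual manual.csv \
                    --labels labels.csv --out validation/
```

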