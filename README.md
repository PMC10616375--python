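# henuclei

Nuclei instance segmentation and morphometrics for H&E histology images,
with panoptic evaluation and downstream ploidy statistics — fully
exercisable offline on synthetic, ground-truthed data.

## What problem this solves

Hematoxylin & eosin (H&E) slides are the workhorse of cancer pathology.
Quantitative analyses — cell-type composition, nuclear morphometry,
joint image/genomics studies — need every nucleus in a gigapixel slide
detected, typed and measured automatically. `henuclei` implements that
pipeline end to end for researchers who want a transparent, hackable,
CPU-friendly implementation:

1. **Preprocess** — tile a large image into fixed-size patches (default
   1250 px), detect tissue by Otsu thresholding of HSV saturation, and
   discard patches with too little tissue or too little signal.
2. **Segment** — a multi-task fully convolutional network (one shared
   encoder, three decoders) predicts per pixel: foreground probability, a
   distribution over five cell classes (neoplastic, inflammatory,
   connective, dead, epithelial), and a distance + flow field.
3. **Post-process** — instances are recovered Omnipose-style: every
   foreground pixel is advected along the flow field to a per-object
   sink; pixels sharing a sink form one nucleus; instances are typed by
   their summed class probabilities.
4. **Measure** — eight features per nucleus (area, perimeter, major and
   minor axis, eccentricity, aspect ratio, solidity, volume), cell-type
   percentages and the Shannon diversity index; results are exported as
   GeoJSON polygons (QuPath dialect) and CSV.
5. **Evaluate** — predictions are scored against ground truth with
   panoptic quality at IoU > 0.5,

   DQ = TP / (TP + FP/2 + FN/2),  SQ = mean IoU over matches,  PQ = DQ·SQ,

   per class and pooled, with 200-round bootstrap percentile CIs.
6. **Correlate** — per-sample medians and variances of neoplastic
   nuclear features are correlated with genomic ploidy (Spearman's ρ
   with a t-approximation p-value), and a one-way ANOVA tests ploidy
   against anatomical site.

Because real tumour slides and pathologist annotations cannot be
redistributed, the package includes a first-class synthetic-data module:
H&E-like patches of elliptical nuclei with exact instance/class ground
truth, and cohort tables with a controlled Spearman correlation (via a
Gaussian copula) between features and ploidy. All experiments and tests
run against this ground truth; see `docs/methods.md` for what that does
and does not demonstrate.

## Worked example

```python
import numpy as np
from henuclei.synthetic import SyntheticImageSpec, generate_scene
from henuclei.model import ModelConfig, build_model, train, predict
from henuclei.pipeline import segment_output
from henuclei.panoptic_eval import match_instances, panoptic_quality
from henuclei.morphometrics import composition

# 8 ground-truthed training patches, 64x64, ~8 nuclei each
scenes = [
    generate_scene(SyntheticImageSpec(
        height=64, width=64, n_nuclei=8,
        major_axis_range=(14, 22), minor_axis_range=(9, 14), seed=100 + i))
    for i in range(8)
]

cfg = ModelConfig(channels=16, epochs=300, seed=0)
model, history = train(build_model(cfg), scenes, cfg)   # ~2.5 min on 1 CPU

scene = scenes[0]
instances, classes = segment_output(predict(model, scene.image))
result = panoptic_quality(match_instances(
    instances, classes, scene.instances, scene.classes, class_aware=False))["all"]
print(f"PQ={result.pq:.3f} DQ={result.dq:.3f} SQ={result.sq:.3f} "
      f"TP={result.tp} FP={result.fp} FN={result.fn}")
print(f"Shannon index: {composition(classes.values()).shannon_entropy:.3f} nats")
```

Output from this exact script:

```
PQ=0.998 DQ=1.000 SQ=0.998 TP=8 FP=0 FN=0
Shannon index: 0.900 nats
```

The trained network memorises the 8 patches (PQ ≈ 1.0 against their
ground truth after flow post-processing); the Shannon index is the
diversity of the 5-class composition of the recovered nuclei (ln 5 ≈
1.609 would be a uniform mix).

A shell interface mirrors the library
(`henuclei preprocess | segment | features | evaluate | ploidy | synth | run`);
try `henuclei synth --out scene/ --seed 3` followed by
`henuclei preprocess scene/image.png --out pre/ --patch-size 128`.

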