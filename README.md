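# octseg

Tools for quantitative analysis of intraoperative optical coherence
tomography (OCT) B-scans of brain tissue, aimed at the glioma
resection-margin problem: diffusely infiltrating tumor is visually
indistinguishable from healthy white matter under the operating
microscope, but the two tissues differ in how strongly they attenuate
and scatter near-infrared light. `octseg` implements the full inference
stack from raw B-scan to scan-level diagnostic call, plus the reader-study
statistics used to evaluate it, and a synthetic-data generator so that
every stage is testable without patient data.

## What it computes

**Parametric maps.** From a linear-intensity B-scan `I(j)` (row `j` =
depth, pixel pitch Δ in mm) the depth-resolved optical attenuation
coefficient is estimated per A-scan as

    μs(j) = I(j) / (2Δ · Σ_{i≥j} I(i))      [mm⁻¹]

(the tail sum truncated at the bottom pixel), and the refined speckle
contrast (RSC) as the local standard deviation over mean of the μs field
in a sliding 10 × 20 px (depth × width) window — an
attenuation-compensated texture measure. Pixels below a 15 dB
signal-to-noise floor are masked and excluded from all statistics.

**Blockwise SVM segmentation.** Scans are partitioned into blocks of 20
adjacent A-scans; each block's (mean OAC, mean RSC) over a depth ROI of
rows [20, 40) feeds a standardized linear one-vs-rest SVM over three
classes — normal white matter (green), damaged white matter (yellow),
tumor (red). Validation is leave-one-scan-out cross-validation with
scaling and fitting strictly contained in each fold, reported as
one-vs-rest ROC/AUC per class and for the binary tumor-vs-rest task.

**Contextual override filter.** A deterministic rule engine models the
human review step that turns a blockwise map into a scan-level call:
isolated red blocks flanked by green are suppressed as false positives,
the surviving red density maps to a tumor probability, red evidence
adjoining yellow is amplified, shallow evidence is attenuated, and the
scan is called Tumor only if the probability strictly exceeds 50%.

**Reader-study statistics.** Forced-choice multi-reader panels pool into
confusion counts; sensitivity, specificity, global accuracy and
inter-rater consistency (mean pairwise agreement, or Fleiss' κ) carry
95% confidence intervals from a 10,000-iteration scan-level percentile
bootstrap. Modalities are compared by CI overlap.

## Worked example

```python
import numpy as np
from octseg import *
from octseg.parametric import compute_maps
from octseg.features import extract_blocks

tissue = TissueModel()  # Normal/Damaged/Tumor: μs = 1.0/2.0/3.5 mm⁻¹
blocks = []
for scan, meta in simulate_training_cohort(seed=7):  # 23 scans × 400 A-scans
    maps = compute_maps(scan, noise_reference=tissue.noise_level)
    blocks.extend(extract_blocks(maps, labels=meta.label))

res = loocv(blocks, grouping="per_scan")
roc = multiclass_roc(res.scores, res.labels, classes=res.classes)

model = train(blocks)
layout = ScanLayout.infiltration(width=400, start=100, length=100)
scan, meta = simulate_bscan(layout, tissue, seed=22, scan_id="demo")
segmap = segment(compute_maps(scan, noise_reference=tissue.noise_level), model)
verdict = score_scan(segmap)
```

Output:

```
training blocks: 460
grouped LOOCV accuracy: 0.974
OvR AUC: {'Normal': 1.0, 'DamagedMatter': 0.317, 'Tumor': 1.0, 'tumor_vs_rest': 1.0}
block labels: GGGGGRRRRRGGGGGGGGGG
tumor probability: 0.56 -> call Tumor
```

The 23 homogeneous training scans partition into 460 blocks; per-scan
LOOCV classifies 97% of them correctly, with perfect one-vs-rest AUC for
the extreme classes (the intermediate damaged-matter class is linearly
squeezed between its neighbours in the 2-D feature space and scores
poorly one-vs-rest — its errors spill into the adjacent classes, not
into the tumor-vs-rest decision). The demo scan carries a contiguous
tumor infiltration across blocks 5–9, which segmentation recovers
exactly; the contextual filter converts the 5-of-20 red run into a 0.56
tumor probability (dense contiguous evidence, moderately attenuated by
the shallower signal penetration of tumor tissue) and calls the scan
Tumor.

A simulated five-reader panel on an 86-scan cohort (42 tumor / 44 white
matter) with per-reader sensitivity 0.95 / specificity 0.90 yields
pooled confusion counts tp=198 tn=200 fp=20 fn=12 and bootstrap
summaries `sensitivity 94% [91–97], specificity 91% [87–95],
accuracy 93% [90–95], consistency 0.86 [0.82–0.91]`.

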