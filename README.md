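# histoscreen

Patch-CNN screening of whole-slide histopathology images: tissue masking,
balanced and augmented patch training, dense whole-slide cancer-likelihood
maps via a fully convolutional network, slide-level scoring, lesion-level
detection, and FROC/ROC evaluation with bootstrap confidence intervals.

## Who this is for

Researchers building or evaluating computer-aided screening of digitized
pathology slides — e.g. excluding benign prostate biopsies from review, or
flagging breast-cancer metastases in sentinel lymph nodes — who need a
compact, fully tested reference implementation of the classic patch-CNN
pipeline, plus a synthetic slide generator so every stage can be exercised
without clinical data.

## The model

A small CNN classifies 128 × 128 RGB patches as cancer vs benign (four
3 × 3 conv + 2 × 2 max-pool blocks, three dense layers, softmax).  Patches
are sampled class-balanced from tissue, labeled by the annotation value at
their **center pixel**, and expanded ×8 by the dihedral group (rotations
0/90/180/270° and their mirrors).  Training is SGD with momentum and
patience-5 early stopping on the validation misclassification rate; an
optional boosting round re-samples patches whose center pixel the initial
model got wrong (weight 5×) and retrains.

For whole-slide application the dense layers are rewritten as convolutions,
so one forward pass yields a likelihood map `L(x, y) ∈ [0, 1]`: at every
stride-16 grid position the dense output equals the patch classifier's
probability for the patch centered there (verified to 1e-5).

Two slide-level read-outs:

* **Percentile screening** — the normalized cumulative histogram (100 bins
  on [0, 1]) of tissue-pixel likelihoods is inverted at a percentile *p*
  (operating *p* selected on validation slides by AUC or by specificity at
  0.999 sensitivity); the resulting likelihood is the slide score for ROC
  analysis.
* **Lesion detection** — threshold the map at 0.3, take 8-connected
  components, drop those with Feret diameter < 0.02 mm (10% of the 0.2 mm
  micro-metastasis bound), score each by its median likelihood.  The top
  component scores the slide; components match annotated lesions at
  Dice ≥ 0.5 for FROC analysis (sensitivity vs false positives per
  tumor-negative slide).

Uncertainty is quantified by slide-level percentile bootstrap
(2.5–97.5%).

## Worked example

```python
from histoscreen.model import CNNConfig
from histoscreen.pipeline import ExperimentConfig, run_experiment
from histoscreen.synthetic import SlideSimSpec

config = ExperimentConfig(
    mode="lesion_detection", seed=7,
    n_train_pos=6, n_train_neg=6, n_val_pos=3, n_val_neg=3,
    n_test_pos=5, n_test_neg=5,
    slide_template=SlideSimSpec(
        width_px=256, height_px=256, microns_per_pixel=8.0,
        n_lesions=1, lesion_diameters_mm=(0.5,),
        tissue_fraction=0.6, texture_separation=4.0),
    patch_px=64, patches_per_slide_per_class=16,
    val_patches_per_slide_per_class=10,
    cnn=CNNConfig(conv_blocks=((8, 3, True), (16, 3, True), (32, 3, True)),
                  fc_sizes=(64, 32, 2), input_px=64, max_epochs=15),
    n_bootstrap=200,
)
report = run_experiment(config)
ld = report["lesion_detection"]
print("slide AUC      ", ld["slide_auc"]["value"])
print("sens @ 1 FP    ", ld["froc_sensitivity_at_1fp"]["value"])
print("sens @ 2 FP    ", ld["froc_sensitivity_at_2fp"]["value"])
```

prints (~30 s on one CPU):

```
slide AUC       1.0
sens @ 1 FP     1.0
sens @ 2 FP     1.0
```

The simulated cohort separates lesion from benign texture by 4 pooled
standard deviations, so a converged model detects every 0.5 mm lesion
(Dice ≈ 0.8 against the planted masks) without false positives above the
0.3 likelihood threshold; the slide-level ROC is saturated at AUC 1.0.
Harder cohorts (lower `texture_separation`, planted distractor blobs)
produce intermediate operating points.

There is also a CLI for stage-by-stage use:

```bash
histoscreen simulate --n-pos 3 --n-neg 3 --out-dir cohort --seed 1
histoscreen preprocess cohort pos_000
histoscreen run experiment.json
```

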