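# nucliq

Detection, classification and quantification of cell-type-specific nuclei
in multi-channel fluorescence images of intact tissue.

## The problem

In tissue sections stained with a nuclear dye (DAPI), a structural
cytoplasmic stain (e.g. α-sarcomeric actin or tropomyosin) and optionally a
functional marker (EdU for DNA synthesis, TUNEL for DNA fragmentation),
cell borders are invisible: deciding which nuclei belong to the cell type
of interest — for example cardiomyocyte nuclei embedded in striated
actin-positive cytoplasm — normally requires an expert to inspect the
texture around every nucleus.  Manual dot-annotation of such images is
slow and shows only moderate agreement between experts.  `nucliq`
automates the workflow for histologists and quantitative-biology groups:
it segments all nuclei, classifies each one as target / non-target from
the texture of the nucleus and its surroundings, supports a scriptable
user-correction pass, quantifies marker colocalization per cell subgroup,
and measures inter-observer agreement.

## Method

1. **Illumination correction.** Each channel is divided pixelwise by the
   local background `B = G_σ * I_red` (Gaussian blur of the structural
   channel, σ = 10 px), removing the smooth illumination gradient of
   confocal imaging.
2. **Segmentation.** The corrected nuclear channel is binarized by Otsu's
   threshold; connected components (8-connectivity) with area < 5 px are
   discarded as noise.
3. **Features.** Five per-pixel families on the nuclear and structural
   channels — rotation-invariant Fourier HOG moment magnitudes
   `|G_σr * (|∇I| e^{imθ})|`, sliding-window Haralick GLCM statistics,
   local intensity entropy, a membrane saliency map (steerable
   second-derivative-of-Gaussian ridge filter + stick tensor voting,
   saliency `λ1 − λ2`), and the extracellular component size (ECS).  Each
   map is summarized over the nucleus and a 15-px surrounding ring by
   mean, median, SD and MAD (360 descriptors), then standardized to zero
   mean and unit variance per image.
4. **Classification.** L2-regularized logistic regression (liblinear).
   Performance is estimated by leave-image-out cross-validation; the
   operating threshold maximizes precision `P = TP/(TP+FP)` subject to a
   recall floor `R = TP/(TP+FN) ≥ r*`.
5. **Quantification.** Marker positivity is called per nucleus (fraction
   of nuclear pixels above the marker Otsu threshold ≥ 0.25); the report
   counts targets, marker-positives and co-labeled nuclei with exact
   count-ratio percentages, per image and pooled.
6. **Agreement.** Rater dots are matched to nuclei within 15 px; Fleiss'
   kappa `κ = (P̄ − P̄e)/(1 − P̄e)` with the Fleiss–Nee–Landis standard
   error, verbal bands (moderate 0.41–0.6, substantial 0.61–0.8, …), and
   a z-test `z = (κa − κb)/√(SEa² + SEb²)` between conditions.

Because no public dataset of this kind exists, the package ships a seeded
synthetic-scene generator (elliptical nuclei, sinusoidal striation around
target nuclei, diffuse interstitium, marker-positive subsets,
multiplicative gain fields, Gaussian noise) that provides ground truth for
every stage.

## Worked example

```python
import nucliq as nq

dataset = nq.generate_dataset(n_images=4, base_seed=7)
vectors, labels = [], nq.LabelSet(labels={}, provenance={})
for scene in dataset.scenes:
    stack = nq.correct_illumination(scene.stack)
    nuclei = nq.segment_nuclei(stack)
    dots = [t.center for t in scene.truth if t.is_target]
    part = nq.match_annotations(nuclei, dots)
    labels.labels.update(part.labels)
    labels.provenance.update(part.provenance)
    vectors.extend(nq.featurize_image(stack, nuclei))

scored = nq.loio_cv(vectors, labels)
curve = nq.pr_curve(scored["score"].to_numpy(),
                    (scored["label"] == "target").to_numpy())
threshold, precision, recall = nq.select_threshold(curve, target_recall=0.9)
print(f"nuclei: {len(vectors)}  features per nucleus: {len(vectors[0].values)}")
print(f"operating point: threshold={threshold:.3f}  "
      f"precision={precision:.3f}  recall={recall:.3f}")
```

Output:

```
nuclei: 600  features per nucleus: 360
operating point: threshold=0.955  precision=0.994  recall=0.994
```

600 nuclei were segmented across the four simulated images and described
by 360 texture descriptors each.  Scoring every nucleus with a model that
never saw its own image, the pooled precision/recall curve admits an
operating point at which 99.4% of detected target nuclei are correct
(precision) while 99.4% of all true target nuclei are found (recall) — on
this strongly-striated synthetic task the two classes are almost
perfectly separable.

The same pipeline is available from the shell:

```bash
nucliq simulate --n-images 8 --seed 7 --out data/
nucliq segment   --image data/img000.tif --config config.json --out nuclei.csv
nucliq featurize --image data/img000.tif --config config.json --out features.csv
nucliq train --features feats/ --nuclei nuclei.csv \
             --annotations dots.csv --out model.json
nucliq quantify --model model.json --images data/ --out report.json
nucliq agree --nuclei nuclei.csv --raters raters/ --out agree.json
```

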