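# actincap

High-content image analysis of the **perinuclear actin cap** in adherent
fibroblasts — nuclear morphometry, stress-fiber organization scoring,
CAG-Age-Product (CAP) disease-burden stratification, and single-cell
migration statistics, with a ground-truthed synthetic image generator for
validation.

## The scientific problem

The actin cap is the apical dome of thick, parallel actomyosin bundles that
covers the nucleus of adherent cells. Its loss deforms the nucleus (rounder,
shorter major axis) and impairs cell migration, and is a cellular hallmark
of laminopathies such as Hutchinson–Gilford progeria (HGPS). Patient-derived
skin fibroblasts — for example from Huntington's-disease (HD) mutation
carriers — can be phenotyped for this deficiency at scale from two-channel
fluorescence micrographs (a DNA stain for nuclei, phalloidin for F-actin).

`actincap` implements that phenotyping pipeline end to end:

- **Nucleus morphometry.** Nuclei are binarized (fixed threshold or Otsu),
  cleaned with binary morphology, and labeled as 8-connected components.
  Each nucleus gets area *A*, perimeter *P* (Crofton estimator), axes, and
  the circularity / form factor

  $$\mathrm{circularity} = \frac{4\pi A}{P^2},$$

  which is 1 for a circle and falls with elongation.

- **Stress-fiber organization.** The actin foreground is partitioned into
  per-cell cytoplasm regions by nearest-nucleus assignment; straight fiber
  segments are detected with a probabilistic Hough transform. Per cell, the
  slope of each fiber, $\mathrm{slope}_i = (y_1-y_2)/(x_1-x_2)$, enters the
  population standard deviation

  $$\mathrm{STD} = \sqrt{\tfrac{1}{N}\textstyle\sum_{i=1}^{N}
  (\mathrm{slope}_i - \overline{\mathrm{slope}})^2},$$

  low values meaning parallel, organized fibers. A bounded circular
  dispersion on doubled (axial) angles is reported alongside, plus
  apical-plane linescan metrics for confocal z-stacks and a PCA-based
  "actin network complexity" summary of six fiber-network descriptors.

- **Cohort statistics.** The CAG-Age Product
  $\mathrm{CAP} = \mathrm{age}\,(\mathrm{CAG}-30)/6.49$ stratifies HD
  donors into Premanifest (< 90), Mild (90–114) and Severe (> 114) classes;
  features are aggregated as per-well/per-sample medians and compared with
  two-sided Mann–Whitney U tests, embedded with PCA, clustered with
  k-means, and regressed against CAP score (least-squares trend lines with
  min/max envelopes). A 28-donor reference HD cohort ships with the
  package (`actincap.cohort.load_hd_cohort`).

- **Motility.** Greedy nearest-neighbor linking of per-frame centroids into
  tracks; total travel length, net displacement, mean speed, directionality
  (net/total), and origin-translated sun-plot coordinates.

- **Synthetic generator.** Every measurement is validated against rendered
  fields with exact ground truth: elliptical nuclei of controllable
  circularity, 2-px anti-aliased straight fibers with controllable
  count/length/orientation dispersion, apical/basal z-stacks, Gaussian
  background, and persistent-random-walk migration tracks.

## Worked example

```python
from actincap.synthgen import make_field_spec, render_field
from actincap.capfeatures import extract_cell_features
from actincap.cohort import cap_score, severity_class

spec = make_field_spec(5, image_size=(512, 512), fiber_angle_sd=8.0, seed=7)
nucleus, actin, truth = render_field(spec)
feats = extract_cell_features(nucleus, actin)
print(feats[["cell", "circularity", "major_axis", "n_fibers",
             "slope_std", "angle_dispersion_deg"]].round(3).to_string(index=False))
cap = cap_score(57, 46)
print(f"\nCAP(57 y, 46 CAG) = {cap:.4f} -> {severity_class(cap)}")
```

prints

```
 cell  circularity  major_axis  n_fibers  slope_std  angle_dispersion_deg
    1        1.009      40.032        11      6.475                 8.014
    2        1.010      40.069        10      0.113                 6.319
    3        1.010      40.069        10      0.208                 6.714
    4        0.994      40.075        12      4.400                11.503
    5        0.991      39.977         8      0.133                 3.736

CAP(57 y, 46 CAG) = 140.5239 -> Severe
```

Five round synthetic nuclei (true circularity 1.0, diameter 40 px) are
recovered with circularity within ~1% and their fiber bundles with roughly
the generated count; cells whose fiber bundle happens to lie near vertical
show inflated slope-SD (slopes diverge near 90°), which is why the bounded
angle-dispersion column is reported alongside. The CAP score of a
57-year-old carrier of 46 CAG repeats lands in the Severe class.

A command-line interface mirrors the library:

```sh
actincap synth --n-cells 5 --angle-sd 8 --seed 7 --out field.tif
actincap segment field.tif --out cell_features.csv
actincap run --seed 1 --out-dir run1     # full synthetic pipeline + manifest
```

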