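# ciliametry

Automated morphometry of primary cilia in fluorescence micrographs, with the
downstream statistics used to study region- and time-of-day-dependent cilia
dynamics:

- **cilia detection** (`ciliametry.cilia`): Gaussian blur → Canny edges with
  median-relative thresholds (lower = 0.67 × median) → morphological closing
  (2×2) / erosion (1×1) → external contours → length/aspect filtering
  (1–15 µm, aspect ≥ 1.5) → minimum-area rotated-rectangle measurement,
  brightest-pixel base localization, and base-to-tip angle finalization with
  hemisphere mirroring;
- **nuclei detection** (`ciliametry.nuclei`): CLAHE → adaptive mean threshold
  (block 41, C = −10) → normalized distance transform (cut 0.2) → dilation →
  contours → DBSCAN centroid clustering (eps 30 px) with convex-hull merging →
  area (20–1000 px²) and circularity (4πA/P² ≥ 0.01) filtering;
- **circular statistics** (`ciliametry.circular`): atan2 circular mean,
  wrapped differences, 30° rose histograms;
- **aggregation** (`ciliametry.quantify`): cilia density (% of cells),
  per-section summaries, direct vs section-based region averages, 0.6 µm
  length histograms;
- **temporal statistics** (`ciliametry.temporal`): one-way ANOVA across
  zeitgeber times, two-stage (Benjamini–Krieger–Yekutieli style) step-up FDR,
  region-pair Pearson matrices, and a 24 h cosinor fit (a least-squares
  stand-in for external deep-learning rhythmicity tools — see its docstring);
- **network analysis** (`ciliametry.network`): injection-volume normalization
  and log-scaling of connectivity, seeded Louvain communities, −ln(1−|r|)
  correlation edge weights, and a permutation test for the fraction of
  significantly correlated region pairs between communities;
- **synthetic scenes** (`ciliametry.synth`): seeded generators for cilia
  images (anti-aliased capsules with a brighter basal blob, photon-limited
  noise), nuclei images, cosine time series, and planted-partition
  connectivity — every pipeline stage is testable against known ground truth;
- **validation** (`ciliametry.validate`): greedy base-position matching,
  recall and length/angle MAE, and the Pythagorean 2D-projection length
  error.

## CLI

One entry point with subcommands:

```bash
# generate a synthetic scene + ground truth, detect, and score
ciliametry simulate cilia --out sim --seed 7 --n 25
ciliametry detect-cilia --input sim/cilia.tif --pixel-size-um 0.5 \
    --hemisphere right --out cilia.csv
ciliametry validate --detected cilia.csv --truth sim/truth.csv --out report.json

# DAPI cell counting and cilia density
ciliametry simulate nuclei --out simn --seed 7 --n 50
ciliametry detect-cells --input simn/nuclei.tif --out cells.csv
ciliametry density --cilia cilia.csv --cells cells.csv --out density.csv

# section summaries, time-of-day statistics, communities
ciliametry summarize --cilia cilia.csv --out sections.csv
ciliametry temporal --sections sections.csv --measure length \
    --out-anova anova.csv --out-corr corr.csv --out-rhythm rhythm.csv
ciliametry network --connectivity W.csv --out communities.csv
```

`--pixel-size-um` is required wherever physical units matter: micrograph
calibration is never assumed. Detector/nuclei thresholds can be overridden
with `--config file` containing `key=value` lines (keys match the
`DetectionParams` / `NucleiParams` fields).

## Conventions

Pixel coordinates are `(x, y) = (column, row)`, row index increasing
downward. Angles are reported in the y-up mathematical convention (0° toward
image right, counter-clockwise) after orienting each cilium from base to
tip; left-hemisphere angles are mirrored across the vertical axis
(θ → 180° − θ mod 360°) so medial/lateral orientations are comparable
across hemispheres.
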