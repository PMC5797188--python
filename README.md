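# larvreg

Standard-brain template construction, staged linear + B-spline registration,
automatic registration quality assessment and landmark-guided correction for
3D confocal stacks of the larval *Drosophila* CNS.

The package implements:

* **Domain model & I/O** — volumetric images with physical μm geometry
  (multi-page TIFF / uncompressed MetaImage), landmark CSV files, QA reports.
* **Transforms** — linear (translation/similarity/affine), cubic B-spline
  free-form deformations, dense displacement fields, resampling, composition,
  field inversion and averaging.
* **Preprocessing** — percentile-landmark histogram matching, artifact-robust
  rescaling, coarse brain masking, anisotropy-aware signed distance
  transforms, orientation normalization and z-flip candidates.
* **Registration** — multiresolution similarity/affine alignment (NCC or
  mutual information; SDT feature registration with rotation multi-start and
  the 0.4-threshold intensity fallback), then masked B-spline registration
  (12 μm grid, adaptive stochastic gradient descent with analytic NCC
  gradients, global-random or 20 μm local subregion sampling) and a
  multi-metric variant coupling NCC with corresponding-point distances whose
  weight balances metric *gradients*.
* **Template construction** — all-pairs deformable registration, mean
  deformation fields into the population average space, voxelwise mean or
  median fusion, NT/GE channel propagation, QA calibration.
* **Quality assessment** — VI (terminal-cord regional MI) and TI = M·S/100
  (thoracic regional MI × Eulerian-strain confidence) with the 50% accept
  threshold.
* **Evaluation** — landmark registration error statistics, cohort
  aggregation, intra-rater statistics and accept/reject confusion matrices.
* **Phantom** — a seeded synthetic CNS generator (NP/NT/GE channels,
  30 labeled landmarks, ground-truth deformations, failure modes) that powers
  the entire test suite; no external data is required.

## CLI

```bash
larvreg phantom --seed 1 --out scan1                # synthetic scan + truth
larvreg build-template --scan scan1 --scan scan2 --scan scan3 --out tpl
larvreg register --template tpl --scan scan4 --out reg1     # exit 0 ok, 2 flagged
larvreg correct  --template tpl --scan scan4 \
                 --landmarks guides.csv --out reg1_fixed
larvreg evaluate --reference-landmarks tpl/gold_landmarks.csv \
                 --subject-landmarks scan4/landmarks.csv \
                 --transform reg1/transform.json --report lre.csv
larvreg batch --template tpl --scan scan4 --scan scan5 --out batch
```

A single YAML file (see `larvreg/config.py` for the schema and defaults)
configures all stages; every run writes a manifest with the config hash and
seeds.

## Conventions

* Arrays are indexed `[x, y, z]` (x = fast in-plane axis, z = slice axis);
  the physical position of voxel *(i, j, k)* is `origin + (i, j, k)·spacing`
  in μm.
* All transforms map **fixed-image points into moving-image space**
  (resampling convention); composites apply right-to-left.
* Landmark files are CSV `label,x_um,y_um,z_um` with one header line; a
  separate importer reads Fiji point lists.
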