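# cryoreg

Multimodal whole-animal image registration and analysis toolkit:

- **volume_io** — NIfTI / multipage-TIFF volumes with physical spacing;
  BT.709 grayscale conversion, linear 8-bit windowing, antialiasing Lanczos
  resampling, physically consistent cropping.
- **blockmatch** — rigid/affine registration by block matching with absolute
  normalized cross-correlation (polarity-invariant, so it works across
  modalities) and trimmed-least-squares global fitting, multiscale.
- **ffd** — nonrigid free-form deformation on a cubic B-spline lattice,
  minimizing `-(1-w1-w2)·NMI + w1·BE + w2·JL` (normalized mutual information
  data term, bending-energy and log-Jacobian regularizers) by gradient
  descent with backtracking line search, coarse to fine; one-step composed
  resampling and Jacobian-determinant maps.
- **histo2d** — 2D histology-to-blockface registration: grayscale open/close
  morphological filtering, Sobel edge magnitude, Nelder-Mead similarity fit
  on edge NCC, 2D B-spline FFD refinement, checkerboard / edge-overlap QC.
- **metrics** — Dice, percent volume difference, symmetric mean surface
  distance, paired landmark error, ROI statistics (population sd).
- **ct_volume** — local tissue volume change across freezing from paired CT
  volumes via Hounsfield units: `V_after/V_before = (1000+CT_b)/(1000+CT_a)`.
- **phantom** — seeded synthetic fixtures with ground truth: multimodal 3D
  pairs under known affine + smooth B-spline warps, organ/tumor masks,
  2D blockface/histology pairs, before/after-freezing CT pairs.
- **analysis** — checkerboard renders, thresholded 26-connected tumor
  labelling with size classes (<0.5 mm / 0.5–2 mm / >2 mm equivalent
  diameter), linked cross-channel patch lookup, per-tumor signal tables.
- **pipeline / cli** — config-driven end-to-end driver
  (phantom/files → affine → FFD → resample → evaluate → QC) with
  deterministic, provenance-stamped reports, plus a weight grid search.

## CLI

```bash
cryoreg phantom --kind pair --seed 1 --out-dir fixtures/
cryoreg preprocess --in vol.nii.gz --gray --window 0:15000 --resample 0.1,0.1,0.1 --out pre.nii.gz
cryoreg affine --ref ref.nii.gz --mov mov.nii.gz --out transform.json
cryoreg ffd --ref ref.nii.gz --mov mov.nii.gz --affine transform.json \
            --out ffd.json --resampled reg.nii.gz --jacobian jac.nii.gz
cryoreg evaluate --mask-a a.nii.gz --mask-b b.nii.gz \
                 --landmarks-a a.csv --landmarks-b b.csv --out report.json
cryoreg ct-expansion --before ct0.nii.gz --after ct1.nii.gz --roi roi.nii.gz --out ct.json
cryoreg histo --ref blockface.png --mov histology.png --out histo.json --qc qc.png
cryoreg run --config run.toml
cryoreg gridsearch --config run.toml --w1 0:0.1:0.05 --w2 0:0.1:0.05 --out grid.csv
```

Transforms are JSON: affine as a row-major 3×3 matrix + translation in mm
(mapping reference physical coordinates to moving physical coordinates),
FFD as the control-point displacement lattice with its domain geometry.
Landmark CSVs use columns `label,x_mm,y_mm,z_mm`.

## Conventions

- Voxel indices are 0-based and node-centered: physical position =
  `origin + index * spacing` (mm). Arrays are (x, y, z[, channel]).
- All transforms map **reference** physical coordinates to **moving**
  physical coordinates; warping is pull-back with a single interpolation.
- Intensities entering NMI should be pre-mapped to [0, 255]
  (`window_to_byte`), matching the 256-bin joint histogram.
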