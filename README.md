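# mitometry

Quantitative morphometrics of mitochondria, cristae and mitochondria–ER
contact sites (MERCs) from **segmented** electron-microscopy label maps:
2D TEM sections and 3D volume-EM stacks (SBF-SEM / FIB-SEM exports).
Segmentation itself (e.g. Ilastik pixel classification / MultiCut) is
upstream; this package consumes its integer label maps as TIFF/OME-TIFF,
PNG (2D) or HDF5, always together with an explicit physical calibration
(nm per pixel in x/y, nm per slice in z — there is no implicit
1 px = 1 nm default).

## What it measures

| module | metrics |
|---|---|
| `core` | calibration, label-map I/O, quadrant partitioning, unbiased random object sampling (default minimum n = 10) |
| `morpho2d` | per-object area, perimeter, circularity index 4π·A/P², maximum Feret length, aspect ratio, count density, area histograms |
| `cristae` | cristae count, volume density (areal fraction), membrane-length surface proxy, lamellar vs tubular classification, validation/aggregation of human 0–4 cristae scores |
| `merc` | membrane gap field (physically weighted distance transform), 2D/3D contact-site detection at a configurable gap threshold (default ≤ 50 nm, inclusive), contact length/area, inter-membrane cleft volume, per-organelle coverage percentages, Ca²⁺-transfer band annotation (default 15–30 nm) |
| `morpho3d` | exact voxel volume, isosurface surface area, centerline skeleton with per-node radii, longest-geodesic length, junction/branching statistics, hyperbranching, nanotunnel / mitochondria-on-a-string (MOAS) detection |
| `phantom` | synthetic 2D/3D phantoms with closed-form ground truth for every metric (discs, spheres, tubes, beads-on-string, apposed membranes, cristae mixes…), plus a topology-preserving boundary-jitter robustness harness |
| `report` | two-group comparison (Welch's t or Mann–Whitney, exact null for small n), significance stars (`*` p<0.05 … `****` p<0.0001, strict inequalities), Markdown report with blinded-workflow provenance fields |

Conventions: 3D arrays are ordered `(z, y, x)`; gap distances are measured
between boundary-element centers (stated in output metadata); object
connectivity is 8-connected in 2D; anisotropic stacks are handled by
physically weighted distance transforms and isotropic resampling before
3D thinning.

## CLI

One `mitometry` entry point with a subcommand per module:

```bash
# 2D morphometrics of a TEM-section label image
mitometry morpho2d --labels mito.tif --px-xy-nm 10 --out mito2d.csv

# cristae metrics with optional human scores (CSV: mito_id,score)
mitometry cristae --mito mito.tif --cristae cristae.tif --px-xy-nm 10 \
    --scores scores.csv --out-prefix cristae

# mitochondria–ER contacts, 2D or 3D decided by input dimensionality
mitometry merc --mito mito.h5 --er er.h5 --px-xy-nm 10 --px-z-nm 50 \
    --threshold-nm 50 --out merc.csv

# 3D architecture from a label volume
mitometry morpho3d --labels mito3d.h5 --px-xy-nm 10 --px-z-nm 50 --out m3d.csv

# synthetic phantom with ground-truth JSON
mitometry phantom --kind apposed_slabs_3d --params '{"gap_nm": 30}' --out ph/

# group comparison from a tidy CSV (group, metric, value)
mitometry report --input measurements.csv --metric circularity \
    --test mann_whitney --out cmp.csv --markdown-out report.md
```

## Validation strategy

Every metric is validated against phantoms with analytic ground truth
(`tests/test_acceptance.py`): disc area within 1% and perimeter within 2%
at r = 50 px; digitized-disc circularity in [0.98, 1.02]; sphere volume
within 2% and surface within 5%; skeleton lengths within 5% for straight
and curved tubes; the distance field agrees exactly with a brute-force
all-pairs oracle; the MOAS detector recovers construction labels with
perfect sensitivity and specificity on a 24-phantom grid; Mann–Whitney
p-values match full enumeration.
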