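# nucleoprofiler

Image-based epigenetic profiling of nuclear marker puncta.

`nucleoprofiler` quantifies the spatial organization of chromatin-associated
markers (H3K27ac and CTCF) inside single cell nuclei imaged by fluorescence
microscopy. Super-resolution imaging resolves these markers into discrete
bright foci ("puncta"); the number, size, intensity, radial placement and
cross-marker colocalization of those puncta differ between biological
conditions. The package provides the full measurement chain:

1. **Synthetic ground truth** (`synthgen`) — a seeded generator of elliptical
   nucleus phantoms with Gaussian puncta of known positions, used to validate
   every downstream stage against known answers.
2. **Nucleus geometry** (`geometry`) — moment-equivalent ellipse fitting and
   a five-zone concentric partition of the nuclear interior (zone 5 is the
   periphery).
3. **Field segmentation and QC** (`nucleus_qc`) — classical
   watershed instance segmentation of multi-nucleus fields, rejection of
   misshapen or clipped segments (size, area, roundness, aspect-ratio
   outliers), and padding of accepted nuclei onto fixed canvases.
4. **Puncta segmentation** (`puncta`) — 4-class multi-Otsu thresholding plus
   distance-transform watershed (`thre_h_watershed`), with per-punctum and
   per-nucleus features including radial zone densities.
5. **Colocalization** (`coloc`) — nearest-neighbor distances and
   radius-overlap ratios between the two marker channels.
6. **Classification** (`classifier`, `nn`) — a compact residual CNN
   (9 convolutions + 1 fully connected layer) implemented directly on NumPy,
   trained to separate conditions from single-nucleus images.
7. **Interpretation** (`cam`) — Score-CAM heatmaps of what the classifier
   attends to, heatmap metrics (nuclear intensity, periphery enrichment),
   ellipse-aligned group averages, and a frozen 24-feature heatmap battery.
8. **Resolution degradation** (`lowres`) — Gaussian-kernel blurring that
   emulates conventional (diffraction-limited) imaging, to show which
   measurements survive the loss of super-resolution detail.
9. **Group statistics** (`stats_compare`) — per-feature two-sample t-tests
   and category-level significant-fraction summaries.
10. **I/O and CLI** (`io`, `cli`) — TIFF/PNG/CSV round-trips with unit and
    config-hash sidecars, and a `nucleoprofiler` command-line interface.

See `docs/methods.md` for the precise mathematical definitions, fixed
parameters, and numerical conventions.

## Worked example

Generate two synthetic conditions (25 nuclei each, 128-px desk-scale crops;
the "treated" condition doubles puncta count and peak intensity), profile
every nucleus, and compare the groups:

```python
import pandas as pd
from nucleoprofiler.pipeline import profile_nucleus
from nucleoprofiler.stats_compare import compare_features
from nucleoprofiler.synthgen import (desk_base_config, desk_separable_config,
                                     generate_nucleus)

cfg_a, cfg_b = desk_base_config(128), desk_separable_config(128)
rows = []
for i in range(25):
    for cond, cfg in (("control", cfg_a), ("treated", cfg_b)):
        img, gt = generate_nucleus(cfg, seed=5000 + 2 * i + (cond == "treated"))
        for row in profile_nucleus(img, f"{cond}{i:02d}"):
            row["condition"] = cond
            rows.append(row)
table = pd.DataFrame(rows)
h3 = table[table.channel == "H3K27ac"]
print(h3.groupby("condition")[["puncta_number", "puncta_area",
                               "puncta_intensity", "overlap_ratio"]]
        .mean().round(3))
for c in compare_features(h3, "control", "treated",
                          feature_cols=["puncta_number", "puncta_intensity",
                                        "puncta_area"]):
    print(f"{c.feature:>17}: mean {c.mean_a:8.2f} -> {c.mean_b:8.2f}, "
          f"t = {c.t_statistic:7.2f}, p = {c.p_value:.3g}")
```

Output (verbatim; everything is seeded, so you will get the same numbers):

```text
           puncta_number  puncta_area  puncta_intensity  overlap_ratio
condition
control            17.24        4.282           658.364          0.216
treated            24.96        3.868          1499.130          0.150
    puncta_number: mean    17.24 ->    24.96, t =   -3.16, p = 0.00272
 puncta_intensity: mean   658.36 ->  1499.13, t =   -8.53, p = 3.55e-11
      puncta_area: mean     4.28 ->     3.87, t =    0.87, p = 0.387
```

The doubled puncta count and intensity of the treated condition are
recovered with high significance, while mean punctum area — which the
generator does not change — is correctly non-significant.

Colocalization between the two marker channels of one nucleus:

```python
from nucleoprofiler.coloc import colocalize
from nucleoprofiler.puncta import segment_puncta

img, gt = generate_nucleus(cfg_a, seed=5000)
s = segment_puncta(img.channels["H3K27ac"], img.mask, channel_name="H3K27ac")
t = segment_puncta(img.channels["CTCF"], img.mask, channel_name="CTCF")
res = colocalize(s, t)
```

prints (via the example script):

```text
nucleus seed 5000: 18 H3K27ac puncta, 18 CTCF puncta, mean NN distance 4.63 px, overlap ratio 0.167
```

## Command-line interface

```text
Usage: nucleoprofiler [OPTIONS] COMMAND [ARGS]...

  Image-based epigenetic profiling of nuclear marker puncta.

Commands:
  blur      Simulate conventional-resolution imaging by Gaussian blurring.
  coloc     Colocalization metrics between two per-punctum CSVs.
  compare   Per-feature two-sample t-tests between two conditions.
  profile   Full field profiling: segment, QC, puncta, coloc, feature table.
  puncta    Segment puncta in one nucleus crop and write labels + CSV.
  segment   Segment nuclei in a multi-cell field and write QC'd crops.
  simulate  Generate a two-class synthetic dataset of nucleus crops.
  train     Train the residual CNN on a manifest of labeled nucleus TIFFs.
```

A typical session: `nucleoprofiler simulate --n 20 --seed 1 --out data/`
writes labeled nucleus TIFFs plus a manifest; `nucleoprofiler profile` turns
a field into a tidy per-cell feature CSV; `nucleoprofiler compare --a ctrl
--b treated` runs the group statistics on such a table.

## Reproduction

All randomness flows from explicit integer seeds; single-threaded runs are
bit-reproducible.

Run the full test suite (includes the acceptance battery; the classifier
training tests dominate the runtime, roughly 10–12 minutes on one CPU):

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

`tests/test_acceptance.py` holds one test per validation criterion: blur
kernel physical width, puncta recovery (≥ 95 % detection, ≤ 1.5 px RMSE at
SNR 5), exact brute-force colocalization oracles, Score-CAM closed forms,
zone-partition conservation, every QC rule at its boundary, desk-scale
classifier accuracy on separable (≥ 0.95, three seeds) and null (≈ 0.5)
data, Score-CAM localization of a planted quadrant signal, low-resolution
degradation of small-punctum detection, and Type-I error calibration of the
group statistics.

The standalone acceptance script recomputes the main quantities from a
single seed and writes them as JSON (about 10–12 minutes, dominated by the
four classifier trainings):

```sh
python scripts/acceptance.py --seed 1 --out acceptance.json
```

## Layout

```text
src/nucleoprofiler/   package modules (see list above)
tests/                unit + acceptance tests (pytest)
scripts/acceptance.py seeded end-to-end validation script
docs/methods.md       methods note: model, parameters, conventions
```
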