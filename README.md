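# spinecyto

Quantitative analysis of signalling protrusions and spatial gene-expression
patterning in the vertebrate neuroepithelium.

Radial glial cells (RGCs) of the embryonic spinal cord extend dynamic,
actin-based protrusions (filopodia/cytonemes) that can carry Notch ligands such
as DLL1 beyond immediately adjacent cells. Signalling at a distance changes the
geometry Notch lateral inhibition can produce: instead of a 2-cell
"salt-and-pepper" alternation, the Notch target HES5 forms microclusters of
high- and low-expressing cells with a spatial period of 3–5 cell diameters
(~30–50 µm) along the dorsoventral (DV) axis. This package implements, as
tested reusable code, the three quantitative pieces needed to study that
hypothesis:

1. **Spatial-period pipeline** (`spinecyto.periodicity`). From a calibrated
   fluorescence image, a 15 µm-wide ROI along the DV axis is blurred with an
   isotropic Gaussian (σ = 3 µm, attenuating a period-*T* sinusoid by
   exp(−2π²σ²/T²), which suppresses the ~10 µm internuclear signal), averaged
   per DV row, and detrended with an order-4 polynomial. The spatial period is
   then estimated two ways:
   - **FFT**: the dominant periodogram ordinate I_k = |X_k|²/n, with Fisher's
     exact g-test, g = max_k I_k / Σ_k I_k, against the white-noise null;
   - **ACF**: the mean spacing of autocorrelation peaks that exceed a per-lag
     permutation-bootstrap envelope (values shuffled, ACF recomputed, upper
     1−α quantile per lag).
   Groups of per-ROI periods are compared with a two-tailed Mann–Whitney
   U test (exact enumeration for combined n ≤ 20).
2. **Protrusion morphometry and dynamics** (`spinecyto.geometry`). Summed
   polyline length; orientation of the base→tip chord with −90° apical
   (towards the ventricle), +90° basal, side-corrected; per-cell density;
   per-track maximum extension and lifetime (frames observed × frame
   interval); lifetime outlier exclusion; puncta counting along a trace;
   median ± i.q.r. summaries.
3. **Idealised packing model** (`spinecyto.packing`). Hexagonally packed
   apical endfeet (mean widths: endfoot 5.2 µm, process 1.6 µm, body 7.7 µm)
   give each cell six touching neighbours; a protrusion reaches a *distal*
   (non-neighbouring) cell when it is strictly longer than the one intervening
   structure: an endfoot (5.2 µm) from an endfoot origin, a cell body
   (7.7 µm) from a process origin.

`spinecyto.synthetic` generates images, profiles and time-lapse tracks with
this exact statistical structure and full ground truth, so every stage is
testable without microscopy data; `spinecyto.io` handles calibrated TIFF,
trace/ROI CSV and config YAML.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
and write tables to `results/` (images go to `scratch/`):

```sh
python analysis/01_simulate_data.py
python analysis/02_spatial_period.py
python analysis/03_protrusion_morphometry.py
python analysis/04_packing_reach.py
```

`02_spatial_period.py` analyses 12 images per condition (ground-truth cluster
period 40 µm vs a weak-contrast control) and prints:

```
per-condition spatial periods (median µm):
  FFT: clustered=40.0 (n=12), weak=10.0 (n=12), two-tailed U-test p=1.91e-06
  ACF: clustered=40.0 (n=12), weak=10.0 (n=12), two-tailed U-test p=1.91e-06
clustered FFT recovery: 100% of ROIs within 10% of the 40 µm ground truth; 100% significant (Fisher g)
```

With strong microclusters both methods recover the 40 µm period in every ROI;
when the cluster contrast is nearly removed the pipeline falls back to the
10 µm internuclear signal, and the two conditions separate decisively in the
rank test. `03` and `04` then print:

```
max extension: 6.8±3.9 µm (median±i.q.r.)
lifetime:      4±6 min (median±i.q.r.)
idealised hexagonal endfoot packing: 6 touching neighbours
  from the endfoot: needs > 5.2 µm; 70.7% of protrusions reach
  from the process: needs > 7.7 µm; 34.7% of protrusions reach
```

i.e. most protrusions are long enough to cross a neighbouring endfoot, and
roughly a third can cross a cell body — protrusions plausibly extend Notch
signalling to non-neighbouring cells.

The same operations are available from the shell:

```sh
spinecyto simulate --out-dir scratch/demo --seed 1
spinecyto period --image scratch/demo/tissue_000.tif --rois rois.csv --out periods.csv
spinecyto compare --a grpA.csv --b grpB.csv
```

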