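#!/usr/bin/env python
"""Spatial-period analysis of the synthetic tissue images.

Runs the full pipeline (blur sd 3 µm, row mean, order-4 detrend, FFT +
Fisher g-test, ACF + bootstrap envelope) on every image produced by
01_simulate_data.py, writes the per-ROI period table, and compares the
clustered vs weak-cluster conditions with a two-tailed Mann-Whitney
U test per method.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import spinecyto as sc
import spinecyto.io as sio

ROOT = Path(__file__).resolve().parents[1]
manifest = sio.read_results(ROOT / "results" / "image_manifest.csv")

all_rows = []
for rec in manifest.itertuples():
    img = sio.read_image(ROOT / "scratch" / "images" / rec.image)
    roi = sc.RoiBox(0.0, img.dv_extent_um, width_um=img.ab_extent_um)
    cfg = sc.RunConfig(seed=int(rec.seed))
    table = sc.run_pipeline(img, [roi], cfg)
    table.insert(0, "image", rec.image)
    table.insert(1, "condition", rec.condition)
    table["true_period_um"] = rec.true_period_um
    all_rows.append(table)

periods = pd.concat(all_rows, ignore_index=True)
sio.write_results(periods, ROOT / "results" / "spatial_periods.csv",
                  sc.RunConfig())

print("per-condition spatial periods (median µm):")
for method in ("FFT", "ACF"):
    sub = periods[periods.method == method]
    med = sub.groupby("condition").period_um.median()
    a = sub[sub.condition == "clustered"].period_um.dropna()
    b = sub[sub.condition == "weak"].period_um.dropna()
    p = sc.compare_groups(a, b) if len(a) and len(b) else np.nan
    sig = sub[sub.condition == "clustered"]
    print(f"  {method}: clustered={med.get('clustered', np.nan):.1f} "
          f"(n={len(a)}), weak={med.get('weak', np.nan):.1f} (n={len(b)}), "
          f"two-tailed U-test p={p:.3g}")

fft_cl = periods[(periods.method == "FFT")
                 & (periods.condition == "clustered")]
err = (fft_cl.period_um - fft_cl.true_period_um).abs() / fft_cl.true_period_um
print(f"clustered FFT recovery: {np.mean(err <= 0.10) * 100:.0f}% of ROIs "
      f"within 10% of the 40 µm ground truth; "
      f"{fft_cl.significant.mean() * 100:.0f}% significant (Fisher g)")
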