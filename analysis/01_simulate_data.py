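#!/usr/bin/env python
"""Generate the synthetic study data.

Writes calibrated tissue images (16-bit TIFF + sidecar YAML) to
scratch/images/ for the spatial-period analysis, and the time-lapse
protrusion tracks plus fixed-tissue length samples as CSV under
results/.  Two tissue conditions are generated: "clustered" images with
the full microcluster contrast, and "weak" images with most of the
cluster contrast removed (emulating a perturbation that degrades the
spatial pattern).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import spinecyto as sc
import spinecyto.io as sio

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_IMAGES = 12

img_dir = ROOT / "scratch" / "images"
img_dir.mkdir(parents=True, exist_ok=True)
(ROOT / "results").mkdir(exist_ok=True)

rows = []
for cond, amplitude in (("clustered", 1.0), ("weak", 0.15)):
    for i in range(N_IMAGES):
        params = sc.TissueImageParams(seed=SEED + i, cluster_amplitude=amplitude)
        img, truth = sc.gen_tissue_image(params)
        name = f"{cond}_{i:03d}.tif"
        sio.write_image(img, img_dir / name)
        rows.append(
            {"image": name, "condition": cond, "seed": SEED + i,
             "true_period_um": truth,
             "dv_extent_um": img.dv_extent_um,
             "roi_width_um": img.ab_extent_um}
        )
manifest = pd.DataFrame(rows)
sio.write_results(manifest, ROOT / "results" / "image_manifest.csv")

pop = sc.ProtrusionPopParams(n=150, seed=SEED)
tracks, gt_max, gt_life = sc.gen_timelapse_tracks(pop)
sio.write_traces(tracks, ROOT / "results" / "tracks.csv")
truth = pd.DataFrame(
    {"track_id": range(pop.n), "true_max_length_um": gt_max,
     "true_lifetime_min": gt_life}
)
sio.write_results(truth, ROOT / "results" / "tracks_ground_truth.csv")

print(f"wrote {len(manifest)} images (ground-truth period "
      f"{manifest.true_period_um.iloc[0]:g} µm for clustered condition) "
      f"to {img_dir}")
print(f"wrote {pop.n} time-lapse tracks "
      f"(max length median {np.median(gt_max):.2f} µm, "
      f"lifetime median {np.median(gt_life):.0f} min) to results/tracks.csv")
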