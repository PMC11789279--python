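#!/usr/bin/env python
"""Idealised packing: can protrusions reach non-neighbouring cells?

Combines the measured maximum-extension distribution from
03_protrusion_morphometry.py with the idealised RGC packing model
(mean widths: endfoot 5.2 µm, process 1.6 µm, body 7.7 µm): required
reach per origin site, the fraction of protrusions able to cover it,
and the neighbour count implied by hexagonal endfoot packing.
"""

from pathlib import Path

import spinecyto as sc
import spinecyto.io as sio

ROOT = Path(__file__).resolve().parents[1]
dyn = sio.read_results(ROOT / "results" / "track_dynamics.csv")
params = sc.PackingParams()

report = sc.contact_report(dyn.max_length_um, params)
sio.write_results(report, ROOT / "results" / "reach_report.csv")

n6 = sc.neighbour_count(sc.Layout(packing="hexagonal", params=params))
print(f"idealised hexagonal endfoot packing: {n6} touching neighbours")
for rec in report.itertuples():
    print(f"  from the {rec.origin}: needs > {rec.required_reach_um:g} µm; "
          f"{rec.fraction_reaching * 100:.1f}% of protrusions reach")
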