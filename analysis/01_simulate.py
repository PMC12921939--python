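"""Simulate the study cohort and run paired exams on both devices.

Generates ground-truth 10-2 fields for 12 subjects (1 normal, 2 OMD,
3 STGD, 6 RP; both eyes), then examines every eye with ZEST on both the
projection perimeter and the head-mounted perimeter models.  Writes
truths.csv, measured_octopus.csv, measured_hmp.csv and the resolved run
configuration under results/.
"""

import logging
from pathlib import Path

import perisim as ps

logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

cfg = ps.RunConfig(seed=1, outdir=Path("results"))
observers, oct_fields, hmp_fields = ps.simulate_cohort(cfg, write=True)

n_oct = sum(f.total_presentations for f in oct_fields)
n_hmp = sum(f.total_presentations for f in hmp_fields)
print(f"simulated {len(observers)} eyes ({len(observers) // 2} subjects)")
print(f"octopus exams: {n_oct} presentations "
      f"(median {sorted(f.total_presentations for f in oct_fields)[len(oct_fields) // 2]}/field)")
print(f"hmp exams:     {n_hmp} presentations")
print(f"outputs in {cfg.outdir}/")
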