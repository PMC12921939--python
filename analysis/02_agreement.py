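"""Pointwise agreement analysis of the simulated paired exams.

Reads the measured CSVs written by 01_simulate.py, harmonizes the HMP
scale (+14 dB, floor stays 0), censors to the HMP's measurable window for
regression, and computes the Deming fit, Bland-Altman limits of agreement
and floor-detection diagnostic metrics.  Writes results/agreement.json and
results/agreement_summary.txt.
"""

import logging
from pathlib import Path

from perisim.pipeline import compare_measurements

logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

results = Path("results")
report = compare_measurements(results / "measured_octopus.csv",
                              results / "measured_hmp.csv")
report.to_json(results / "agreement.json")
(results / "agreement_summary.txt").write_text(report.summary() + "\n")
print(report.summary())
print(f"\nwrote {results / 'agreement.json'} and "
      f"{results / 'agreement_summary.txt'}")
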