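"""Grayscale field plots of one characteristic eye per diagnosis.

Renders the right-eye fields of the first subject of each diagnosis, for
both devices, as clinical-style 10-2 grayscale tessellations (HMP fields
in Octopus-equivalent mode: +14 dB, floor 0 stays 0; blind-spot oval marks
laterality).  Writes PNGs under results/figures/.
"""

from pathlib import Path

from perisim.zest import measured_from_csv
from perisim.plotting import plot_field

results = Path("results")
outdir = results / "figures"
outdir.mkdir(parents=True, exist_ok=True)

wanted = {f"{d}01" for d in ("normal", "OMD", "STGD", "RP")}
for csv, mode in [("measured_octopus.csv", "raw"),
                  ("measured_hmp.csv", "equivalent")]:
    for field in measured_from_csv(results / csv):
        if field.subject_id in wanted and field.eye == "OD":
            name = f"{field.subject_id}_{field.eye}_{field.device}.png"
            plot_field(field, mode=mode, path=outdir / name)
            print(f"wrote {outdir / name}")
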