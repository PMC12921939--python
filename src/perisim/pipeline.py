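"""End-to-end simulation pipeline: config, orchestration, persistence.

``simulate_cohort`` generates ground truths and runs paired exams of every
observer on both device models; ``compare_measurements`` feeds matched CSV
outputs into the agreement analysis.  A single master seed in
:class:`RunConfig` determines every stochastic output; the resolved
configuration is written next to the results so each run is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import agreement
from .devices import DeviceModel, load_device, get_preset
from .observer import CohortConfig, generate_cohort, truths_to_csv
from .zest import (MeasuredField, ZestParams, run_exam, measured_to_csv,
                   measured_from_csv)

__all__ = ["RunConfig", "load_config", "simulate_cohort",
           "compare_measurements"]

log = logging.getLogger("perisim")


@dataclass
class RunConfig:
    """Full configuration of a simulate-and-compare run."""

    seed: int = 0
    octopus: DeviceModel = field(default_factory=lambda: get_preset("octopus900"))
    hmp: DeviceModel = field(default_factory=lambda: get_preset("iowa_hmp"))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    zest: ZestParams = field(default_factory=ZestParams)
    offset: float = 14.0
    lam: float = 1.0
    ba_drop_floored: bool = False
    outdir: Path = Path("results")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


_KNOWN_KEYS = {"seed", "octopus", "hmp", "cohort", "zest", "offset",
               "lambda", "ba_drop_floored", "outdir"}


def load_config(source: str | Path | dict) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or a plain dict.

    Device sections accept either a preset name or a mapping with a
    ``preset`` key plus field overrides; ``cohort`` and ``zest`` sections
    override the corresponding dataclass defaults field by field.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
    else:
        data = dict(source)
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def _device(entry, default_name):
        if entry is None:
            return get_preset(default_name)
        if isinstance(entry, str):
            return get_preset(entry)
        return load_device(entry)

    cfg = RunConfig(
        seed=int(data.get("seed", 0)),
        octopus=_device(data.get("octopus"), "octopus900"),
        hmp=_device(data.get("hmp"), "iowa_hmp"),
        cohort=CohortConfig(**data.get("cohort", {})),
        zest=ZestParams(**data.get("zest", {})),
        offset=float(data.get("offset", 14.0)),
        lam=float(data.get("lambda", 1.0)),
        ba_drop_floored=bool(data.get("ba_drop_floored", False)),
        outdir=Path(data.get("outdir", "results")),
    )
    return cfg


def simulate_cohort(config: RunConfig, write: bool = True):
    """Generate the cohort and run both devices' exams on every eye.

    Returns ``(observers, octopus_fields, hmp_fields)``; when ``write`` is
    set, persists truths, per-device measurements, and the resolved config
    under ``config.outdir``.
    """
    rng = np.random.default_rng(config.seed)
    cohort_rng, exam_rng = rng.spawn(2)
    observers = generate_cohort(config.cohort, cohort_rng)
    log.info("cohort: %d observers (%d subjects x 2 eyes), seed %d",
             len(observers), len(observers) // 2, config.seed)
    oct_fields, hmp_fields = [], []
    for obs in observers:
        oct_fields.append(run_exam(config.octopus, obs, params=config.zest,
                                   rng=exam_rng))
        hmp_fields.append(run_exam(config.hmp, obs, params=config.zest,
                                   rng=exam_rng))
    log.info("exams: %d fields per device, %d + %d presentations total",
             len(oct_fields),
             sum(f.total_presentations for f in oct_fields),
             sum(f.total_presentations for f in hmp_fields))
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        truths_to_csv([o.true_field for o in observers],
                      outdir / "truths.csv")
        measured_to_csv(oct_fields, outdir / "measured_octopus.csv")
        measured_to_csv(hmp_fields, outdir / "measured_hmp.csv")
        (outdir / "run_config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=False))
    return observers, oct_fields, hmp_fields


def compare_measurements(octopus_csv: str | Path, hmp_csv: str | Path,
                         offset: float = 14.0, lam: float = 1.0,
                         ba_drop_floored: bool = False
                         ) -> agreement.AgreementReport:
    """Load two measurement CSVs and run the full agreement analysis."""
    oct_fields = measured_from_csv(octopus_csv)
    hmp_fields = measured_from_csv(hmp_csv)
    report = agreement.full_report(oct_fields, hmp_fields, offset=offset,
                                   lam=lam, ba_drop_floored=ba_drop_floored)
    log.info("agreement: n=%d pairs, regression n=%d, Bland-Altman n=%d",
             report.n_pairs, report.n_regression, report.n_bland_altman)
    return report
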