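"""Synthetic observers: ground-truth visual fields and seen/not-seen responses.

Ground truths emulate the central-field loss patterns of the inherited
retinal diseases in the study cohort:

* **normal** — an intact hill of vision, a plane declining gently with
  eccentricity from a foveal peak;
* **OMD** (occult macular dystrophy) — a Gaussian-shaped relative central
  depression on an otherwise normal field;
* **STGD** (Stargardt disease) — an annular "bull's-eye" depression,
  optionally with an absolute central scotoma;
* **RP** (retinitis pigmentosa) — concentric loss: sensitivity preserved
  within a central island, falling through a transition zone to an
  absolute scotoma (or a deep relative floor) outside.

True sensitivities are expressed on the Octopus-equivalent decibel scale
(referenced to a 318 cd/m^2 maximal increment) so one ground truth can
drive simulated exams on any device; ``-inf`` encodes an absolute scotoma.

Responses follow a standard frequency-of-seeing model: a cumulative
Gaussian of the stimulus level around the true threshold, with
false-positive and false-negative lapse rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grid import TestGrid, generate_10_2

__all__ = [
    "TrueField",
    "PsychometricObserver",
    "CohortConfig",
    "DIAGNOSES",
    "make_true_field",
    "respond",
    "generate_cohort",
    "truths_to_csv",
    "truths_from_csv",
]

DIAGNOSES = ("normal", "OMD", "STGD", "RP")

#: Hill-of-vision defaults: foveal peak and linear decline per degree of
#: eccentricity, placing normal central sensitivities near the top of the
#: projection perimeter's 33 dB range.
DEFAULT_HILL = {"peak_db": 33.0, "decay_db_per_deg": 0.5}

#: Default loss-pattern parameters per diagnosis (dB and degrees).
DEFAULT_PATTERNS: dict[str, dict] = {
    "normal": {},
    "OMD": {"depth_db": 18.0, "radius_deg": 4.0},
    "STGD": {
        "depth_db": 25.0,
        "ring_radius_deg": 4.0,
        "ring_width_deg": 2.0,
        "scotoma_radius_deg": 0.0,
    },
    "RP": {
        "preserved_radius_deg": 4.0,
        "transition_width_deg": 3.0,
        "floor_db": -10.0,
        "absolute": True,
    },
}

# Bounds for finite true sensitivities; -inf (absolute scotoma) is outside.
_TRUE_DB_MIN, _TRUE_DB_MAX = -10.0, 45.0


@dataclass(frozen=True)
class TrueField:
    """Ground-truth sensitivity surface for one eye, Octopus-equivalent dB."""

    grid: TestGrid
    true_db: np.ndarray
    diagnosis: str
    subject_id: str = ""
    eye: str = "OD"

    def __post_init__(self) -> None:
        vals = np.asarray(self.true_db, dtype=float)
        if vals.shape != (len(self.grid),):
            raise ValueError("one true value per grid location required")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < _TRUE_DB_MIN or finite.max() > _TRUE_DB_MAX):
            raise ValueError(
                f"finite true sensitivities must lie in "
                f"[{_TRUE_DB_MIN}, {_TRUE_DB_MAX}] dB"
            )
        if np.any(np.isnan(vals)) or np.any(vals == np.inf):
            raise ValueError("true sensitivities must be finite or -inf")
        object.__setattr__(self, "true_db", vals)


@dataclass(frozen=True)
class PsychometricObserver:
    """Frequency-of-seeing response model around a :class:`TrueField`.

    ``P(seen | stimulus s at location with threshold t)``
    ``= fp + (1 - fp - fn) * Phi((t - s) / slope_sd)``

    with stimulus and threshold on the same (Octopus-equivalent) dB scale;
    higher dB = dimmer stimulus, so ``s`` far below ``t`` is almost always
    seen.  An absolute scotoma (``t = -inf``) responds only through the
    false-positive rate.  ``device_effects`` optionally shifts the
    effective thresholds by a per-device dB amount (e.g. to emulate
    adaptation differences under different background luminances).
    """

    true_field: TrueField
    slope_sd: float = 1.5
    fp_rate: float = 0.03
    fn_rate: float = 0.03
    device_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slope_sd <= 0:
            raise ValueError("slope_sd must be positive")
        if not (0 <= self.fp_rate and 0 <= self.fn_rate
                and self.fp_rate + self.fn_rate < 1):
            raise ValueError("need 0 <= fp, fn and fp + fn < 1")

    def threshold(self, index: int, device: str | None = None) -> float:
        t = self.true_field.true_db[index]
        if device is not None:
            t = t + self.device_effects.get(device, 0.0)
        return t

    def prob_seen(self, index: int, stimulus_db: float,
                  device: str | None = None) -> float:
        t = self.threshold(index, device)
        if t == -math.inf:
            core = 0.0
        else:
            core = norm.cdf((t - stimulus_db) / self.slope_sd)
        return self.fp_rate + (1.0 - self.fp_rate - self.fn_rate) * core


def respond(observer: PsychometricObserver, index: int, stimulus_db: float,
            rng: np.random.Generator, device: str | None = None) -> bool:
    """Draw one seen/not-seen response to a stimulus at a grid location."""
    return bool(rng.random() < observer.prob_seen(index, stimulus_db, device))


def _hill(ecc: np.ndarray, hill: dict) -> np.ndarray:
    return hill["peak_db"] - hill["decay_db_per_deg"] * ecc


def make_true_field(
    diagnosis: str,
    params: dict | None = None,
    grid: TestGrid | None = None,
    rng: np.random.Generator | None = None,
    jitter_sd: float = 0.0,
    hill: dict | None = None,
    subject_id: str = "",
    eye: str = "OD",
) -> TrueField:
    """Construct a ground-truth field for one diagnosis.

    Starts from the hill of vision ``peak - decay * eccentricity`` and
    applies the diagnosis' loss pattern, then adds per-location Gaussian
    jitter of SD ``jitter_sd`` to finite values.  All pattern parameters
    in ``params`` override :data:`DEFAULT_PATTERNS`.
    """
    if diagnosis not in DIAGNOSES:
        raise ValueError(f"unknown diagnosis {diagnosis!r}; one of {DIAGNOSES}")
    if grid is None:
        grid = generate_10_2(eye=eye)
    p = {**DEFAULT_PATTERNS[diagnosis], **(params or {})}
    h = {**DEFAULT_HILL, **(hill or {})}
    ecc = grid.eccentricity
    vals = _hill(ecc, h)

    if diagnosis == "OMD":
        r = p["radius_deg"]
        vals = vals - p["depth_db"] * np.exp(-(ecc**2) / (2.0 * r**2))
    elif diagnosis == "STGD":
        rr, w = p["ring_radius_deg"], p["ring_width_deg"]
        vals = vals - p["depth_db"] * np.exp(-((ecc - rr) ** 2) / (2.0 * w**2))
        if p["scotoma_radius_deg"] > 0:
            vals = np.where(ecc < p["scotoma_radius_deg"], -np.inf, vals)
    elif diagnosis == "RP":
        r, w = p["preserved_radius_deg"], p["transition_width_deg"]
        frac = np.clip((ecc - r) / w, 0.0, 1.0)
        vals = (1.0 - frac) * vals + frac * p["floor_db"]
        if p.get("absolute", True):
            vals = np.where(ecc >= r + w, -np.inf, vals)

    if jitter_sd > 0:
        if rng is None:
            raise ValueError("rng required when jitter_sd > 0")
        vals = vals + np.where(np.isfinite(vals),
                               rng.normal(0.0, jitter_sd, len(grid)), 0.0)
    finite = np.isfinite(vals)
    vals[finite] = np.clip(vals[finite], _TRUE_DB_MIN, _TRUE_DB_MAX)
    return TrueField(grid=grid, true_db=vals, diagnosis=diagnosis,
                     subject_id=subject_id, eye=eye)


@dataclass
class CohortConfig:
    """Composition and variability of a simulated study cohort.

    Defaults mirror the pilot-study cohort: 1 normal subject, 2 with occult
    macular dystrophy, 3 with Stargardt disease, 6 with retinitis
    pigmentosa; both eyes of each subject are examined.
    """

    counts: dict = field(default_factory=lambda: {
        "normal": 1, "OMD": 2, "STGD": 3, "RP": 6})
    patterns: dict = field(default_factory=dict)   # per-diagnosis overrides
    hill: dict = field(default_factory=dict)
    inter_subject_sd: float = 2.0    # dB, shared hill-peak offset per subject
    radius_jitter_sd: float = 0.5    # deg, per-subject size-parameter jitter
    location_jitter_sd: float = 1.0  # dB, independent per eye and location
    slope_sd: float = 1.5            # frequency-of-seeing spread, dB
    fp_rate: float = 0.03
    fn_rate: float = 0.03
    device_effects: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("cohort counts must be non-negative")
        unknown = set(self.counts) - set(DIAGNOSES)
        if unknown:
            raise ValueError(f"unknown diagnoses in counts: {sorted(unknown)}")


# Which pattern parameter carries the per-subject size jitter.
_SIZE_PARAM = {"OMD": "radius_deg", "STGD": "ring_radius_deg",
               "RP": "preserved_radius_deg"}


def generate_cohort(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> list[PsychometricObserver]:
    """Generate both eyes of every subject in the configured cohort.

    Each subject draws a hill-peak offset (inter-subject variability) and a
    small perturbation of their pattern's size parameter; both eyes share
    these and differ only by independent per-location jitter.  Fully
    reproducible from the RNG (or ``config.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    observers: list[PsychometricObserver] = []
    for diagnosis in DIAGNOSES:
        n = config.counts.get(diagnosis, 0)
        for i in range(n):
            subject_id = f"{diagnosis}{i + 1:02d}"
            peak_offset = rng.normal(0.0, config.inter_subject_sd)
            params = {**DEFAULT_PATTERNS[diagnosis],
                      **config.patterns.get(diagnosis, {})}
            size_key = _SIZE_PARAM.get(diagnosis)
            if size_key is not None and config.radius_jitter_sd > 0:
                params[size_key] = max(
                    0.5, params[size_key]
                    + rng.normal(0.0, config.radius_jitter_sd))
            hill = {**DEFAULT_HILL, **config.hill}
            hill["peak_db"] = hill["peak_db"] + peak_offset
            for eye in ("OD", "OS"):
                tf = make_true_field(
                    diagnosis, params, generate_10_2(eye=eye), rng,
                    jitter_sd=config.location_jitter_sd, hill=hill,
                    subject_id=subject_id, eye=eye)
                observers.append(PsychometricObserver(
                    true_field=tf, slope_sd=config.slope_sd,
                    fp_rate=config.fp_rate, fn_rate=config.fn_rate,
                    device_effects=dict(config.device_effects)))
    return observers


def truths_to_csv(fields: list[TrueField], path: str | Path) -> None:
    """Write ground truths as CSV; ``-inf`` is serialized as the literal
    token ``-inf``."""
    rows = []
    for f in fields:
        for (x, y), t in zip(f.grid.xy, f.true_db):
            rows.append({"subject_id": f.subject_id, "eye": f.eye,
                         "diagnosis": f.diagnosis, "x_deg": int(x),
                         "y_deg": int(y),
                         "true_db": "-inf" if t == -math.inf else repr(float(t))})
    pd.DataFrame(rows).to_csv(path, index=False)


def truths_from_csv(path: str | Path) -> list[TrueField]:
    """Read ground truths written by :func:`truths_to_csv`."""
    df = pd.read_csv(path, dtype={"true_db": str})
    fields = []
    for (sid, eye), g in df.groupby(["subject_id", "eye"], sort=False):
        vals = g["true_db"].map(float).to_numpy()
        grid = TestGrid(g[["x_deg", "y_deg"]].to_numpy(), eye=eye,
                        pattern_name="10-2")
        fields.append(TrueField(grid=grid, true_db=vals,
                                diagnosis=g["diagnosis"].iloc[0],
                                subject_id=sid, eye=eye))
    return fields
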