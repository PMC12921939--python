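"""Bayesian ZEST threshold estimation and whole-field exam simulation.

ZEST (Zippy Estimation by Sequential Testing) maintains a probability mass
function over candidate thresholds on the device's decibel scale.  Each
trial presents a stimulus at the pdf mean (clamped to what the hardware can
produce and snapped to its luminance quantization ladder), multiplies the
pdf pointwise by the likelihood of the observed response under a
cumulative-Gaussian listener model, and renormalizes.  The procedure stops
when the pdf standard deviation falls below a criterion or a presentation
cap is reached; the threshold estimate is the final pdf mean, clamped to
the measurable range.  An estimate of exactly 0 dB signals the floor: the
brightest stimulus the device can present was not reliably seen.

Exams run an independent ZEST at each of the 68 grid locations in
randomized interleaved order.  Ground truths live on the Octopus-equivalent
scale; the exam converts each physical stimulus to that scale (an exact
luminance identity) before querying the observer, so one truth drives both
simulated devices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .devices import (
    DeviceModel,
    dynamic_range,
    equivalent_offset,
    increment_from_sensitivity,
    quantize_increment,
    sensitivity_from_increment,
)
from .grid import TestGrid
from .observer import PsychometricObserver

__all__ = [
    "ZestParams",
    "ZestState",
    "MeasuredField",
    "zest_init",
    "zest_step",
    "zest_estimate",
    "run_zest",
    "run_exam",
    "measured_to_csv",
    "measured_from_csv",
]


@dataclass(frozen=True)
class ZestParams:
    """Tunable ZEST engine parameters.

    The listener model (``sigma_model``, ``fp_model``, ``fn_model``) is the
    psychometric function the *engine assumes* when computing likelihoods;
    it may deliberately differ from the simulated observer's true one to
    study misspecification.
    """

    domain_step_db: float = 0.5
    guard_db: float = 5.0          # domain extends this far past [0, range]
    stop_sd_db: float = 1.5
    max_presentations: int = 12
    sigma_model: float = 1.5
    fp_model: float = 0.03
    fn_model: float = 0.03


@dataclass
class ZestState:
    """Per-location ZEST state: threshold pdf over a dB domain."""

    domain: np.ndarray
    pdf: np.ndarray
    n_presentations: int = 0
    finished: bool = False

    @property
    def mean(self) -> float:
        return float(np.dot(self.domain, self.pdf))

    @property
    def sd(self) -> float:
        m = self.mean
        return float(math.sqrt(np.dot((self.domain - m) ** 2, self.pdf)))


@dataclass(frozen=True)
class MeasuredField:
    """Threshold estimates from one simulated (or imported) exam."""

    grid: TestGrid
    sensitivity_db: np.ndarray   # device scale, in [0, dynamic range]
    n_presentations: np.ndarray
    device: str
    subject_id: str = ""
    eye: str = "OD"

    def __post_init__(self) -> None:
        vals = np.asarray(self.sensitivity_db, dtype=float)
        if vals.shape != (len(self.grid),):
            raise ValueError("one estimate per grid location required")
        if np.any(vals < 0) or np.any(~np.isfinite(vals)):
            raise ValueError("estimates must be finite and >= 0 dB")
        object.__setattr__(self, "sensitivity_db", vals)
        object.__setattr__(
            self, "n_presentations",
            np.asarray(self.n_presentations, dtype=int))

    @property
    def total_presentations(self) -> int:
        return int(self.n_presentations.sum())


def zest_init(device: DeviceModel, prior: np.ndarray | None = None,
              params: ZestParams = ZestParams()) -> ZestState:
    """Initialize a ZEST state for one location on a device.

    The domain spans ``[-guard, dynamic_range + guard]`` dB at
    ``domain_step_db`` spacing; guard bands let the pdf mass move beyond
    the measurable range so floor and ceiling outcomes are expressible.
    The prior is uniform unless supplied (it is normalized either way).
    """
    dr = dynamic_range(device)
    n = int(round((dr + 2 * params.guard_db) / params.domain_step_db)) + 1
    domain = -params.guard_db + params.domain_step_db * np.arange(n)
    if prior is None:
        pdf = np.full(n, 1.0 / n)
    else:
        pdf = np.asarray(prior, dtype=float)
        if pdf.shape != domain.shape:
            raise ValueError(
                f"prior must have {n} entries matching the domain")
        if np.any(pdf < 0) or pdf.sum() <= 0:
            raise ValueError("prior must be non-negative with positive mass")
        pdf = pdf / pdf.sum()
    return ZestState(domain=domain, pdf=pdf)


def _likelihood_seen(domain: np.ndarray, stimulus_db: float,
                     params: ZestParams) -> np.ndarray:
    """P(seen | threshold t) over the domain, for one stimulus level."""
    core = norm.cdf((domain - stimulus_db) / params.sigma_model)
    return params.fp_model + (1.0 - params.fp_model - params.fn_model) * core


def zest_step(state: ZestState, device: DeviceModel,
              respond: Callable[[float], bool],
              params: ZestParams = ZestParams()) -> float:
    """Run one ZEST trial in place; returns the stimulus level presented.

    The target level is the pdf mean clamped to the measurable range; the
    actually presented level is that target pushed through the device's
    luminance quantization.  ``respond`` receives the presented level on
    the *device* dB scale and returns seen (True) / not seen (False).
    """
    if state.finished:
        raise RuntimeError("zest_step called on a finished state")
    dr = dynamic_range(device)
    target = min(max(state.mean, 0.0), dr)
    dl = quantize_increment(device, increment_from_sensitivity(device, target))
    stimulus = sensitivity_from_increment(device, dl)
    seen = respond(stimulus)
    lik = _likelihood_seen(state.domain, stimulus, params)
    post = state.pdf * (lik if seen else 1.0 - lik)
    total = post.sum()
    if total <= 0:  # unreachable with lapse rates > 0; guard for fp=fn=0
        post = state.pdf
        total = post.sum()
    state.pdf = post / total
    state.n_presentations += 1
    if state.sd < params.stop_sd_db or state.n_presentations >= params.max_presentations:
        state.finished = True
    return stimulus


def zest_estimate(state: ZestState, device: DeviceModel) -> float:
    """Final threshold estimate: pdf mean clamped to [0, dynamic range]."""
    if not state.finished:
        raise RuntimeError("zest_estimate called before the procedure finished")
    return min(max(state.mean, 0.0), dynamic_range(device))


def run_zest(device: DeviceModel, respond: Callable[[float], bool],
             params: ZestParams = ZestParams(),
             prior: np.ndarray | None = None) -> tuple[float, int]:
    """Run one full per-location ZEST; returns (estimate dB, n presented)."""
    state = zest_init(device, prior, params)
    while not state.finished:
        zest_step(state, device, respond, params)
    return zest_estimate(state, device), state.n_presentations


def run_exam(device: DeviceModel, observer: PsychometricObserver,
             grid: TestGrid | None = None,
             params: ZestParams = ZestParams(),
             rng: np.random.Generator | None = None) -> MeasuredField:
    """Simulate a whole-field exam of one observer on one device.

    Runs an independent ZEST per location, interleaving presentations
    across locations in randomized order.  Stimuli are selected and
    reported on the device's dB scale; each presented stimulus is
    converted to the Octopus-equivalent scale by the exact luminance
    offset before querying the observer's frequency-of-seeing model.
    """
    if grid is None:
        grid = observer.true_field.grid
    if len(grid) != len(observer.true_field.grid) or not np.array_equal(
            grid.xy, observer.true_field.grid.xy):
        raise ValueError("exam grid does not match the observer's grid")
    if rng is None:
        rng = np.random.default_rng()
    offset = equivalent_offset(device)
    n = len(grid)
    states = [zest_init(device, None, params) for _ in range(n)]
    active = list(range(n))
    while active:
        order = rng.permutation(len(active))
        for j in order:
            i = active[j]
            if states[i].finished:
                continue
            zest_step(
                states[i], device,
                lambda s, i=i: bool(
                    rng.random() < observer.prob_seen(i, s + offset,
                                                      device=device.name)),
                params)
        active = [i for i in active if not states[i].finished]
    est = np.array([zest_estimate(s, device) for s in states])
    npres = np.array([s.n_presentations for s in states])
    return MeasuredField(grid=grid, sensitivity_db=est, n_presentations=npres,
                         device=device.name,
                         subject_id=observer.true_field.subject_id,
                         eye=observer.true_field.eye)


def measured_to_csv(fields: list[MeasuredField], path: str | Path) -> None:
    rows = []
    for f in fields:
        for (x, y), s, k in zip(f.grid.xy, f.sensitivity_db,
                                f.n_presentations):
            rows.append({"subject_id": f.subject_id, "eye": f.eye,
                         "device": f.device, "x_deg": int(x), "y_deg": int(y),
                         "sensitivity_db": repr(float(s)),
                         "n_presentations": int(k)})
    pd.DataFrame(rows).to_csv(path, index=False)


def measured_from_csv(path: str | Path) -> list[MeasuredField]:
    df = pd.read_csv(path, float_precision="round_trip")
    fields = []
    for (sid, eye, dev), g in df.groupby(["subject_id", "eye", "device"],
                                         sort=False):
        grid = TestGrid(g[["x_deg", "y_deg"]].to_numpy(), eye=eye,
                        pattern_name="10-2")
        fields.append(MeasuredField(
            grid=grid, sensitivity_db=g["sensitivity_db"].to_numpy(float),
            n_presentations=g["n_presentations"].to_numpy(int),
            device=dev, subject_id=sid, eye=eye))
    return fields
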