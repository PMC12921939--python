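"""Perimeter device models and decibel/luminance conversions.

A perimeter presents brief luminance increments ``dL`` on a uniform
background and reports the detection threshold on a decibel attenuation
scale referenced to the brightest increment the device can produce::

    sensitivity [dB] = 10 * log10(dL_max / dL_threshold)

so 0 dB is the brightest presentable stimulus and higher dB means a dimmer
(harder) stimulus.  Because each device has its own ``dL_max``, the 0 dB
points of two perimeters differ by ``10*log10(dL_max_A / dL_max_B)`` — the
*sensitivity offset*.  The span between the brightest and the dimmest
reliably presentable increment is the *dynamic range*; sensitivities outside
it are floored (reported as 0 dB) or ceilinged.

Two presets are shipped: a projection perimeter (Octopus 900 style, large
dynamic range) and a smartphone head-mounted perimeter (Iowa-HMP style,
RGB display with 255 luminance steps viewed through a 0.6 OD neutral
density filter).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DeviceModel",
    "OCTOPUS900",
    "IOWA_HMP",
    "REFERENCE_DELTA_L_MAX",
    "get_preset",
    "load_device",
    "sensitivity_from_increment",
    "increment_from_sensitivity",
    "offset_between",
    "to_octopus_equivalent",
    "equivalent_offset",
    "dynamic_range",
    "screen_setting_for_background",
    "quantize_increment",
]

#: dL_max (cd/m^2) of the projection perimeter; the reference 0 dB point of
#: the "Octopus-equivalent" sensitivity scale used for ground truths.
REFERENCE_DELTA_L_MAX = 318.0


@dataclass(frozen=True)
class DeviceModel:
    """Stimulus capabilities of one perimeter.

    Parameters
    ----------
    name
        Text label, e.g. ``"octopus900"``.
    background_luminance
        Adapting background in cd/m^2 (as seen by the observer, i.e. behind
        any ND filter).
    delta_L_max
        Brightest presentable luminance increment in cd/m^2; defines 0 dB.
    delta_L_min
        Dimmest *reliably* presentable increment in cd/m^2; defines the top
        of the measurable range.
    n_levels
        Number of equally spaced achievable increments between
        ``delta_L_min`` and ``delta_L_max`` (255 for 8-bit displays).
        ``None`` models a continuously adjustable projection system.
    nd_filter_od
        Optical density of a neutral density filter in the light path
        (attenuation factor ``10**od``); 0 for none.
    stimulus_size_deg
        Stimulus diameter in degrees of visual angle (0.43 = Goldmann III).
    stimulus_duration_ms
        Stimulus presentation time in milliseconds.
    display_step
        Optional metadata: the display's minimal luminance step in cd/m^2
        (for 8-bit phone screens this can be smaller than the *reliable*
        ``delta_L_min``).
    """

    name: str
    background_luminance: float
    delta_L_max: float
    delta_L_min: float
    n_levels: int | None = None
    nd_filter_od: float = 0.0
    stimulus_size_deg: float = 0.43
    stimulus_duration_ms: float = 100.0
    display_step: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.delta_L_min < self.delta_L_max):
            raise ValueError(
                f"require 0 < delta_L_min < delta_L_max, got "
                f"{self.delta_L_min}, {self.delta_L_max}"
            )
        if self.background_luminance <= 0:
            raise ValueError("background_luminance must be positive")
        if self.n_levels is not None and self.n_levels < 2:
            raise ValueError("n_levels must be at least 2")

    @property
    def dynamic_range_db(self) -> float:
        return dynamic_range(self)

    def to_dict(self) -> dict:
        return asdict(self)


#: Projection perimeter (legacy 1.27 cd/m^2 background protocol).
#: delta_L_min is not a published figure; it is set so the dynamic range is
#: exactly the instrument's stated 33 dB.
OCTOPUS900 = DeviceModel(
    name="octopus900",
    background_luminance=1.27,
    delta_L_max=318.0,
    delta_L_min=318.0 * 10 ** (-3.3),  # 0.1594 cd/m^2 -> 33 dB range
    n_levels=None,
)

#: Smartphone head-mounted perimeter behind a 0.6 OD filter.  The effective
#: delta_L_min is set so the dynamic range is exactly 16 dB (a 40x luminance
#: ratio); the finer 0.13 cd/m^2 display step is kept as metadata.
IOWA_HMP = DeviceModel(
    name="iowa_hmp",
    background_luminance=10.0,
    delta_L_max=12.76,
    delta_L_min=12.76 * 10 ** (-1.6),  # 0.3206 cd/m^2 -> 16 dB range
    n_levels=255,
    nd_filter_od=0.6,
    display_step=0.13,
)

_PRESETS = {"octopus900": OCTOPUS900, "iowa_hmp": IOWA_HMP}


def get_preset(name: str) -> DeviceModel:
    """Return a shipped device preset by name (``octopus900`` | ``iowa_hmp``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown device preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def load_device(source: str | Path | dict) -> DeviceModel:
    """Build a :class:`DeviceModel` from a dict or a YAML/JSON file.

    A ``preset`` key selects a shipped preset; any other keys override its
    fields.  Without ``preset`` all constructor fields must be given.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("device definition must be a mapping")
    preset = data.pop("preset", None)
    if preset is not None:
        base = get_preset(preset).to_dict()
        base.update(data)
        data = base
    valid = {f for f in DeviceModel.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown device fields: {sorted(unknown)}")
    return DeviceModel(**data)


def sensitivity_from_increment(device: DeviceModel, delta_L) -> float:
    """Sensitivity in dB of an increment ``delta_L`` (cd/m^2) on this device.

    ``10*log10(delta_L_max / delta_L)``: 0 dB at the device's brightest
    stimulus, strictly decreasing in ``delta_L``.
    """
    delta_L = np.asarray(delta_L, dtype=float)
    if np.any(delta_L <= 0):
        raise ValueError("delta_L must be positive")
    out = 10.0 * np.log10(device.delta_L_max / delta_L)
    return float(out) if out.ndim == 0 else out


def increment_from_sensitivity(device: DeviceModel, s) -> float:
    """Luminance increment (cd/m^2) corresponding to sensitivity ``s`` dB."""
    s = np.asarray(s, dtype=float)
    out = device.delta_L_max * 10.0 ** (-s / 10.0)
    return float(out) if out.ndim == 0 else out


def offset_between(device_a: DeviceModel, device_b: DeviceModel) -> float:
    """Sensitivity-scale offset ``10*log10(dL_max_a / dL_max_b)`` in dB.

    A stimulus of one physical luminance reads ``offset_between(a, b)`` dB
    higher on device *b*'s scale than on device *a*'s.  Antisymmetric.
    """
    return 10.0 * math.log10(device_a.delta_L_max / device_b.delta_L_max)


def equivalent_offset(device: DeviceModel) -> float:
    """Exact dB offset from this device's scale to the Octopus-equivalent
    scale (referenced to :data:`REFERENCE_DELTA_L_MAX`)."""
    return 10.0 * math.log10(REFERENCE_DELTA_L_MAX / device.delta_L_max)


def to_octopus_equivalent(s_hmp, offset: float = 14.0):
    """Harmonize HMP sensitivities onto the projection perimeter's scale.

    Adds ``round(offset)`` dB to every value above the floor; exact 0 dB
    (floor: the brightest HMP stimulus was not reliably seen) stays 0,
    because a floored value is a censoring indicator, not a measurement.
    """
    arr = np.asarray(s_hmp, dtype=float)
    if np.any(arr < 0):
        raise ValueError("HMP sensitivities must be >= 0 dB")
    shift = float(round(offset))
    out = np.where(arr > 0, arr + shift, 0.0)
    return float(out) if out.ndim == 0 else out


def dynamic_range(device: DeviceModel) -> float:
    """Measurable span ``10*log10(delta_L_max / delta_L_min)`` in dB."""
    return 10.0 * math.log10(device.delta_L_max / device.delta_L_min)


def screen_setting_for_background(target: float, nd_od: float) -> float:
    """Screen luminance (cd/m^2) needed so that ``target`` cd/m^2 is seen
    through a neutral density filter of optical density ``nd_od``."""
    if target <= 0:
        raise ValueError("target luminance must be positive")
    if nd_od < 0:
        raise ValueError("optical density must be non-negative")
    return target * 10.0 ** nd_od


def quantize_increment(device: DeviceModel, delta_L: float) -> float:
    """Snap an increment to the device's nearest achievable luminance level.

    Display devices can only produce ``n_levels`` equally spaced increments
    between ``delta_L_min`` and ``delta_L_max``; requests outside that range
    clamp to the nearest end.  Continuous devices (``n_levels is None``)
    only clamp.  Idempotent.
    """
    if delta_L <= 0:
        raise ValueError("delta_L must be positive")
    lo, hi = device.delta_L_min, device.delta_L_max
    x = min(max(delta_L, lo), hi)
    if device.n_levels is None:
        return x
    step = (hi - lo) / (device.n_levels - 1)
    k = round((x - lo) / step)
    return lo + k * step
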