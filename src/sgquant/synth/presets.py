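"""Named parameter bundles reproducing the study conditions.

Each preset fixes the generator parameters at the values measured in the
original experiments: cortical granule fractions of 70% (interphase) and
13% (metaphase), the exact fixture totals of 227 and 376 granules over
three cells, responder probabilities of 0.81 / 0.67 with a metaphase
intensity attenuation of 0.61, and directed velocities of 0.23 um/s
(anaphase) and 0.34 um/s (cytokinesis). Presets are immutable; ``get``
returns a fresh params object with any overrides applied.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Any

from .em import EMSceneParams
from .fluor import FluorSceneParams
from .tracks import TrackSetParams

_PRESETS: dict[str, tuple[type, dict[str, Any]]] = {
    "em_interphase": (
        EMSceneParams,
        dict(
            cortical_probability=0.70,
            granules_per_cell=75,
            stage_class="interphase",
        ),
    ),
    "em_metaphase": (
        EMSceneParams,
        dict(
            cortical_probability=0.13,
            granules_per_cell=125,
            stage_class="metaphase",
        ),
    ),
    "em_interphase_fixture": (
        EMSceneParams,
        dict(
            n_cells=3,
            granules_total=227,
            cortical_probability=0.70,
            stage_class="interphase",
        ),
    ),
    "em_metaphase_fixture": (
        EMSceneParams,
        dict(
            n_cells=3,
            granules_total=376,
            cortical_probability=0.13,
            stage_class="metaphase",
        ),
    ),
    "fluor_stimulated": (
        FluorSceneParams,
        dict(
            responder_probability={"interphase": 0.81, "metaphase": 0.67},
            intensity_scale_by_class={"interphase": 1.0, "metaphase": 0.61},
            condition="stimulated",
        ),
    ),
    "fluor_control": (
        FluorSceneParams,
        dict(responder_probability=0.0, condition="control"),
    ),
    "tracks_anaphase": (
        TrackSetParams,
        dict(speed_mean_um_s=0.23, speed_sd_um_s=0.09),
    ),
    "tracks_cytokinesis": (
        TrackSetParams,
        dict(speed_mean_um_s=0.34, speed_sd_um_s=0.09),
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))
PRESETS = MappingProxyType({k: MappingProxyType(v[1]) for k, v in _PRESETS.items()})


def get(name: str, **overrides: Any):
    """Instantiate a preset's parameter object, optionally overridden.

    Overrides are applied on top of the preset fields; unknown preset
    names and unknown parameter fields both raise.
    """
    try:
        cls, fields = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    merged = {**fields, **overrides}
    return cls(**merged)
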