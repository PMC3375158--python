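"""Synthetic three-channel fluorescence scenes.

Each scene emulates a widefield field of view of stimulated (or control)
neuroendocrine cells: a WGA membrane stain forming a bright closed ring
around every cell, a Hoechst DNA channel distinguishing interphase nuclei
from metaphase plates, and an SgII immunostain channel in which only
*responder* cells carry punctate surface signal on a band straddling their
membrane. Exact ground truth (class, responder flag, true surface signal
density, outline polygon) is returned alongside the pixel data so that the
downstream segmentation and densitometry stages can be tested by parameter
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np
import pandas as pd

from ..types import MultiChannelScene
from ._geometry import (
    boundary_distance_field,
    perimeter,
    polyline_arclength_samples,
    rasterize_interior,
    stamp_gaussian,
    star_polygon,
)

INTERPHASE = "interphase"
METAPHASE = "metaphase"

#: fixed rendering constants (arbitrary units / pixels)
_HOECHST_AMPLITUDE = 150.0
_INTERIOR_FILL_FRAC = 0.15   # dim WGA cytoplasmic fill relative to the ring
_PUNCTA_SIGMA_PX = 1.3
_PUNCTA_DENSITY_PER_PX = 0.06
_PUNCTA_OFFSET_SD_PX = 1.2
_SURFACE_BAND_HALFWIDTH_PX = 3.0


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without illegal overlap."""


@dataclass(frozen=True)
class FluorSceneParams:
    """Parameters of one synthetic fluorescence scene.

    ``responder_probability`` may be a single probability or a mapping
    stage-class -> probability; ``intensity_scale_by_class`` multiplies
    ``responder_surface_mean`` per class (the metaphase exocytosis
    attenuation). ``nonresponder_surface_mean`` is the *added* surface
    signal of non-responding cells; its default 0 leaves them exactly at
    the background level, i.e. indistinguishable from unstimulated cells.
    """

    n_cells: int = 16
    cluster_layout: str = "grid"          # "grid" (isolated) | "pairs" (touching)
    cell_radius_px: float = 28.0
    cell_radius_sd_px: float = 2.0
    membrane_ring_intensity: float = 200.0
    membrane_ring_width_px: float = 3.0
    responder_probability: Union[float, Mapping[str, float]] = 0.0
    responder_surface_mean: float = 30.0
    nonresponder_surface_mean: float = 0.0
    intensity_scale_by_class: Mapping[str, float] = field(
        default_factory=lambda: {INTERPHASE: 1.0, METAPHASE: 1.0}
    )
    surface_mean_cv: float = 0.25
    metaphase_fraction: float = 0.0
    background_mean: float = 20.0
    noise_sd: float = 0.0
    pixel_size_nm: float = 100.0
    condition: str = "stimulated"
    seed: int = 0

    def responder_p(self, stage_class: str) -> float:
        if isinstance(self.responder_probability, Mapping):
            return float(self.responder_probability.get(stage_class, 0.0))
        return float(self.responder_probability)

    def validate(self) -> None:
        probs = (
            list(self.responder_probability.values())
            if isinstance(self.responder_probability, Mapping)
            else [self.responder_probability]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("responder_probability must lie in [0, 1]")
        if not 0.0 <= self.metaphase_fraction <= 1.0:
            raise ValueError("metaphase_fraction must lie in [0, 1]")
        for name in (
            "membrane_ring_intensity",
            "responder_surface_mean",
            "nonresponder_surface_mean",
            "background_mean",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cluster_layout not in ("grid", "pairs"):
            raise ValueError(f"unknown cluster_layout {self.cluster_layout!r}")


@dataclass
class FluorGroundTruth:
    """Exact per-cell ground truth for a generated scene."""

    cells: pd.DataFrame                 # cell_id, stage_class, responder, ...
    polygons: dict[int, np.ndarray]     # cell_id -> (n, 2) outline, (row, col)


def _cell_centers(
    params: FluorSceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, int]]:
    """Deterministic cell placement; returns centers and image shape."""
    r_max = 1.45 * (params.cell_radius_px + 3 * params.cell_radius_sd_px)
    if params.cluster_layout == "grid":
        spacing = 2.0 * r_max + 24.0
        n_col = int(math.ceil(math.sqrt(params.n_cells)))
        n_row = int(math.ceil(params.n_cells / n_col))
        margin = r_max + 14.0
        centers = []
        for i in range(params.n_cells):
            gr, gc = divmod(i, n_col)
            jitter = rng.uniform(-3.0, 3.0, size=2)
            centers.append(
                (margin + gr * spacing + jitter[0], margin + gc * spacing + jitter[1])
            )
        shape = (
            int(math.ceil(2 * margin + (n_row - 1) * spacing)),
            int(math.ceil(2 * margin + (n_col - 1) * spacing)),
        )
        return np.array(centers), shape
    # pairs: slots of two cells whose membranes touch
    n_pairs = (params.n_cells + 1) // 2
    slot = 2.0 * (2.0 * r_max) + 30.0
    n_col = int(math.ceil(math.sqrt(n_pairs)))
    n_row = int(math.ceil(n_pairs / n_col))
    margin = 2.0 * r_max + 14.0
    centers: list[tuple[float, float]] = []
    sep = 1.8 * params.cell_radius_px
    for i in range(params.n_cells):
        pair, member = divmod(i, 2)
        gr, gc = divmod(pair, n_col)
        base = (margin + gr * slot, margin + gc * slot)
        off = (-sep / 2.0, 0.0) if member == 0 else (sep / 2.0, 0.0)
        centers.append((base[0] + off[0], base[1] + off[1]))
    shape = (
        int(math.ceil(2 * margin + (n_row - 1) * slot)),
        int(math.ceil(2 * margin + (n_col - 1) * slot)),
    )
    return np.array(centers), shape


def _window(poly: np.ndarray, shape: tuple[int, int], pad: int):
    rlo = max(int(np.floor(poly[:, 0].min())) - pad, 0)
    rhi = min(int(np.ceil(poly[:, 0].max())) + pad + 1, shape[0])
    clo = max(int(np.floor(poly[:, 1].min())) - pad, 0)
    chi = min(int(np.ceil(poly[:, 1].max())) + pad + 1, shape[1])
    return slice(rlo, rhi), slice(clo, chi), (rlo, clo)


def generate_fluorescence_scene(
    params: FluorSceneParams,
) -> tuple[MultiChannelScene, FluorGroundTruth]:
    """Render one scene and its exact ground truth.

    All randomness flows from ``params.seed``; identical parameters yield
    bit-identical pixel data.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    centers, shape = _cell_centers(params, rng)

    wga = np.zeros(shape, dtype=float)
    hoechst = np.zeros(shape, dtype=float)
    sgii = np.full(shape, params.background_mean, dtype=float)

    # deterministic class split: exact counts, shuffled order
    n_meta = int(round(params.metaphase_fraction * params.n_cells))
    classes = np.array([METAPHASE] * n_meta + [INTERPHASE] * (params.n_cells - n_meta))
    rng.shuffle(classes)

    rows = []
    polygons: dict[int, np.ndarray] = {}
    for i in range(params.n_cells):
        cid = i + 1
        stage = str(classes[i])
        radius = float(
            np.clip(
                rng.normal(params.cell_radius_px, params.cell_radius_sd_px),
                0.5 * params.cell_radius_px,
                1.5 * params.cell_radius_px,
            )
        )
        poly = star_polygon(tuple(centers[i]), radius, rng)
        if params.cluster_layout == "pairs":
            # bounded retries to keep pair members from engulfing each other
            for attempt in range(20):
                if np.all(np.abs(poly - centers[i]) < 2.05 * radius):
                    break
                poly = star_polygon(tuple(centers[i]), radius, rng)
            else:  # pragma: no cover - extremely unlikely
                raise PlacementError(
                    f"cell placement failed after bounded retries (seed={params.seed})"
                )
        polygons[cid] = poly

        pad = int(params.membrane_ring_width_px + 8)
        rsl, csl, (roff, coff) = _window(poly, shape, pad)
        local_poly = poly - np.array([roff, coff])
        wshape = (rsl.stop - rsl.start, csl.stop - csl.start)
        interior = rasterize_interior(local_poly, wshape)
        dist = boundary_distance_field(interior)
        ring = dist <= params.membrane_ring_width_px / 2.0
        np.maximum(
            wga[rsl, csl],
            np.where(ring, params.membrane_ring_intensity, 0.0),
            out=wga[rsl, csl],
        )
        fill = interior & ~ring
        np.maximum(
            wga[rsl, csl],
            np.where(fill, _INTERIOR_FILL_FRAC * params.membrane_ring_intensity, 0.0),
            out=wga[rsl, csl],
        )

        # Hoechst: interphase nucleus blob vs condensed metaphase plate
        if stage == INTERPHASE:
            stamp_gaussian(hoechst, tuple(centers[i]), 0.40 * radius, _HOECHST_AMPLITUDE)
        else:
            theta = rng.uniform(0.0, np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            rr = np.arange(rsl.start, rsl.stop, dtype=float)[:, None] - centers[i][0]
            cc = np.arange(csl.start, csl.stop, dtype=float)[None, :] - centers[i][1]
            along = rr * u[0] + cc * u[1]
            perp = -rr * u[1] + cc * u[0]
            bar = (np.abs(along) <= 0.60 * radius) & (np.abs(perp) <= 0.15 * radius)
            np.maximum(
                hoechst[rsl, csl],
                np.where(bar, _HOECHST_AMPLITUDE, 0.0),
                out=hoechst[rsl, csl],
            )

        # SgII surface puncta
        responder = bool(rng.random() < params.responder_p(stage))
        scale_class = float(
            dict(params.intensity_scale_by_class).get(stage, 1.0)
        )
        base_mean = (
            params.responder_surface_mean * scale_class
            if responder
            else params.nonresponder_surface_mean
        )
        true_mean = 0.0
        if base_mean > 0:
            true_mean = float(
                max(
                    base_mean * (1.0 + params.surface_mean_cv * rng.standard_normal()),
                    0.1 * base_mean,
                )
            )
            band = dist <= _SURFACE_BAND_HALFWIDTH_PX
            n_puncta = max(4, int(round(perimeter(poly) * _PUNCTA_DENSITY_PER_PX)))
            pts = polyline_arclength_samples(local_poly, n_puncta, rng)
            pts = pts + _PUNCTA_OFFSET_SD_PX * rng.standard_normal(pts.shape)
            unit = np.zeros(wshape, dtype=float)
            for p in pts:
                stamp_gaussian(unit, (p[0], p[1]), _PUNCTA_SIGMA_PX, 1.0)
            band_mean = unit[band].mean() if band.any() else 0.0
            if band_mean > 0:
                sgii[rsl, csl] += (true_mean / band_mean) * unit
            else:  # pragma: no cover - band cannot be empty for a valid cell
                true_mean = 0.0

        rows.append(
            {
                "cell_id": cid,
                "stage_class": stage,
                "responder": responder,
                "true_surface_mean_au": true_mean,
                "center_row": float(centers[i][0]),
                "center_col": float(centers[i][1]),
            }
        )

    if params.noise_sd > 0:
        wga += rng.normal(0.0, params.noise_sd, size=shape)
        hoechst += rng.normal(0.0, params.noise_sd, size=shape)
        sgii += rng.normal(0.0, params.noise_sd, size=shape)

    truth = FluorGroundTruth(cells=pd.DataFrame(rows), polygons=polygons)
    annotations = truth.cells[["cell_id", "stage_class", "center_row", "center_col"]].rename(
        columns={"center_row": "row", "center_col": "col"}
    )
    annotations = annotations.assign(condition=params.condition)
    scene = MultiChannelScene(
        channels={"WGA": wga, "Hoechst": hoechst, "SgII": sgii},
        pixel_size_nm=params.pixel_size_nm,
        annotations=annotations,
    )
    return scene, truth


def control_params(params: FluorSceneParams, seed_offset: int = 1) -> FluorSceneParams:
    """Matched unstimulated arm: same imaging settings, no responders."""
    return replace(
        params,
        responder_probability=0.0,
        condition="control",
        seed=params.seed + seed_offset,
    )
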