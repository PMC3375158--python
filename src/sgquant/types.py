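"""Core in-memory containers shared by the analysis stages.

Conventions
-----------
* Raster coordinates are 0-based ``(row, col)`` with the origin at the
  top-left pixel, matching numpy / scikit-image indexing.
* Physical coordinates (EM scenes, tracks) are ``(x_nm, y_nm)``.
* Calibration is carried explicitly as nm/pixel; nothing is implicitly
  rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# fluorescence scenes and segmentation results
# --------------------------------------------------------------------------

#: default nm/pixel for widefield fluorescence data; near-Nyquist sampling of
#: an optical resolution of 200-250 nm with a 100x/1.4 NA objective.
DEFAULT_PIXEL_SIZE_NM = 100.0

#: positional channel names used when a scene file carries no sidecar.
DEFAULT_CHANNEL_ORDER = ("WGA", "Hoechst", "SgII")


@dataclass
class MultiChannelScene:
    """Registered 2-D channel rasters plus physical calibration.

    ``annotations`` is an optional per-cell table with columns
    ``cell_id, stage_class, row, col, condition`` — the user-supplied
    counterpart of picking cells by their Hoechst appearance.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("scene must contain at least one channel")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in scene (have {sorted(self.channels)})"
            ) from None


@dataclass
class CellLabelMap:
    """Integer cell labels: 0 = background, k >= 1 = cell k."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


@dataclass
class BorderMask:
    """Boundary pixels of each cell split into cluster-outer and
    cluster-internal sets.

    A boundary pixel is a pixel of the label with at least one 8-neighbor
    outside the label (inner-boundary convention); it is *internal* iff one
    of those differing neighbors carries another nonzero label.
    """

    outer: dict[int, np.ndarray]      # cell_id -> (N, 2) int array of (row, col)
    internal: dict[int, np.ndarray]   # cell_id -> (M, 2)
    labels: np.ndarray                # the label raster the mask was derived from

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.outer)


@dataclass
class SurfaceMask:
    """Per-cell ribbon of pixels around the outer border.

    ``pixels[cid]`` is an (N, 2) array of (row, col); cells whose ribbon
    cannot be formed (no outer border, or truncated by the image edge) are
    listed in ``excluded`` with a reason and carry no pixel set.
    """

    pixels: dict[int, np.ndarray]
    width_each_side: int
    excluded: dict[int, str] = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.pixels)


@dataclass
class CellIntensityRecord:
    """Surface-mask densitometry for one cell."""

    cell_id: int
    stage_class: Optional[str]
    total_intensity: float
    mask_area: int
    mean_intensity: float
    corrected_mean: Optional[float] = None
    responder: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.mask_area <= 0:
            raise ValueError("mask_area must be positive")


def records_to_frame(records: Sequence[CellIntensityRecord]) -> pd.DataFrame:
    """Stable tabular view of intensity records (columns never reordered)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "stage_class": [r.stage_class for r in records],
            "total_intensity": [r.total_intensity for r in records],
            "mask_area": [r.mask_area for r in records],
            "mean_intensity": [r.mean_intensity for r in records],
            "corrected_mean": [r.corrected_mean for r in records],
            "responder": [r.responder for r in records],
        }
    )


@dataclass
class PopulationSummary:
    """Per-stage-class population statistics of the surface signal."""

    n_cells: dict[str, int]
    responder_fraction_pct: dict[str, Optional[float]]
    mean_corrected_responders: dict[str, Optional[float]]
    relative_intensity_pct: Optional[float]  # metaphase vs interphase, x100

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "responder_fraction_pct": self.responder_fraction_pct,
            "mean_corrected_responders": self.mean_corrected_responders,
            "relative_intensity_pct": self.relative_intensity_pct,
        }


# --------------------------------------------------------------------------
# EM-style granule scenes
# --------------------------------------------------------------------------


@dataclass
class GranuleScene:
    """One cell's membrane outline and granule centroids, in nm.

    ``true_cortical`` is generator ground truth (shell membership at
    placement time); it is absent for real, digitized data.
    """

    cell_id: int
    stage_class: str
    boundary: np.ndarray            # (N, 2) closed polygon, (x_nm, y_nm)
    granules: np.ndarray            # (M, 2) centroids, (x_nm, y_nm)
    true_cortical: Optional[np.ndarray] = None  # (M,) bool

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.granules = np.asarray(self.granules, dtype=float).reshape(-1, 2)
        if self.boundary.ndim != 2 or self.boundary.shape[0] < 3:
            raise ValueError("boundary must be a polygon with >= 3 vertices")


@dataclass
class ShellResult:
    cell_id: int
    stage_class: str
    n_total: int
    n_cortical: int

    @property
    def fraction(self) -> float:
        return self.n_cortical / self.n_total

    def __post_init__(self) -> None:
        if not 0 <= self.n_cortical <= self.n_total:
            raise ValueError("0 <= n_cortical <= n_total violated")


@dataclass
class GroupComparison:
    """Two-sample comparison of per-cell cortical percentages."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    welch: bool = False
    zero_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_a": self.mean_a, "sd_a": self.sd_a, "n_a": self.n_a,
            "mean_b": self.mean_b, "sd_b": self.sd_b, "n_b": self.n_b,
            "t": self.t, "df": self.df, "p": self.p,
            "welch": self.welch, "zero_variance": self.zero_variance,
        }


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------


@dataclass
class Detection:
    frame_index: int
    position: tuple[float, float]   # (row, col), subpixel
    intensity: float


@dataclass
class Track:
    """Time-ordered detections on strictly consecutive frames."""

    track_id: int
    detections: list[Detection]
    pixel_size_nm: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if len(self.detections) < 2:
            raise ValueError("a track needs >= 2 detections")
        frames = [d.frame_index for d in self.detections]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly consecutive")
        if self.frame_interval_s <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("calibration must be positive")

    @property
    def positions_px(self) -> np.ndarray:
        return np.array([d.position for d in self.detections], dtype=float)


@dataclass
class TrackSummary:
    track_id: int
    n_detections: int
    path_length_um: float
    net_displacement_um: float
    straightness: float
    duration_s: float
    mean_velocity_um_s: float
    directed: bool
    mt_coloc_fraction: Optional[float] = None


def summaries_to_frame(summaries: Sequence[TrackSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": [s.track_id for s in summaries],
            "n_detections": [s.n_detections for s in summaries],
            "path_length_um": [s.path_length_um for s in summaries],
            "net_displacement_um": [s.net_displacement_um for s in summaries],
            "straightness": [s.straightness for s in summaries],
            "duration_s": [s.duration_s for s in summaries],
            "mean_velocity_um_s": [s.mean_velocity_um_s for s in summaries],
            "directed": [s.directed for s in summaries],
            "mt_coloc_fraction": [s.mt_coloc_fraction for s in summaries],
        }
    )
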