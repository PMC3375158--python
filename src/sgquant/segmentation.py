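"""Cell segmentation from the uniform WGA membrane stain.

The membrane stain forms bright closed ridges around each cell; cells are
recovered by a marker-controlled watershed on the smoothed membrane image,
with the ridges acting as flooding barriers. Markers come either from
user-supplied seed points (the semi-automatic mode, one click per chosen
cell) or automatically from the connected low-intensity basins enclosed by
the ridge mask. Regions touching the image frame are treated as
background; ridge gaps therefore make a cell merge with the background or
a neighbour, which is reported as an undetected-border warning rather than
an error.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .types import BorderMask, CellLabelMap, MultiChannelScene

#: minimum region area in px^2; smaller watershed regions become background
DEFAULT_MIN_AREA_PX = 500


class UndetectedBorderWarning(UserWarning):
    """A membrane ridge expected to separate cells was not found."""


def _frame_mask(shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def segment_cells(
    scene: MultiChannelScene,
    membrane_channel: str = "WGA",
    seeds: Optional[Sequence[tuple[float, float]]] = None,
    *,
    smoothing_sigma: float = 1.5,
    ridge_threshold: Optional[float] = None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> CellLabelMap:
    """Marker-controlled watershed segmentation of the membrane channel.

    Parameters
    ----------
    seeds
        Optional per-cell ``(row, col)`` points, one per chosen cell
        (semi-automatic mode). When given, marker ``i+1`` grows from seed
        ``i`` so label identities follow seed order; two seeds ending in
        one watershed region trigger an :class:`UndetectedBorderWarning`.
    ridge_threshold
        Intensity cut separating membrane ridges from interiors on the
        smoothed image; Otsu's threshold when omitted.

    Returns an empty (all-zero) label map with a warning, not an error,
    when no ridge signal exceeds the threshold.
    """
    membrane = np.asarray(scene.channel(membrane_channel), dtype=float)
    smoothed = gaussian(membrane, sigma=smoothing_sigma, preserve_range=True)
    if ridge_threshold is None:
        ridge_threshold = float(threshold_otsu(smoothed))
    ridge = smoothed >= ridge_threshold
    provenance = {
        "membrane_channel": membrane_channel,
        "smoothing_sigma": smoothing_sigma,
        "ridge_threshold": float(ridge_threshold),
        "min_area_px": int(min_area_px),
        "mode": "seeded" if seeds is not None else "automatic",
    }
    if not ridge.any():
        warnings.warn(
            "no membrane ridge signal above threshold; returning empty segmentation",
            UndetectedBorderWarning,
        )
        return CellLabelMap(np.zeros(membrane.shape, dtype=np.int32), provenance)

    markers = np.zeros(membrane.shape, dtype=np.int32)
    background_id = 0
    if seeds is not None:
        seeds = [tuple(s) for s in seeds]
        background_id = len(seeds) + 1
        for i, (r, c) in enumerate(seeds):
            markers[int(round(r)), int(round(c))] = i + 1
        # background floods from the frame and any sub-threshold frame basin
        basins = ~ridge
        frame_basin = _frame_mask(membrane.shape) & basins
        markers[frame_basin & (markers == 0)] = background_id
        if not frame_basin.any():
            markers[0, 0] = background_id
    else:
        basins, _ = ndi.label(~ridge, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        frame_ids = np.unique(basins[_frame_mask(membrane.shape)])
        frame_ids = set(int(i) for i in frame_ids if i > 0)
        next_id = 1
        id_map: dict[int, int] = {}
        areas = np.bincount(basins.ravel())
        for bid in range(1, basins.max() + 1):
            if bid in frame_ids or areas[bid] < max(min_area_px // 4, 9):
                continue
            id_map[bid] = next_id
            next_id += 1
        background_id = next_id
        for bid, new in id_map.items():
            markers[basins == bid] = new
        frame_sel = np.isin(basins, list(frame_ids)) if frame_ids else _frame_mask(
            membrane.shape
        )
        markers[frame_sel] = background_id

    labels = watershed(smoothed, markers=markers, connectivity=1)
    labels[labels == background_id] = 0

    # drop undersized regions, then relabel contiguously in ascending order
    areas = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    for lid in range(1, labels.max() + 1):
        if 0 < areas[lid] < min_area_px:
            labels[labels == lid] = 0
    old_ids = [int(i) for i in np.unique(labels) if i > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    for new, old in enumerate(old_ids, start=1):
        remap[old] = new
    labels = remap[labels]

    # a healthy cell's final boundary runs along the ridge crest; boundary
    # segments on sub-threshold membrane indicate a ridge gap
    diff = np.zeros(labels.shape, dtype=bool)
    diff[:-1, :] |= labels[:-1, :] != labels[1:, :]
    diff[1:, :] |= labels[1:, :] != labels[:-1, :]
    diff[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    diff[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    boundary = diff & (labels > 0)
    off_ridge = boundary & (smoothed < ridge_threshold)
    n_boundary = np.bincount(labels[boundary], minlength=labels.max() + 1)
    n_off = np.bincount(labels[off_ridge], minlength=labels.max() + 1)
    for lid in range(1, labels.max() + 1):
        if n_boundary[lid] > 0 and n_off[lid] / n_boundary[lid] > 0.10:
            warnings.warn(
                f"cell {lid}: {100.0 * n_off[lid] / n_boundary[lid]:.0f}% of its "
                "boundary lies on sub-threshold membrane signal (undetected border)",
                UndetectedBorderWarning,
            )

    if seeds is not None:
        hits = {}
        for i, (r, c) in enumerate(seeds):
            lab = int(labels[int(round(r)), int(round(c))])
            if lab == 0:
                warnings.warn(
                    f"seed {i} at ({r}, {c}) fell into background: its cell border "
                    "was not detected",
                    UndetectedBorderWarning,
                )
            elif lab in hits:
                warnings.warn(
                    f"seeds {hits[lab]} and {i} share one region: the border between "
                    "them was not detected",
                    UndetectedBorderWarning,
                )
            else:
                hits[lab] = i

    return CellLabelMap(labels.astype(np.int32), provenance)


_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def classify_borders(labelmap: CellLabelMap) -> BorderMask:
    """Split each cell's boundary pixels into cluster-outer and internal.

    A boundary pixel (inner-boundary convention: a labelled pixel with at
    least one 8-neighbour outside its label) is *internal* iff one of its
    differing 8-neighbours carries another nonzero label, and *outer*
    otherwise. Pixels beyond the image frame count as background.
    """
    labels = labelmap.labels
    padded = np.pad(labels, 1, mode="constant", constant_values=0)
    any_diff = np.zeros(labels.shape, dtype=bool)
    diff_nonzero = np.zeros(labels.shape, dtype=bool)
    for dr, dc in _SHIFTS:
        neigh = padded[1 + dr : 1 + dr + labels.shape[0], 1 + dc : 1 + dc + labels.shape[1]]
        differs = neigh != labels
        any_diff |= differs
        diff_nonzero |= differs & (neigh > 0)
    fg = labels > 0
    boundary = fg & any_diff
    internal_mask = boundary & diff_nonzero
    outer_mask = boundary & ~diff_nonzero

    outer: dict[int, np.ndarray] = {}
    internal: dict[int, np.ndarray] = {}
    for cid in (int(i) for i in np.unique(labels) if i > 0):
        outer[cid] = np.argwhere(outer_mask & (labels == cid))
        internal[cid] = np.argwhere(internal_mask & (labels == cid))
    return BorderMask(outer=outer, internal=internal, labels=labels)
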