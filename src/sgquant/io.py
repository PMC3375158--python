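"""File formats: multi-page TIFF scenes with JSON sidecars, CSV tables for
granule scenes and tracks, YAML parameter snapshots."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    DEFAULT_CHANNEL_ORDER,
    DEFAULT_PIXEL_SIZE_NM,
    GranuleScene,
    MultiChannelScene,
)


class FormatError(ValueError):
    """Raised when an input file does not match its declared layout."""


def _sidecar_path(tif_path: Path) -> Path:
    return tif_path.with_suffix(".json")


def write_scene(scene: MultiChannelScene, tif_path: str | Path) -> Path:
    """Write a scene as a multi-page TIFF (one page per channel) plus a JSON
    sidecar carrying channel names, calibration and any annotations."""
    tif_path = Path(tif_path)
    names = list(scene.channels)
    stack = np.stack([np.asarray(scene.channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    sidecar = {
        "channels": names,
        "pixel_size_nm": scene.pixel_size_nm,
    }
    if scene.annotations is not None:
        sidecar["annotations"] = scene.annotations.to_dict(orient="list")
    _sidecar_path(tif_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return tif_path


def read_scene(
    tif_path: str | Path,
    *,
    default_pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> MultiChannelScene:
    """Read a multi-page TIFF scene.

    Channel names and calibration come from the sidecar when present;
    otherwise pages are named positionally (WGA, Hoechst, SgII) and the
    default calibration is used, with a warning. A sidecar declaring a
    different number of channels than the file has pages is a format
    error.
    """
    tif_path = Path(tif_path)
    stack = tifffile.imread(tif_path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"{tif_path}: expected 2-D pages, got shape {stack.shape}")
    sidecar_file = _sidecar_path(tif_path)
    annotations = None
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        names = sidecar["channels"]
        if len(names) != stack.shape[0]:
            raise FormatError(
                f"{tif_path}: sidecar declares {len(names)} channels "
                f"but the file has {stack.shape[0]} pages"
            )
        pixel_size = float(sidecar.get("pixel_size_nm", default_pixel_size_nm))
        if "pixel_size_nm" not in sidecar:
            warnings.warn(f"{tif_path}: no calibration in sidecar; using default")
        if "annotations" in sidecar:
            annotations = pd.DataFrame(sidecar["annotations"])
    else:
        names = list(DEFAULT_CHANNEL_ORDER[: stack.shape[0]])
        if stack.shape[0] > len(names):
            names += [f"ch{i}" for i in range(len(names), stack.shape[0])]
        pixel_size = default_pixel_size_nm
        warnings.warn(
            f"{tif_path}: no sidecar; positional channel names {names} and "
            f"default calibration {pixel_size} nm/px"
        )
    channels = {n: np.asarray(stack[i], dtype=float) for i, n in enumerate(names)}
    return MultiChannelScene(
        channels=channels, pixel_size_nm=pixel_size, annotations=annotations
    )


# --------------------------------------------------------------------------
# granule scenes
# --------------------------------------------------------------------------


def write_granule_scenes(
    scenes: Sequence[GranuleScene],
    boundaries_csv: str | Path,
    granules_csv: str | Path,
) -> None:
    brows, grows = [], []
    for s in scenes:
        for vi, (x, y) in enumerate(s.boundary):
            brows.append(
                {"cell_id": s.cell_id, "stage_class": s.stage_class,
                 "vertex_index": vi, "x_nm": x, "y_nm": y}
            )
        for x, y in s.granules:
            grows.append(
                {"cell_id": s.cell_id, "stage_class": s.stage_class,
                 "x_nm": x, "y_nm": y}
            )
    pd.DataFrame(brows).to_csv(boundaries_csv, index=False)
    pd.DataFrame(grows).to_csv(granules_csv, index=False)


def read_granule_scenes(
    boundaries_csv: str | Path, granules_csv: str | Path
) -> list[GranuleScene]:
    bdf = pd.read_csv(boundaries_csv)
    gdf = pd.read_csv(granules_csv)
    scenes = []
    for cid, bsub in bdf.groupby("cell_id", sort=True):
        bsub = bsub.sort_values("vertex_index")
        gsub = gdf[gdf["cell_id"] == cid]
        stage = str(bsub["stage_class"].iloc[0]) if "stage_class" in bsub else "unknown"
        scenes.append(
            GranuleScene(
                cell_id=int(cid),
                stage_class=stage,
                boundary=bsub[["x_nm", "y_nm"]].to_numpy(float),
                granules=gsub[["x_nm", "y_nm"]].to_numpy(float),
            )
        )
    return scenes


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------


def write_track_table(track_set, path: str | Path) -> None:
    """Reported track coordinates as CSV (track_id, frame, x_nm, y_nm)."""
    px = track_set.pixel_size_nm
    rows = []
    for t in track_set.tracks:
        for f, (r, c) in zip(t.frames, t.reported_positions_px):
            rows.append(
                {"track_id": t.track_id, "frame": int(f),
                 "x_nm": c * px, "y_nm": r * px}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_params_yaml(params, path: str | Path) -> None:
    from dataclasses import asdict, is_dataclass

    payload = asdict(params) if is_dataclass(params) else dict(params)
    payload = {
        k: (dict(v) if isinstance(v, (dict,)) or hasattr(v, "items") else
            list(v) if isinstance(v, tuple) else v)
        for k, v in payload.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
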