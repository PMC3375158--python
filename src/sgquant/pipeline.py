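"""End-to-end orchestration: simulate (optional) -> segment -> borders ->
surface mask -> densitometry -> background subtraction -> responder
classification -> population summary, plus the cortical and tracking
subpipelines. Every output carries the config hash; warnings are tallied
in the run log but never abort a run."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cortical as cortical_mod
from . import io as io_mod
from . import surface as surface_mod
from . import tracking as tracking_mod
from .config import RunConfig, SegmentationConfig, SurfaceConfig
from .segmentation import classify_borders, segment_cells
from .synth import presets as preset_mod
from .synth.fluor import control_params, generate_fluorescence_scene
from .synth.em import generate_em_scene
from .synth.tracks import generate_track_set, render_track_frames
from .types import (
    CellIntensityRecord,
    MultiChannelScene,
    PopulationSummary,
    records_to_frame,
    summaries_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    out_dir: Path
    files: dict[str, Path]
    config_hash: str
    n_warnings: int = 0


def _stage_map_from_annotations(
    scene: MultiChannelScene, labels: np.ndarray
) -> tuple[list[tuple[float, float]], dict[int, str]]:
    """Seed points (annotation order) and label -> stage-class mapping."""
    if scene.annotations is None:
        return [], {}
    seeds = [
        (float(row.row), float(row.col)) for row in scene.annotations.itertuples()
    ]
    stage_by_cell: dict[int, str] = {}
    for row in scene.annotations.itertuples():
        lab = int(labels[int(round(row.row)), int(round(row.col))])
        if lab > 0:
            stage_by_cell[lab] = str(row.stage_class)
    return seeds, stage_by_cell


def quantify_scene_surface(
    scene: MultiChannelScene,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    surf_cfg: SurfaceConfig = SurfaceConfig(),
) -> list[CellIntensityRecord]:
    """Segmentation through densitometry for one scene.

    Uses the scene's annotation points as watershed seeds (the
    semi-automatic mode) when present, and restricts the output to
    annotated cells so unpicked neighbours do not enter the statistics.
    """
    membrane = seg_cfg.membrane_channel
    if scene.annotations is not None:
        seeds = [(float(r.row), float(r.col)) for r in scene.annotations.itertuples()]
    else:
        seeds = None
    labelmap = segment_cells(
        scene,
        membrane,
        seeds,
        smoothing_sigma=seg_cfg.smoothing_sigma,
        ridge_threshold=seg_cfg.ridge_threshold,
        min_area_px=seg_cfg.min_area_px,
    )
    _, stage_by_cell = _stage_map_from_annotations(scene, labelmap.labels)
    borders = classify_borders(labelmap)
    mask = surface_mod.build_surface_mask(borders, surf_cfg.width_each_side)
    records = surface_mod.measure_surface_intensity(
        scene, mask, surf_cfg.sgii_channel, stage_by_cell or None
    )
    if stage_by_cell:
        records = [r for r in records if r.cell_id in stage_by_cell]
    return records


@dataclass
class ExocytosisResult:
    records: list[CellIntensityRecord]
    fractions: dict[str, Optional[float]]
    summary: PopulationSummary
    background: float


def run_exocytosis(
    stimulated: MultiChannelScene,
    control: MultiChannelScene,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    surf_cfg: SurfaceConfig = SurfaceConfig(),
) -> ExocytosisResult:
    """The full surface-exocytosis quantification on a stimulated scene
    with a matched unstimulated control."""
    stim_records = quantify_scene_surface(stimulated, seg_cfg, surf_cfg)
    ctrl_records = quantify_scene_surface(control, seg_cfg, surf_cfg)
    corrected, background = surface_mod.subtract_background(stim_records, ctrl_records)
    flagged, fractions = surface_mod.classify_responders(corrected)
    summary = surface_mod.summarize_population(flagged)
    return ExocytosisResult(
        records=flagged, fractions=fractions, summary=summary, background=background
    )


# --------------------------------------------------------------------------
# result bundle plumbing
# --------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def _write_json(payload: dict, path: Path, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the pipeline selected by the config's simulate block (or
    input files) and write a reproducible result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    files: dict[str, Path] = {}
    caught: list[warnings.WarningMessage] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if config.simulate is not None:
            kind = config.simulate.kind
        elif "boundaries" in config.inputs:
            kind = "em"
        elif "scene" in config.inputs:
            kind = "fluor"
        else:
            raise ValueError("config selects no pipeline (no simulate block or inputs)")

        if kind == "fluor":
            if config.simulate is not None:
                over = dict(config.simulate.overrides)
                over.setdefault("seed", config.seed)
                params = preset_mod.get(config.simulate.preset or "fluor_stimulated", **over)
                stim, _ = generate_fluorescence_scene(params)
                ctrl, _ = generate_fluorescence_scene(control_params(params))
            else:
                stim = io_mod.read_scene(config.inputs["scene"])
                ctrl = io_mod.read_scene(config.inputs["control"])
            res = run_exocytosis(stim, ctrl, config.segmentation, config.surface)
            cells = out / "cells.csv"
            _write_csv(records_to_frame(res.records), cells, chash)
            files["cells"] = cells
            pop = out / "population.json"
            _write_json(
                {"background": res.background, **res.summary.to_dict()}, pop, chash
            )
            files["population"] = pop

        elif kind == "em":
            if config.simulate is not None:
                over = dict(config.simulate.overrides)
                over.setdefault("seed", config.seed)
                params = preset_mod.get(config.simulate.preset or "em_interphase", **over)
                scenes = generate_em_scene(params)
            else:
                scenes = io_mod.read_granule_scenes(
                    config.inputs["boundaries"], config.inputs["granules"]
                )
            results = [
                cortical_mod.cortical_fraction(s, config.cortical.shell_thickness_nm)
                for s in scenes
            ]
            df = pd.DataFrame(
                {
                    "cell_id": [r.cell_id for r in results],
                    "stage_class": [r.stage_class for r in results],
                    "n_total": [r.n_total for r in results],
                    "n_cortical": [r.n_cortical for r in results],
                    "fraction": [r.fraction for r in results],
                }
            )
            shell = out / "shell_results.csv"
            _write_csv(df, shell, chash)
            files["shell_results"] = shell
            classes = sorted(df["stage_class"].unique())
            if len(classes) == 2:
                ga = [r for r in results if r.stage_class == classes[0]]
                gb = [r for r in results if r.stage_class == classes[1]]
                comp = cortical_mod.compare_groups(ga, gb, welch=config.cortical.welch)
                cpath = out / "comparison.json"
                _write_json(
                    {"group_a": classes[0], "group_b": classes[1], **comp.to_dict()},
                    cpath,
                    chash,
                )
                files["comparison"] = cpath

        elif kind == "tracks":
            over = dict(config.simulate.overrides) if config.simulate else {}
            over.setdefault("seed", config.seed)
            preset = (config.simulate.preset if config.simulate else None) or "tracks_anaphase"
            params = preset_mod.get(preset, **over)
            track_set, skeleton, truth = generate_track_set(params)
            movie = render_track_frames(track_set, params.field_shape_px)
            tcfg = config.tracking
            dets = [
                tracking_mod.detect_puncta(frame, tcfg.sigma_px, tcfg.threshold)
                for frame in movie
            ]
            tracks = tracking_mod.link_tracks(
                dets,
                tcfg.max_disp_px,
                pixel_size_nm=params.pixel_size_nm,
                frame_interval_s=params.frame_interval_s,
            )
            summaries = []
            for t in tracks:
                s = tracking_mod.summarize_track(
                    t,
                    tcfg.straightness_threshold,
                    min_directed_detections=tcfg.min_directed_detections,
                )
                s.mt_coloc_fraction = tracking_mod.mt_colocalization(
                    t, skeleton, tcfg.coloc_radius_px
                )
                summaries.append(s)
            tpath = out / "track_summaries.csv"
            _write_csv(summaries_to_frame(summaries), tpath, chash)
            files["track_summaries"] = tpath
            gpath = out / "track_ground_truth.csv"
            _write_csv(truth, gpath, chash)
            files["track_ground_truth"] = gpath
        else:
            raise ValueError(f"unknown pipeline kind {kind!r}")

    # config snapshot + run log
    snap = out / "config.json"
    snap.write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True, default=str))
    files["config"] = snap
    log = out / "run.log"
    lines = [f"config_hash={chash}", f"seed={config.seed}", f"warnings={len(caught)}"]
    lines += [f"warning: {w.category.__name__}: {w.message}" for w in caught]
    log.write_text("\n".join(lines) + "\n")
    files["log"] = log
    return ResultBundle(out_dir=out, files=files, config_hash=chash, n_warnings=len(caught))
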