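"""Synthetic particle tracks and filament skeletons.

Directed tracks move at a constant per-track speed drawn from a Normal
distribution truncated at zero, either along a straight free path or along
one of the straight filaments of a synthetic skeleton (emulating granules
riding spindle microtubules). Non-directed tracks are isotropic Gaussian
random walks. Reported coordinates carry isotropic localization noise;
rendered movies place spots at the *true* positions so that the
detect -> link -> summarize pipeline contributes its own, and only its own,
localization error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line


@dataclass(frozen=True)
class TrackSetParams:
    n_tracks: int = 50
    speed_mean_um_s: float = 0.23
    speed_sd_um_s: float = 0.09
    frame_interval_s: float = 1.0
    n_frames: int = 15
    localization_noise_nm: float = 20.0
    fraction_directed: float = 0.7
    diffusive_step_sd_nm: float = 80.0
    on_skeleton_fraction: float = 0.7
    pixel_size_nm: float = 100.0
    field_shape_px: tuple[int, int] = (256, 256)
    n_filaments: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.speed_mean_um_s < 0 or self.speed_sd_um_s < 0:
            raise ValueError("speeds must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("fraction_directed", "on_skeleton_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.localization_noise_nm < 0 or self.diffusive_step_sd_nm < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class SimulatedTrack:
    track_id: int
    frames: np.ndarray                  # (T,) consecutive frame indices
    true_positions_px: np.ndarray       # (T, 2) (row, col)
    reported_positions_px: np.ndarray   # true + localization noise


@dataclass
class TrackSet:
    tracks: list[SimulatedTrack]
    pixel_size_nm: float
    frame_interval_s: float


def _clip_ray(center: np.ndarray, u: np.ndarray, shape, margin: float = 3.0):
    """Parameter interval of the line ``center + t*u`` inside the raster."""
    tmin, tmax = -np.inf, np.inf
    for k in (0, 1):
        if abs(u[k]) < 1e-12:
            continue
        t0 = (margin - center[k]) / u[k]
        t1 = (shape[k] - 1 - margin - center[k]) / u[k]
        lo, hi = min(t0, t1), max(t0, t1)
        tmin, tmax = max(tmin, lo), min(tmax, hi)
    return tmin, tmax


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    return 0.0  # pragma: no cover


def generate_track_set(
    params: TrackSetParams,
) -> tuple[TrackSet, np.ndarray, pd.DataFrame]:
    """Returns (track set, boolean skeleton raster, per-track ground truth)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.field_shape_px
    px = params.pixel_size_nm

    # skeleton: straight filaments spanning the field
    skeleton = np.zeros(shape, dtype=bool)
    filaments = []
    for _ in range(params.n_filaments):
        center = np.array(
            [rng.uniform(0.2, 0.8) * shape[0], rng.uniform(0.2, 0.8) * shape[1]]
        )
        theta = rng.uniform(0.0, np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        tmin, tmax = _clip_ray(center, u, shape)
        p0 = np.round(center + tmin * u).astype(int)
        p1 = np.round(center + tmax * u).astype(int)
        rr, cc = draw_line(p0[0], p0[1], p1[0], p1[1])
        skeleton[rr, cc] = True
        filaments.append((center, u, tmin, tmax))

    frames = np.arange(params.n_frames)
    dt = params.frame_interval_s
    tracks: list[SimulatedTrack] = []
    rows = []
    for tid in range(1, params.n_tracks + 1):
        directed = bool(rng.random() < params.fraction_directed)
        on_skel = False
        speed = 0.0
        if directed:
            speed = _truncated_normal(
                params.speed_mean_um_s, params.speed_sd_um_s, rng
            )
            step_px = speed * 1000.0 / px * dt
            path_px = step_px * (params.n_frames - 1)
            on_skel = bool(rng.random() < params.on_skeleton_fraction)
            pos = None
            if on_skel and filaments:
                order = rng.permutation(len(filaments))
                for j in order:
                    center, u, tmin, tmax = filaments[j]
                    if tmax - tmin < path_px:
                        continue
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    lo = tmin if sign > 0 else tmin + path_px
                    hi = tmax - path_px if sign > 0 else tmax
                    t0 = rng.uniform(lo, hi)
                    pos = center + (t0 + sign * step_px * frames)[:, None] * u
                    break
                if pos is None:
                    on_skel = False
            if pos is None:
                for _ in range(100):
                    theta = rng.uniform(0.0, 2 * np.pi)
                    u = np.array([np.cos(theta), np.sin(theta)])
                    start = np.array(
                        [rng.uniform(5, shape[0] - 6), rng.uniform(5, shape[1] - 6)]
                    )
                    end = start + path_px * u
                    if (3 <= end[0] <= shape[0] - 4) and (3 <= end[1] <= shape[1] - 4):
                        break
                else:  # pragma: no cover - only for pathological speeds
                    start = np.array([shape[0] / 2.0, shape[1] / 2.0])
                    u = np.array([0.0, 1.0])
                pos = start + (step_px * frames)[:, None] * u
        else:
            start = np.array(
                [rng.uniform(20, shape[0] - 21), rng.uniform(20, shape[1] - 21)]
            )
            steps = rng.normal(
                0.0, params.diffusive_step_sd_nm / px, size=(params.n_frames - 1, 2)
            )
            pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            pos[:, 0] = np.clip(pos[:, 0], 2, shape[0] - 3)
            pos[:, 1] = np.clip(pos[:, 1], 2, shape[1] - 3)

        noise = (
            rng.normal(0.0, params.localization_noise_nm / px, size=pos.shape)
            if params.localization_noise_nm > 0
            else np.zeros_like(pos)
        )
        tracks.append(
            SimulatedTrack(
                track_id=tid,
                frames=frames.copy(),
                true_positions_px=pos,
                reported_positions_px=pos + noise,
            )
        )
        rows.append(
            {
                "track_id": tid,
                "directed": directed,
                "on_skeleton": on_skel,
                "true_speed_um_s": speed,
            }
        )

    truth = pd.DataFrame(rows)
    return (
        TrackSet(tracks=tracks, pixel_size_nm=px, frame_interval_s=dt),
        skeleton,
        truth,
    )


def render_track_frames(
    track_set: TrackSet,
    shape: tuple[int, int],
    *,
    spot_sigma_px: float = 1.3,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a (T, H, W) movie with a Gaussian spot per track per frame."""
    from ._geometry import stamp_gaussian

    n_frames = max(int(t.frames.max()) for t in track_set.tracks) + 1
    movie = np.full((n_frames,) + tuple(shape), background, dtype=float)
    for t in track_set.tracks:
        for f, p in zip(t.frames, t.true_positions_px):
            stamp_gaussian(movie[int(f)], (p[0], p[1]), spot_sigma_px, amplitude)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        movie += rng.normal(0.0, noise_sd, size=movie.shape)
    return movie
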