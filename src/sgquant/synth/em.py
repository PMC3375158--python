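"""Synthetic EM-style granule scenes: a smooth membrane outline per cell
plus dense-core granule centroids with a controllable cortical fraction.

A granule is placed, independently, *inside the cortical shell* (within
``shell_thickness_nm`` of the membrane) with probability
``cortical_probability`` and otherwise uniformly over the deep interior
(strictly farther than the shell from the membrane). The measured shell
fraction of a scene is therefore a binomial draw around
``cortical_probability``, which is what the recovery tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import Polygon

from ..types import GranuleScene
from ._geometry import star_polygon


@dataclass(frozen=True)
class EMSceneParams:
    n_cells: int = 20
    granules_per_cell: int = 75
    granules_total: Optional[int] = None   # exact-total fixture mode
    cortical_probability: float = 0.5
    shell_thickness_nm: float = 500.0
    cell_radius_nm: float = 5000.0
    pixel_size_nm: float = 10.0
    stage_class: str = "interphase"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.cortical_probability <= 1.0:
            raise ValueError("cortical_probability must lie in [0, 1]")
        if self.shell_thickness_nm <= 0:
            raise ValueError("shell_thickness_nm must be > 0")
        if self.shell_thickness_nm >= self.cell_radius_nm:
            raise ValueError("shell must be thinner than the cell radius")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.granules_total is None and self.granules_per_cell < 1:
            raise ValueError("granules_per_cell must be >= 1")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")


def _sample_region(
    poly: Polygon,
    n: int,
    rng: np.random.Generator,
    shell_nm: float,
    *,
    cortical: bool,
) -> np.ndarray:
    """Uniform rejection sampling in the shell or the deep interior."""
    if n == 0:
        return np.empty((0, 2))
    ring = poly.exterior
    minx, miny, maxx, maxy = poly.bounds
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        m = max(8 * need, 256)
        x = rng.uniform(minx, maxx, size=m)
        y = rng.uniform(miny, maxy, size=m)
        inside = shapely.contains_xy(poly, x, y)
        d = shapely.distance(shapely.points(x, y), ring)
        ok = inside & ((d <= shell_nm) if cortical else (d > shell_nm))
        sel = np.flatnonzero(ok)[:need]
        if sel.size:
            out.append(np.column_stack([x[sel], y[sel]]))
            need -= sel.size
    return np.vstack(out)


def generate_em_scene(params: EMSceneParams) -> list[GranuleScene]:
    """Generate ``n_cells`` granule scenes with exact ground truth.

    In exact-total mode (``granules_total`` set) the per-cell counts are a
    multinomial draw conditioned on the requested total, so the scenes sum
    to it exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    if params.granules_total is not None:
        counts = rng.multinomial(
            params.granules_total, np.full(params.n_cells, 1.0 / params.n_cells)
        )
    else:
        counts = np.full(params.n_cells, params.granules_per_cell, dtype=int)

    scenes: list[GranuleScene] = []
    for i in range(params.n_cells):
        boundary = star_polygon(
            (0.0, 0.0), params.cell_radius_nm, rng, radial_sd_frac=0.07
        )
        poly = Polygon(boundary)
        n_gran = int(counts[i])
        in_shell = rng.random(n_gran) < params.cortical_probability
        pts = np.empty((n_gran, 2))
        pts[in_shell] = _sample_region(
            poly, int(in_shell.sum()), rng, params.shell_thickness_nm, cortical=True
        )
        pts[~in_shell] = _sample_region(
            poly, int((~in_shell).sum()), rng, params.shell_thickness_nm, cortical=False
        )
        scenes.append(
            GranuleScene(
                cell_id=i + 1,
                stage_class=params.stage_class,
                boundary=boundary,
                granules=pts,
                true_cortical=in_shell,
            )
        )
    return scenes
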