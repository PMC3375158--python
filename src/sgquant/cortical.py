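"""Cortical-shell localization statistic for EM-style granule scenes.

A granule is *cortical* when the Euclidean distance from its centroid to
the membrane polygon is at most the shell thickness (500 nm by default,
the operational definition of a morphologically docked granule). Per-cell
percentages are compared between groups with a classical pooled-variance
two-sample t-test (Welch available as an option); a summary-statistic
entry path covers the case where only group means/SDs/sizes are known.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .types import GranuleScene, GroupComparison, ShellResult

DEFAULT_SHELL_THICKNESS_NM = 500.0


def granule_boundary_distances(scene: GranuleScene) -> np.ndarray:
    """Distance (nm) from each granule centroid to the membrane polygon."""
    poly = Polygon(scene.boundary)
    if not poly.is_valid:
        raise ValueError(f"cell {scene.cell_id}: boundary polygon is not simple")
    return shapely.distance(
        shapely.points(scene.granules[:, 0], scene.granules[:, 1]), poly.exterior
    )


def cortical_fraction(
    scene: GranuleScene, shell_thickness_nm: float = DEFAULT_SHELL_THICKNESS_NM
) -> ShellResult:
    """Count granules within the cortical shell of one cell.

    Granules exactly at the shell boundary count as cortical (closed
    shell). Raises on an empty granule list — the fraction is undefined.
    """
    if shell_thickness_nm <= 0:
        raise ValueError("shell_thickness_nm must be > 0")
    if len(scene.granules) == 0:
        raise ValueError(f"cell {scene.cell_id}: no granules, fraction undefined")
    d = granule_boundary_distances(scene)
    n_cortical = int(np.count_nonzero(d <= shell_thickness_nm))
    return ShellResult(
        cell_id=scene.cell_id,
        stage_class=scene.stage_class,
        n_total=len(scene.granules),
        n_cortical=n_cortical,
    )


def _pooled_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float, bool]:
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0.0:
        return (0.0 if m1 == m2 else math.inf * math.copysign(1, m1 - m2)), df, True
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, df, False


def _welch_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float, bool]:
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0.0:
        return (0.0 if m1 == m2 else math.inf * math.copysign(1, m1 - m2)), n1 + n2 - 2, True
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df, False


def compare_groups_from_stats(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    *,
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test from summary statistics (means, SDs, sizes)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 cells per group")
    tfun = _welch_t if welch else _pooled_t
    t, df, degenerate = tfun(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    if degenerate:
        # zero pooled variance: identical means -> no evidence; different
        # means -> p below the machine floor, flagged.
        p = 1.0 if t == 0.0 else float(np.nextafter(0.0, 1.0))
        t_out = 0.0 if t == 0.0 else t
    else:
        p = 2.0 * float(stats.t.sf(abs(t), df))
        t_out = t
    return GroupComparison(
        mean_a=mean_a, sd_a=sd_a, n_a=n_a,
        mean_b=mean_b, sd_b=sd_b, n_b=n_b,
        t=t_out, df=df, p=p, welch=welch, zero_variance=degenerate,
    )


def compare_groups(
    results_a: Sequence[ShellResult],
    results_b: Sequence[ShellResult],
    *,
    welch: bool = False,
) -> GroupComparison:
    """Compare per-cell cortical percentages between two groups.

    The observations are the per-cell fractions expressed in percent; the
    test is the classical pooled-variance Student's t (two-sided) unless
    ``welch`` is requested. SDs use the n-1 (sample) convention.
    """
    a = np.array([100.0 * r.fraction for r in results_a], dtype=float)
    b = np.array([100.0 * r.fraction for r in results_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 cells per group")
    return compare_groups_from_stats(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        welch=welch,
    )
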