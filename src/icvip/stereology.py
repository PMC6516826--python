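"""Design-based stereology: systematic random sampling and the optical
fractionator.

A square sampling grid with a uniformly random origin is overlaid on a
section; at the upper-left corner of every grid square that falls over the
region, a counting frame (a Z-stack of ``frame_size`` x ``frame_size``) is
collected.  Cells are counted by the top of the cell inside a central
counting slab (guard zones at the slice surfaces are discarded) with the
unbiased border rule: cells touching the right and top frame borders are
counted, those touching the left and bottom borders are not.  Labeled
fractions are reported both as the mean +/- SEM of per-frame percentages and
as pooled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon, box
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigurationError, InsufficientDataError

DEFAULT_GRID_SPACING = 370.0   # um
DEFAULT_FRAME_SIZE = 184.0     # um
DEFAULT_COUNTING_DEPTH = 15.0  # um
MIN_GUARD = 2.0                # um


@dataclass
class SamplingGrid:
    spacing: float = DEFAULT_GRID_SPACING
    origin: tuple = (0.0, 0.0)
    frame_size: float = DEFAULT_FRAME_SIZE

    def __post_init__(self) -> None:
        if not (0.0 < self.frame_size <= self.spacing):
            raise ConfigurationError("need 0 < frame_size <= spacing")
        if not all(0.0 <= o < self.spacing for o in self.origin):
            raise ConfigurationError("origin must lie in [0, spacing)^2")


@dataclass
class CountingFrame:
    site_origin: tuple            # (x, y) um, upper-left grid intersection
    z_top: float                  # um, upper slice surface
    z_bottom: float               # um, lower slice surface (z_top > z_bottom)
    frame_size: float = DEFAULT_FRAME_SIZE
    guard: float = MIN_GUARD
    counting_depth: float = DEFAULT_COUNTING_DEPTH

    def __post_init__(self) -> None:
        if self.guard < MIN_GUARD:
            raise ConfigurationError(f"guard zones must be >= {MIN_GUARD} um")
        thickness = self.z_top - self.z_bottom
        if thickness < self.counting_depth + 2.0 * self.guard:
            raise ConfigurationError(
                f"slice thickness {thickness} um cannot hold a "
                f"{self.counting_depth} um counting window with "
                f"{self.guard} um guards")

    @property
    def z_window(self) -> tuple:
        zc = 0.5 * (self.z_top + self.z_bottom)
        return (zc - 0.5 * self.counting_depth, zc + 0.5 * self.counting_depth)


@dataclass
class StereoSample:
    n_total_marker: int           # NeuN-analog count
    n_labeled: int                # tdTomato-analog count
    n_double: int
    site_id: Optional[str] = None
    region: Optional[str] = None          # ICc | shell
    slice_plane: Optional[str] = None     # caudal | middle | rostral

    def __post_init__(self) -> None:
        if self.n_double > min(self.n_total_marker, self.n_labeled):
            raise ConfigurationError(
                "double-labeled count exceeds a single-channel count")


@dataclass
class FractionEstimate:
    mean_pct: float
    sem_pct: float
    n_samples: int
    pooled_counts: tuple          # (labeled-or-double, denominator)

    @property
    def pooled_pct(self) -> float:
        num, den = self.pooled_counts
        return 100.0 * num / den if den else float("nan")


@dataclass
class GradientTestReport:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame           # pairwise HSD comparisons
    group_means: dict


def _as_polygon(region_mask) -> Polygon:
    if isinstance(region_mask, Polygon):
        return region_mask
    return Polygon(np.asarray(region_mask, dtype=float))


def place_grid(region_mask, spacing: float = DEFAULT_GRID_SPACING,
               seed: Optional[int] = None,
               origin: Optional[tuple] = None) -> np.ndarray:
    """Systematic random sampling sites over a section mask.

    The grid origin is drawn uniformly in [0, spacing)^2 from ``seed`` unless
    given explicitly.  A site is the upper-left corner of a grid square, and
    is retained when that square overlaps the region with positive area.
    Returns an (n, 2) array of site coordinates (possibly empty).
    """
    poly = _as_polygon(region_mask)
    if poly.is_empty or poly.area == 0:
        return np.empty((0, 2))
    if origin is None:
        rng = np.random.default_rng(seed)
        origin = tuple(rng.uniform(0.0, spacing, size=2))
    minx, miny, maxx, maxy = poly.bounds
    i0 = int(np.floor((minx - origin[0]) / spacing)) - 1
    i1 = int(np.ceil((maxx - origin[0]) / spacing)) + 1
    j0 = int(np.floor((miny - origin[1]) / spacing)) - 1
    j1 = int(np.ceil((maxy - origin[1]) / spacing)) + 1
    sites = []
    for i in range(i0, i1 + 1):
        x = origin[0] + i * spacing
        for j in range(j0, j1 + 1):
            y = origin[1] + j * spacing
            square = box(x, y, x + spacing, y + spacing)
            inter = poly.intersection(square)
            if inter.area > 0:
                sites.append((x, y))
    return np.asarray(sites, dtype=float).reshape(-1, 2)


def count_in_frame(points: pd.DataFrame, frame: CountingFrame,
                   site_id: Optional[str] = None,
                   region: Optional[str] = None,
                   slice_plane: Optional[str] = None) -> StereoSample:
    """Optical-fractionator count of a labeled point field in one frame.

    ``points`` needs columns ``x_um, y_um, z_um, labeled`` (``z_um`` is the
    top of each cell) and optionally ``marker`` (default: all cells carry the
    pan-neuronal marker).  A cell is counted when its top lies inside the
    central counting slab and its (x, y) obeys the unbiased border rule:
    right/top borders included, left/bottom excluded.
    """
    x0, y0 = frame.site_origin
    f = frame.frame_size
    zlo, zhi = frame.z_window
    x = points["x_um"].to_numpy(dtype=float)
    y = points["y_um"].to_numpy(dtype=float)
    z = points["z_um"].to_numpy(dtype=float)
    inside = ((x > x0) & (x <= x0 + f) &
              (y > y0) & (y <= y0 + f) &
              (z >= zlo) & (z <= zhi))
    labeled = points["labeled"].to_numpy(dtype=bool)
    marker = (points["marker"].to_numpy(dtype=bool)
              if "marker" in points.columns else np.ones_like(labeled))
    return StereoSample(
        n_total_marker=int((inside & marker).sum()),
        n_labeled=int((inside & labeled).sum()),
        n_double=int((inside & labeled & marker).sum()),
        site_id=site_id, region=region, slice_plane=slice_plane)


def estimate_fraction(samples: Sequence[StereoSample],
                      grouping: Optional[str] = None,
                      denominator: str = "total",
                      ) -> Union[FractionEstimate, dict]:
    """Labeled-fraction estimate(s): per-sample percentages, mean +/- SEM,
    and pooled counts.

    ``denominator`` selects the per-sample ratio: ``"total"`` gives
    100*double/total (the labeled share of marker-positive neurons);
    ``"labeled"`` gives 100*double/labeled (the co-label share of labeled
    cells, the GAD67-style analysis).  ``grouping`` may name a
    :class:`StereoSample` attribute (e.g. ``"slice_plane"``); a dict of
    per-group estimates is then returned.
    """
    if grouping is not None:
        groups: dict = {}
        for s in samples:
            groups.setdefault(getattr(s, grouping), []).append(s)
        return {g: estimate_fraction(v, denominator=denominator)
                for g, v in groups.items()}
    if not samples:
        raise InsufficientDataError("no samples")
    pcts, num_tot, den_tot = [], 0, 0
    for s in samples:
        den = s.n_total_marker if denominator == "total" else s.n_labeled
        if den == 0:
            warnings.warn(f"sample {s.site_id!r} has zero denominator; excluded")
            continue
        pcts.append(100.0 * s.n_double / den)
        num_tot += s.n_double
        den_tot += den
    if not pcts:
        raise InsufficientDataError("all samples had zero denominators")
    mean = float(np.mean(pcts))
    sem = float(np.std(pcts, ddof=1) / np.sqrt(len(pcts))) if len(pcts) > 1 else 0.0
    return FractionEstimate(mean_pct=mean, sem_pct=sem, n_samples=len(pcts),
                            pooled_counts=(num_tot, den_tot))


def gradient_test(samples: Sequence[StereoSample],
                  grouping: str = "slice_plane",
                  denominator: str = "total") -> GradientTestReport:
    """One-way ANOVA across groups of per-sample percentages, with Tukey HSD
    pairwise comparisons (the caudal/middle/rostral gradient test)."""
    groups: dict = {}
    for s in samples:
        den = s.n_total_marker if denominator == "total" else s.n_labeled
        if den == 0:
            continue
        groups.setdefault(getattr(s, grouping), []).append(100.0 * s.n_double / den)
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups with >= 2 samples each")
    names = sorted(groups)
    arrays = [np.asarray(groups[g]) for g in names]
    f_stat, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    n = values.size
    return GradientTestReport(
        f_statistic=float(f_stat), df_between=len(names) - 1,
        df_within=n - len(names), p_value=float(p), tukey=tukey,
        group_means={g: float(np.mean(a)) for g, a in zip(names, arrays)})
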