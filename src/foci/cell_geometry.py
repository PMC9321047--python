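"""Ellipsoid volumes, conceptual-sphere fitting and periphery mapping.

Focus and cell sizes are measured as three full axis lengths; the
ellipsoid volume uses their halves as semi-axes, V = (4/3) π a b c.  The
cell membrane is summarised by a "conceptual sphere" — fitted to edge
coordinates by algebraic least squares, or built from the mean of
diameter measurements — and an aggregate's position is expressed as its
relative distance from the periphery: 0.0 on the membrane, 0.5 at the
cell centre.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .trajectory_io import CellEdgeSet

logger = logging.getLogger(__name__)


@dataclass
class EllipsoidMeasure:
    """Three measured full axis lengths (μm) and the implied volume."""

    axis_lengths: np.ndarray  # (3,) μm, full extents

    def __post_init__(self) -> None:
        self.axis_lengths = np.asarray(self.axis_lengths, dtype=float)
        if self.axis_lengths.shape != (3,):
            raise ValidationError("axis_lengths must have exactly 3 entries")
        if np.any(~np.isfinite(self.axis_lengths)) or np.any(self.axis_lengths <= 0):
            raise ValidationError("axis lengths must be finite and positive")

    @property
    def volume(self) -> float:
        """Ellipsoid volume in μm³."""
        return ellipsoid_volume(*self.axis_lengths)


@dataclass
class FittedSphere:
    """Conceptual sphere for one cell: centre, radius R and fit residual."""

    cell_id: str
    center: np.ndarray  # (3,) μm
    radius: float  # μm
    method: str  # 'least_squares_edges' or 'mean_diameter'
    rms_residual: float = 0.0  # μm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValidationError("center must be a 3-vector")
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValidationError("radius must be positive and finite")
        if self.rms_residual < 0:
            raise ValidationError("rms_residual must be nonnegative")


@dataclass
class PeripheryPosition:
    """Position of an aggregate expressed relative to the cell periphery."""

    aggregate_xyz: np.ndarray  # (3,) μm
    radial_distance: float  # μm, centre-to-aggregate
    relative_distance: float  # dimensionless in [0, 0.5]


def ellipsoid_volume(len_x: float, len_y: float, len_z: float) -> float:
    """Volume (μm³) of an ellipsoid from three measured full lengths.

    The measured lengths are full extents along each axis; the standard
    formula V = (4/3) π a b c takes semi-axes, so each length is halved.
    """
    lengths = np.array([len_x, len_y, len_z], dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValidationError(f"axis lengths must be positive; got {lengths}")
    a, b, c = lengths / 2.0
    return float(4.0 / 3.0 * np.pi * a * b * c)


def volume_ratio(focus: EllipsoidMeasure, cell: EllipsoidMeasure) -> float:
    """Focus volume divided by cell volume (dimensionless, expected < 1)."""
    ratio = focus.volume / cell.volume
    if ratio > 1:
        logger.warning(
            "volume ratio %.3f > 1: focus larger than cell suggests a "
            "measurement error",
            ratio,
        )
    return float(ratio)


def _fit_sphere_algebraic(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere: |p|^2 = 2 c.p + (R^2 - |c|^2)."""
    A = np.hstack([2.0 * points, np.ones((points.shape[0], 1))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValidationError("degenerate sphere fit (nonpositive radius)")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(points - center, axis=1) - radius
    return center, radius, float(np.sqrt(np.mean(resid**2)))


def fit_sphere(edges: CellEdgeSet, method: str = "auto") -> FittedSphere:
    """Fit the conceptual cell sphere from membrane measurements.

    ``least_squares_edges`` fits an algebraic least-squares sphere through
    the edge coordinates and needs >= 4 non-coplanar points;
    ``mean_diameter`` sets R = mean(diameters)/2 with the centre at the
    centroid of any edge points (required if no edge points exist).
    ``auto`` prefers the edge fit when >= 6 edge points are available.
    """
    if method not in ("auto", "least_squares_edges", "mean_diameter"):
        raise ValidationError(f"unknown sphere method {method!r}")
    n_pts = 0 if edges.edge_points is None else edges.edge_points.shape[0]
    if method == "auto":
        method = "least_squares_edges" if n_pts >= 6 else "mean_diameter"
        if method == "mean_diameter" and edges.diameters is None:
            # fewer than six edges but no diameters either: use what we have
            method = "least_squares_edges"
    if method == "least_squares_edges":
        if n_pts < 4:
            raise ValidationError(
                f"cell {edges.cell_id!r}: {n_pts} edge points < 4; fall "
                "back to method='mean_diameter'"
            )
        pts = edges.edge_points
        centered = pts - pts.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        if svals[2] < 1e-9 * max(svals[0], 1e-30):
            raise ValidationError(
                f"cell {edges.cell_id!r}: edge points are coplanar; fall "
                "back to method='mean_diameter'"
            )
        center, radius, rms = _fit_sphere_algebraic(pts)
        return FittedSphere(edges.cell_id, center, radius, method, rms)
    # mean_diameter
    if edges.diameters is None:
        raise ValidationError(
            f"cell {edges.cell_id!r}: mean_diameter method needs diameters"
        )
    radius = float(np.mean(edges.diameters) / 2.0)
    if edges.edge_points is not None and edges.edge_points.shape[0] > 0:
        center = edges.edge_points.mean(axis=0)
    else:
        raise ValidationError(
            f"cell {edges.cell_id!r}: mean_diameter needs edge points for "
            "the centre (none recorded)"
        )
    return FittedSphere(edges.cell_id, center, radius, "mean_diameter", 0.0)


def relative_periphery_distance(
    aggregate_xyz, sphere: FittedSphere
) -> PeripheryPosition:
    """Map an aggregate position to its relative periphery distance.

    With r the centre-to-aggregate distance and R the sphere radius, the
    relative distance is (R - r) / (2R): 0.0 on the membrane, 0.5 at the
    centre.  Aggregates outside the fitted sphere (r > R, expected
    occasionally from manual membrane coordinates) clip to 0.0 with a
    warning.
    """
    if sphere.radius <= 0:
        raise ValidationError("sphere radius must be positive")
    p = np.asarray(aggregate_xyz, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValidationError("aggregate position must be a finite 3-vector")
    r = float(np.linalg.norm(p - sphere.center))
    if r > sphere.radius * (1.0 + 1e-9):
        warnings.warn(
            f"aggregate lies {r - sphere.radius:.3g} um outside the fitted "
            "sphere; relative distance clipped to 0",
            stacklevel=2,
        )
    rel = float(np.clip((sphere.radius - r) / (2.0 * sphere.radius), 0.0, 0.5))
    return PeripheryPosition(aggregate_xyz=p, radial_distance=r, relative_distance=rel)
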