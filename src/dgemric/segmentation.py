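"""Elliptical disc segmentation into 60 sectors (5 rings x 12 wedges).

An ellipse is fitted to landmark points placed on the disc boundary
(direct least-squares conic fit with the ellipse constraint).  Pixels
inside the ellipse are assigned a ring (equal bands of normalized
elliptical radius, 1 = innermost) and a 30-degree wedge (wedge 0 centered
on the anterior midline).  Rings 1-2 form the nucleus pulposus, rings 3-5
the annulus fibrosus; anterior/posterior zones are wedge windows of the
annulus.

Conventions: pixels are 0-based (row, col) with pixel-center sampling;
planar math uses x = col, y = row; angles are degrees measured
counterclockwise (in the x-y frame) from the +x (column) axis.
Orientation is normalized to [0, 180), anterior direction to [0, 360).
Ties at ring boundaries go to the outer ring and at wedge boundaries to
the higher wedge index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import EllipseModel

from .errors import FitError, InputError

__all__ = [
    "EllipseParams",
    "SectorLabelMap",
    "RegionDefinition",
    "N_RINGS",
    "N_WEDGES",
    "fit_ellipse",
    "elliptical_coords",
    "assign_sectors",
]

N_RINGS = 5
N_WEDGES = 12
_WEDGE_DEG = 360.0 / N_WEDGES


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse parameters in pixel units.

    center: (row, col); semi_axes: (a, b) with a >= b > 0;
    orientation_deg: major-axis direction in [0, 180); anterior_deg:
    anterior midline direction in [0, 360), same angular frame.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation_deg: float
    anterior_deg: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise InputError("semi-axes must be strictly positive")
        if b > a:
            object.__setattr__(self, "semi_axes", (b, a))
            object.__setattr__(self, "orientation_deg", self.orientation_deg + 90.0)
        object.__setattr__(self, "orientation_deg", float(self.orientation_deg) % 180.0)
        object.__setattr__(self, "anterior_deg", float(self.anterior_deg) % 360.0)

    def boundary_point(self, parametric_deg: float) -> tuple[float, float]:
        """Point (row, col) at the given parametric angle on the boundary."""
        a, b = self.semi_axes
        t = np.deg2rad(parametric_deg)
        phi = np.deg2rad(self.orientation_deg)
        x = a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi)
        y = a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi)
        return (self.center[0] + y, self.center[1] + x)

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "orientation_deg": self.orientation_deg,
            "anterior_deg": self.anterior_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseParams":
        return cls(
            center=tuple(d["center"]),
            semi_axes=tuple(d["semi_axes"]),
            orientation_deg=float(d["orientation_deg"]),
            anterior_deg=float(d.get("anterior_deg", 0.0)),
        )


@dataclass(frozen=True)
class RegionDefinition:
    """Anatomical regions over the (ring, wedge) grid.

    Nucleus pulposus = rings 1-2, annulus fibrosus = rings 3-5.  Anterior
    and posterior zones are disjoint wedge windows (default 90 degrees:
    three wedges centered on the anterior/posterior midline) restricted
    to the annulus rings.
    """

    nucleus_rings: frozenset[int] = frozenset({1, 2})
    annulus_rings: frozenset[int] = frozenset({3, 4, 5})
    anterior_wedges: frozenset[int] = frozenset({11, 0, 1})
    posterior_wedges: frozenset[int] = frozenset({5, 6, 7})

    def __post_init__(self) -> None:
        if self.anterior_wedges & self.posterior_wedges:
            raise InputError("anterior and posterior wedge sets must be disjoint")
        if self.nucleus_rings | self.annulus_rings != set(range(1, N_RINGS + 1)):
            raise InputError("nucleus and annulus must cover rings 1..5")
        if self.nucleus_rings & self.annulus_rings:
            raise InputError("nucleus and annulus rings must be disjoint")


@dataclass
class SectorLabelMap:
    """Per-pixel (ring, wedge) labels; ring 0 marks background.

    ``ring`` in {0, 1..5}, ``wedge`` in {0..11} (wedge meaningful only
    where ring > 0).  ``encoded()`` packs labels as ring*100 + wedge for
    file output (0 = background).
    """

    ring: np.ndarray
    wedge: np.ndarray
    ellipse: EllipseParams

    def __post_init__(self) -> None:
        if self.ring.shape != self.wedge.shape:
            raise InputError("ring and wedge label arrays must share a shape")

    @property
    def inside(self) -> np.ndarray:
        return self.ring > 0

    def encoded(self) -> np.ndarray:
        return np.where(self.inside, self.ring * 100 + self.wedge, 0).astype(np.int32)

    @classmethod
    def from_encoded(cls, enc: np.ndarray, ellipse: EllipseParams) -> "SectorLabelMap":
        enc = np.asarray(enc)
        ring = np.where(enc > 0, enc // 100, 0).astype(np.int16)
        wedge = np.where(enc > 0, enc % 100, 0).astype(np.int16)
        return cls(ring=ring, wedge=wedge, ellipse=ellipse)


def fit_ellipse(
    points: np.ndarray,
    anterior_deg: float | None = None,
    anterior_index: int | None = None,
) -> EllipseParams:
    """Direct least-squares ellipse fit to >= 5 planar (row, col) points.

    The anterior midline direction can be given explicitly
    (``anterior_deg``) or as the index of the anterior landmark
    (``anterior_index``; the direction from the fitted center to that
    point is used).  Raises :class:`FitError` for degenerate input or a
    non-elliptical conic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError(f"points must be (n, 2), got {pts.shape}")
    if pts.shape[0] < 5:
        raise FitError(f"need at least 5 points to fit an ellipse, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise InputError("landmark coordinates must be finite")
    # collinearity check via singular values of centered points
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise FitError("landmark points are (nearly) collinear")

    xy = pts[:, ::-1]  # (x=col, y=row) for the conic fit
    model = EllipseModel.from_estimate(xy)
    if not model:
        raise FitError("direct least-squares conic fit failed (not an ellipse)")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = np.rad2deg(model.theta)
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        raise FitError("fitted conic is degenerate")

    ell = EllipseParams(
        center=(float(yc), float(xc)),
        semi_axes=(float(a), float(b)),
        orientation_deg=float(theta),
        anterior_deg=0.0,
    )
    if anterior_index is not None:
        dr = pts[anterior_index, 0] - ell.center[0]
        dc = pts[anterior_index, 1] - ell.center[1]
        anterior_deg = float(np.rad2deg(np.arctan2(dr, dc)))
    if anterior_deg is not None:
        ell = EllipseParams(
            center=ell.center,
            semi_axes=ell.semi_axes,
            orientation_deg=ell.orientation_deg,
            anterior_deg=anterior_deg,
        )
    return ell


def elliptical_coords(
    ellipse: EllipseParams,
    rows: np.ndarray | float,
    cols: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized elliptical coordinates (rho, theta_deg) of pixels.

    rho is 0 at the center and 1 on the boundary; theta is measured
    counterclockwise (x-y frame) from the anterior midline direction
    mapped into the normalized (axis-scaled) frame, in [0, 360).
    """
    a, b = ellipse.semi_axes
    phi = np.deg2rad(ellipse.orientation_deg)
    dx = np.asarray(cols, dtype=float) - ellipse.center[1]
    dy = np.asarray(rows, dtype=float) - ellipse.center[0]
    u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
    v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
    rho = np.hypot(u, v)

    alpha = np.deg2rad(ellipse.anterior_deg)
    ua = np.cos(alpha - phi) / a
    va = np.sin(alpha - phi) / b
    psi_anterior = np.arctan2(va, ua)
    theta = (np.rad2deg(np.arctan2(v, u) - psi_anterior)) % 360.0
    # a tiny negative angle wraps to 360-eps; snap it back onto 0
    theta = np.where(360.0 - theta < 1e-9, 0.0, theta)
    return rho, theta


def assign_sectors(
    ellipse: EllipseParams,
    grid_shape: tuple[int, int],
    regions: RegionDefinition | None = None,
) -> SectorLabelMap:
    """Label every pixel of a grid with its (ring, wedge) sector.

    Ring k covers normalized radii [(k-1)/5, k/5); wedge w covers
    theta in [30w - 15, 30w + 15) so wedge 0 is centered on the anterior
    midline.  Pixels with rho >= 1 are background.  Warns and returns an
    empty map if the ellipse lies entirely outside the grid.
    """
    del regions  # geometry is region-agnostic; kept for interface symmetry
    rr, cc = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
    rho, theta = elliptical_coords(ellipse, rr, cc)
    inside = rho < 1.0

    ring = np.zeros(grid_shape, dtype=np.int16)
    wedge = np.zeros(grid_shape, dtype=np.int16)
    # floor puts an exact band boundary in the outer ring; clip keeps
    # rho just below 1 in ring 5
    ring[inside] = np.minimum(np.floor(rho[inside] * N_RINGS).astype(np.int16) + 1, N_RINGS)
    wedge[inside] = (
        np.floor(((theta[inside] + _WEDGE_DEG / 2) % 360.0) / _WEDGE_DEG).astype(np.int16)
        % N_WEDGES
    )
    wedge[inside & (rho == 0.0)] = 0  # angle undefined at the center

    if not inside.any():
        warnings.warn("ellipse lies entirely outside the grid; empty label map", UserWarning)
    return SectorLabelMap(ring=ring, wedge=wedge, ellipse=ellipse)
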