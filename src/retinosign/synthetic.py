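"""Ground-truth synthetic cortices, penetration sampling, and noise models.

A synthetic cortex is a set of polygonal areas, each carrying a smooth
cortex -> visual field mapping ``(x, y) -> (r, theta)``.  The intended sign
of an area follows from the orientation (Jacobian determinant sign) of the
cortex -> hemifield-chart mapping viewed from the pial surface of a right
hemisphere.  Writing the left-hemifield chart as ``u = -r cos(theta)``,
``v = r sin(theta)`` (theta clockwise from the left horizontal meridian),
``det d(u,v)/d(x,y) = -r * det d(r,theta)/d(x,y)``, so an area is nonmirror
exactly when the determinant of the (r, theta) Jacobian is negative.

The default geography is a stack of parallel strips with alternating field
sign (a V2 / DLp / DLi / DLa / MT-like sequence): eccentricity increases
along the strips while polar angle sweeps the hemifield across each strip,
reversing direction at every border, as adjoining congruent areas require.

Electrode sampling emulates the acute experiments: penetrations in long
rows at ~0.5 mm spacing (at least 4 per mm^2), with receptive-field centers
scattered in visual-field coordinates (the measurement-noise budget is about
1 deg in r and theta) and receptive-field size growing linearly with
eccentricity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .rf_data import RFRecord, RFTable

__all__ = [
    "AffineRetinotopy",
    "SyntheticArea",
    "SyntheticCortex",
    "truth_field_sign",
    "strip_cortex",
    "conformal_patch",
    "sample_penetrations",
    "penetration_budget",
    "grid_density",
]

NONMIRROR = 1
MIRROR = -1


class AffineRetinotopy:
    """Affine cortex -> (r, theta) mapping: ``[r, theta] = A @ [x, y] + b``."""

    def __init__(self, matrix, offset):
        self.matrix = np.asarray(matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(offset, dtype=float).reshape(2)

    def __call__(self, xy) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(xy, dtype=float))
        return pts @ self.matrix.T + self.offset

    def jacobian(self, xy=None) -> np.ndarray:
        return self.matrix.copy()


@dataclass
class SyntheticArea:
    """One area: polygon, retinotopic mapping, and RF models.

    ``rf_a``/``rf_b`` give the linear RF-size model ``l = rf_a + rf_b * r``
    (deg); ``scatter_sd`` is the default per-record visual-field scatter.
    """

    polygon: Polygon
    mapping: AffineRetinotopy
    name: str = ""
    scatter_sd: float = 0.0
    rf_a: float = 2.0
    rf_b: float = 0.15

    @property
    def sign(self) -> int:
        return _sign_int(self)


def _jacobian_at(mapping, xy, h: float = 1e-5) -> np.ndarray:
    if hasattr(mapping, "jacobian"):
        return np.asarray(mapping.jacobian(xy), dtype=float)
    p = np.asarray(xy, dtype=float)
    cols = []
    for axis in range(2):
        e = np.zeros(2)
        e[axis] = h
        cols.append((mapping(p + e)[0] - mapping(p - e)[0]) / (2 * h))
    return np.column_stack(cols)


def _probe_points(poly: Polygon, n_side: int = 5) -> np.ndarray:
    x0, y0, x1, y1 = poly.bounds
    xs = np.linspace(x0, x1, n_side + 2)[1:-1]
    ys = np.linspace(y0, y1, n_side + 2)[1:-1]
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if pts.shape[0] == 0:
        rp = poly.representative_point()
        pts = np.array([[rp.x, rp.y]])
    return pts


def _sign_int(area: SyntheticArea) -> int:
    dets = [np.linalg.det(_jacobian_at(area.mapping, p))
            for p in _probe_points(area.polygon)]
    dets = np.asarray(dets)
    if np.any(np.abs(dets) < 1e-12):
        raise ValueError(f"degenerate retinotopic mapping in area "
                         f"{area.name!r}")
    signs = np.sign(dets)
    if not np.all(signs == signs[0]):
        raise ValueError(f"mapping orientation changes sign within area "
                         f"{area.name!r}")
    # det d(chart)/d(x,y) = -r * det d(r,theta)/d(x,y): nonmirror <=> det < 0
    return NONMIRROR if signs[0] < 0 else MIRROR


def truth_field_sign(area: SyntheticArea) -> str:
    """Ground-truth sign label ('nonmirror' or 'mirror') of an area, from
    the orientation of its cortex -> hemifield mapping."""
    return "nonmirror" if _sign_int(area) == NONMIRROR else "mirror"


@dataclass
class SyntheticCortex:
    """Areas tiling a cortical patch, with true sign labels and borders."""

    areas: list[SyntheticArea]
    borders: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.areas:
            raise ValueError("cortex must contain at least one area")

    @property
    def union(self) -> Polygon:
        return shapely.unary_union([a.polygon for a in self.areas])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.union.bounds

    def area_at(self, x: float, y: float) -> SyntheticArea | None:
        for area in self.areas:
            if shapely.intersects_xy(area.polygon, x, y):
                return area
        return None

    def sign_at(self, points) -> np.ndarray:
        """True sign (+1 nonmirror / -1 mirror / 0 outside) at points.

        Points on a shared border are resolved to the first containing area
        in sequence order.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(pts.shape[0], dtype=np.int8)
        remaining = np.ones(pts.shape[0], dtype=bool)
        for area in self.areas:
            hit = remaining & shapely.intersects_xy(
                area.polygon, pts[:, 0], pts[:, 1])
            out[hit] = area.sign
            remaining &= ~hit
        return out

    def sign_grid(self, origin, spacing, shape) -> np.ndarray:
        """Rasterized true-sign labels on a grid frame (ny, nx)."""
        ny, nx = shape
        xs = origin[0] + spacing * np.arange(nx)
        ys = origin[1] + spacing * np.arange(ny)
        xx, yy = np.meshgrid(xs, ys)
        return self.sign_at(
            np.column_stack([xx.ravel(), yy.ravel()])).reshape(ny, nx)

    def border_lines(self) -> list[LineString]:
        return [LineString(b) for b in self.borders]


def strip_cortex(n_strips: int = 5, strip_width: float = 2.0,
                 height: float = 8.0, r0: float = 3.0, r_slope: float = 5.0,
                 theta_span: float = 180.0, first_sign: int = NONMIRROR,
                 scatter_sd: float = 0.0, names=None,
                 seed: int = 0) -> SyntheticCortex:
    """Stack of vertical strips with alternating field sign.

    Strip ``i`` occupies ``x in [i*w, (i+1)*w]``, ``y in [0, height]``.
    Eccentricity is shared across strips (``r = r0 + r_slope * y``) and the
    polar angle sweeps ``+-theta_span/2`` across each strip, reversing
    direction at every border, so adjacent areas are congruent and of
    opposite sign.  True borders are the vertical inter-strip lines.
    """
    if n_strips < 1:
        raise ValueError("need at least one strip")
    default_names = ["V2", "DLp", "DLi", "DLa", "MT", "FSTd", "TP", "TA"]
    areas = []
    slope = theta_span / strip_width
    for i in range(n_strips):
        x_lo = i * strip_width
        poly = Polygon([(x_lo, 0), (x_lo + strip_width, 0),
                        (x_lo + strip_width, height), (x_lo, height)])
        direction = 1 if (i % 2 == 0) == (first_sign == NONMIRROR) else -1
        # theta = +-theta_span/2 at strip edges, linear across the strip
        s = direction * slope
        t_off = -s * (x_lo + strip_width / 2.0)
        mapping = AffineRetinotopy([[0.0, r_slope], [s, 0.0]], [r0, t_off])
        name = (names[i] if names else
                default_names[i % len(default_names)] + f"_{i}" * (i >= 8))
        areas.append(SyntheticArea(polygon=poly, mapping=mapping, name=name,
                                   scatter_sd=scatter_sd))
    borders = [np.array([[i * strip_width, 0.0], [i * strip_width, height]])
               for i in range(1, n_strips)]
    return SyntheticCortex(areas=areas, borders=borders, seed=seed)


def conformal_patch(size: float = 12.0, r0: float = 5.0,
                    r_slope: float = 6.0, theta_slope: float = 14.0,
                    mirror: bool = False, scatter_sd: float = 0.0,
                    seed: int = 0) -> SyntheticCortex:
    """Single square area with orthogonal, constant r/theta gradients.

    Nonmirror by default (``r`` grows with y, ``theta`` grows with x), so the
    sign angle is exactly 90 deg everywhere; ``mirror=True`` reflects the
    theta axis, giving exactly 270 deg.
    """
    poly = Polygon([(0, 0), (size, 0), (size, size), (0, size)])
    s = -theta_slope if mirror else theta_slope
    t_off = -s * size / 2.0
    mapping = AffineRetinotopy([[0.0, r_slope], [s, 0.0]], [r0, t_off])
    area = SyntheticArea(polygon=poly, mapping=mapping,
                         name="mirror" if mirror else "nonmirror",
                         scatter_sd=scatter_sd)
    return SyntheticCortex(areas=[area], seed=seed)


def _axis_points(lo: float, hi: float, spacing: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


def sample_penetrations(cortex: SyntheticCortex, row_spacing: float = 0.5,
                        within_row_spacing: float = 0.5,
                        scatter_sd: float | None = None,
                        seed: int | None = None) -> RFTable:
    """Simulate row-wise electrode penetrations over the cortex.

    Penetrations lie on a lattice (rows along x at ``row_spacing`` in y,
    ``within_row_spacing`` along each row) clipped to the cortex; each
    record's ``(r, theta)`` is the area mapping plus independent Gaussian
    scatter in visual-field degrees.  ``scatter_sd=None`` uses each area's
    own value.  Deterministic given the seed (default: the cortex's).
    """
    if row_spacing <= 0 or within_row_spacing <= 0:
        raise ValueError("spacings must be positive")
    rng = np.random.default_rng(cortex.seed if seed is None else seed)
    x0, y0, x1, y1 = cortex.bounds
    xs = _axis_points(x0, x1, within_row_spacing)
    ys = _axis_points(y0, y1, row_spacing)
    records: list[RFRecord] = []
    pen_id = 0
    for y in ys:          # one anterior-posterior row at a time
        for x in xs:
            area = cortex.area_at(x, y)
            if area is None:
                continue
            r, theta = area.mapping([x, y])[0]
            sd = area.scatter_sd if scatter_sd is None else scatter_sd
            if sd > 0:
                r += rng.normal(0.0, sd)
                theta += rng.normal(0.0, sd)
            r = max(0.0, r)
            theta = float(np.clip(theta, -100.0, 100.0))
            l = max(0.0, area.rf_a + area.rf_b * r)
            pen_id += 1
            records.append(RFRecord(x=x, y=y, r=r, theta=theta, l=l,
                                    w=0.75 * l,
                                    phi=float(rng.uniform(0.0, 180.0)),
                                    pen_id=pen_id))
    return RFTable(records=records, hemisphere="right", normalized=True)


def penetration_budget(area_mm2: float, spacing_mm: float) -> float:
    """Penetrations needed to cover ``area_mm2`` on a square lattice with
    ``spacing_mm`` between penetrations: ``area / spacing**2``.  Resolving
    areal borders over a 400 mm^2 exposure at 100 micron steps needs about
    40,000 penetrations."""
    if area_mm2 <= 0 or spacing_mm <= 0:
        raise ValueError("area and spacing must be positive")
    count = area_mm2 / spacing_mm ** 2
    if abs(count - round(count)) < 1e-6 * max(1.0, count):
        count = float(round(count))
    return count


def grid_density(spacing_mm: float) -> float:
    """Penetrations per mm^2 of a square lattice: ``1 / spacing**2`` (4 per
    mm^2 at the 500 micron spacing used in the mapping experiments)."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    return 1.0 / spacing_mm ** 2
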