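"""Visual field sign: gradient estimation, the sign angle, and shading.

For a right-hemisphere (left-hemifield) map viewed from the pial surface, the
local visual field sign is the clockwise angle ``lambda`` from the direction
of the cortical eccentricity gradient (grad r) to the direction of the polar
angle gradient (grad theta).  ``lambda`` near 90 deg (0 < lambda < pi) marks
a nonmirror-image representation of the left hemifield; near 270 deg
(pi < lambda < 2 pi) a mirror image.  ``lambda`` near 0 or pi is
indeterminate.  The angle depends only on relative receptive-field and
cortical positions, so it is invariant to rotations, translations, and
scalings of either coordinate system.

Gradients are estimated with central finite differences over ~0.5 mm to
suppress noise; cells whose gradient magnitude falls below a floor are
flagged indeterminate rather than classified (gradient estimates are
noisiest where the gradients themselves are small, e.g. near the center of
gaze).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .gridding import GridField, interpolate_at_points
from .rf_data import RFRecord, RFTable

__all__ = [
    "VectorField",
    "GradientField",
    "FieldSignMap",
    "estimate_gradients",
    "field_sign_angle",
    "classify_sign",
    "meridian_correct",
    "sign_at_points",
    "NONMIRROR",
    "MIRROR",
    "INDETERMINATE",
]

NONMIRROR = 1
MIRROR = -1
INDETERMINATE = 0

#: Cells with either gradient magnitude below this (deg/mm) are indeterminate.
DEFAULT_MIN_GRADIENT = 0.5
#: Default finite-difference step (mm), matching the 500-600 micron range.
DEFAULT_STEP = 0.5
DEFAULT_GRAY_THRESHOLD = 0.2
DEFAULT_SIGMOID_K = 2.5


@dataclass
class VectorField:
    """Per-cell 2-D vectors (components along grid x and y) on a grid frame."""

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    step: float
    origin: tuple[float, float]
    spacing: float

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class GradientField:
    """Eccentricity and polar-angle gradients (deg per mm of cortex)."""

    grad_r: VectorField
    grad_theta: VectorField

    def __post_init__(self) -> None:
        if self.grad_r.u.shape != self.grad_theta.u.shape:
            raise ValueError("gradient fields must share a grid frame")


@dataclass
class FieldSignMap:
    """Per-cell sign angle ``lam`` (radians in [0, 2 pi)), discrete class,
    and continuous sigmoidal shade in [-1, +1] (+1 saturated nonmirror,
    -1 saturated mirror, 0 indeterminate gray)."""

    lam: np.ndarray
    sign_class: np.ndarray
    shade: np.ndarray
    valid: np.ndarray
    origin: tuple[float, float]
    spacing: float
    #: cells whose gradient stencil was available (superset of ``valid``,
    #: which additionally requires gradients above the magnitude floor)
    supported: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.lam.shape

    def to_text(self, path_prefix: str) -> None:
        """Write lambda, class, and shade matrices as three text files
        sharing the grid header (``<prefix>.{lambda,class,shade}.txt``)."""
        for name, vals in (("lambda", self.lam),
                           ("class", self.sign_class.astype(float)),
                           ("shade", self.shade)):
            GridField(
                origin=self.origin, spacing=self.spacing,
                values=np.where(self.valid, vals, np.nan),
                mask=self.valid, quantity=f"fieldsign_{name}",
            ).to_text(f"{path_prefix}.{name}.txt")


def estimate_gradients(field: GridField, step: float = DEFAULT_STEP,
                       ) -> VectorField:
    """Central-difference gradient of a grid field over +-step/2.

    The half-step is rounded to a whole number of cells (at least one); cells
    whose four stencil neighbors are not all supported are excluded.  ``step``
    below the grid spacing is an error.
    """
    if step < field.spacing - 1e-12:
        raise ValueError(
            f"finite-difference step {step} mm is below grid spacing "
            f"{field.spacing} mm"
        )
    k = max(1, int(round((step / 2.0) / field.spacing)))
    h = k * field.spacing
    ny, nx = field.shape
    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    core = np.zeros((ny, nx), dtype=bool)
    core[k:ny - k, k:nx - k] = True
    m = field.mask
    ok = core.copy()
    ok[k:ny - k, k:nx - k] &= (
        m[k:ny - k, 2 * k:] & m[k:ny - k, :nx - 2 * k]
        & m[2 * k:, k:nx - k] & m[:ny - 2 * k, k:nx - k]
        & m[k:ny - k, k:nx - k]
    )
    z = field.values
    u[ok] = ((np.roll(z, -k, axis=1) - np.roll(z, k, axis=1)) / (2 * h))[ok]
    v[ok] = ((np.roll(z, -k, axis=0) - np.roll(z, k, axis=0)) / (2 * h))[ok]
    valid = ok & np.isfinite(u) & np.isfinite(v)
    u[~valid] = np.nan
    v[~valid] = np.nan
    return VectorField(u=u, v=v, valid=valid, step=2 * h, origin=field.origin,
                       spacing=field.spacing)


def _clockwise_angle(ru, rv, tu, tv):
    """Clockwise angle from (ru, rv) to (tu, tv) in [0, 2 pi), y-up view."""
    return (np.arctan2(rv, ru) - np.arctan2(tv, tu)) % (2.0 * np.pi)


def field_sign_angle(grads: GradientField,
                     min_magnitude: float = DEFAULT_MIN_GRADIENT,
                     ) -> FieldSignMap:
    """Compute the sign angle ``lambda`` per cell (class/shade left unfilled).

    Cells where either gradient magnitude is below ``min_magnitude`` (deg/mm)
    are flagged invalid (indeterminate), not errors.
    """
    gr, gt = grads.grad_r, grads.grad_theta
    supported = gr.valid & gt.valid
    valid = (
        supported
        & (gr.magnitude() >= min_magnitude)
        & (gt.magnitude() >= min_magnitude)
    )
    lam = np.full(gr.u.shape, np.nan)
    lam[valid] = _clockwise_angle(gr.u[valid], gr.v[valid],
                                  gt.u[valid], gt.v[valid])
    return FieldSignMap(
        lam=lam,
        sign_class=np.zeros(lam.shape, dtype=np.int8),
        shade=np.zeros(lam.shape),
        valid=valid,
        origin=gr.origin,
        spacing=gr.spacing,
        supported=supported,
    )


def classify_sign(fsmap: FieldSignMap,
                  gray_threshold: float = DEFAULT_GRAY_THRESHOLD,
                  sigmoid_k: float = DEFAULT_SIGMOID_K) -> FieldSignMap:
    """Fill the discrete class and the sigmoidal shade.

    ``shade = tanh(k sin(lambda)) / tanh(k)``: an odd sigmoid of sin(lambda),
    +1 for saturated nonmirror, -1 for saturated mirror, 0 near lambda = 0 or
    pi.  Cells with ``|shade| <= gray_threshold`` are indeterminate (gray).
    """
    shade = np.zeros(fsmap.lam.shape)
    s = np.sin(fsmap.lam[fsmap.valid])
    shade[fsmap.valid] = np.tanh(sigmoid_k * s) / math.tanh(sigmoid_k)
    cls = np.zeros(fsmap.lam.shape, dtype=np.int8)
    cls[fsmap.valid & (shade > gray_threshold)] = NONMIRROR
    cls[fsmap.valid & (shade < -gray_threshold)] = MIRROR
    return replace(fsmap, sign_class=cls, shade=shade)


def _circ_half_extent(rec: RFRecord) -> float:
    """Half-extent of the RF ellipse along the circumferential direction
    (deg of visual field)."""
    psi = math.radians(rec.phi - (rec.theta + 90.0))
    return math.hypot(rec.l / 2.0 * math.cos(psi),
                      rec.w / 2.0 * math.sin(psi))


def meridian_correct(table: RFTable, beta: float) -> RFTable:
    """Conservative RF-size-dependent meridian correction.

    Reversals in areas with large receptive fields occur when the RF *edge*
    (not its center) reaches a meridian, displacing apparent reversals away
    from the meridians.  This correction pushes each RF center toward the
    nearer meridian (horizontal when |theta| <= 45, else vertical) by
    ``beta`` times the RF half-extent along the push direction, expressed in
    polar-angle degrees, capped so the center never crosses the meridian.
    ``beta = 0`` is the identity.  The original study found this had
    virtually no effect on field sign border positions.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if beta == 0.0:
        return table
    out = []
    for rec in table.records:
        if rec.r <= 0.0:
            out.append(rec)
            continue
        extent = _circ_half_extent(rec)
        dtheta = beta * extent * 180.0 / (math.pi * rec.r)
        a = abs(rec.theta)
        if a <= 45.0:
            new_a = max(0.0, a - dtheta)
        elif a <= 90.0:
            new_a = min(90.0, a + dtheta)
        else:  # slight ipsilateral overshoot: pull back toward the vertical
            new_a = max(90.0, a - dtheta)
        out.append(replace(rec, theta=math.copysign(new_a, rec.theta)
                           if rec.theta != 0.0 else new_a))
    return replace(table, records=out)


def sign_at_points(data_xy, r_values, theta_values, points, *,
                   alpha: float, epsilon: float, step: float = DEFAULT_STEP,
                   axes: np.ndarray | None = None,
                   min_magnitude: float = DEFAULT_MIN_GRADIENT,
                   min_magnitude_r: float | None = None,
                   min_magnitude_theta: float | None = None,
                   gray_threshold: float = DEFAULT_GRAY_THRESHOLD,
                   sigmoid_k: float = DEFAULT_SIGMOID_K):
    """Grid-free field sign at arbitrary cortical points.

    Interpolates r and theta at the four finite-difference stencil points
    around each query and returns ``(lam, sign_class)`` arrays.  ``axes``
    (2x2, columns = stencil directions) lets the caller differentiate along a
    rotated lattice, making the rotation invariance of ``lam`` exact.  A
    mirrored dataset analyzed in the standard (right-handed, y-up pial view)
    frame reports ``2 pi - lam``, i.e. swapped classes, as mirroring a
    hemisphere must.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    frame = np.eye(2) if axes is None else np.asarray(axes, dtype=float)
    h = step / 2.0
    ex, ey = frame[:, 0], frame[:, 1]
    stencil = np.concatenate([pts + h * ex, pts - h * ex,
                              pts + h * ey, pts - h * ey])
    n = pts.shape[0]
    comps = {}
    for name, vals in (("r", r_values), ("theta", theta_values)):
        z = interpolate_at_points(data_xy, vals, stencil, alpha, epsilon)
        comps[name] = ((z[0:n] - z[n:2 * n]) / step,
                       (z[2 * n:3 * n] - z[3 * n:]) / step)
    ru, rv = comps["r"]
    tu, tv = comps["theta"]
    floor_r = min_magnitude if min_magnitude_r is None else min_magnitude_r
    floor_t = (min_magnitude if min_magnitude_theta is None
               else min_magnitude_theta)
    valid = (np.hypot(ru, rv) >= floor_r) & (np.hypot(tu, tv) >= floor_t)
    lam = np.full(n, np.nan)
    lam[valid] = _clockwise_angle(ru[valid], rv[valid], tu[valid], tv[valid])
    shade = np.zeros(n)
    shade[valid] = np.tanh(sigmoid_k * np.sin(lam[valid])) / math.tanh(sigmoid_k)
    cls = np.zeros(n, dtype=np.int8)
    cls[valid & (shade > gray_threshold)] = NONMIRROR
    cls[valid & (shade < -gray_threshold)] = MIRROR
    return lam, cls
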