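"""Receptive-field records, ASCII table I/O, and flat-chart corrections.

One responsive microelectrode penetration is digitized as seven numbers: the
cortical recording-site position ``(x, y)`` in mm, the receptive-field (RF)
center eccentricity ``r`` and polar angle ``theta`` in degrees, and the RF
ellipse length ``l``, width ``w``, and angle ``phi`` in degrees.

Angle conventions (right hemisphere, left hemifield): ``theta`` is measured
clockwise from the left horizontal meridian, so upper-quadrant RFs have
``0 < theta <= 90`` and lower-quadrant RFs have ``-90 <= theta < 0``.  A few
RF centers may sit slightly into the ipsilateral field, hence the soft bound
``|theta| <= 100``.  The ellipse angle ``phi`` follows the same clockwise
convention and is stored reduced modulo 180.

The flat hemifield chart represents radial distances from the center of gaze
faithfully (azimuthal-equidistant projection of the hemisphere of visual
space), which stretches circumferential distances by ``r_rad / sin(r_rad)``
-- no distortion at the center of gaze, and a factor of pi/2 (~1.57x) at
90 deg eccentricity.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RFRecord",
    "RFTable",
    "RFTableFormatError",
    "read_rf_table",
    "write_rf_table",
    "normalize_hemisphere",
    "flat_correction_factor",
    "flat_correct_rf",
]

_HEMISPHERES = ("left", "right", "unknown")

#: Soft bound on |theta| allowing slight ipsilateral overshoot (deg).
THETA_SOFT_BOUND = 100.0


class RFTableFormatError(ValueError):
    """Raised when an ASCII receptive-field table cannot be parsed."""


def _chart_dir(psi_deg: float) -> np.ndarray:
    """Unit vector on the flat hemifield chart at clockwise angle ``psi_deg``
    from the left horizontal meridian (chart axes: u right, v up)."""
    p = math.radians(psi_deg)
    return np.array([-math.cos(p), math.sin(p)])


@dataclass(frozen=True)
class RFRecord:
    """One responsive penetration: cortical site plus receptive field."""

    x: float
    y: float
    r: float
    theta: float
    l: float
    w: float
    phi: float
    pen_id: int | None = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "r", "theta", "l", "w", "phi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"RFRecord field {name!r} must be finite")
        if self.r < 0:
            raise ValueError(f"eccentricity r must be >= 0, got {self.r}")
        if self.w < 0 or self.l < self.w:
            raise ValueError(
                f"RF ellipse must satisfy l >= w >= 0, got l={self.l}, w={self.w}"
            )
        if abs(self.theta) > THETA_SOFT_BOUND:
            raise ValueError(
                f"|theta| must be <= {THETA_SOFT_BOUND} deg, got {self.theta}"
            )
        object.__setattr__(self, "phi", self.phi % 180.0)


@dataclass
class RFTable:
    """Ordered receptive-field records plus hemisphere/units metadata."""

    records: list[RFRecord] = field(default_factory=list)
    hemisphere: str = "right"
    normalized: bool = False
    units: tuple[str, str] = ("mm", "deg")

    def __post_init__(self) -> None:
        if self.hemisphere not in _HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {_HEMISPHERES}")
        ids = [rec.pen_id for rec in self.records if rec.pen_id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError("penetration ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def xy(self) -> np.ndarray:
        """Cortical positions as an (n, 2) array (mm)."""
        return np.array([[rec.x, rec.y] for rec in self.records]).reshape(-1, 2)

    @property
    def r(self) -> np.ndarray:
        return np.array([rec.r for rec in self.records])

    @property
    def theta(self) -> np.ndarray:
        return np.array([rec.theta for rec in self.records])


def read_rf_table(path: str | os.PathLike) -> RFTable:
    """Read a whitespace-separated ASCII receptive-field table.

    Data lines carry ``x y r theta l w phi`` (7 columns) or an extra leading
    integer penetration id (8 columns); the dialect is auto-detected from the
    first data line.  ``#``-prefixed lines are comments; ``# hemisphere:`` and
    ``# normalized:`` comments restore table metadata.
    """
    hemisphere = "right"
    normalized = False
    records: list[RFRecord] = []
    has_id: bool | None = None
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("hemisphere:"):
                    hemisphere = body.split(":", 1)[1].strip().lower()
                elif body.lower().startswith("normalized:"):
                    normalized = body.split(":", 1)[1].strip().lower() == "true"
                continue
            fields = line.split()
            if len(fields) < 7:
                raise RFTableFormatError(
                    f"{path}: line {lineno}: expected >= 7 fields, got {len(fields)}"
                )
            if has_id is None:
                has_id = len(fields) >= 8
            vals = []
            start = 1 if has_id else 0
            pen_id = None
            if has_id:
                try:
                    pen_id = int(float(fields[0]))
                except ValueError:
                    raise RFTableFormatError(
                        f"{path}: line {lineno}, column 1: bad id field {fields[0]!r}"
                    ) from None
            for col in range(start, start + 7):
                try:
                    vals.append(float(fields[col]))
                except ValueError:
                    raise RFTableFormatError(
                        f"{path}: line {lineno}, column {col + 1}: "
                        f"bad numeric field {fields[col]!r}"
                    ) from None
            x, y, r, theta, l, w, phi = vals
            try:
                records.append(
                    RFRecord(x=x, y=y, r=r, theta=theta, l=l, w=w, phi=phi,
                             pen_id=pen_id)
                )
            except ValueError as exc:
                raise RFTableFormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from None
    return RFTable(records=records, hemisphere=hemisphere, normalized=normalized)


def write_rf_table(table: RFTable, path: str | os.PathLike) -> None:
    """Write a table re-readable by :func:`read_rf_table` (9 significant
    digits, lossless for practically encountered values)."""
    has_id = any(rec.pen_id is not None for rec in table.records)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# receptive field table\n")
        fh.write(f"# hemisphere: {table.hemisphere}\n")
        fh.write(f"# normalized: {'true' if table.normalized else 'false'}\n")
        cols = "id x y r theta l w phi" if has_id else "x y r theta l w phi"
        fh.write(f"# columns: {cols} (mm mm deg deg deg deg deg)\n")
        for rec in table.records:
            nums = " ".join(
                format(v, ".9g")
                for v in (rec.x, rec.y, rec.r, rec.theta, rec.l, rec.w, rec.phi)
            )
            if has_id:
                fh.write(f"{0 if rec.pen_id is None else rec.pen_id} {nums}\n")
            else:
                fh.write(f"{nums}\n")


def normalize_hemisphere(table: RFTable) -> RFTable:
    """Mirror a left-hemisphere table into the right-hemisphere convention.

    All analysis downstream assumes a pial view of a right hemisphere with
    receptive fields in the left hemifield.  Left-hemisphere inputs are
    reflected: cortical ``x`` is negated about the map midline and receptive
    fields are reflected into the left hemifield.  Because a left-hemisphere
    table stores ``theta``/``phi`` in the mirrored (clockwise from the right
    horizontal meridian) convention, the reflection keeps ``r`` and ``theta``
    numerically unchanged and negates ``phi`` modulo 180.  Right-hemisphere
    input is returned unchanged apart from the ``normalized`` flag; an unknown
    hemisphere is an error.  The operation is idempotent.
    """
    if table.hemisphere == "unknown":
        raise ValueError("cannot normalize a table with unknown hemisphere")
    if table.normalized or table.hemisphere == "right":
        return dataclasses.replace(table, hemisphere="right", normalized=True)
    xs = [rec.x for rec in table.records]
    pivot = (min(xs) + max(xs)) if xs else 0.0
    recs = [
        replace(rec, x=pivot - rec.x, phi=(-rec.phi) % 180.0)
        for rec in table.records
    ]
    return RFTable(records=recs, hemisphere="right", normalized=True,
                   units=table.units)


def flat_correction_factor(r):
    """Circumferential stretch of the flat hemifield chart at eccentricity
    ``r`` (deg).

    The chart keeps radial distances from the center of gaze faithful, which
    forces circumferential distances to stretch by ``r_rad / sin(r_rad)``:
    1 at the center of gaze, pi/2 (~1.57) at 90 deg.  Accepts scalars or
    arrays; domain is ``0 <= r < 180``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0.0) or np.any(arr >= 180.0):
        raise ValueError("eccentricity must lie in [0, 180) deg")
    out = 1.0 / np.sinc(arr / 180.0)  # sinc(x) = sin(pi x)/(pi x)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def flat_correct_rf(rec: RFRecord) -> RFRecord:
    """Flat-correct one receptive-field ellipse onto the planar chart.

    The ellipse component circumferential to the center of gaze is stretched
    by :func:`flat_correction_factor` at the RF center's eccentricity; the
    radial component and the center ``(r, theta)`` are unchanged.  The
    stretched ellipse is refit so the returned record keeps ``l >= w``.
    """
    f = flat_correction_factor(rec.r)
    u_major = _chart_dir(rec.phi)
    u_minor = _chart_dir(rec.phi + 90.0)
    shape = np.column_stack([u_major * rec.l / 2.0, u_minor * rec.w / 2.0])
    circ = _chart_dir(rec.theta + 90.0)
    stretch = np.eye(2) + (f - 1.0) * np.outer(circ, circ)
    corrected = stretch @ shape
    u_mat, sv, _ = np.linalg.svd(corrected)
    vec = u_mat[:, 0]
    phi_new = math.degrees(math.atan2(vec[1], -vec[0])) % 180.0
    return replace(rec, l=2.0 * sv[0], w=2.0 * sv[1], phi=phi_new)
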