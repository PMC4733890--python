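"""Landmark-based deformable warp from photo frame to flatmount frame.

Penetration sites are marked on a cortex photograph, but the analysis frame
is the stained flatmount; a handful of marker lesions (8-12 per case) give
control pairs between the two.  The warp is a global affine part plus a
radially symmetric kernel term per control (Gaussian-kernel / thin-plate
spline family), which interpolates every control exactly, is smooth, and
degrades gracefully to the affine far from the controls.  With one control
the warp is a translation, with two a similarity transform, with three
non-collinear controls an exact affine.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ControlPair", "LandmarkWarp", "fit_warp", "apply_warp",
           "read_control_pairs", "write_control_pairs"]

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class ControlPair:
    """One landmark: photo-frame source and flatmount-frame target (mm)."""

    source: tuple[float, float]
    target: tuple[float, float]

    def __post_init__(self) -> None:
        for p in (self.source, self.target):
            if not all(math.isfinite(c) for c in p):
                raise ValueError("control coordinates must be finite")


def _kernel(d: np.ndarray, kind: str, bandwidth: float) -> np.ndarray:
    if kind == "gaussian":
        return np.exp(-(d / bandwidth) ** 2)
    if kind == "thin_plate":
        with np.errstate(divide="ignore", invalid="ignore"):
            k = d * d * np.log(d)
        return np.where(d > 0, k, 0.0)
    raise ValueError(f"unknown kernel {kind!r}")


@dataclass
class LandmarkWarp:
    """Fitted smooth 2-D mapping: affine part + per-control kernel terms."""

    affine: np.ndarray            # 2x2
    offset: np.ndarray            # (2,)
    centers: np.ndarray           # (n, 2) control sources
    coeffs: np.ndarray            # (n, 2) kernel coefficients
    kernel: str = "gaussian"
    bandwidth: float = 1.0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __call__(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.affine.T + self.offset
        if self.coeffs.size:
            d = np.linalg.norm(pts[:, None, :] - self.centers[None, :, :],
                               axis=-1)
            out = out + _kernel(d, self.kernel, self.bandwidth) @ self.coeffs
        return out

    def affine_only(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.affine.T + self.offset

    def jacobian(self, point, h: float = 1e-5) -> np.ndarray:
        """Finite-difference Jacobian of the warp at one point."""
        p = np.asarray(point, dtype=float)
        cols = []
        for axis in range(2):
            e = np.zeros(2)
            e[axis] = h
            cols.append((self(p + e)[0] - self(p - e)[0]) / (2 * h))
        return np.column_stack(cols)

    def jacobian_anisotropy(self, points) -> np.ndarray:
        """Per-point local distortion: ratio of Jacobian singular values
        (1 means locally shape-preserving)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(pts.shape[0])
        for i, p in enumerate(pts):
            sv = np.linalg.svd(self.jacobian(p), compute_uv=False)
            out[i] = sv[0] / sv[1]
        return out

    def to_text(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("# landmark warp\n")
            fh.write(f"# kernel: {self.kernel}\n")
            fh.write(f"# bandwidth: {self.bandwidth:.9g}\n")
            fh.write("# affine rows then offset:\n")
            for row in self.affine:
                fh.write("A " + " ".join(format(v, ".12g") for v in row) + "\n")
            fh.write("B " + " ".join(format(v, ".12g") for v in self.offset)
                     + "\n")
            fh.write("# center_x center_y coeff_x coeff_y\n")
            for c, k in zip(self.centers, self.coeffs):
                fh.write("C " + " ".join(format(v, ".12g")
                                         for v in (*c, *k)) + "\n")


def _collinear(src: np.ndarray) -> bool:
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[-1] <= _COLLINEAR_TOL * max(1.0, sv[0])


def fit_warp(pairs, kernel: str = "gaussian",
             bandwidth: float | None = None) -> LandmarkWarp:
    """Fit an interpolating landmark warp to control pairs.

    Requires at least one pair with pairwise-distinct sources.  With one or
    two pairs the warp falls back to a translation / similarity transform;
    with three non-collinear pairs it is the exact affine; with more it adds
    kernel terms so every control is still interpolated exactly.  The kernel
    bandwidth defaults to the median inter-control distance.
    """
    pairs = [p if isinstance(p, ControlPair) else ControlPair(tuple(p[0]),
                                                              tuple(p[1]))
             for p in pairs]
    if not pairs:
        raise ValueError("need at least one control pair")
    src = np.array([p.source for p in pairs], dtype=float)
    tgt = np.array([p.target for p in pairs], dtype=float)
    n = len(pairs)
    d_pair = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
    if n > 1 and np.min(d_pair[np.triu_indices(n, 1)]) <= 1e-12:
        raise ValueError("duplicate control sources")
    if bandwidth is None:
        bandwidth = float(np.median(d_pair[np.triu_indices(n, 1)])) if n > 1 \
            else 1.0

    if n == 1:
        warp = LandmarkWarp(np.eye(2), tgt[0] - src[0], src[:0],
                            np.zeros((0, 2)), kernel, bandwidth)
    elif n == 2:
        # similarity transform through both pairs, via complex ratio
        zs = src[:, 0] + 1j * src[:, 1]
        zt = tgt[:, 0] + 1j * tgt[:, 1]
        a = (zt[1] - zt[0]) / (zs[1] - zs[0])
        b = zt[0] - a * zs[0]
        aff = np.array([[a.real, -a.imag], [a.imag, a.real]])
        warp = LandmarkWarp(aff, np.array([b.real, b.imag]), src[:0],
                            np.zeros((0, 2)), kernel, bandwidth)
    else:
        if _collinear(src):
            raise ValueError("control sources are collinear; affine part "
                             "is rank deficient")
        if n == 3:
            basis = np.column_stack([src, np.ones(3)])
            sol = np.linalg.solve(basis, tgt)  # (3, 2)
            warp = LandmarkWarp(sol[:2].T, sol[2], src[:0],
                                np.zeros((0, 2)), kernel, bandwidth)
        else:
            k_mat = _kernel(d_pair, kernel, bandwidth)
            p_mat = np.column_stack([np.ones(n), src])
            sys = np.zeros((n + 3, n + 3))
            sys[:n, :n] = k_mat
            sys[:n, n:] = p_mat
            sys[n:, :n] = p_mat.T
            rhs = np.zeros((n + 3, 2))
            rhs[:n] = tgt
            sol = np.linalg.solve(sys, rhs)
            coeffs, poly = sol[:n], sol[n:]
            warp = LandmarkWarp(poly[1:].T, poly[0], src, coeffs, kernel,
                                bandwidth)
    warp.residuals = warp(src) - tgt
    return warp


def apply_warp(warp: LandmarkWarp, points) -> np.ndarray:
    """Map points from the photo frame to the flatmount frame."""
    return warp(points)


def read_control_pairs(path: str | os.PathLike) -> list[ControlPair]:
    """Read a 4-column text table: source_x source_y target_x target_y."""
    pairs = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns")
            xs, ys, xt, yt = (float(t) for t in toks[:4])
            pairs.append(ControlPair((xs, ys), (xt, yt)))
    return pairs


def write_control_pairs(pairs, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# source_x source_y target_x target_y\n")
        for p in pairs:
            fh.write(" ".join(format(v, ".9g")
                              for v in (*p.source, *p.target)) + "\n")
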