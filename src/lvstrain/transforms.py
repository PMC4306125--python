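"""Parametric deformation models for hierarchical cardiac image registration.

The hierarchical model is the sum of a global affine transformation (scale,
rotation, translation) and a local free-form deformation (FFD) defined by a
lattice of control-point displacements interpolated with cubic B-splines.
The two parts combine *additively as displacement fields*,

    T(x) = x + T_global(x) + T_local(x),

not by functional composition; for large affine components the two differ,
and the additive form is the one implemented throughout this package.

Conventions
-----------
* Points are ``(x, y)`` pairs in pixel units, 0-based, pixel centres at
  integer coordinates.  Arrays of points have shape ``(..., 2)``.
* The affine rotation matrix has first row ``(cos th, sin th)`` and second
  row ``(-sin th, cos th)``, which rotates clockwise in the usual y-down
  image convention.  This is deliberate and is not "corrected".
* Physical pixel spacing is applied only in the strain module; everything
  here is in pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffineParams",
    "FFDGrid",
    "FFDSupportError",
    "HierarchicalTransform",
    "affine_apply",
    "global_displacement",
    "bspline_basis",
    "bspline_weights",
    "ffd_displacement",
    "combined_apply",
    "combined_displacement",
]


class FFDSupportError(ValueError):
    """A point's 4x4 control-point support falls outside the lattice."""


@dataclass(frozen=True)
class AffineParams:
    """Global affine motion: isotropic scale ``k``, rotation ``theta``
    (radians, wrapped into (-pi, pi]) and translation ``(dx, dy)`` in pixels.
    """

    k: float = 1.0
    theta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.k, self.theta, self.dx, self.dy]).all():
            raise ValueError("affine parameters must be finite")
        if self.k <= 0:
            raise ValueError(f"scale factor k must be positive, got {self.k}")
        th = float(self.theta)
        th = (th + np.pi) % (2.0 * np.pi) - np.pi
        if th == -np.pi:
            th = np.pi
        object.__setattr__(self, "k", float(self.k))
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "dx", float(self.dx))
        object.__setattr__(self, "dy", float(self.dy))

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part ``k * R(theta)``."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        return self.k * np.array([[c, s], [-s, c]])

    def to_vector(self) -> np.ndarray:
        return np.array([self.k, self.theta, self.dx, self.dy])

    @classmethod
    def from_vector(cls, mu: np.ndarray) -> "AffineParams":
        k, th, dx, dy = np.asarray(mu, dtype=float)
        return cls(k=k, theta=th, dx=dx, dy=dy)

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    def inverse(self) -> "AffineParams":
        """Parameters of the exact inverse map (useful for synthesising
        targets with a known recoverable affine)."""
        inv_k = 1.0 / self.k
        inv_th = -self.theta
        c, s = np.cos(inv_th), np.sin(inv_th)
        m = inv_k * np.array([[c, s], [-s, c]])
        d = -m @ np.array([self.dx, self.dy])
        return AffineParams(k=inv_k, theta=inv_th, dx=d[0], dy=d[1])


def affine_apply(params: AffineParams, point) -> np.ndarray:
    """Apply ``x' = k R(theta) x + (dx, dy)`` to one point or an array of
    points of shape ``(..., 2)``."""
    pts = np.asarray(point, dtype=float)
    if pts.shape[-1] != 2:
        raise ValueError("points must have shape (..., 2)")
    if not np.isfinite(pts).all():
        raise ValueError("point coordinates must be finite")
    return pts @ params.matrix.T + np.array([params.dx, params.dy])


def global_displacement(params: AffineParams, point) -> np.ndarray:
    """Global displacement field: ``affine_apply(point) - point``."""
    pts = np.asarray(point, dtype=float)
    return affine_apply(params, pts) - pts


# ----------------------------------------------------------------------------
# Cubic B-spline basis
# ----------------------------------------------------------------------------

def bspline_basis(m: int, u) -> np.ndarray:
    """Cubic B-spline basis function ``B_m(u)`` for ``m`` in 0..3 and
    ``u`` in [0, 1).

    B0 = (1-u)^3/6,  B1 = (3u^3-6u^2+4)/6,
    B2 = (-3u^3+3u^2+3u+1)/6,  B3 = u^3/6.
    """
    if m not in (0, 1, 2, 3):
        raise ValueError(f"basis index m must be in 0..3, got {m}")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u >= 1):
        raise ValueError("u must lie in [0, 1)")
    if m == 0:
        out = (1.0 - u) ** 3 / 6.0
    elif m == 1:
        out = (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0
    elif m == 2:
        out = (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0
    else:
        out = u**3 / 6.0
    return out[()] if out.ndim == 0 else out


def bspline_weights(u) -> np.ndarray:
    """All four basis values stacked on a trailing axis: shape ``(..., 4)``."""
    u = np.asarray(u, dtype=float)
    return np.stack([bspline_basis(m, u) for m in range(4)], axis=-1)


# ----------------------------------------------------------------------------
# Free-form deformation lattice
# ----------------------------------------------------------------------------

@dataclass
class FFDGrid:
    """Lattice of 2-vector control-point displacements.

    Parameters
    ----------
    phi : ndarray, shape (nx, ny, 2)
        Control-point displacements in pixels; axis 0 indexes the x
        direction, axis 1 the y direction.
    delta : (float, float)
        Control-point spacing per axis, pixels.
    origin : (float, float)
        Image coordinate of control point ``phi[0, 0]``.

    A point ``x`` lies in lattice cell ``a0 = floor((x - origin)/delta)``
    with fraction ``u = (x - origin)/delta - a0``; its 4x4 support is
    control points ``a0-1 .. a0+2`` per axis (the floor/fraction rule of
    the Rueckert FFD formulation).  ``for_image`` pads the lattice by one
    ring beyond the image so every in-image pixel has full support.
    """

    phi: np.ndarray
    delta: tuple
    origin: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 3 or self.phi.shape[2] != 2:
            raise ValueError("phi must have shape (nx, ny, 2)")
        if self.phi.shape[0] < 4 or self.phi.shape[1] < 4:
            raise ValueError("lattice needs at least 4x4 control points")
        dx, dy = (float(self.delta[0]), float(self.delta[1])) if np.iterable(self.delta) \
            else (float(self.delta), float(self.delta))
        if dx <= 0 or dy <= 0:
            raise ValueError("control-point spacing must be positive")
        self.delta = (dx, dy)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple:
        return self.phi.shape[:2]

    @classmethod
    def for_image(cls, image_shape, spacing) -> "FFDGrid":
        """Zero lattice covering an ``(H, W)`` image with one padding ring,
        so all pixels ``0..W-1 x 0..H-1`` have full 4x4 support."""
        h, w = image_shape
        if np.iterable(spacing):
            dx, dy = float(spacing[0]), float(spacing[1])
        else:
            dx = dy = float(spacing)
        nx = int(np.floor((w - 1) / dx)) + 4
        ny = int(np.floor((h - 1) / dy)) + 4
        return cls(phi=np.zeros((nx, ny, 2)), delta=(dx, dy), origin=(-dx, -dy))

    def support_indices(self, point):
        """Cell indices and fractions ``(a0, b0, u, v)`` for points of shape
        ``(..., 2)``; raises :class:`FFDSupportError` if any 4x4 support
        leaves the lattice."""
        pts = np.asarray(point, dtype=float)
        relx = (pts[..., 0] - self.origin[0]) / self.delta[0]
        rely = (pts[..., 1] - self.origin[1]) / self.delta[1]
        a0 = np.floor(relx).astype(int)
        b0 = np.floor(rely).astype(int)
        nx, ny = self.shape
        bad = (a0 < 1) | (a0 > nx - 3) | (b0 < 1) | (b0 > ny - 3)
        if np.any(bad):
            n_bad = int(np.count_nonzero(bad))
            raise FFDSupportError(
                f"{n_bad} point(s) lack a full 4x4 control-point support "
                f"inside the {nx}x{ny} lattice"
            )
        return a0, b0, relx - a0, rely - b0

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "delta": list(self.delta),
            "origin": list(self.origin),
            "phi": self.phi.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FFDGrid":
        nx, ny = d["shape"]
        phi = np.asarray(d["phi"], dtype=float).reshape(nx, ny, 2)
        return cls(phi=phi, delta=tuple(d["delta"]), origin=tuple(d["origin"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FFDGrid":
        return cls.from_dict(json.loads(s))


def ffd_displacement(grid: FFDGrid, point) -> np.ndarray:
    """FFD displacement at points of shape ``(..., 2)``: the tensor-product
    B-spline sum over the 4x4 control-point support,
    ``sum_{m,n} B_m(u) B_n(v) phi[i+m, j+n]``."""
    pts = np.asarray(point, dtype=float)
    a0, b0, u, v = grid.support_indices(pts)
    wx = bspline_weights(u)                      # (..., 4)
    wy = bspline_weights(v)
    offs = np.arange(4)
    ix = (a0 - 1)[..., None] + offs              # (..., 4)
    iy = (b0 - 1)[..., None] + offs
    sub = grid.phi[ix[..., :, None], iy[..., None, :]]   # (..., 4, 4, 2)
    w = wx[..., :, None] * wy[..., None, :]              # (..., 4, 4)
    return np.einsum("...mn,...mnc->...c", w, sub)


@dataclass
class HierarchicalTransform:
    """Additive combination of the global affine and the local FFD."""

    affine: AffineParams
    grid: FFDGrid

    def apply(self, point) -> np.ndarray:
        return combined_apply(self, point)

    def displacement(self, point) -> np.ndarray:
        pts = np.asarray(point, dtype=float)
        return global_displacement(self.affine, pts) + ffd_displacement(self.grid, pts)

    def to_dict(self) -> dict:
        return {
            "affine": {"k": self.affine.k, "theta": self.affine.theta,
                       "dx": self.affine.dx, "dy": self.affine.dy},
            "grid": self.grid.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchicalTransform":
        return cls(affine=AffineParams(**d["affine"]), grid=FFDGrid.from_dict(d["grid"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "HierarchicalTransform":
        return cls.from_dict(json.loads(s))


def combined_apply(t: HierarchicalTransform, point) -> np.ndarray:
    """``T(x) = x + T_global(x) + T_local(x)`` (displacements added)."""
    pts = np.asarray(point, dtype=float)
    return pts + t.displacement(pts)


def combined_displacement(t: HierarchicalTransform, point) -> np.ndarray:
    return t.displacement(point)
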