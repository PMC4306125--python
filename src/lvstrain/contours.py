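"""Endocardial/epicardial contours: GVF snake extraction and curvature.

Contours are ordered closed point lists.  Each point carries a signed
curvature (1/pixels) that serves as the invariant feature in the
contour-matching term of the registration cost: two contour points are
compared both by position and by curvature, so points on convex and
concave stretches of the wall are not confused even when close in space.

The snake implementation is the classic two-step scheme: a gradient
vector flow (GVF) field is diffused from an edge map, then a closed
active contour with tension/rigidity internal energy is evolved
semi-implicitly in that field.  Contours may instead be supplied from
CSV files, bypassing this module entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ContourPointSet",
    "estimate_curvature",
    "smooth_closed_contour",
    "resample_contour",
    "edge_map",
    "gvf_field",
    "snake_evolve",
    "read_contours_csv",
    "write_contours_csv",
]


def _polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area; positive for counterclockwise orientation
    in a standard (x right, y up) mathematical frame."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def estimate_curvature(points, window: int = 5, closed: bool = True) -> np.ndarray:
    """Signed per-point curvature by local parabola fit.

    For every point, the ``2*window+1`` neighbouring points are rotated
    into a local frame aligned with the chord tangent and a parabola
    ``y = a x^2 + b x + c`` is fitted by least squares; the curvature is
    ``2a / (1+b^2)^{3/2}``.  For closed contours the sign is normalised
    so that circles are positive regardless of sampling orientation.

    Parameters
    ----------
    points : (N, 2) ordered contour points.
    window : half-width of the fitting window (default 5).
    closed : treat the point list as a closed polygon (wrapping windows).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2 * window + 1:
        raise ValueError(f"need at least {2*window+1} points for window={window}")
    seg = np.diff(pts, axis=0, append=pts[:1]) if closed else np.diff(pts, axis=0)
    if np.any(np.all(seg == 0.0, axis=1)):
        raise ValueError("duplicate consecutive contour points")

    offs = np.arange(-window, window + 1)
    if closed:
        idx = (np.arange(n)[:, None] + offs[None, :]) % n
    else:
        start = np.clip(np.arange(n) - window, 0, n - (2 * window + 1))
        idx = start[:, None] + np.arange(2 * window + 1)[None, :]
    win = pts[idx]                                   # (n, 2w+1, 2)
    rel = win - pts[:, None, :]
    chord = win[:, -1, :] - win[:, 0, :]
    clen = np.linalg.norm(chord, axis=1, keepdims=True)
    if np.any(clen == 0):
        raise ValueError("degenerate window chord (coincident window endpoints)")
    t = chord / clen
    nvec = np.stack([-t[:, 1], t[:, 0]], axis=1)     # left normal
    X = np.einsum("npk,nk->np", rel, t)
    Y = np.einsum("npk,nk->np", rel, nvec)
    # batched least squares via normal equations of [x^2, x, 1]
    A = np.stack([X**2, X, np.ones_like(X)], axis=-1)    # (n, 2w+1, 3)
    G = np.einsum("npi,npj->nij", A, A)
    rhs = np.einsum("npi,np->ni", A, Y)
    coef = np.linalg.solve(G, rhs[..., None])[..., 0]
    a, b = coef[:, 0], coef[:, 1]
    kappa = 2.0 * a / (1.0 + b**2) ** 1.5
    if closed and _polygon_area(pts) < 0:
        kappa = -kappa
    return kappa


def smooth_closed_contour(points, half_width: int = 3) -> np.ndarray:
    """Circular triangular-kernel smoothing of a closed contour's point
    positions; suppresses wiggles below the kernel scale while leaving
    the large-scale shape (hence its curvature) almost untouched."""
    pts = np.asarray(points, dtype=float)
    if half_width <= 0:
        return pts.copy()
    w = half_width + 1 - np.abs(np.arange(-half_width, half_width + 1))
    w = w / w.sum()
    out = np.empty_like(pts)
    for k in range(2):
        padded = np.concatenate([pts[-half_width:, k], pts[:, k],
                                 pts[:half_width, k]])
        out[:, k] = np.convolve(padded, w, mode="valid")
    return out


def resample_contour(points, n: int, closed: bool = True) -> np.ndarray:
    """Resample an ordered contour to ``n`` points at uniform arc length."""
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("contour has zero length")
    snew = np.linspace(0.0, total, n, endpoint=False) if closed else \
        np.linspace(0.0, total, n)
    x = np.interp(snew, s, pts[:, 0])
    y = np.interp(snew, s, pts[:, 1])
    return np.stack([x, y], axis=1)


@dataclass
class ContourPointSet:
    """Ordered contour with per-point curvature.

    ``label`` is ``"endo"`` or ``"epi"`` for the two myocardial borders.
    """

    points: np.ndarray
    curvatures: np.ndarray = None
    closed: bool = True
    label: str = "endo"
    curvature_window: int = 5

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (N, 2)")
        if len(self.points) < 8:
            raise ValueError("a contour needs at least 8 points")
        if self.curvatures is None:
            self.curvatures = estimate_curvature(
                self.points, window=self.curvature_window, closed=self.closed)
        else:
            self.curvatures = np.asarray(self.curvatures, dtype=float)
        if len(self.curvatures) != len(self.points):
            raise ValueError("curvature list length must equal point list length")

    def __len__(self) -> int:
        return len(self.points)

    def resampled(self, n: int) -> "ContourPointSet":
        return ContourPointSet(resample_contour(self.points, n, self.closed),
                               closed=self.closed, label=self.label,
                               curvature_window=self.curvature_window)

    def transformed(self, fn, recompute_curvature: bool = True) -> "ContourPointSet":
        """New contour with ``fn`` applied to the points; curvatures are
        recomputed by default (deformation changes curvature)."""
        new_pts = np.asarray(fn(self.points), dtype=float)
        curv = None if recompute_curvature else self.curvatures.copy()
        return ContourPointSet(new_pts, curvatures=curv, closed=self.closed,
                               label=self.label,
                               curvature_window=self.curvature_window)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


# ----------------------------------------------------------------------------
# Gradient vector flow and the active contour
# ----------------------------------------------------------------------------

def edge_map(image, sigma: float = 0.5) -> np.ndarray:
    """Gradient-magnitude edge map ``|grad(G_sigma * I)|`` for GVF.

    Light smoothing only: heavier blurring (or squaring the magnitude)
    measurably shifts the ridge of an annular edge inward and with it
    the snake's equilibrium.
    """
    sm = ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma)
    gy, gx = np.gradient(sm)
    return np.hypot(gx, gy)


def gvf_field(edge_map, mu: float = 0.2, iterations: int = 200,
              tol: float = 1e-4) -> np.ndarray:
    """Gradient vector flow field of a non-negative edge map.

    Iterates the standard GVF diffusion update
    ``u_t = mu lap(u) - (fx^2+fy^2)(u - fx)`` (and likewise for v) with a
    CFL-stable explicit step.  The result equals the edge gradient where
    the gradient is strong and diffuses smoothly into homogeneous
    regions, which is what lets the snake lock onto weak edges.

    Returns a field of shape ``(H, W, 2)`` holding ``(u, v)`` components
    along ``x`` and ``y``.
    """
    f = np.asarray(edge_map, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("edge map must be finite")
    if mu <= 0:
        raise ValueError("mu must be positive")
    gy, gx = np.gradient(f)
    mag2 = gx**2 + gy**2
    u, v = gx.copy(), gy.copy()
    dt = 0.9 / (4.0 * mu + mag2.max() + 1e-12)
    converged = False
    for _ in range(iterations):
        lu = ndimage.laplace(u, mode="nearest")
        lv = ndimage.laplace(v, mode="nearest")
        du = dt * (mu * lu - mag2 * (u - gx))
        dv = dt * (mu * lv - mag2 * (v - gy))
        u += du
        v += dv
        if max(np.abs(du).max(), np.abs(dv).max()) < tol * (np.abs(gx).max() + 1e-12):
            converged = True
            break
    if not converged and iterations > 0:
        warnings.warn("GVF diffusion did not converge within the iteration "
                      "budget; returning best iterate", RuntimeWarning)
    return np.stack([u, v], axis=-1)


def _internal_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Cyclic pentadiagonal internal-energy matrix of the closed snake."""
    row = np.zeros(n)
    row[0] = 2 * alpha + 6 * beta
    row[1] = row[-1] = -alpha - 4 * beta
    row[2] = row[-2] = beta
    a = np.empty((n, n))
    for i in range(n):
        a[i] = np.roll(row, i)
    return a


def snake_evolve(init: ContourPointSet, field: np.ndarray, alpha: float = 0.02,
                 beta: float = 0.1, gamma: float = 1.0, kappa: float = 1.0,
                 iterations: int = 100, resample_every: int = 10,
                 n_points: int | None = None, min_area: float = 4.0,
                 normalize_force: bool = True,
                 frame: int | None = None) -> ContourPointSet:
    """Semi-implicit closed active contour driven by a GVF field.

    Each step solves the pentadiagonal internal-energy system
    ``(gamma I + A) x_new = gamma x_old + kappa f_ext(x_old)`` with the
    external force interpolated from ``field``; the contour is
    periodically resampled to uniform arc length and is returned with
    ``n_points`` points (default: the input count) and fresh curvatures.
    By default the GVF vectors are normalized to unit length (the usual
    GVF-snake convention — the diffused field's direction is the signal,
    its decaying magnitude is not).

    Raises ``RuntimeError`` if the contour collapses (area < ``min_area``).
    """
    if min(alpha, beta, gamma, kappa) < 0 or gamma == 0:
        raise ValueError("snake parameters must be positive")
    if not init.closed:
        raise ValueError("snake_evolve expects a closed initial contour")
    pts = init.points.copy()
    n = len(pts)
    n_out = n_points or n
    solve = np.linalg.inv(gamma * np.eye(n) + _internal_matrix(n, alpha, beta))
    fx, fy = field[..., 0], field[..., 1]
    if normalize_force:
        mag = np.hypot(fx, fy)
        scale = np.where(mag > 1e-12 * (mag.max() + 1e-300), 1.0 / (mag + 1e-300), 0.0)
        fx, fy = fx * scale, fy * scale
    for it in range(iterations):
        ex = ndimage.map_coordinates(fx, [pts[:, 1], pts[:, 0]], order=1,
                                     mode="nearest")
        ey = ndimage.map_coordinates(fy, [pts[:, 1], pts[:, 0]], order=1,
                                     mode="nearest")
        force = kappa * np.stack([ex, ey], axis=1)
        pts = solve @ (gamma * pts + force)
        if resample_every and (it + 1) % resample_every == 0:
            pts = resample_contour(pts, n, closed=True)
        area = abs(_polygon_area(pts))
        if area < min_area:
            where = f" at frame {frame}" if frame is not None else ""
            raise RuntimeError(f"snake contour collapsed{where} "
                               f"(area {area:.2f} < {min_area})")
    pts = resample_contour(pts, n_out, closed=True)
    return ContourPointSet(pts, closed=True, label=init.label,
                           curvature_window=init.curvature_window)


# ----------------------------------------------------------------------------
# Contour CSV dialect: frame,label,point_index,x,y
# ----------------------------------------------------------------------------

def write_contours_csv(path, contours: dict) -> None:
    """Write ``{(frame, label): ContourPointSet}`` to the CSV dialect
    ``frame,label,point_index,x,y``.  Curvature is never serialized; it is
    always recomputed from the points."""
    rows = []
    for (frame, label), cset in sorted(contours.items()):
        for i, (x, y) in enumerate(cset.points):
            rows.append({"frame": frame, "label": label, "point_index": i,
                         "x": x, "y": y})
    pd.DataFrame(rows, columns=["frame", "label", "point_index", "x", "y"]) \
        .to_csv(path, index=False)


def read_contours_csv(path) -> dict:
    """Read the contour CSV dialect into ``{(frame, label): ContourPointSet}``."""
    df = pd.read_csv(path)
    required = {"frame", "label", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"contour CSV must have columns {sorted(required)}")
    out = {}
    for (frame, label), g in df.groupby(["frame", "label"]):
        g = g.sort_values("point_index")
        out[(int(frame), str(label))] = ContourPointSet(
            g[["x", "y"]].to_numpy(float), label=str(label))
    return out
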