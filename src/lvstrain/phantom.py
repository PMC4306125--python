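"""Synthetic short-axis left-ventricle phantom with analytic ground truth.

The phantom is a bright myocardial annulus between a darker blood pool
and background that contracts and thickens over a cardiac cycle.  The
programmed deformation is radial (piecewise linear in radius along each
ray, hence exactly invertible in closed form) with optional rigid
rotation and endo-to-epi twist, modulated in time by a smooth
systole-diastole activation curve.  Frames are rendered by pulling
intensities back through the *analytic inverse* of the deformation, so
the intensity motion equals the stated displacement field exactly;
Gaussian noise is added last from the stated seed.

Two departures from a perfect annulus keep the phantom honest about
what real short-axis frames look like:

* a smooth angular intensity ``texture`` on the myocardium (real frames
  are never rotationally symmetric — RV insertion, trabeculation — and a
  symmetric annulus would make rotation unobservable to any
  intensity-driven method), and
* a mild ``ellipticity`` of the endo/epicardial borders, so contour
  curvature genuinely varies along the wall (on an exact circle the
  curvature feature of the contour-matching term would carry no
  information).

Everything downstream needs a known answer — dense displacement fields,
endo/epi contours, two landmark trajectories (one at a high-deformation
site, one on a weak edge) and the closed-form Green radial strain — and
the phantom provides all of them exactly.

A ``weak_edge`` arc lowers the myocardium/background contrast locally to
reproduce the weak-edge failure mode that motivates the contour term of
the registration cost; a ``hypokinetic`` sector locally scales the
motion down to emulate regional dysfunction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .contours import ContourPointSet
from .core import CineSequence
from .registration import DisplacementField

__all__ = ["PhantomSpec", "PhantomGroundTruth", "generate",
           "analytic_radial_strain", "weak_edge_variant"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, motion, intensity and noise of the synthetic annulus.

    Radii and the deformation are in pixels at end diastole; intensities
    are arbitrary units; ``contraction`` is the peak inward endocardial
    excursion as a fraction of the inner radius and ``thickening`` the
    peak fractional wall-thickness increase.  ``rotation_deg`` /
    ``twist_deg`` add a rigid / endo-to-epi differential rotation at
    peak activation.  ``hypokinetic`` and ``weak_edge`` are
    ``(center_deg, width_deg, amount)`` sector descriptors (amount =
    motion scale in [0,1] / contrast reduction in [0,1]).

    ``ellipticity`` modulates both border radii by
    ``1 + ellipticity * cos(2 (theta - axis))``; combining it with twist
    is not supported (the closed-form inverse would be lost).
    """

    size: int = 64
    inner_radius: float = 12.0
    outer_radius: float = 20.0
    contraction: float = 0.25
    thickening: float = 0.30
    rotation_deg: float = 0.0
    twist_deg: float = 0.0
    frames: int = 16
    systole_fraction: float = 1.0 / 3.0
    intensity_cavity: float = 0.25
    intensity_myocardium: float = 0.85
    intensity_background: float = 0.10
    texture: float = 0.25
    ellipticity: float = 0.10
    ellipse_axis_deg: float = 20.0
    edge_width: float = 1.0
    noise_sigma: float = 0.01
    seed: int = 0
    hypokinetic: tuple | None = None
    weak_edge: tuple | None = None
    outer_support: float | None = None
    pixel_spacing: tuple = (1.4, 1.4)
    frame_interval: float = 50.0

    def __post_init__(self) -> None:
        ri, ro = self.inner_radius, self.outer_radius
        if not (0 < ri < ro < self.size / 2):
            raise ValueError("need 0 < inner < outer < size/2")
        if self.frames < 8:
            raise ValueError("need at least 8 frames per cycle")
        if not (0 <= self.contraction < 1):
            raise ValueError("contraction must keep the endo radius positive")
        if not (0 <= self.ellipticity < 0.5):
            raise ValueError("ellipticity must be in [0, 0.5)")
        emax = 1.0 + self.ellipticity
        rs = self.support_radius
        ro_peak = (ri * (1 - self.contraction)
                   + (ro - ri) * (1 + self.thickening)) * emax
        if not max(ro_peak, ro * emax) < rs:
            raise ValueError("peak epicardial radius exceeds the support radius")
        if self.hypokinetic is not None and (self.rotation_deg or self.twist_deg):
            raise ValueError("hypokinetic sector requires zero rotation/twist")
        if self.twist_deg and self.ellipticity:
            raise ValueError("twist requires zero ellipticity")

    @property
    def support_radius(self) -> float:
        return self.outer_support if self.outer_support is not None \
            else self.size / 2.0 - 2.0

    @property
    def center(self) -> tuple:
        c = (self.size - 1) / 2.0
        return (c, c)


def activation(spec: PhantomSpec, t):
    """Smooth systole-diastole activation in [0, 1]: raised-cosine rise
    to peak at end systole, slower cosine recovery; exactly 0 at t = 0
    and t = F (cyclic)."""
    t = np.asarray(t, dtype=float)
    f = float(spec.frames)
    ts = spec.systole_fraction * f
    rise = 0.5 * (1.0 - np.cos(np.pi * t / ts))
    fall = 0.5 * (1.0 + np.cos(np.pi * (t - ts) / (f - ts)))
    return np.where(t <= ts, rise, fall)[()]


def _sector_window(theta, center_deg: float, width_deg: float,
                   transition_deg: float = 15.0):
    """Flat-top angular window: exactly 1 across the stated sector width,
    cosine taper to 0 over ``transition_deg`` on either side (the whole
    sector is affected, not just its centre line)."""
    d = np.abs(np.angle(np.exp(1j * (theta - np.deg2rad(center_deg)))))
    half = np.deg2rad(width_deg) / 2.0
    trans = np.deg2rad(transition_deg)
    taper = 0.5 * (1.0 + np.cos(np.pi * (d - half) / trans))
    return np.select([d <= half, d <= half + trans], [1.0, taper], default=0.0)


def _activation_at(spec: PhantomSpec, t, theta):
    """Per-angle effective activation (hypokinetic sector scales it)."""
    a = activation(spec, t)
    if spec.hypokinetic is None:
        return a * np.ones_like(np.asarray(theta, dtype=float))
    c, wdeg, scale = spec.hypokinetic
    win = _sector_window(theta, c, wdeg)
    return a * (1.0 - (1.0 - scale) * win)


def _boundary_scale(spec: PhantomSpec, theta):
    """Angular modulation of both border radii (mild ellipticity)."""
    if not spec.ellipticity:
        return np.ones_like(np.asarray(theta, dtype=float))
    ax = np.deg2rad(spec.ellipse_axis_deg)
    return 1.0 + spec.ellipticity * np.cos(2.0 * (theta - ax))


def _base_radii(spec: PhantomSpec, theta):
    e = _boundary_scale(spec, theta)
    return spec.inner_radius * e, spec.outer_radius * e


def _radii_at(spec: PhantomSpec, a, theta):
    """Deformed border radii along each ray at activation ``a``."""
    ri, ro = _base_radii(spec, theta)
    ri_t = ri * (1.0 - spec.contraction * a)
    ro_t = ri_t + (ro - ri) * (1.0 + spec.thickening * a)
    return ri, ro, ri_t, ro_t


def _radial_forward(spec: PhantomSpec, r, a, theta):
    """Deformed radius for reference radius ``r`` (piecewise linear per
    ray: cavity / wall / exterior / beyond support)."""
    rs = spec.support_radius
    ri, ro, ri_t, ro_t = _radii_at(spec, a, theta)
    cavity = r * ri_t / ri
    wall = ri_t + (r - ri) * (ro_t - ri_t) / (ro - ri)
    outer = ro_t + (r - ro) * (rs - ro_t) / (rs - ro)
    return np.select([r < ri, r < ro, r < rs], [cavity, wall, outer], default=r)


def _radial_inverse(spec: PhantomSpec, s, a, theta):
    """Reference radius for deformed radius ``s`` (exact inverse of
    :func:`_radial_forward` along the same ray)."""
    rs = spec.support_radius
    ri, ro, ri_t, ro_t = _radii_at(spec, a, theta)
    cavity = s * ri / ri_t
    wall = ri + (s - ri_t) * (ro - ri) / (ro_t - ri_t)
    outer = ro + (s - ro_t) * (rs - ro) / (rs - ro_t)
    return np.select([s < ri_t, s < ro_t, s < rs], [cavity, wall, outer], default=s)


def _twist_profile(spec: PhantomSpec, r):
    ri, ro = spec.inner_radius, spec.outer_radius
    return np.clip((r - ri) / (ro - ri), 0.0, 1.0)


def _angle_shift(spec: PhantomSpec, r, a0):
    return a0 * (np.deg2rad(spec.rotation_deg)
                 + np.deg2rad(spec.twist_deg) * _twist_profile(spec, r))


def forward_map(spec: PhantomSpec, points, t):
    """Exact deformed position of reference-frame ``(x, y)`` points at
    frame ``t`` (the ground-truth transform the registration estimates)."""
    pts = np.asarray(points, dtype=float)
    cx, cy = spec.center
    dx, dy = pts[..., 0] - cx, pts[..., 1] - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    a = _activation_at(spec, t, theta)
    r2 = _radial_forward(spec, r, a, theta)
    th2 = theta + _angle_shift(spec, r, activation(spec, t))
    return np.stack([cx + r2 * np.cos(th2), cy + r2 * np.sin(th2)], axis=-1)


def _base_intensity(spec: PhantomSpec, r, theta):
    w = spec.edge_width
    cav, myo, bg = (spec.intensity_cavity, spec.intensity_myocardium,
                    spec.intensity_background)
    ri, ro = _base_radii(spec, theta)
    if spec.texture:
        myo = myo * (1.0 + spec.texture * (0.4 * np.cos(theta - 0.7)
                                           + 0.3 * np.cos(4.0 * theta + 1.1)
                                           + 0.3 * np.cos(9.0 * theta + 2.4)))
    if spec.weak_edge is not None:
        c, wdeg, red = spec.weak_edge
        bg = myo + (bg - myo) * (1.0 - red * _sector_window(theta, c, wdeg))
    s1 = 1.0 / (1.0 + np.exp(-(r - ri) / w))
    s2 = 1.0 / (1.0 + np.exp(-(r - ro) / w))
    return cav + (myo - cav) * s1 + (bg - myo) * s2


def _render_frame(spec: PhantomSpec, t) -> np.ndarray:
    cx, cy = spec.center
    ys, xs = np.mgrid[0:spec.size, 0:spec.size]
    dx, dy = xs - cx, ys - cy
    s = np.hypot(dx, dy)
    th2 = np.arctan2(dy, dx)
    a0 = activation(spec, t)
    if spec.twist_deg:
        # twist excludes ellipticity, so the radius map is theta-free and
        # can be inverted before recovering the reference angle
        a = _activation_at(spec, t, th2)
        r = _radial_inverse(spec, s, a, th2)
        theta = th2 - _angle_shift(spec, r, a0)
    else:
        # rigid rotation shifts every ray equally; purely radial motion
        # (hypokinesia allowed) keeps theta fixed
        theta = th2 - a0 * np.deg2rad(spec.rotation_deg)
        a = _activation_at(spec, t, theta)
        r = _radial_inverse(spec, s, a, theta)
    return _base_intensity(spec, r, theta)


@dataclass
class PhantomGroundTruth:
    """Exact deformation, contours, landmarks and strain of a phantom."""

    spec: PhantomSpec
    n_contour_points: int = 64

    @property
    def centroid(self) -> tuple:
        return self.spec.center

    def myocardium_mask(self) -> np.ndarray:
        cx, cy = self.spec.center
        ys, xs = np.mgrid[0:self.spec.size, 0:self.spec.size]
        r = np.hypot(xs - cx, ys - cy)
        theta = np.arctan2(ys - cy, xs - cx)
        ri, ro = _base_radii(self.spec, theta)
        return (r >= ri) & (r <= ro)

    def displacement_field(self, t) -> DisplacementField:
        ys, xs = np.mgrid[0:self.spec.size, 0:self.spec.size]
        pts = np.stack([xs, ys], axis=-1).astype(float)
        u = forward_map(self.spec, pts, t) - pts
        return DisplacementField(u=u, frame=int(t))

    def displacement_fields(self):
        return [self.displacement_field(t) for t in range(self.spec.frames)]

    def _reference_boundary(self, base_radius: float) -> np.ndarray:
        phi = 2.0 * np.pi * np.arange(self.n_contour_points) / self.n_contour_points
        cx, cy = self.spec.center
        r = base_radius * _boundary_scale(self.spec, phi)
        return np.stack([cx + r * np.cos(phi), cy + r * np.sin(phi)], axis=1)

    def contours(self, t) -> dict:
        """Exact advected endo/epi contours at frame ``t``."""
        out = {}
        for label, radius in (("endo", self.spec.inner_radius),
                              ("epi", self.spec.outer_radius)):
            pts = forward_map(self.spec, self._reference_boundary(radius), t)
            out[label] = ContourPointSet(pts, closed=True, label=label)
        return out

    def all_contours(self) -> dict:
        """``{(frame, label): ContourPointSet}`` for the whole cycle."""
        out = {}
        for t in range(self.spec.frames):
            for label, c in self.contours(t).items():
                out[(t, label)] = c
        return out

    def landmark_reference_points(self) -> np.ndarray:
        """Frame-0 positions of the two tracked landmarks: A mid-wall at a
        high-deformation site, B mid-wall on the weak edge (or opposite A
        if no weak edge is configured)."""
        theta_a = np.pi / 2.0
        theta_b = np.deg2rad(self.spec.weak_edge[0]) if self.spec.weak_edge \
            else -np.pi / 2.0
        cx, cy = self.spec.center
        out = []
        for th in (theta_a, theta_b):
            ri, ro = _base_radii(self.spec, th)
            rmid = 0.5 * (ri + ro)
            out.append([cx + rmid * np.cos(th), cy + rmid * np.sin(th)])
        return np.array(out)

    def landmark_trajectories(self) -> np.ndarray:
        """(2, F, 2) exact landmark positions over the cycle."""
        ref = self.landmark_reference_points()
        return np.stack([np.stack([forward_map(self.spec, p, t)
                                   for t in range(self.spec.frames)])
                         for p in ref])


def generate(spec: PhantomSpec):
    """Render the phantom cine and its ground truth.

    Returns ``(CineSequence, PhantomGroundTruth)``; regeneration with the
    same spec (same seed) is bitwise identical.
    """
    frames = np.stack([_render_frame(spec, t) for t in range(spec.frames)])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sigma, frames.shape)
    cine = CineSequence(frames=frames, pixel_spacing=spec.pixel_spacing,
                        frame_interval=spec.frame_interval,
                        meta={"phantom": True, "seed": spec.seed})
    return cine, PhantomGroundTruth(spec=spec)


def analytic_radial_strain(spec: PhantomSpec, frame) -> np.ndarray:
    """Closed-form Green radial strain (dimensionless) of the programmed
    deformation on the reference grid; exact on the myocardium.

    The radial stretch of the per-ray map ``(r, th) -> (r'(r), th +
    beta(r))`` is ``sqrt((dr'/dr)^2 + (r' dbeta/dr)^2)`` and the Green
    radial strain is half its squared excess.
    """
    if not 0 <= frame < spec.frames:
        raise ValueError(f"frame must be in 0..{spec.frames-1}")
    cx, cy = spec.center
    ys, xs = np.mgrid[0:spec.size, 0:spec.size]
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    a = _activation_at(spec, frame, theta)
    rs = spec.support_radius
    ri, ro, ri_t, ro_t = _radii_at(spec, a, theta)
    lam = np.select(
        [r < ri, r < ro, r < rs],
        [ri_t / ri, (ro_t - ri_t) / (ro - ri), (rs - ro_t) / (rs - ro)],
        default=1.0,
    )
    a0 = activation(spec, frame)
    beta_r = np.where((r >= ri) & (r <= ro),
                      a0 * np.deg2rad(spec.twist_deg)
                      / (spec.outer_radius - spec.inner_radius), 0.0)
    r2 = _radial_forward(spec, r, a, theta)
    return 0.5 * (lam**2 + (r2 * beta_r) ** 2 - 1.0)


def weak_edge_variant(spec: PhantomSpec, center_deg: float = -90.0,
                      width_deg: float = 70.0,
                      reduction: float = 1.0) -> PhantomSpec:
    """Spec variant with the myocardium/background contrast lowered along
    an epicardial arc (``reduction`` = 1 removes the edge entirely,
    0 leaves the spec unchanged)."""
    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must be in [0, 1]")
    if reduction == 0.0:
        return spec
    return replace(spec, weak_edge=(float(center_deg), float(width_deg),
                                    float(reduction)))
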