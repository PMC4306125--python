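"""Myocardial strain, strain rate and AHA-segment regional averaging.

Strain is Lagrangian with respect to end diastole: every displacement
field maps reference-frame (frame-0) coordinates into frame ``t``, so the
deformation gradient ``F = I + grad(u)`` and the Green-Lagrange tensor
``E = (F^T F - I)/2`` are evaluated on the fixed reference-frame
myocardium mask.  Radial strain is the projection ``r^T E r`` with the
unit radial direction from the LV centroid (positive = wall thickening /
tension, negative = compression), reported in percent.  Because the
conventional clinical description "percentage of thickness variation"
reads as engineering strain, an engineering projection
``sqrt(r^T F^T F r) - 1`` is available as well; Green is the default.

Strain rate is the time derivative of the segment-mean strain (units
1/s), by central differences over the uniformly sampled cine frames.

Regional averaging follows the AHA 17-segment model: 6 sectors of 60 deg
for basal and mid slices, 4 of 90 deg for apical, counted from the
anterior RV-insertion angle.  Segment 17 (the true apex) has no
short-axis representation and is not produced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StrainField",
    "SegmentModel",
    "deformation_gradient",
    "strain_tensor",
    "radial_strain",
    "circumferential_strain",
    "strain_rate",
    "aha_segments",
    "segment_curves",
    "compute_strain_fields",
]

_LEVELS = {"basal": (6, 1), "mid": (6, 7), "apical": (4, 13)}


def deformation_gradient(field, spacing=(1.0, 1.0)) -> np.ndarray:
    """Per-pixel 2x2 deformation gradient ``F = I + du/dX`` in physical
    units (mm), by central differences (one-sided at image borders).

    ``field`` is a DisplacementField or an ``(H, W, 2)`` array of pixel
    displacements; ``spacing`` is the (x, y) pixel spacing in mm.
    """
    u = np.asarray(getattr(field, "u", field), dtype=float)
    if u.ndim != 3 or u.shape[2] != 2:
        raise ValueError("field must have shape (H, W, 2)")
    sx, sy = float(spacing[0]), float(spacing[1])
    ux_mm, uy_mm = u[..., 0] * sx, u[..., 1] * sy
    f = np.empty((*u.shape[:2], 2, 2))
    kw = dict(edge_order=2)  # second-order one-sided at the image borders
    f[..., 0, 0] = 1.0 + np.gradient(ux_mm, sx, axis=1, **kw)
    f[..., 0, 1] = np.gradient(ux_mm, sy, axis=0, **kw)
    f[..., 1, 0] = np.gradient(uy_mm, sx, axis=1, **kw)
    f[..., 1, 1] = 1.0 + np.gradient(uy_mm, sy, axis=0, **kw)
    return f


def strain_tensor(f: np.ndarray) -> np.ndarray:
    """Green-Lagrange tensor ``E = (F^T F - I)/2`` per pixel."""
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("deformation gradient must be finite")
    c = np.einsum("...ki,...kj->...ij", f, f)
    c[..., 0, 0] -= 1.0
    c[..., 1, 1] -= 1.0
    return 0.5 * c


def _directions(shape, centroid, spacing):
    h, w = shape
    sx, sy = float(spacing[0]), float(spacing[1])
    ys, xs = np.mgrid[0:h, 0:w]
    rx = (xs - centroid[0]) * sx
    ry = (ys - centroid[1]) * sy
    rn = np.hypot(rx, ry)
    at_centroid = rn == 0
    rn = np.where(at_centroid, 1.0, rn)
    return rx / rn, ry / rn, at_centroid


def radial_strain(e: np.ndarray, centroid, spacing=(1.0, 1.0),
                  kind: str = "green", f: np.ndarray | None = None) -> np.ndarray:
    """Radial strain in percent: ``100 * r^T E r`` (Green, default) or the
    engineering stretch ``100 * (sqrt(r^T F^T F r) - 1)`` (requires ``f``).
    The pixel at the centroid itself is NaN (undefined direction)."""
    rx, ry, at_c = _directions(e.shape[:2], centroid, spacing)
    if kind == "green":
        val = (e[..., 0, 0] * rx**2 + 2.0 * e[..., 0, 1] * rx * ry
               + e[..., 1, 1] * ry**2)
    elif kind == "engineering":
        if f is None:
            raise ValueError("engineering strain needs the deformation gradient f")
        c = np.einsum("...ki,...kj->...ij", f, f)
        val = np.sqrt(c[..., 0, 0] * rx**2 + 2.0 * c[..., 0, 1] * rx * ry
                      + c[..., 1, 1] * ry**2) - 1.0
    else:
        raise ValueError("kind must be 'green' or 'engineering'")
    out = 100.0 * val
    out[at_c] = np.nan
    return out


def circumferential_strain(e: np.ndarray, centroid,
                           spacing=(1.0, 1.0)) -> np.ndarray:
    """Circumferential Green strain in percent (tangential projection)."""
    rx, ry, at_c = _directions(e.shape[:2], centroid, spacing)
    tx, ty = -ry, rx
    out = 100.0 * (e[..., 0, 0] * tx**2 + 2.0 * e[..., 0, 1] * tx * ty
                   + e[..., 1, 1] * ty**2)
    out[at_c] = np.nan
    return out


def strain_rate(series, frame_interval) -> np.ndarray:
    """Time derivative of a strain series, in 1/s.

    ``series`` has time on axis 0 (at least 3 frames); ``frame_interval``
    is the uniform frame spacing in milliseconds (an array of per-frame
    intervals is accepted but must be constant — cine sampling is
    uniform).  Central differences in the interior, one-sided at the ends.
    """
    s = np.asarray(series, dtype=float)
    if s.shape[0] < 3:
        raise ValueError("strain rate needs at least 3 frames")
    dt = np.asarray(frame_interval, dtype=float)
    if dt.ndim > 0:
        if not np.allclose(dt, dt.flat[0]):
            raise ValueError("non-uniform frame interval")
        dt = dt.flat[0]
    if dt <= 0:
        raise ValueError("frame interval must be positive")
    return np.gradient(s, float(dt) / 1000.0, axis=0)


@dataclass
class SegmentModel:
    """Per-pixel AHA segment labels for one short-axis slice level."""

    labels: np.ndarray             # (H, W) int, 0 outside the myocardium
    centroid: tuple
    rv_insertion_angle: float      # radians
    level: str                     # basal | mid | apical
    segment_ids: tuple

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def aha_segments(mask: np.ndarray, centroid, rv_insertion_angle: float,
                 level: str = "mid") -> SegmentModel:
    """Partition an annular myocardium mask into AHA angular sectors.

    Sectors are counted counterclockwise from the anterior RV-insertion
    angle; basal slices get labels 1-6, mid 7-12, apical 13-16.  An empty
    sector raises an error naming the segment.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {sorted(_LEVELS)}")
    n_sect, base = _LEVELS[level]
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    ys, xs = np.mgrid[0:h, 0:w]
    ang = np.arctan2(ys - centroid[1], xs - centroid[0])
    rel = (ang - rv_insertion_angle) % (2.0 * np.pi)
    sect = np.minimum((rel / (2.0 * np.pi / n_sect)).astype(int), n_sect - 1)
    labels = np.where(mask, base + sect, 0)
    ids = tuple(range(base, base + n_sect))
    for sid in ids:
        if not np.any(labels == sid):
            raise ValueError(f"AHA segment {sid} is empty for this mask")
    return SegmentModel(labels=labels, centroid=tuple(centroid),
                        rv_insertion_angle=float(rv_insertion_angle),
                        level=level, segment_ids=ids)


@dataclass
class StrainField:
    """Per-pixel strain of one frame on the reference myocardium mask."""

    e: np.ndarray                  # (H, W, 2, 2) Green-Lagrange tensor
    radial_pct: np.ndarray
    circ_pct: np.ndarray
    frame: int
    mask: np.ndarray


def compute_strain_fields(fields, mask: np.ndarray, centroid,
                          spacing=(1.0, 1.0), kind: str = "green") -> list:
    """Green-Lagrange strain fields for a displacement-field sequence,
    evaluated on the reference-frame myocardium ``mask``."""
    out = []
    for fld in fields:
        f = deformation_gradient(fld, spacing)
        e = strain_tensor(f)
        rad = radial_strain(e, centroid, spacing, kind=kind,
                            f=f if kind == "engineering" else None)
        circ = circumferential_strain(e, centroid, spacing)
        out.append(StrainField(e=e, radial_pct=rad, circ_pct=circ,
                               frame=getattr(fld, "frame", len(out)),
                               mask=np.asarray(mask, dtype=bool)))
    return out


def segment_curves(strain_fields, model: SegmentModel,
                   frame_interval: float = 50.0) -> pd.DataFrame:
    """Per-segment and global-mean radial strain and strain-rate curves.

    Returns a tidy frame with columns ``frame, time_ms, segment,
    radial_strain_pct, radial_strain_rate_per_s``; ``segment`` holds the
    AHA segment id or ``"global"`` for the mask-wide mean.  A segment
    emptied by the mask at some frame is recorded as NaN, never
    interpolated.
    """
    ids = list(model.segment_ids)
    n_frames = len(strain_fields)
    series = np.full((n_frames, len(ids) + 1), np.nan)
    for t, sf in enumerate(strain_fields):
        m = model.mask & sf.mask & np.isfinite(sf.radial_pct)
        for j, sid in enumerate(ids):
            sel = m & (model.labels == sid)
            if np.any(sel):
                series[t, j] = sf.radial_pct[sel].mean()
            else:
                warnings.warn(f"segment {sid} empty at frame {t}", RuntimeWarning)
        if np.any(m):
            series[t, -1] = sf.radial_pct[m].mean()
    rate = strain_rate(series / 100.0, frame_interval) if n_frames >= 3 \
        else np.full_like(series, np.nan)
    rows = []
    names = [str(s) for s in ids] + ["global"]
    for t in range(n_frames):
        for j, name in enumerate(names):
            rows.append({"frame": t, "time_ms": t * frame_interval,
                         "segment": name,
                         "radial_strain_pct": series[t, j],
                         "radial_strain_rate_per_s": rate[t, j]})
    return pd.DataFrame(rows)
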