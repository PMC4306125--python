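"""Cine readers, result writers and the reproducible run configuration.

Supported cine inputs: a DICOM series directory (frames sorted by
instance/trigger order, spacing and frame interval read from the tags),
a 3D NIfTI volume interpreted as a time-stack (third axis = time), or a
directory of ordered grayscale PNG/TIFF frames (lexical order).  All
intensities are rescaled to [0, 1] so optimizer settings are
transferable across inputs.

Result artifacts are plain files — per-frame transform JSON, dense NPZ
displacement fields, tidy strain CSV, cost logs, a copy of the run
configuration and a manifest with content checksums — so a run is fully
reproducible and checkable from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["RunConfig", "read_cine", "write_cine_png", "write_results"]

from .core import CineSequence

_DEFAULT_SPACING = (1.0, 1.0)
_DEFAULT_INTERVAL = 50.0

_PNG_EXTS = {".png", ".tif", ".tiff"}


@dataclass
class RunConfig:
    """Everything needed to reproduce a registration run."""

    input_path: str = ""
    input_format: str | None = None     # dicom | nifti | png | None=detect
    reference_frame: int = 0
    grid_spacing: float = 8.0
    lam: float = 1.0
    contour_source: str = "none"        # file | snake | none
    contour_file: str | None = None
    max_iterations_global: int = 200
    max_iterations_local: int = 300
    warm_start: bool = True
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.reference_frame < 0:
            raise ValueError("reference frame index must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls(**json.loads(s))


# ----------------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    if path.is_dir():
        if any(p.suffix.lower() in _PNG_EXTS for p in path.iterdir()):
            return "png"
        return "dicom"
    if path.suffix.lower() in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer cine format of {path}")


def _normalize(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    lo, hi = frames.min(), frames.max()
    return (frames - lo) / (hi - lo) if hi > lo else np.zeros_like(frames)


def _read_png_dir(path: Path) -> CineSequence:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _PNG_EXTS)
    if not files:
        raise ValueError(f"no PNG/TIFF frames in {path}")
    imgs = [np.asarray(iio.imread(f)) for f in files]
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1:
        raise ValueError(f"mixed frame sizes in {path}: {sorted(shapes)}")
    stack = np.stack([im if im.ndim == 2 else im[..., 0] for im in imgs]).astype(float)
    maxval = {np.uint8: 255.0, np.uint16: 65535.0}.get(imgs[0].dtype.type)
    frames = stack / maxval if maxval else _normalize(stack)
    warnings.warn("PNG frames carry no spacing/timing; using defaults",
                  RuntimeWarning)
    return CineSequence(frames=frames, pixel_spacing=_DEFAULT_SPACING,
                        frame_interval=_DEFAULT_INTERVAL,
                        meta={"format": "png", "files": [f.name for f in files]})


def _read_dicom_dir(path: Path) -> CineSequence:
    import pydicom

    datasets = []
    for p in sorted(path.iterdir()):
        if p.is_file():
            try:
                datasets.append((p.name, pydicom.dcmread(str(p))))
            except Exception:  # noqa: BLE001 - skip non-DICOM files
                continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {path}")

    def sort_key(item):
        name, ds = item
        for tag in ("InstanceNumber", "TriggerTime"):
            v = getattr(ds, tag, None)
            if v is not None:
                return (0, float(v), name)
        return (1, 0.0, name)

    keys = [sort_key(d)[0] for d in datasets]
    if any(k == 1 for k in keys):
        warnings.warn("missing temporal DICOM tags; falling back to file order",
                      RuntimeWarning)
    datasets.sort(key=sort_key)
    arrays = [ds.pixel_array.astype(float) for _, ds in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        offenders = [n for n, ds in datasets]
        raise ValueError(f"mixed frame sizes among {offenders}")
    ds0 = datasets[0][1]
    spacing = _DEFAULT_SPACING
    ps = getattr(ds0, "PixelSpacing", None)
    if ps is not None:
        # DICOM PixelSpacing is (row, col) mm -> (x, y) = (col, row)
        spacing = (float(ps[1]), float(ps[0]))
    else:
        warnings.warn("no PixelSpacing tag; using default spacing", RuntimeWarning)
    interval = _DEFAULT_INTERVAL
    ft = getattr(ds0, "FrameTime", None)
    if ft is not None:
        interval = float(ft)
    else:
        tt = [getattr(ds, "TriggerTime", None) for _, ds in datasets]
        if all(t is not None for t in tt) and len(tt) > 1:
            diffs = np.diff([float(t) for t in tt])
            if len(diffs) and np.all(diffs > 0):
                interval = float(np.mean(diffs))
        else:
            warnings.warn("no frame-timing tags; using default interval",
                          RuntimeWarning)
    return CineSequence(frames=_normalize(np.stack(arrays)),
                        pixel_spacing=spacing, frame_interval=interval,
                        meta={"format": "dicom",
                              "files": [n for n, _ in datasets]})


def _read_nifti(path: Path) -> CineSequence:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError("expected a 3D NIfTI volume (slice axis = time)")
    # (i, j, t) voxel order -> frame t as image rows=j, cols=i
    frames = np.stack([data[:, :, t].T for t in range(data.shape[2])])
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 \
        else _DEFAULT_SPACING
    interval = _DEFAULT_INTERVAL
    if len(zooms) >= 3 and zooms[2] > 0:
        interval = float(zooms[2]) * 1000.0 if zooms[2] < 10 else float(zooms[2])
    return CineSequence(frames=_normalize(frames), pixel_spacing=spacing,
                        frame_interval=interval, meta={"format": "nifti"})


def read_cine(path, format: str | None = None) -> CineSequence:
    """Read a cine sequence from a DICOM directory, NIfTI time-stack or
    PNG/TIFF frame directory; frame order follows temporal tags where
    present, file order otherwise."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "png":
        return _read_png_dir(path)
    if fmt == "dicom":
        return _read_dicom_dir(path)
    if fmt == "nifti":
        return _read_nifti(path)
    raise ValueError(f"unknown cine format {fmt!r}")


def write_cine_png(outdir, cine: CineSequence) -> list:
    """Write frames as 16-bit grayscale PNGs (intensities clipped to [0, 1]);
    reading the stack back reproduces the quantized values bitwise."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(cine.frames):
        q = np.clip(frame, 0.0, 1.0)
        arr = np.round(q * 65535.0).astype(np.uint16)
        p = outdir / f"frame_{t:03d}.png"
        iio.imwrite(p, arr)
        paths.append(p)
    return paths


# ----------------------------------------------------------------------------
# Result writer
# ----------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(outdir, transforms=None, fields=None, strain_curves=None,
                  cost_logs=None, config: RunConfig | None = None) -> dict:
    """Write all run artifacts and return the checksum manifest.

    ``transforms`` is a per-frame list of HierarchicalTransform (or None
    for the reference frame), ``fields`` a per-frame list of
    DisplacementField, ``strain_curves`` a tidy DataFrame, ``cost_logs``
    a per-frame list of iteration logs.  A ``.incomplete`` marker guards
    against partially written directories.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".incomplete"
    marker.touch()
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        p = outdir / name
        writer(p)
        written.append(p)

    n_frames = len(transforms) if transforms else (len(fields) if fields else 0)
    for t in range(n_frames):
        if transforms and transforms[t] is not None:
            emit(f"transform_{t:03d}.json",
                 lambda p, tr=transforms[t]: p.write_text(tr.to_json()))
        if fields and fields[t] is not None:
            emit(f"field_{t:03d}.npz",
                 lambda p, f=fields[t]: np.savez_compressed(
                     p, u=f.u, mask=f.mask, frame=f.frame))
    if strain_curves is not None:
        emit("strain.csv", lambda p: strain_curves.to_csv(p, index=False))
    if cost_logs:
        import pandas as pd
        rows = [dict(rec, frame=t) for t, log in enumerate(cost_logs)
                if log for rec in log]
        emit("cost_log.csv", lambda p: pd.DataFrame(
            rows, columns=["frame", "iteration", "c_sim", "c_icp", "total"])
            .to_csv(p, index=False))
    if config is not None:
        emit("config.json", lambda p: p.write_text(config.to_json()))

    manifest = {"n_frames": n_frames,
                "files": {p.name: _sha256(p) for p in sorted(written)}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    marker.unlink()
    return manifest
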