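"""Readers and writers for the plain-text and image formats the toolkit uses.

Formats:

* scattering curves — 2- or 3-column ASCII (q [Å⁻¹], I, optional σ),
  whitespace- or comma-separated, ``#`` comment lines tolerated;
* FRAP traces — CSV with columns ``time_s, intensity`` plus metadata
  either as constant extra columns (``bleach_index, roi_radius_um, label,
  vesicle_id``) or a YAML sidecar;
* micrographs — single-channel TIFF or PNG;
* 31P spectra — 2-column CSV (ppm, intensity), either ppm order.

Unit conventions at the boundary: q in Å⁻¹ and lengths in Å for
scattering; seconds and μm for FRAP; nm for pixel size.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from .frap import FrapTrace
from .guv import Micrograph
from .nmr import Spectrum31P
from .sans import ScatteringCurve

__all__ = [
    "read_scattering_curve",
    "write_scattering_curve",
    "read_trace",
    "write_trace",
    "read_image",
    "write_image",
    "read_spectrum",
    "write_spectrum",
]


class ParseError(ValueError):
    """Input file could not be parsed; message carries the line number."""


# ---------------------------------------------------------------------------
# scattering curves
# ---------------------------------------------------------------------------


def read_scattering_curve(path: str | Path) -> ScatteringCurve:
    """Parse a 2/3-column ASCII curve; rows are re-sorted by ascending q."""
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric row at line {lineno}") from exc
            if len(vals) < 2:
                raise ParseError(f"{path}: fewer than 2 columns at line {lineno}")
            if ncol is None:
                ncol = min(len(vals), 3)
            rows.append(vals[:ncol])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(arr[:, 0] <= 0):
        raise ValueError(f"{path}: q values must be positive")
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma)


def write_scattering_curve(path: str | Path, curve: ScatteringCurve) -> None:
    """Write the same 3-column (or 2-column) '#'-headed ASCII dialect."""
    with open(path, "w") as fh:
        if curve.sigma is not None:
            fh.write("# q_A-1 intensity sigma\n")
            for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
                fh.write(f"{q:.12g} {i:.12g} {s:.12g}\n")
        else:
            fh.write("# q_A-1 intensity\n")
            for q, i in zip(curve.q, curve.intensity):
                fh.write(f"{q:.12g} {i:.12g}\n")


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def read_trace(path: str | Path, sidecar: str | Path | None = None) -> FrapTrace:
    """Read a FRAP trace CSV; metadata from extra columns or a YAML sidecar."""
    df = pd.read_csv(path)
    required = {"time_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    meta: dict = {}
    if sidecar is not None:
        import yaml

        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    for key in ("bleach_index", "roi_radius_um", "label", "vesicle_id"):
        if key not in meta and key in df.columns:
            meta[key] = df[key].iloc[0]
    if "bleach_index" not in meta or "roi_radius_um" not in meta:
        raise ParseError(
            f"{path}: bleach_index and roi_radius_um must be provided "
            "(extra columns or sidecar)"
        )
    return FrapTrace(
        time=df["time_s"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
        bleach_index=int(meta["bleach_index"]),
        roi_radius_um=float(meta["roi_radius_um"]),
        label=str(meta.get("label", "")),
        vesicle_id=str(meta.get("vesicle_id", "")),
    )


def write_trace(path: str | Path, trace: FrapTrace) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "intensity": trace.intensity,
            "bleach_index": trace.bleach_index,
            "roi_radius_um": trace.roi_radius_um,
            "label": trace.label,
            "vesicle_id": trace.vesicle_id,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image(path: str | Path, pixel_size_nm: float = 64.0) -> Micrograph:
    """Read a single-channel TIFF/PNG micrograph; RGB input is rejected."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: multi-channel image; extract a single channel first "
            "(e.g. arr[..., 0])"
        )
    return Micrograph(arr.astype(float), pixel_size_nm)


def write_image(path: str | Path, img: Micrograph, dtype: str = "uint16") -> None:
    """Write a micrograph as integer TIFF/PNG, clipping to the dtype range."""
    path = Path(path)
    info = np.iinfo(dtype)
    arr = np.clip(np.round(img.pixels), info.min, info.max).astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# 31P spectra
# ---------------------------------------------------------------------------


def read_spectrum(path: str | Path) -> Spectrum31P:
    """Read a 2-column CSV (ppm, intensity); either ppm order is accepted."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns (ppm, intensity)")
    return Spectrum31P(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_spectrum(path: str | Path, spec: Spectrum31P) -> None:
    pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(
        path, index=False
    )
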