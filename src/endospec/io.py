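"""File I/O: hyperspectral cubes (ENVI BSQ and multi-band TIFF), combined
model JSON, and dataset-manifest accounting.

The combined model file bundles the polynomial correction, the PCA
transformation and (optionally) the NBI band model as one JSON document with
canonical key order and full-precision floats, so a write/read/write cycle is
bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CorrectionModel
from .colorimetry import SpectralGrid
from .nbi import NbiModel
from .spectral_basis import HyperspectralCube, TransformationModel

__all__ = [
    "write_cube_envi",
    "read_cube_envi",
    "write_cube_tiff",
    "read_cube_tiff",
    "save_model",
    "load_model",
    "read_manifest",
    "summarize_manifest",
]

SPLITS = ("train", "validation", "test")


class FormatError(ValueError):
    """Raised on malformed cube files or inconsistent headers."""


# ---------------------------------------------------------------------------
# ENVI BSQ
# ---------------------------------------------------------------------------

def write_cube_envi(path: str | Path, cube: HyperspectralCube) -> tuple[Path, Path]:
    """Write ``<path>.hdr`` + raw BSQ float32 payload at ``<path>``."""
    path = Path(path)
    h, w, b = cube.shape
    data = np.ascontiguousarray(
        cube.values.transpose(2, 0, 1).astype("<f4")  # BSQ: band, line, sample
    )
    path.write_bytes(data.tobytes())
    wl = ", ".join(f"{v:.1f}" for v in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    hdr_path.write_text(hdr)
    return path, hdr_path


def _parse_envi_header(text: str) -> dict:
    # join continuation lines of { ... } blocks, then split on '='
    merged = []
    buf = ""
    for line in text.splitlines():
        buf = f"{buf} {line}".strip() if buf else line.strip()
        if buf.count("{") > buf.count("}"):
            continue
        merged.append(buf)
        buf = ""
    fields: dict[str, str] = {}
    for line in merged:
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip().lower()] = v.strip()
    return fields


def read_cube_envi(path: str | Path) -> HyperspectralCube:
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    f = _parse_envi_header(hdr_path.read_text())
    try:
        h, w, b = int(f["lines"]), int(f["samples"]), int(f["bands"])
        dtype = f["data type"]
        interleave = f["interleave"].lower()
    except KeyError as e:
        raise FormatError(f"ENVI header missing field: {e}") from None
    if dtype != "4" or interleave != "bsq":
        raise FormatError("only float32 BSQ cubes are supported")
    wl_field = f.get("wavelength", "")
    wl = [float(x) for x in wl_field.strip("{} ").split(",") if x.strip()]
    if len(wl) != b:
        raise FormatError("wavelength list length does not match band count")
    data = np.frombuffer(path.read_bytes(), dtype="<f4")
    if data.size != h * w * b:
        raise FormatError("payload size does not match header dimensions")
    values = data.reshape(b, h, w).transpose(1, 2, 0).astype(float)
    return HyperspectralCube(SpectralGrid(np.array(wl)), values)


# ---------------------------------------------------------------------------
# multi-band TIFF
# ---------------------------------------------------------------------------

def write_cube_tiff(path: str | Path, cube: HyperspectralCube) -> Path:
    """Lossless float32 multi-band TIFF with the wavelength list in metadata."""
    path = Path(path)
    meta = {
        "wavelengths_nm": cube.grid.wavelengths.tolist(),
        "integration_window": list(cube.grid.integration_window),
    }
    tifffile.imwrite(
        path,
        cube.values.transpose(2, 0, 1).astype(np.float32),
        description=json.dumps(meta),
    )
    return path


def read_cube_tiff(path: str | Path) -> HyperspectralCube:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise FormatError("TIFF cube is missing its wavelength metadata")
        meta = json.loads(desc.value)
    wl = np.array(meta["wavelengths_nm"], float)
    if data.shape[0] != wl.size:
        raise FormatError("wavelength list length does not match band count")
    grid = SpectralGrid(wl, tuple(meta.get("integration_window", (wl[0], wl[-1]))))
    return HyperspectralCube(grid, data.transpose(1, 2, 0).astype(float))


# ---------------------------------------------------------------------------
# combined model JSON
# ---------------------------------------------------------------------------

def save_model(
    path: str | Path,
    correction: CorrectionModel,
    transformation: TransformationModel,
    nbi: NbiModel | None = None,
) -> Path:
    doc = {
        "format": "endospec-model",
        "version": 1,
        "correction": correction.to_dict(),
        "transformation": transformation.to_dict(),
        "nbi": nbi.to_dict() if nbi is not None else None,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def load_model(path: str | Path) -> tuple[CorrectionModel, TransformationModel, NbiModel | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "endospec-model":
        raise FormatError("not an endospec model file")
    nbi = NbiModel.from_dict(doc["nbi"]) if doc.get("nbi") else None
    return (
        CorrectionModel.from_dict(doc["correction"]),
        TransformationModel.from_dict(doc["transformation"]),
        nbi,
    )


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a (class_name, split, count) CSV manifest."""
    df = pd.read_csv(path)
    required = {"class_name", "split", "count"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}")
    return df


def summarize_manifest(manifest: pd.DataFrame) -> dict:
    """Exact integer totals per split, per class, and overall.

    Rejects negative counts, unknown split labels and duplicated
    (class, split) rows.
    """
    df = manifest.copy()
    if df.empty:
        return {"per_split": {s: 0 for s in SPLITS}, "per_class": {}, "total": 0}
    if (df["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    bad = set(df["split"]) - set(SPLITS)
    if bad:
        raise ValueError(f"unknown split labels: {sorted(bad)}")
    if df.duplicated(["class_name", "split"]).any():
        raise ValueError("class names must be unique per split")
    per_split = {s: int(df.loc[df["split"] == s, "count"].sum()) for s in SPLITS}
    per_class = {
        str(c): int(g["count"].sum()) for c, g in df.groupby("class_name", sort=False)
    }
    return {"per_split": per_split, "per_class": per_class, "total": int(df["count"].sum())}
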