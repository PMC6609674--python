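"""File formats: strips as multi-page TIFF or HDF5, metadata as CSV/JSON,
tile layout as a minimal XML dialect.

The instrument's native camera format is proprietary and not supported;
TIFF and HDF5 are the canonical strip containers here.  Every container
carries the full stage metadata needed for de-skew (origin, frame interval,
sampling, tilt), and missing metadata is a hard schema error rather than a
silent default.  The tile-layout XML is a deliberately small, repo-specific
dialect: one setup per strip with a pure-translation affine assembled from
nominal origin plus refinement correction.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import tifffile

from .phantom import RawStrip, StripRecord

__all__ = [
    "StripSchemaError",
    "CorruptFileError",
    "write_strip",
    "read_strip",
    "write_metadata_csv",
    "read_metadata_csv",
    "write_metadata_json",
    "read_metadata_json",
    "write_tile_xml",
    "read_tile_xml",
]

_META_KEYS = ("stage_origin_um", "frame_interval_um", "sampling_um",
              "tilt_deg", "channel", "seed", "strip_id")


class StripSchemaError(ValueError):
    """A strip container is missing required metadata."""


class CorruptFileError(IOError):
    """A strip container could not be parsed."""


def _strip_meta(strip: RawStrip) -> dict:
    return {
        "schema": "otlskit-strip-1",
        "stage_origin_um": list(strip.stage_origin_um),
        "frame_interval_um": strip.frame_interval_um,
        "sampling_um": strip.sampling_um,
        "tilt_deg": strip.tilt_deg,
        "channel": strip.channel,
        "seed": int(strip.seed),
        "strip_id": strip.strip_id,
    }


def _strip_from(frames: np.ndarray, meta: Mapping) -> RawStrip:
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise StripSchemaError(f"strip metadata missing keys: {missing}")
    return RawStrip(
        frames=np.asarray(frames),
        stage_origin_um=tuple(float(v) for v in meta["stage_origin_um"]),
        frame_interval_um=float(meta["frame_interval_um"]),
        sampling_um=float(meta["sampling_um"]),
        tilt_deg=float(meta["tilt_deg"]),
        channel=str(meta["channel"]),
        seed=int(meta["seed"]),
        strip_id=str(meta["strip_id"]),
    )


def write_strip(strip: RawStrip, path: str | Path) -> Path:
    """Write a strip to ``path``; format chosen by suffix (.tif/.tiff/.h5/.hdf5)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, strip.frames,
                         description=json.dumps(_strip_meta(strip)))
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("frames", data=strip.frames,
                                  chunks=(1,) + strip.frames.shape[1:],
                                  compression="gzip", compression_opts=4)
            for key, val in _strip_meta(strip).items():
                ds.attrs[key] = json.dumps(val) if isinstance(val, list) else val
    else:
        raise ValueError(f"unsupported strip format {suffix!r}")
    return path


def read_strip(path: str | Path) -> RawStrip:
    """Read a strip; raises :class:`CorruptFileError` on unreadable files and
    :class:`StripSchemaError` on missing metadata."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".tif", ".tiff", ".h5", ".hdf5"):
        raise ValueError(f"unsupported strip format {suffix!r}")
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                frames = tf.asarray()
                desc = tf.pages[0].tags.get("ImageDescription")
                if desc is None:
                    raise StripSchemaError(f"{path}: no metadata in TIFF")
                meta = json.loads(desc.value)
        elif suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as f:
                if "frames" not in f:
                    raise StripSchemaError(f"{path}: no 'frames' dataset")
                ds = f["frames"]
                frames = ds[()]
                meta = {}
                for key in ds.attrs:
                    val = ds.attrs[key]
                    if isinstance(val, (bytes, str)) and str(val).startswith("["):
                        val = json.loads(val)
                    meta[key] = val
        else:  # pragma: no cover - guarded above
            raise ValueError(f"unsupported strip format {suffix!r}")
    except StripSchemaError:
        raise
    except Exception as exc:  # truncated / malformed container
        raise CorruptFileError(f"cannot read strip {path}: {exc}") from exc
    return _strip_from(frames, meta)


# ---------------------------------------------------------------------------
# Stage metadata tables
# ---------------------------------------------------------------------------

def write_metadata_csv(records: Sequence[StripRecord], path: str | Path) -> Path:
    path = Path(path)
    fields = [f.name for f in dataclasses.fields(StripRecord)]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in records:
            writer.writerow(dataclasses.asdict(rec))
    return path


def read_metadata_csv(path: str | Path) -> list[StripRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(StripRecord(
                strip_id=row["strip_id"], channel=row["channel"],
                y_index=int(row["y_index"]), z_tier=int(row["z_tier"]),
                x_origin_um=float(row["x_origin_um"]),
                y_origin_um=float(row["y_origin_um"]),
                z_origin_um=float(row["z_origin_um"]),
                n_frames=int(row["n_frames"]),
                frame_interval_um=float(row["frame_interval_um"]),
                sampling_um=float(row["sampling_um"]),
                tilt_deg=float(row["tilt_deg"]), seed=int(row["seed"])))
    return out


def write_metadata_json(records: Sequence[StripRecord], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([dataclasses.asdict(r) for r in records],
                               indent=2))
    return path


def read_metadata_json(path: str | Path) -> list[StripRecord]:
    return [StripRecord(**rec) for rec in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# Tile layout XML
# ---------------------------------------------------------------------------

def write_tile_xml(
    records: Sequence[StripRecord],
    corrections_um: Mapping[str, Sequence[float]] | None,
    path: str | Path,
) -> Path:
    """Write one setup per strip with a translation-only affine.

    The affine row-major 3x4 matrix is identity rotation plus a translation
    equal to nominal origin + correction (um).  Nominal origin and the
    correction are also stored separately so the file round-trips exactly.
    """
    ids = [r.strip_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate strip ids in tile layout")
    root = ET.Element("TileLayout", version="otlskit-1")
    setups = ET.SubElement(root, "Setups")
    for i, rec in enumerate(records):
        corr = list(corrections_um.get(rec.strip_id, (0.0, 0.0, 0.0))
                    if corrections_um else (0.0, 0.0, 0.0))
        origin = [rec.x_origin_um, rec.y_origin_um, rec.z_origin_um]
        trans = [o + c for o, c in zip(origin, corr)]
        setup = ET.SubElement(setups, "Setup", id=str(i), name=rec.strip_id,
                              channel=rec.channel)
        ET.SubElement(setup, "NominalOrigin").text = " ".join(
            repr(v) for v in origin)
        ET.SubElement(setup, "Correction").text = " ".join(repr(v) for v in corr)
        affine = [1.0, 0.0, 0.0, trans[0],
                  0.0, 1.0, 0.0, trans[1],
                  0.0, 0.0, 1.0, trans[2]]
        ET.SubElement(setup, "Affine").text = " ".join(repr(v) for v in affine)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    tree.write(path, encoding="unicode", xml_declaration=True)
    return path


def read_tile_xml(path: str | Path) -> list[dict]:
    """Load setups back as dicts with origin, correction and translation."""
    root = ET.parse(path).getroot()
    out = []
    for setup in root.iter("Setup"):
        origin = [float(v) for v in setup.find("NominalOrigin").text.split()]
        corr = [float(v) for v in setup.find("Correction").text.split()]
        affine = [float(v) for v in setup.find("Affine").text.split()]
        out.append({
            "id": int(setup.get("id")),
            "strip_id": setup.get("name"),
            "channel": setup.get("channel"),
            "origin_um": origin,
            "correction_um": corr,
            "translation_um": [affine[3], affine[7], affine[11]],
        })
    return out
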