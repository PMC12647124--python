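"""Volume, mask, table and ratio-map I/O with strict metadata handling.

Supported volume formats: multi-page TIFF stacks (via tifffile) and NRRD
(raw-encoded, via a small built-in codec).  The axis order is fixed to
(z, y, x) everywhere; the voxel size (µm, isotropic) must come from file
metadata or an explicit argument — there is no silent default.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VolumeMeta",
    "read_volume",
    "write_volume",
    "read_score_csv",
    "write_ratio_map",
    "ratio_color",
    "RATIO_SCALES",
    "EXCLUDED_COLOR",
]

# Fig-style rendering defaults: area ratio shown on 0-30 %, contact on 0-100 %
RATIO_SCALES = {"area": 0.30, "contact": 1.00}
EXCLUDED_COLOR = (0, 0, 255)  # unconnected components render blue

_NRRD_TYPES = {
    "uint8": np.uint8,
    "int16": np.int16,
    "uint16": np.uint16,
    "int32": np.int32,
    "uint32": np.uint32,
    "int64": np.int64,
    "float": np.float32,
    "double": np.float64,
}
_NUMPY_TO_NRRD = {np.dtype(v): k for k, v in _NRRD_TYPES.items()}


@dataclass(frozen=True)
class VolumeMeta:
    """Shape (z, y, x), isotropic voxel size in µm, dtype tag, provenance."""

    shape: tuple[int, int, int]
    voxel_size_um: float
    dtype: str
    provenance: str = ""

    def __post_init__(self):
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")


def _write_nrrd(path: Path, volume: np.ndarray, voxel_size_um: float, provenance: str):
    dtype = np.dtype(volume.dtype)
    if dtype == np.bool_:
        volume = volume.astype(np.uint8)
        dtype = np.dtype(np.uint8)
    if dtype not in _NUMPY_TO_NRRD:
        raise ValueError(f"unsupported dtype for NRRD: {dtype}")
    sizes = " ".join(str(s) for s in volume.shape[::-1])  # fastest axis first
    spac = f"{voxel_size_um:.9g}"
    header = (
        "NRRD0004\n"
        f"# provenance: {provenance}\n"
        f"type: {_NUMPY_TO_NRRD[dtype]}\n"
        "dimension: 3\n"
        f"sizes: {sizes}\n"
        f"spacings: {spac} {spac} {spac}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(volume).tobytes())


def _read_nrrd(path: Path) -> tuple[np.ndarray, VolumeMeta]:
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        head_end = raw.index(b"\n\n")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed NRRD header") from exc
    fields: dict[str, str] = {}
    provenance = ""
    for line in raw[:head_end].decode("ascii").splitlines()[1:]:
        if line.startswith("# provenance:"):
            provenance = line.split(":", 1)[1].strip()
        elif ":" in line and not line.startswith("#"):
            key, val = line.split(":", 1)
            fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw":
        raise ValueError(f"{path}: only raw-encoded NRRD is supported")
    dtype = _NRRD_TYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    sizes = [int(s) for s in fields["sizes"].split()]
    if len(sizes) != 3:
        raise ValueError(f"{path}: expected a 3-D NRRD, sizes={sizes}")
    if "spacings" in fields:
        spacings = [float(s) for s in fields["spacings"].split()]
    elif "space directions" in fields:
        vecs = [
            [float(x) for x in chunk.strip("()").split(",")]
            for chunk in fields["space directions"].split()
        ]
        spacings = [float(np.linalg.norm(v)) for v in vecs]
    else:
        raise ValueError(f"{path}: NRRD has no voxel spacing; cannot infer voxel size")
    if max(spacings) - min(spacings) > 1e-9 * max(spacings):
        raise ValueError(
            f"{path}: anisotropic voxel spacing {spacings} is unsupported; "
            "volumes must be isotropic"
        )
    data = np.frombuffer(raw[head_end + 2 :], dtype=dtype)
    expected = sizes[0] * sizes[1] * sizes[2]
    if data.size != expected:
        raise ValueError(f"{path}: data size {data.size} != header size {expected}")
    volume = data.reshape(sizes[::-1]).copy()  # (z, y, x)
    meta = VolumeMeta(volume.shape, spacings[0], str(volume.dtype), provenance)
    return volume, meta


def read_volume(
    path: str | os.PathLike, voxel_size_um: float | None = None
) -> tuple[np.ndarray, VolumeMeta]:
    """Read a TIFF stack or NRRD volume, axis order (z, y, x).

    The voxel size must be present in the file metadata or supplied via
    ``voxel_size_um``; a missing voxel size is an error, not a default.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    suffix = p.suffix.lower()
    if suffix == ".nrrd":
        volume, meta = _read_nrrd(p)
        if voxel_size_um is not None:
            meta = VolumeMeta(meta.shape, voxel_size_um, meta.dtype, meta.provenance)
        return volume, meta
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(p) as tf:
            volume = tf.asarray()
            md = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if volume.ndim == 2:
            volume = volume[None]
        if volume.ndim != 3:
            raise ValueError(f"{p}: expected a 3-D stack, got shape {volume.shape}")
        vs = md.get("voxel_size_um") if isinstance(md, dict) else None
        if vs is None:
            vs = voxel_size_um
        if vs is None:
            raise ValueError(
                f"{p}: TIFF carries no voxel size metadata; pass voxel_size_um "
                "(e.g. --voxel-um on the CLI)"
            )
        provenance = md.get("provenance", "") if isinstance(md, dict) else ""
        meta = VolumeMeta(volume.shape, float(vs), str(volume.dtype), provenance)
        return volume, meta
    raise ValueError(f"{p}: unsupported volume format {suffix!r} (use .tif or .nrrd)")


def write_volume(
    volume: np.ndarray,
    meta: VolumeMeta,
    path: str | os.PathLike,
    force: bool = False,
) -> None:
    """Write a volume so that :func:`read_volume` roundtrips it bit-exactly."""
    p = Path(path)
    if volume.ndim != 3 or volume.size == 0:
        raise ValueError(f"volume must be 3-D and non-empty, got shape {volume.shape}")
    if tuple(volume.shape) != tuple(meta.shape):
        raise ValueError(f"volume shape {volume.shape} != metadata shape {meta.shape}")
    if p.exists() and not force:
        raise FileExistsError(f"{p} exists; pass force=True / --force to overwrite")
    p.parent.mkdir(parents=True, exist_ok=True)
    suffix = p.suffix.lower()
    if suffix == ".nrrd":
        _write_nrrd(p, volume, meta.voxel_size_um, meta.provenance)
    elif suffix in (".tif", ".tiff"):
        out = volume.astype(np.uint8) if volume.dtype == np.bool_ else volume
        tifffile.imwrite(
            p,
            out,
            photometric="minisblack",
            metadata={
                "voxel_size_um": meta.voxel_size_um,
                "provenance": meta.provenance,
            },
        )
    else:
        raise ValueError(f"{p}: unsupported volume format {suffix!r}")


def read_score_csv(path: str | os.PathLike, catalog: pd.DataFrame) -> pd.DataFrame:
    """Read and validate an ordinal score table.

    Required columns: animal_id, genotype, age_group, segment_label, lobe,
    generation, score.  Scores must be in {0, 1, 2}, generations in 1-11
    (generation 0, the trachea, is excluded from scoring by design), and
    segment labels must exist in the nomenclature catalog.
    """
    df = pd.read_csv(path)
    required = [
        "animal_id",
        "genotype",
        "age_group",
        "segment_label",
        "lobe",
        "generation",
        "score",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    known_labels = set(catalog["segment_label"])
    from .scoring import LOBES  # local import to avoid a cycle

    for i, row in df.iterrows():
        if row["score"] not in (0, 1, 2):
            raise ValueError(
                f"{path} row {i}: score {row['score']!r} outside {{0, 1, 2}}"
            )
        gen = int(row["generation"])
        if gen == 0:
            raise ValueError(
                f"{path} row {i}: generation 0 is the trachea, which is "
                "excluded from visual mucus scoring"
            )
        if not 1 <= gen <= 11:
            raise ValueError(f"{path} row {i}: generation {gen} outside 1-11")
        if row["lobe"] not in LOBES:
            raise ValueError(f"{path} row {i}: unknown lobe {row['lobe']!r}")
        if row["segment_label"] not in known_labels:
            raise ValueError(
                f"{path} row {i}: segment label {row['segment_label']!r} "
                "not in the nomenclature catalog"
            )
    df["generation"] = df["generation"].astype(int)
    df["score"] = df["score"].astype(int)
    return df


def ratio_color(ratio: float, scale_max: float) -> tuple[int, int, int]:
    """Green-to-red linear gradient, clamped at ``scale_max``."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    t = min(ratio / scale_max, 1.0) if scale_max > 0 else 1.0
    r = int(np.round(255 * t))
    return (r, 255 - r, 0)


def write_ratio_map(
    shape: tuple[int, int, int],
    records,
    ratios,
    which: str,
    path: str | os.PathLike,
    excluded_mask: np.ndarray | None = None,
    scale_max: float | None = None,
    force: bool = False,
) -> None:
    """Render cross-section ratios as an 8-bit RGB TIFF stack.

    Each record's voxels get the green-to-red gradient colour of its ratio
    (default scales: 0-30 % for area, 0-100 % for contact); excluded
    components render blue; background stays black.  Records must carry
    voxel coordinates (``keep_voxels=True`` at extraction time).
    """
    if which not in RATIO_SCALES:
        raise ValueError(f"which must be 'area' or 'contact', got {which!r}")
    if scale_max is None:
        scale_max = RATIO_SCALES[which]
    p = Path(path)
    if p.exists() and not force:
        raise FileExistsError(f"{p} exists; pass force=True / --force to overwrite")
    rgb = np.zeros((*shape, 3), dtype=np.uint8)
    for rec, ratio in zip(records, ratios):
        if rec.voxels is None:
            raise ValueError(
                "record has no voxel coordinates; re-extract with keep_voxels=True"
            )
        color = ratio_color(float(ratio), scale_max)
        idx = tuple(rec.voxels.T)
        for c in range(3):
            rgb[(*idx, c)] = color[c]
    if excluded_mask is not None:
        for c in range(3):
            rgb[..., c][excluded_mask] = EXCLUDED_COLOR[c]
    p.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(p, rgb, photometric="rgb")
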