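"""Raster and mesh I/O for the SXT morphometrics pipeline.

Volumes are isotropic 3D grids indexed ``(z, y, x)``; the physical position
of voxel ``(i, j, k)`` is ``(i, j, k) * voxel_um`` plus the volume origin.
Two raster containers are used throughout:

* :class:`LACVolume` — the reconstructed linear absorption coefficient
  (LAC) field in µm⁻¹, i.e. the grayscale tomogram.
* :class:`LabeledVolume` — an integer label map on the same grid, either
  semantic (background / cell / nucleus / vacuole / lipid droplet) or
  instance-valued (one positive id per cell).

Supported file formats: multi-page TIFF (with a JSON sidecar carrying the
voxel size, since TIFF has no reliable spacing convention), MRC2014 (voxel
size from the header cell dimensions), STL and binary PLY for meshes, and
CSV for morphometrics tables.  All writers are deterministic byte-for-byte
for identical inputs.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

#: Semantic label dictionary used across the pipeline.
SEMANTIC_LABELS: dict[int, str] = {
    0: "background",
    1: "cell",
    2: "nucleus",
    3: "vacuole",
    4: "lipid_droplet",
}

#: name -> integer label, inverse of :data:`SEMANTIC_LABELS`.
LABEL_IDS: dict[str, int] = {v: k for k, v in SEMANTIC_LABELS.items()}


class VolumeIOError(RuntimeError):
    """Raised for malformed or unsupported volume files."""


@dataclass
class LACVolume:
    """Isotropic grayscale volume of linear absorption coefficients (µm⁻¹)."""

    data: np.ndarray
    voxel_um: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("LACVolume data must be 3D")
        if not np.isfinite(self.data).all():
            raise ValueError("LACVolume contains non-finite values")
        if not self.voxel_um > 0:
            raise ValueError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabeledVolume:
    """Integer multi-label volume sharing the grid of its LACVolume."""

    data: np.ndarray
    voxel_um: float
    label_dictionary: dict[int, str] = field(
        default_factory=lambda: dict(SEMANTIC_LABELS)
    )
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabeledVolume data must be integer-typed")
        if self.data.ndim != 3:
            raise ValueError("LabeledVolume data must be 3D")
        if not self.voxel_um > 0:
            raise ValueError("voxel_um must be positive")

    def validate_labels(self) -> None:
        """Raise if any voxel carries a label outside the dictionary."""
        present = set(np.unique(self.data).tolist())
        unknown = present - set(self.label_dictionary)
        if unknown:
            raise VolumeIOError(f"labels {sorted(unknown)} not in label dictionary")

    def mask(self, label: int | str) -> np.ndarray:
        """Binary mask of one label (by id or by dictionary name)."""
        if isinstance(label, str):
            inv = {v: k for k, v in self.label_dictionary.items()}
            label = inv[label]
        return self.data == label

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# MRC2014 (mode 1 int16, mode 2 float32, mode 6 uint16)

_MRC_MODE_FROM_DTYPE = {np.dtype(np.int16): 1, np.dtype(np.float32): 2,
                        np.dtype(np.uint16): 6}
_MRC_DTYPE_FROM_MODE = {1: np.int16, 2: np.float32, 6: np.uint16}


def _write_mrc(path: Path, data: np.ndarray, voxel_um: float,
               origin: tuple[float, float, float]) -> None:
    data = np.ascontiguousarray(data)
    if data.dtype not in _MRC_MODE_FROM_DTYPE:
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.int16)
        else:
            data = data.astype(np.float32)
    mode = _MRC_MODE_FROM_DTYPE[data.dtype]
    nz, ny, nx = data.shape
    voxel_A = voxel_um * 1e4  # MRC cell dimensions are in Ångström
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)          # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * voxel_A, ny * voxel_A,
                     nz * voxel_A)                            # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)     # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)              # mapc/mapr/maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                     # ispg
    # origin (MRC2014 words 50-52), stored in Ångström
    struct.pack_into("<3f", header, 196,
                     origin[2] * 1e4, origin[1] * 1e4, origin[0] * 1e4)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))         # little-endian
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _read_mrc(path: Path) -> tuple[np.ndarray, float, tuple[float, float, float]]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise VolumeIOError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        ox, oy, oz = struct.unpack_from("<3f", header, 196)
        if mode not in _MRC_DTYPE_FROM_MODE:
            raise VolumeIOError(f"{path}: unsupported MRC mode {mode}")
        if min(mx, my, mz) <= 0 or min(cella) <= 0:
            raise VolumeIOError(
                f"{path}: missing voxel size (cella/m grid fields are zero)")
        spacing = np.array(cella) / np.array([mx, my, mz]) * 1e-4  # µm
        if not np.allclose(spacing, spacing[0], rtol=1e-4):
            raise VolumeIOError(
                f"{path}: anisotropic voxel spacing {spacing} µm not supported")
        fh.seek(1024 + nsymbt)
        data = np.frombuffer(fh.read(), dtype=_MRC_DTYPE_FROM_MODE[mode],
                             count=nx * ny * nz).reshape(nz, ny, nx)
    origin = (oz * 1e-4, oy * 1e-4, ox * 1e-4)
    return data.copy(), float(spacing[0]), origin


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_tiff(path: Path, data: np.ndarray, voxel_um: float,
                origin: tuple[float, float, float], kind: str,
                label_dictionary: dict[int, str] | None = None) -> None:
    tifffile.imwrite(path, np.ascontiguousarray(data))
    meta = {"voxel_um": voxel_um, "origin": list(origin), "kind": kind}
    if label_dictionary is not None:
        meta["label_dictionary"] = {str(k): v
                                    for k, v in label_dictionary.items()}
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True) + "\n")


def _read_tiff(path: Path) -> tuple[np.ndarray, float,
                                    tuple[float, float, float], dict]:
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D TIFF stack")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeIOError(
            f"{path}: missing voxel-size metadata; expected sidecar "
            f"{sidecar.name} with field 'voxel_um'")
    meta = json.loads(sidecar.read_text())
    if "voxel_um" not in meta:
        raise VolumeIOError(f"{sidecar}: missing required field 'voxel_um'")
    origin = tuple(meta.get("origin", (0.0, 0.0, 0.0)))
    return data, float(meta["voxel_um"]), origin, meta


# ---------------------------------------------------------------------------
# public volume API

def write_volume(vol: LACVolume | LabeledVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (.tif/.tiff + sidecar) or MRC (.mrc)."""
    path = Path(path)
    labeled = isinstance(vol, LabeledVolume)
    data = vol.data.astype(np.uint16) if labeled else vol.data
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_tiff(path, data, vol.voxel_um, vol.origin,
                    "labels" if labeled else "lac",
                    label_dictionary=vol.label_dictionary if labeled
                    else None)
    elif path.suffix.lower() == ".mrc":
        _write_mrc(path, data, vol.voxel_um, vol.origin)
    else:
        raise VolumeIOError(f"unknown volume format: {path.suffix!r}")
    return path


def read_volume(path: str | Path,
                kind: str | None = None) -> LACVolume | LabeledVolume:
    """Read a TIFF or MRC volume.

    ``kind`` forces interpretation ("lac" or "labels"); otherwise integer
    data (or a TIFF sidecar ``kind`` field) is read as a LabeledVolume and
    float data as a LACVolume.
    """
    path = Path(path)
    label_dict = None
    if path.suffix.lower() in (".tif", ".tiff"):
        data, voxel_um, origin, meta = _read_tiff(path)
        kind = kind or meta.get("kind")
        if "label_dictionary" in meta:
            label_dict = {int(k): v
                          for k, v in meta["label_dictionary"].items()}
    elif path.suffix.lower() == ".mrc":
        data, voxel_um, origin = _read_mrc(path)
    else:
        raise VolumeIOError(f"unknown volume format: {path.suffix!r}")
    if kind is None:
        kind = "labels" if np.issubdtype(data.dtype, np.integer) else "lac"
    if kind == "labels":
        vol = LabeledVolume(data.astype(np.int32), voxel_um, origin=origin,
                            **({"label_dictionary": label_dict}
                               if label_dict else {}))
        vol.validate_labels()
        return vol
    return LACVolume(data.astype(np.float32), voxel_um, origin=origin)


# ---------------------------------------------------------------------------
# meshes

def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an STL or PLY triangle mesh (vertices in physical µm)."""
    path = Path(path)
    mesh = trimesh.load_mesh(str(path), process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise VolumeIOError(f"{path}: does not contain a single triangle mesh")
    if path.suffix.lower() == ".stl":
        # STL duplicates vertices per facet; merge to recover topology
        mesh.merge_vertices()
    if mesh.faces.shape[1] != 3:
        raise VolumeIOError(f"{path}: non-triangular faces are not supported")
    raw = mesh.metadata.get("_ply_raw", {}) if mesh.metadata else {}
    # trimesh silently triangulates polygonal PLY faces; reject them instead
    face_data = raw.get("face", {}).get("data")
    if isinstance(face_data, dict):
        for key in ("vertex_indices", "vertex_index"):
            if key in face_data:
                lengths = [len(f) for f in face_data[key]]
                if any(n != 3 for n in lengths):
                    raise VolumeIOError(
                        f"{path}: non-triangular faces are not supported")
    elif face_data is not None and getattr(face_data, "dtype", None) is not None \
            and face_data.dtype.names:
        for key in ("vertex_indices", "vertex_index"):
            if key in (face_data.dtype.names or ()):
                col = face_data[key]
                if col.ndim == 2 and col.shape[1] != 3:
                    raise VolumeIOError(
                        f"{path}: non-triangular faces are not supported")
                if col.dtype == object and any(len(f) != 3 for f in col):
                    raise VolumeIOError(
                        f"{path}: non-triangular faces are not supported")
    # hoist extra per-vertex PLY properties (H, K, signed_distance, ...)
    vertex_data = raw.get("vertex", {}).get("data")
    if vertex_data is not None and hasattr(vertex_data, "dtype") \
            and vertex_data.dtype.names:
        for name in vertex_data.dtype.names:
            if name not in ("x", "y", "z"):
                mesh.vertex_attributes[name] = np.asarray(vertex_data[name])
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path,
               scalars: dict[str, np.ndarray] | None = None) -> Path:
    """Write STL (geometry only) or binary PLY (geometry + vertex scalars).

    ``scalars`` maps names (e.g. ``"H"``, ``"K"``, ``"signed_distance"``) to
    per-vertex float arrays; they round-trip bit-exactly through PLY.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        if scalars:
            raise VolumeIOError("STL cannot carry per-vertex scalars; use PLY")
        path.write_bytes(trimesh.exchange.stl.export_stl(mesh))
    elif suffix == ".ply":
        out = mesh.copy()
        for name, values in (scalars or {}).items():
            values = np.asarray(values)
            if values.shape[0] != len(mesh.vertices):
                raise VolumeIOError(
                    f"scalar {name!r} has {values.shape[0]} values for "
                    f"{len(mesh.vertices)} vertices")
            out.vertex_attributes[name] = values
        path.write_bytes(trimesh.exchange.ply.export_ply(
            out, encoding="binary", include_attributes=True))
    else:
        raise VolumeIOError(f"unknown mesh format: {suffix!r}")
    return path


# ---------------------------------------------------------------------------
# morphometrics tables

#: Stable column order of the per-object morphometrics CSV.
MORPHOMETRICS_COLUMNS = [
    "strain", "cell_id", "structure", "component",
    "volume_um3", "voxel_area_um2", "sphericity",
    "lac_mean", "lac_sd", "volume_fraction",
]


def write_morphometrics_table(records, path: str | Path) -> Path:
    """Write CellRecord-like mappings as a CSV with a stable column schema."""
    path = Path(path)
    rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
    frame = pd.DataFrame(rows, columns=MORPHOMETRICS_COLUMNS)
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def read_morphometrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
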