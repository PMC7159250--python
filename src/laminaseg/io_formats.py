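"""Volume, mesh, label and table I/O plus block partitioning.

Volumes are isotropic 3D scalar grids (NIfTI-1 or MINC on disk). World
coordinates are millimetres; voxel indices are 0-based and voxel *centers*
sit at ``origin + (i + 0.5) * spacing``. The y axis runs posterior→anterior.

Large histological volumes are processed in overlapping blocks so that any
cortical column (shorter than the overlap) lies entirely inside at least one
block; :func:`partition_volume` implements that contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import pandas as pd
import trimesh as _trimesh


class FormatError(ValueError):
    """Unreadable or unsupported file format."""


class GeometryError(ValueError):
    """Unsupported geometry (anisotropic voxels, non-triangular faces...)."""


class ConfigurationError(ValueError):
    """Invalid processing parameters."""


@dataclass
class Volume3D:
    """Isotropic 3D intensity volume with a world↔voxel affine mapping."""

    data: np.ndarray
    voxel_size_um: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError("volume data must be 3D")
        if self.voxel_size_um <= 0:
            raise GeometryError("voxel_size_um must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def spacing_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (voxel centers at integers)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.origin) / self.spacing_mm - 0.5

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (ijk + 0.5) * self.spacing_mm


@dataclass
class Mesh:
    """Triangulated surface, world coordinates in mm."""

    vertices: np.ndarray
    triangles: np.ndarray
    per_vertex_scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise GeometryError("triangle indices out of range")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise GeometryError("faces must be triangles")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) sorted-index array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass
class BlockSet:
    """Overlapping partition of a parent volume."""

    blocks: list[Volume3D]
    n_subdivisions: int
    overlap_mm: float
    # voxel index ranges of each block and of its non-overlapping core,
    # in parent-volume coordinates: (lo, hi) per axis, hi exclusive
    block_ranges: list[tuple[tuple[int, int], ...]]
    core_ranges: list[tuple[tuple[int, int], ...]]


# ---------------------------------------------------------------------------
# volumes

_NIFTI_EXTS = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 or MINC volume into a :class:`Volume3D`.

    Raises :class:`FormatError` for unknown formats and
    :class:`GeometryError` for anisotropic voxel grids.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    if not (_is_nifti(path) or path.suffix.lower() == ".mnc"):
        raise FormatError(f"unsupported volume format: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several exception types
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise GeometryError(f"anisotropic voxels {zooms} in {path}")
    affine = img.affine
    origin = np.asarray(affine[:3, 3], dtype=float) - 0.5 * zooms[0]
    data = np.asanyarray(img.dataobj)
    return Volume3D(data=np.asarray(data), voxel_size_um=float(zooms[0]) * 1000.0,
                    origin=origin)


def write_volume(v: Volume3D, path: str | Path) -> Path:
    """Write as NIfTI-1. MINC writing is not supported."""
    path = Path(path)
    if path.suffix.lower() == ".mnc":
        raise FormatError("writing MINC volumes is not supported; use NIfTI")
    if not _is_nifti(path):
        raise FormatError(f"unsupported volume format for writing: {path}")
    s = v.spacing_mm
    affine = np.diag([s, s, s, 1.0])
    affine[:3, 3] = v.origin + 0.5 * s
    img = nib.Nifti1Image(v.data, affine)
    img.header.set_zooms((s, s, s))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# meshes


def read_surface(path: str | Path) -> Mesh:
    """Read a GIFTI (.gii), FreeSurfer binary surf, or Wavefront OBJ mesh."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such surface file: {path}")
    name = path.name.lower()
    if name.endswith(".gii"):
        img = nib.load(str(path))
        verts = tris = None
        scalars: dict[str, np.ndarray] = {}
        for i, da in enumerate(img.darrays):
            code = da.intent
            if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = np.asarray(da.data, dtype=float)
            elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                tris = np.asarray(da.data, dtype=np.int64)
            else:
                key = da.meta.get("Name", f"scalar{i}") if da.meta else f"scalar{i}"
                scalars[key] = np.asarray(da.data)
        if verts is None or tris is None:
            raise FormatError(f"GIFTI file {path} lacks a surface")
        return Mesh(verts, tris, scalars)
    if name.endswith(".obj"):
        tm = _trimesh.load(str(path), file_type="obj", process=False)
        faces = np.asarray(tm.faces)
        if faces.shape[1] != 3:
            raise GeometryError(f"non-triangular faces in {path}")
        return Mesh(np.asarray(tm.vertices), faces)
    # fall through: FreeSurfer binary surf
    try:
        verts, tris = nib.freesurfer.io.read_geometry(str(path))
    except Exception as exc:
        raise FormatError(f"could not read surface {path}: {exc}") from exc
    return Mesh(np.asarray(verts, dtype=float), np.asarray(tris, dtype=np.int64))


def write_surface(m: Mesh, path: str | Path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".gii"):
        darrays = [
            nib.gifti.GiftiDataArray(
                m.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(
                m.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
        ]
        for key, vals in m.per_vertex_scalars.items():
            da = nib.gifti.GiftiDataArray(
                np.asarray(vals, dtype=np.float32), intent="NIFTI_INTENT_SHAPE")
            da.meta = nib.gifti.GiftiMetaData(Name=key)
            darrays.append(da)
        nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))
    elif name.endswith(".obj"):
        tm = _trimesh.Trimesh(m.vertices, m.triangles, process=False)
        tm.export(str(path), file_type="obj")
    else:
        nib.freesurfer.io.write_geometry(str(path), m.vertices, m.triangles)
    return path


# ---------------------------------------------------------------------------
# labels and tables


def read_labels(path: str | Path) -> np.ndarray:
    """Per-vertex integer labels from GIFTI label files or plain text."""
    path = Path(path)
    if path.name.lower().endswith(".gii"):
        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=np.int64)
    return np.loadtxt(str(path), dtype=np.int64)


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    labels = np.asarray(labels, dtype=np.int32)
    if path.name.lower().endswith(".gii"):
        da = nib.gifti.GiftiDataArray(labels, intent="NIFTI_INTENT_LABEL")
        nib.save(nib.gifti.GiftiImage(darrays=[da]), str(path))
    else:
        np.savetxt(str(path), labels, fmt="%d")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# partitioning and downsampling


def partition_volume(v: Volume3D, n_subdivisions: int,
                     overlap_mm: float = 0.0) -> BlockSet:
    """Split a volume into ``n³`` overlapping blocks.

    Cores (the non-overlapping parts) tile the parent exactly; each block is
    its core expanded by ``ceil(overlap_mm / spacing)`` voxels on every side
    (clipped at the volume border), so any segment shorter than ``overlap_mm``
    lies entirely within at least one block.
    """
    if n_subdivisions < 1:
        raise ConfigurationError("n_subdivisions must be >= 1")
    if overlap_mm < 0:
        raise ConfigurationError("overlap_mm must be >= 0")
    pad = math.ceil(overlap_mm / v.spacing_mm - 1e-9) if overlap_mm > 0 else 0
    shape = v.shape
    core_edges = []
    for ax in range(3):
        cuts = np.linspace(0, shape[ax], n_subdivisions + 1).round().astype(int)
        if np.any(np.diff(cuts) <= pad) and n_subdivisions > 1:
            raise ConfigurationError(
                f"overlap {overlap_mm} mm exceeds the block core size on axis {ax}")
        core_edges.append(cuts)

    blocks: list[Volume3D] = []
    block_ranges: list[tuple[tuple[int, int], ...]] = []
    core_ranges: list[tuple[tuple[int, int], ...]] = []
    for i in range(n_subdivisions):
        for j in range(n_subdivisions):
            for k in range(n_subdivisions):
                core = tuple(
                    (int(core_edges[ax][idx]), int(core_edges[ax][idx + 1]))
                    for ax, idx in enumerate((i, j, k)))
                blk = tuple(
                    (max(0, lo - pad), min(shape[ax], hi + pad))
                    for ax, (lo, hi) in enumerate(core))
                sl = tuple(slice(lo, hi) for lo, hi in blk)
                origin = v.origin + np.array([b[0] for b in blk]) * v.spacing_mm
                blocks.append(Volume3D(v.data[sl].copy(), v.voxel_size_um, origin))
                block_ranges.append(blk)
                core_ranges.append(core)
    return BlockSet(blocks, n_subdivisions, overlap_mm, block_ranges, core_ranges)


def reassemble_cores(bs: BlockSet, shape: tuple[int, int, int]) -> np.ndarray:
    """Stitch the block cores back into a parent-sized array."""
    out = np.empty(shape, dtype=bs.blocks[0].data.dtype)
    for vol, blk, core in zip(bs.blocks, bs.block_ranges, bs.core_ranges):
        src = tuple(slice(c[0] - b[0], c[1] - b[0]) for b, c in zip(blk, core))
        dst = tuple(slice(c[0], c[1]) for c in core)
        out[dst] = vol.data[src]
    return out


def downsample_volume(v: Volume3D, target_um: float) -> Volume3D:
    """Block-mean pooling to a coarser isotropic resolution.

    ``target_um`` must be an integer multiple of the current voxel size.
    Edge blocks that do not divide evenly are averaged over the voxels
    actually present (output dimensions are ceil(n / factor)).
    """
    ratio = target_um / v.voxel_size_um
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6 or factor < 1:
        raise ConfigurationError(
            f"target {target_um} µm is not an integer multiple of "
            f"{v.voxel_size_um} µm")
    if factor == 1:
        return Volume3D(v.data.copy(), v.voxel_size_um, v.origin.copy())
    data = v.data.astype(np.float64)
    for ax in range(3):
        n = data.shape[ax]
        idx = np.arange(0, n, factor)
        sums = np.add.reduceat(data, idx, axis=ax)
        counts = np.minimum(idx + factor, n) - idx
        shape = [1, 1, 1]
        shape[ax] = len(idx)
        data = sums / counts.reshape(shape)
    return Volume3D(data, target_um, v.origin.copy())
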