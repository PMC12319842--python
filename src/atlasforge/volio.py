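"""Volume containers, NIfTI/NRRD I/O and grid-level preprocessing operators.

Conventions
-----------
* Voxel indices are 0-based; the world coordinate (µm) of voxel ``i`` along an
  axis is ``origin + i * voxel_size`` (voxel-centre convention).
* Axis roles name the anatomical direction each array axis runs along:
  ``rostrocaudal``, ``dorsoventral``, ``leftright``.  Index 0 on the
  left-right axis is the left side.
* NIfTI headers store spacing in mm (converted to µm here); NRRD spacing is
  taken as µm unless overridden.
"""
from __future__ import annotations

import gzip as _gzip
import re
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .transforms import DeformationField

AXIS_ROLES = ("rostrocaudal", "dorsoventral", "leftright")


@dataclass(frozen=True)
class GridMeta:
    """Physical metadata of a voxel grid (all lengths in µm)."""

    voxel_size: tuple  # µm per axis
    origin: tuple = None  # world position of voxel (0,...,0), µm
    axis_roles: tuple = AXIS_ROLES
    shape: tuple = None

    def __post_init__(self):
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size))
        object.__setattr__(self, "voxel_size", vs)
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be positive, got {vs}")
        origin = self.origin if self.origin is not None else (0.0,) * len(vs)
        object.__setattr__(self, "origin", tuple(float(o) for o in origin))
        roles = tuple(self.axis_roles)[: len(vs)]
        object.__setattr__(self, "axis_roles", roles)
        if len(set(roles)) != len(roles):
            raise ValueError("axis roles must be distinct")
        if self.shape is not None:
            object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def ndim(self) -> int:
        return len(self.voxel_size)

    def axis_of(self, role: str) -> int:
        try:
            return self.axis_roles.index(role)
        except ValueError:
            raise ValueError(f"no axis with role {role!r} (have {self.axis_roles})")

    def world(self, index) -> np.ndarray:
        """World coordinate (µm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, float) * np.asarray(self.voxel_size)

    def index(self, world) -> np.ndarray:
        """Fractional voxel index of a world coordinate (µm)."""
        return (np.asarray(world, float) - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``shape + (ndim,)``."""
        if self.shape is None:
            raise ValueError("meta has no shape attached")
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in self.shape],
                                   indexing="ij"), axis=-1).astype(float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def with_shape(self, shape) -> "GridMeta":
        return replace(self, shape=tuple(int(s) for s in shape))


@dataclass
class IntensityVolume:
    values: np.ndarray
    meta: GridMeta

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity volume contains non-finite values")
        self.meta = self.meta.with_shape(self.values.shape)

    @property
    def data(self):
        return self.values

    def foreground(self) -> np.ndarray:
        return self.values != 0


@dataclass
class LabeledVolume:
    labels: np.ndarray
    meta: GridMeta

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("labels must be integers")
            labels = np.round(labels).astype(np.int64)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.labels = labels.astype(np.int64, copy=False)
        self.meta = self.meta.with_shape(labels.shape)

    @property
    def data(self):
        return self.labels

    def foreground(self) -> np.ndarray:
        return self.labels != 0

    def label_counts(self) -> dict:
        ids, counts = np.unique(self.labels[self.labels != 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


Volume = (IntensityVolume, LabeledVolume)


# ---------------------------------------------------------------------------
# I/O — NIfTI via nibabel, NRRD via a small built-in codec
# ---------------------------------------------------------------------------

def _roles_to_str(roles):
    return ",".join(roles)


def _roles_from_str(s, ndim):
    parts = tuple(p for p in s.split(",") if p)
    return parts if len(parts) == ndim else AXIS_ROLES[:ndim]


def read_volume(path, kind: str | None = None, nrrd_units_um: bool = True):
    """Read a NIfTI or NRRD file into an Intensity- or LabeledVolume.

    Integer-typed files load as :class:`LabeledVolume`, floating point as
    :class:`IntensityVolume`; pass ``kind='intensity'``/``'labels'`` to
    override.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:data.ndim]
        spacing = tuple(float(z) * 1000.0 for z in zooms)  # mm → µm
        origin = tuple(float(v) * 1000.0 for v in img.affine[:data.ndim, data.ndim])
        descrip = img.header["descrip"].tobytes().decode("ascii", "ignore").rstrip("\x00")
        m = re.search(r"roles=([a-z,]+)", descrip)
        roles = _roles_from_str(m.group(1), data.ndim) if m else AXIS_ROLES[:data.ndim]
    elif name.endswith(".nrrd"):
        data, header = _read_nrrd(path)
        spacing = header["spacing"]
        if not nrrd_units_um:
            spacing = tuple(s * 1000.0 for s in spacing)
        origin = header.get("origin", (0.0,) * data.ndim)
        roles = _roles_from_str(header.get("axis roles", ""), data.ndim)
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing in {path}: {spacing}")
    meta = GridMeta(spacing, origin, roles, data.shape)
    is_int = np.issubdtype(data.dtype, np.integer)
    if kind == "labels" or (kind is None and is_int):
        return LabeledVolume(data, meta)
    return IntensityVolume(data, meta)


def write_volume(vol, path, dtype=None) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd).

    Labels are written losslessly as integers; asking for a float dtype on a
    labelled volume is refused.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabeledVolume):
        if dtype is not None and not np.issubdtype(np.dtype(dtype), np.integer):
            raise ValueError("labels must be written with an integer dtype")
        data = vol.labels.astype(dtype or np.uint32)
    else:
        data = vol.values.astype(dtype or np.float32)
    meta = vol.meta
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        for ax in range(meta.ndim):
            affine[ax, ax] = meta.voxel_size[ax] / 1000.0  # µm → mm
            affine[ax, 3] = meta.origin[ax] / 1000.0
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(tuple(v / 1000.0 for v in meta.voxel_size))
        img.header["descrip"] = f"roles={_roles_to_str(meta.axis_roles)}".encode()
        nib.save(img, str(path))
    elif name.endswith(".nrrd"):
        _write_nrrd(path, data, meta)
    else:
        raise ValueError(f"unsupported volume format: {path}")


_NRRD_TYPES = {
    "uint8": np.uint8, "uint16": np.uint16, "uint32": np.uint32,
    "int16": np.int16, "int32": np.int32, "int64": np.int64,
    "float": np.float32, "double": np.float64,
    "unsigned char": np.uint8, "unsigned int": np.uint32,
    "unsigned short": np.uint16,
}


def _read_nrrd(path):
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path} is not an NRRD file")
        header = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, val = text.partition(":")
            header[key.strip().lower()] = val.lstrip("= ").strip()
        raw = fh.read()
    dtype = _NRRD_TYPES[header["type"]]
    sizes = tuple(int(s) for s in header["sizes"].split())
    encoding = header.get("encoding", "raw")
    if encoding == "raw":
        buf = raw
    elif encoding in ("gzip", "gz"):
        buf = _gzip.decompress(raw)
    else:
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    data = np.frombuffer(buf, dtype=np.dtype(dtype).newbyteorder("<"))
    data = data.reshape(sizes, order="F")  # NRRD sizes are fastest-first
    spacing = (1.0,) * len(sizes)
    if "space directions" in header:
        dirs = re.findall(r"\(([^)]*)\)", header["space directions"])
        spacing = tuple(float(max(abs(float(x)) for x in d.split(",")))
                        for d in dirs)
    elif "spacings" in header:
        spacing = tuple(float(s) for s in header["spacings"].split())
    out = {"spacing": spacing}
    if "space origin" in header:
        out["origin"] = tuple(float(x) for x in
                              header["space origin"].strip("()").split(","))
    if "axis roles" in header:
        out["axis roles"] = header["axis roles"]
    return np.ascontiguousarray(data), out


def _write_nrrd(path, data, meta: GridMeta) -> None:
    inv = {np.dtype(v).name: k for k, v in _NRRD_TYPES.items()
           if k in ("uint8", "uint16", "uint32", "int16", "int32", "int64",
                    "float", "double")}
    tname = inv[np.dtype(data.dtype).name]
    dirs = " ".join("(" + ",".join(str(meta.voxel_size[a]) if a == ax else "0"
                                   for a in range(meta.ndim)) + ")"
                    for ax in range(meta.ndim))
    lines = [
        "NRRD0004",
        f"type: {tname}",
        f"dimension: {data.ndim}",
        f"sizes: {' '.join(str(s) for s in data.shape)}",
        "encoding: gzip",
        "endian: little",
        f"space dimension: {meta.ndim}",
        f"space directions: {dirs}",
        f"space origin: ({','.join(str(o) for o in meta.origin)})",
        f"axis roles: {_roles_to_str(meta.axis_roles)}",
    ]
    payload = _gzip.compress(np.asfortranarray(data).tobytes(order="F"))
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(payload)


# ---------------------------------------------------------------------------
# Grid-level preprocessing operators
# ---------------------------------------------------------------------------

def _blocks(arr, factor):
    """Pad with zeros to a multiple of ``factor`` and return a view of shape
    coarse_shape + block_shape."""
    factor = np.broadcast_to(np.asarray(factor, int), (arr.ndim,))
    if np.any(factor < 1):
        raise ValueError("block factor must be >= 1")
    pad = [(0, (-s) % f) for s, f in zip(arr.shape, factor)]
    if any(p[1] for p in pad):
        arr = np.pad(arr, pad, mode="constant")
    coarse = tuple(s // f for s, f in zip(arr.shape, factor))
    newshape = []
    for c, f in zip(coarse, factor):
        newshape.extend([c, f])
    view = arr.reshape(newshape)
    # bring block axes last
    order = list(range(0, 2 * arr.ndim, 2)) + list(range(1, 2 * arr.ndim, 2))
    return view.transpose(order), coarse, factor


def downsample_labels(ann: LabeledVolume, factor) -> LabeledVolume:
    """Block-majority label downsampling.

    Each output voxel takes the most frequent label of its block (background
    included); ties break toward the smallest label id.
    """
    blocks, coarse, factor = _blocks(ann.labels, factor)
    flat = blocks.reshape(*coarse, -1)
    labels = np.unique(ann.labels)
    counts = np.stack([(flat == lab).sum(axis=-1) for lab in labels], axis=-1)
    out = labels[np.argmax(counts, axis=-1)]
    meta = GridMeta(tuple(v * f for v, f in zip(ann.meta.voxel_size, factor)),
                    ann.meta.origin, ann.meta.axis_roles)
    return LabeledVolume(out, meta)


def downsample_intensity(vol: IntensityVolume, factor) -> IntensityVolume:
    """Block-mean intensity downsampling."""
    blocks, coarse, factor = _blocks(vol.values, factor)
    out = blocks.reshape(*coarse, -1).mean(axis=-1)
    meta = GridMeta(tuple(v * f for v, f in zip(vol.meta.voxel_size, factor)),
                    vol.meta.origin, vol.meta.axis_roles)
    return IntensityVolume(out, meta)


_CONN = {6: 1, 18: 2, 26: 3}


def clean_border_voxels(ann: LabeledVolume, min_component: int = 5,
                        connectivity: int = 26):
    """Remove small isolated same-label islands (stray border voxels).

    A connected component of a label is removed when it is smaller than
    ``min_component`` voxels *and* not face-adjacent to a larger component of
    the same label.  Returns ``(cleaned volume, removed voxel count)``.
    """
    if min_component < 1:
        raise ValueError("min_component must be >= 1")
    struct = ndimage.generate_binary_structure(ann.labels.ndim, _CONN[connectivity])
    face = ndimage.generate_binary_structure(ann.labels.ndim, 1)
    out = ann.labels.copy()
    removed = 0
    for lab in np.unique(ann.labels):
        if lab == 0:
            continue
        mask = ann.labels == lab
        comp, n = ndimage.label(mask, structure=struct)
        if n <= 1:
            continue
        sizes = np.bincount(comp.ravel())
        small = [i for i in range(1, n + 1) if sizes[i] < min_component]
        if not small:
            continue
        large_mask = mask & ~np.isin(comp, small)
        near_large = ndimage.binary_dilation(large_mask, structure=face)
        for i in small:
            cmask = comp == i
            if not (cmask & near_large).any():
                out[cmask] = 0
                removed += int(sizes[i])
    return LabeledVolume(out, ann.meta), removed


def symmetrize(vol, source_hemisphere: str = "right", midplane_axis: int | None = None):
    """Mirror one hemisphere onto the other about the left-right midplane.

    Index 0 along the left-right axis is the left side; the ``right``
    hemisphere is the high-index half.  The output is exactly mirror
    symmetric (for odd extents the centre plane maps to itself).
    """
    meta = vol.meta
    axis = meta.axis_of("leftright") if midplane_axis is None else midplane_axis
    if meta.axis_roles[axis] != "leftright":
        raise ValueError(f"axis {axis} has role {meta.axis_roles[axis]!r}, "
                         "symmetrization requires the left-right axis")
    data = vol.data.copy()
    n = data.shape[axis]
    mirrored = np.flip(data, axis=axis)
    half = n // 2
    sl = [slice(None)] * data.ndim
    if source_hemisphere == "right":
        sl[axis] = slice(0, half)  # overwrite left with mirrored right
    elif source_hemisphere == "left":
        sl[axis] = slice(n - half, n)
    else:
        raise ValueError("source_hemisphere must be 'left' or 'right'")
    data[tuple(sl)] = mirrored[tuple(sl)]
    cls = type(vol)
    return cls(data, meta)


def pad(vol, slabs_per_face, fill=0):
    """Grow the grid by whole voxel slabs per face.

    ``slabs_per_face`` is a sequence of (before, after) counts per axis.  The
    origin shifts by ``-before × voxel_size`` on every padded axis so world
    coordinates of existing content are preserved (e.g. 14 rostral slabs of
    25 µm shift the origin by −350 µm).
    """
    slabs = [(int(b), int(a)) for b, a in slabs_per_face]
    if any(b < 0 or a < 0 for b, a in slabs):
        raise ValueError("slab counts must be non-negative")
    data = np.pad(vol.data, slabs, mode="constant", constant_values=fill)
    origin = tuple(o - b * v for o, (b, _), v in
                   zip(vol.meta.origin, slabs, vol.meta.voxel_size))
    meta = GridMeta(vol.meta.voxel_size, origin, vol.meta.axis_roles)
    return type(vol)(data, meta)


def crop(vol, slices):
    """Crop a volume to index slices, keeping world coordinates consistent
    (origin advances by the slice starts)."""
    slices = tuple(slices)
    starts = [s.start or 0 for s in slices]
    data = vol.data[slices]
    origin = tuple(o + st * v for o, st, v in
                   zip(vol.meta.origin, starts, vol.meta.voxel_size))
    meta = GridMeta(vol.meta.voxel_size, origin, vol.meta.axis_roles)
    return type(vol)(data, meta)


def bounding_box(mask, margin: int = 0, shape=None):
    """Index slices of the tight bounding box of a boolean mask, grown by
    ``margin`` voxels and clipped to ``shape``."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    shape = shape or mask.shape
    slices = []
    for ax in range(mask.ndim):
        proj = mask.any(axis=tuple(i for i in range(mask.ndim) if i != ax))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + 1 + margin, shape[ax])
        slices.append(slice(lo, hi))
    return tuple(slices)


def upsample_field(fld: DeformationField, factor) -> DeformationField:
    """Linearly interpolate a displacement field onto a finer grid.

    Displacement *magnitudes* are physical (µm) and are not rescaled; only
    the sampling grid is refined by the integer ``factor`` per axis.
    """
    factor = np.broadcast_to(np.asarray(factor, float), (fld.ndim,))
    if np.any(factor < 1):
        raise ValueError("upsampling factor must be >= 1")
    coarse_shape = fld.shape
    fine_shape = tuple(int(round(s * f)) for s, f in zip(coarse_shape, factor))
    # fine voxel j centre sits at coarse fractional index j / f
    grids = [np.arange(n) / f for n, f in zip(fine_shape, factor)]
    mesh = np.meshgrid(*grids, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    comps = [ndimage.map_coordinates(fld.displacements[..., c], coords,
                                     order=1, mode="nearest").reshape(fine_shape)
             for c in range(fld.ndim)]
    fine_vs = tuple(v / f for v, f in zip(fld.meta.voxel_size, factor))
    meta = GridMeta(fine_vs, fld.meta.origin, fld.meta.axis_roles, fine_shape)
    return DeformationField(np.stack(comps, axis=-1), meta)
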