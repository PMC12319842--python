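"""Spatial transform types shared by the I/O layer and the registration engine.

World coordinates are in micrometres.  A transform maps *fixed*-space world
points to *moving*-space world points (the resampling convention): warping an
image through a transform samples the moving image at the mapped points.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class AffineTransform:
    """Affine point map ``y = M x + t`` in world (µm) coordinates."""

    matrix: np.ndarray  # (d, d) linear part
    translation: np.ndarray  # (d,) µm

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        d = self.translation.shape[0]
        if self.matrix.shape != (d, d):
            raise ValueError("matrix/translation dimensionality mismatch")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, ndim: int = 3) -> "AffineTransform":
        return cls(np.eye(ndim), np.zeros(ndim))

    @property
    def ndim(self) -> int:
        return self.translation.shape[0]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map world points, shape (..., d)."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + self.translation

    def compose_affine(self, inner: "AffineTransform") -> "AffineTransform":
        """Point map of the result is ``inner ∘ self`` (see :func:`compose`)."""
        return AffineTransform(inner.matrix @ self.matrix,
                               inner.matrix @ self.translation + inner.translation)

    def invert(self) -> "AffineTransform":
        minv = np.linalg.inv(self.matrix)
        return AffineTransform(minv, -minv @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """Homogeneous (d+1)×(d+1) matrix."""
        d = self.ndim
        h = np.eye(d + 1)
        h[:d, :d] = self.matrix
        h[:d, d] = self.translation
        return h

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (np.allclose(self.matrix, np.eye(self.ndim), atol=tol)
                and np.allclose(self.translation, 0.0, atol=tol))

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix.tolist(),
                       "translation": self.translation.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(np.array(doc["matrix"]), np.array(doc["translation"]))


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (µm) on the fixed grid.

    ``displacements`` has shape ``grid_shape + (d,)``.  The point map is
    ``x ↦ x + u(x)`` with ``u`` interpolated linearly between voxel centres.
    """

    displacements: np.ndarray
    meta: "GridMeta"  # forward ref; see volio.GridMeta

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("deformation field contains non-finite values")
        d = self.displacements.shape[-1]
        if self.displacements.ndim != d + 1:
            raise ValueError("displacement array must have shape grid + (ndim,)")

    @property
    def ndim(self) -> int:
        return self.displacements.shape[-1]

    @property
    def shape(self) -> tuple:
        return self.displacements.shape[:-1]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map world points (µm) through ``x + u(x)``; u sampled linearly."""
        pts = np.asarray(pts, dtype=float)
        idx = (pts - self.meta.origin) / self.meta.voxel_size  # fractional voxel
        coords = idx.reshape(-1, self.ndim).T
        out = pts.reshape(-1, self.ndim).copy()
        for c in range(self.ndim):
            out[:, c] += map_coordinates(self.displacements[..., c], coords,
                                         order=1, mode="nearest")
        return out.reshape(pts.shape)

    def max_displacement(self) -> float:
        return float(np.sqrt((self.displacements ** 2).sum(axis=-1)).max())


def compose(outer, inner, out_meta=None):
    """Compose two transforms so that warping an image through the result
    equals warping through ``inner`` first, then ``outer``.

    With the resampling convention this means the composed *point map* is
    ``p ↦ pm_inner(pm_outer(p))``.  Affine∘affine stays affine; any mix
    involving a field is materialised as a :class:`DeformationField` on
    ``out_meta`` (default: the outer field's grid).
    """
    if isinstance(outer, AffineTransform) and isinstance(inner, AffineTransform):
        return outer.compose_affine(inner)
    if out_meta is None:
        for t in (outer, inner):
            if isinstance(t, DeformationField):
                out_meta = t.meta
                break
        else:  # pragma: no cover - guarded by isinstance checks above
            raise ValueError("no grid available for composed field")
    pts = out_meta.world_grid()
    mapped = outer.apply_points(pts)
    mapped = inner.apply_points(mapped)
    return DeformationField(mapped - pts, out_meta)
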