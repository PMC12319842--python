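"""Population-average template construction from 2D sections.

The template is initialized as the voxel-wise mean of co-registered reference
volumes.  Each 2D section is nonlinearly registered to its anatomical plane
in the *fixed* initialization (never a progressively updated average, so the
result is independent of section order), its warped intensities are summed
into an accumulator, and a per-voxel contribution count is incremented where
the section has tissue.  The final template divides ``init + sum`` by
``1 + count`` wherever at least one section contributed — the initialization
counts as one contributing dataset — and falls back to the initialization
elsewhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .register import RegistrationParams, demons_displacement
from .volio import GridMeta, IntensityVolume
from scipy import ndimage


@dataclass
class SectionRecord:
    """A 2D section with its position in the reference grid."""

    image: np.ndarray
    plane_axis: int
    plane_index: int
    source_id: str = ""
    true_warp: np.ndarray | None = None  # generator bookkeeping only

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("section image must be 2D")


@dataclass
class Accumulator:
    """Per-voxel intensity sums and contribution counts over the init volume."""

    sum_volume: np.ndarray
    count_volume: np.ndarray
    init_volume: np.ndarray
    meta: GridMeta

    @classmethod
    def empty(cls, init: IntensityVolume) -> "Accumulator":
        return cls(np.zeros_like(init.values),
                   np.zeros(init.values.shape, dtype=np.int64),
                   init.values.copy(), init.meta)

    def validate(self):
        if (self.count_volume < 0).any():
            raise ValueError("negative contribution count")
        if np.abs(self.sum_volume[self.count_volume == 0]).max(initial=0.0) > 0:
            raise ValueError("sum without contribution")


def init_average(volumes) -> IntensityVolume:
    """Voxel-wise arithmetic mean of co-registered volumes on one grid."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].values.shape
    for v in volumes[1:]:
        if v.values.shape != shape:
            raise ValueError("volumes must share a grid")
    mean = np.mean([v.values for v in volumes], axis=0)
    return IntensityVolume(mean, volumes[0].meta)


def _plane(arr, axis, index):
    return np.take(arr, index, axis=axis)


def _register_section(sec_img, ref_img, spacing, params):
    """2D demons alignment of a section to its reference plane; returns the
    warped image (identity warp if either image is too empty to drive it)."""
    if (sec_img != 0).sum() < 16 or np.ptp(ref_img) == 0 or np.ptp(sec_img) == 0:
        return sec_img
    disp_vox, _ = demons_displacement(sec_img, ref_img, spacing, params)
    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in sec_img.shape],
                      indexing="ij")
    coords = [idx[c] + disp_vox[..., c] for c in range(2)]
    return ndimage.map_coordinates(sec_img, coords, order=1, mode="constant",
                                   cval=0.0)


def accumulate_section(acc: Accumulator, sec: SectionRecord,
                       params: RegistrationParams | None = None,
                       register: bool = True) -> Accumulator:
    """Register one section to its plane of the init volume and add it in.

    The count increments only where the warped section has tissue, so partial
    sections do not dilute uncovered voxels.  Empty sections are skipped.
    ``register=False`` accumulates sections as-is (for pre-aligned data).
    Returns ``acc`` (modified in place) for chaining.
    """
    params = params or RegistrationParams(metric="ssd", pyramid_levels=(2, 1),
                                          iterations=(30, 15))
    n = acc.init_volume.shape[sec.plane_axis]
    if not 0 <= sec.plane_index < n:
        raise ValueError(f"plane index {sec.plane_index} outside grid of {n}")
    if not (sec.image != 0).any():
        return acc  # empty section: nothing to add
    ref = _plane(acc.init_volume, sec.plane_axis, sec.plane_index)
    spacing = [s for i, s in enumerate(acc.meta.voxel_size)
               if i != sec.plane_axis]
    warped = (_register_section(sec.image, ref, spacing, params)
              if register else sec.image)
    covered = warped != 0
    sl = [slice(None)] * acc.init_volume.ndim
    sl[sec.plane_axis] = sec.plane_index
    sl = tuple(sl)
    plane_sum = acc.sum_volume[sl]
    plane_cnt = acc.count_volume[sl]
    plane_sum[covered] += warped[covered]
    plane_cnt[covered] += 1
    acc.sum_volume[sl] = plane_sum
    acc.count_volume[sl] = plane_cnt
    return acc


def normalize(acc: Accumulator, include_init: bool = True) -> IntensityVolume:
    """Average the accumulator: ``(init + sum) / (1 + count)`` where sections
    contributed (the init reference counts as one dataset), init elsewhere."""
    acc.validate()
    out = acc.init_volume.copy()
    covered = acc.count_volume > 0
    if include_init:
        out[covered] = ((acc.init_volume[covered] + acc.sum_volume[covered])
                        / (1.0 + acc.count_volume[covered]))
    else:
        out[covered] = acc.sum_volume[covered] / acc.count_volume[covered]
    return IntensityVolume(out, acc.meta)


def build_template(init_volumes, sections, params=None, include_init=True,
                   register=True):
    """Full build: init average → accumulate every section → normalize.

    Returns ``(average volume, count volume, report)`` where the report lists
    sections used/skipped, per-plane contribution counts and the fraction of
    init-foreground voxels covered by at least one section.
    """
    init = init_average(init_volumes)
    acc = Accumulator.empty(init)
    used, skipped = [], []
    ordered = sorted(sections, key=lambda s: (s.source_id, s.plane_index))
    for sec in ordered:
        before = acc.count_volume.sum()
        accumulate_section(acc, sec, params, register=register)
        (used if acc.count_volume.sum() > before else skipped).append(
            (sec.source_id, sec.plane_index))
    avg = normalize(acc, include_init=include_init)
    fg = init.values != 0
    report = {
        "sections_used": used,
        "sections_skipped": skipped,
        "per_plane_counts": {
            int(i): int(np.take(acc.count_volume, i, axis=0).max())
            for i in range(acc.count_volume.shape[0])},
        "coverage_fraction": float((acc.count_volume[fg] > 0).mean())
        if fg.any() else 0.0,
    }
    return avg, IntensityVolume(acc.count_volume.astype(float), acc.meta), report
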