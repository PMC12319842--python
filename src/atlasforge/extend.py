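"""Rostral/caudal tissue extension and annotation-volume merging.

A truncated target volume (tissue missing at one end of the rostro-caudal
axis) is completed from a donor volume of the same stain: the donor is
globally affine-aligned, both are cropped to the full region mask, the donor
is masked with the *truncated* annotation so only mutually present tissue
drives a nonlinear registration, the resulting field is applied to the
unmasked donor, intensities are histogram-matched over the overlap, missing
voxels are copied in, and a three-voxel slab at the junction is averaged to
remove any step.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .register import (RegistrationParams, apply_transform, register_affine,
                       register_nonlinear)
from .volio import IntensityVolume, LabeledVolume, bounding_box, crop


def histogram_match(src: IntensityVolume, ref: IntensityVolume,
                    mask=None, ref_mask=None, nbins: int = 256) -> IntensityVolume:
    """Monotone intensity remapping of ``src`` so its cumulative distribution
    over ``mask`` matches ``ref``'s over ``ref_mask`` (256 quantile bins).

    The mapping is applied to the whole volume; zero (background) stays zero.
    """
    mask = src.values != 0 if mask is None else np.asarray(mask, bool)
    ref_mask = ref.values != 0 if ref_mask is None else np.asarray(ref_mask, bool)
    if not mask.any() or not ref_mask.any():
        raise ValueError("histogram matching requires non-empty masks")
    s = src.values[mask]
    if np.ptp(s) == 0:
        raise ValueError("source intensities are constant over the mask")
    q = np.linspace(0.0, 1.0, nbins)
    s_q = np.quantile(s, q)
    r_q = np.quantile(ref.values[ref_mask], q)
    s_q, idx = np.unique(s_q, return_index=True)
    out = np.where(src.values != 0, np.interp(src.values, s_q, r_q[idx]), 0.0)
    return IntensityVolume(out, src.meta)


def blend_junction(base: IntensityVolume, addition: IntensityVolume,
                   axis: int, plane_index: int, thickness: int = 3,
                   mask=None) -> IntensityVolume:
    """Average two sources over a ``thickness``-voxel slab centred at
    ``plane_index`` along ``axis``; everything outside the slab is ``base``.

    Where only one source has tissue inside the slab, that source is kept.
    """
    if base.values.shape != addition.values.shape:
        raise ValueError("volumes must share a grid")
    half = thickness // 2
    lo, hi = plane_index - half, plane_index + half + 1
    if lo < 0 or hi > base.values.shape[axis]:
        raise ValueError("junction slab exceeds volume bounds")
    out = base.values.copy()
    sl = [slice(None)] * out.ndim
    sl[axis] = slice(lo, hi)
    sl = tuple(sl)
    b, a = out[sl], addition.values[sl]
    both = (b != 0) & (a != 0)
    blended = np.where(both, 0.5 * (b + a), np.where(b != 0, b, a))
    if mask is not None:
        blended = np.where(np.asarray(mask, bool)[sl], blended, b)
    out[sl] = blended
    return IntensityVolume(out, base.meta)


@dataclass
class ExtensionReport:
    steps: list = dfield(default_factory=list)
    filled_voxels: int = 0
    junction_plane: int | None = None

    def log(self, msg):
        self.steps.append(msg)


def extend_region(target: IntensityVolume, donor: IntensityVolume,
                  full_mask, truncated_mask,
                  params: RegistrationParams | None = None,
                  margin: int = 4, junction_thickness: int = 3):
    """Fill the missing part of a region in ``target`` from ``donor``.

    ``full_mask`` covers the complete region; ``truncated_mask`` its part
    actually present in the target (a subset).  Returns
    ``(extended target, {'affine', 'field'}, ExtensionReport)``.
    """
    params = params or RegistrationParams(metric="ssd",
                                          pyramid_levels=(4, 2),
                                          iterations=(60, 30))
    full_mask = np.asarray(full_mask, bool)
    truncated_mask = np.asarray(truncated_mask, bool)
    if (truncated_mask & ~full_mask).any():
        raise ValueError("truncated mask must be a subset of the full mask")
    report = ExtensionReport()
    axis = target.meta.axis_of("rostrocaudal")

    # (1) global affine donor→target (rigid + scaling)
    aff = register_affine(donor, target, params, dof="similarity")
    donor_on_target = apply_transform(donor, aff, interpolation="linear",
                                      out_meta=target.meta)
    report.log("global similarity registration of donor to target")

    # (2) crop to the full-mask bounding box
    box = bounding_box(full_mask, margin=margin, shape=target.values.shape)
    tgt_c = crop(target, box)
    don_c = crop(donor_on_target, box)
    full_c = full_mask[box]
    trunc_c = truncated_mask[box]
    report.log(f"cropped to region bounding box {box}")

    # (3) mask the donor with the truncated annotation so its tissue covering
    # matches the target's; both sides take a small dilation so the shared
    # rim drives the registration rather than fighting it
    from scipy import ndimage as _ndi
    trunc_dil = _ndi.binary_dilation(trunc_c, iterations=2)
    don_masked = IntensityVolume(np.where(trunc_dil, don_c.values, 0.0),
                                 don_c.meta)
    tgt_masked = IntensityVolume(np.where(trunc_dil, tgt_c.values, 0.0),
                                 tgt_c.meta)
    if not ((don_masked.values != 0) & (tgt_masked.values != 0)).any():
        raise ValueError("no overlap between donor tissue and the truncated mask")

    # (4) nonlinear registration of the masked donor (no linear stage)
    fld = register_nonlinear(don_masked, tgt_masked, params)
    report.log("nonlinear registration of masked donor crop")

    # (5) apply the field to the unmasked donor crop
    don_warped = apply_transform(don_c, fld, interpolation="linear",
                                 out_meta=tgt_c.meta)

    # (6) histogram matching over the overlap
    overlap = trunc_c & (don_warped.values != 0) & (tgt_c.values != 0)
    don_matched = histogram_match(don_warped, tgt_c, mask=overlap,
                                  ref_mask=overlap)
    report.log("histogram matching over the overlap")

    # (7) copy donor tissue where the region is missing in the target
    out_c = tgt_c.values.copy()
    fill = full_c & ~trunc_c & (out_c == 0) & (don_matched.values != 0)
    out_c[fill] = don_matched.values[fill]
    report.filled_voxels = int(fill.sum())
    report.log(f"filled {report.filled_voxels} voxels")

    # (8) blend a three-voxel junction slab along the rostro-caudal axis,
    # centred on the first originally-populated target plane
    populated = np.where(trunc_c.any(axis=tuple(i for i in range(3) if i != axis)))[0]
    extended = IntensityVolume(out_c, tgt_c.meta)
    if populated.size and fill.any():
        fill_planes = np.where(fill.any(axis=tuple(i for i in range(3) if i != axis)))[0]
        junction = (int(populated.min()) if fill_planes.min() < populated.min()
                    else int(populated.max()))
        junction = int(np.clip(junction, junction_thickness // 2,
                               out_c.shape[axis] - junction_thickness // 2 - 1))
        extended = blend_junction(extended, don_matched, axis, junction,
                                  thickness=junction_thickness, mask=full_c)
        report.junction_plane = junction
        report.log(f"blended junction slab at plane {junction}")

    # paste the crop back into the full target grid
    out_full = target.values.copy()
    out_full[box] = extended.values
    return (IntensityVolume(out_full, target.meta),
            {"affine": aff, "field": fld}, report)


def merge_annotations(base: LabeledVolume, addon: LabeledVolume,
                      placement=None, precedence: str = "addon",
                      remap: dict | None = None):
    """Integrate an annotation volume into another.

    ``placement`` is ``None`` (same grid overlay), an affine transform, or
    ``{'mode': 'concat', 'axis': k, 'end': 'caudal'|'rostral'}`` which grows
    the grid and concatenates.  Label id spaces must be disjoint unless a
    ``remap`` (old id → new id) is given.  Returns ``(merged, overlap_count)``.
    """
    if precedence not in ("base", "addon"):
        raise ValueError("precedence must be 'base' or 'addon'")
    addon_labels = addon.labels
    if remap:
        addon_labels = addon_labels.copy()
        for old, new in remap.items():
            addon_labels[addon.labels == old] = new
    if isinstance(placement, dict) and placement.get("mode") == "concat":
        axis, end = placement["axis"], placement.get("end", "caudal")
        if base.labels.ndim != addon_labels.ndim:
            raise ValueError("dimensionality mismatch")
        parts = ([base.labels, addon_labels] if end == "caudal"
                 else [addon_labels, base.labels])
        merged = np.concatenate(parts, axis=axis)
        origin = list(base.meta.origin)
        if end == "rostral":
            origin[axis] -= addon_labels.shape[axis] * base.meta.voxel_size[axis]
        meta = base.meta.__class__(base.meta.voxel_size, tuple(origin),
                                   base.meta.axis_roles)
        return LabeledVolume(merged, meta), 0

    if placement is not None:  # affine placement onto the base grid
        addon_placed = apply_transform(
            LabeledVolume(addon_labels, addon.meta), placement,
            interpolation="nearest", out_meta=base.meta)
        addon_labels = addon_placed.labels
    if addon_labels.shape != base.labels.shape:
        raise ValueError("overlay requires a shared grid (or a placement)")
    shared_ids = (set(np.unique(base.labels)) & set(np.unique(addon_labels))
                  - {0})
    if shared_ids and not remap:
        raise ValueError(f"label id collision without remap: {sorted(shared_ids)}")
    overlap = (base.labels != 0) & (addon_labels != 0)
    merged = base.labels.copy()
    write = (addon_labels != 0) if precedence == "addon" else \
        ((addon_labels != 0) & (base.labels == 0))
    merged[write] = addon_labels[write]
    return LabeledVolume(merged, base.meta), int(overlap.sum())
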