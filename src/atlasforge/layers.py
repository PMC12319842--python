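"""Cerebellar sublayer segmentation.

Each lobule of the cerebellar cortex contains a dense granular layer (bright
in Nissl stains — high cell density) and a sparse molecular layer (dark).
The split is computed per lobule with Otsu's threshold on the intensity
histogram inside the lobule mask; the granular layer takes the above-
threshold voxels.  At fine (10 µm-class) resolution a two-voxel Purkinje
layer — one voxel from each side of the granular/molecular interface — is
synthesized along the boundary, reflecting the single-cell sheet of Purkinje
somata that a coarse grid cannot resolve.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .volio import LabeledVolume


def otsu_threshold(values, bins: int = 256) -> float:
    """Otsu's threshold: the histogram-bin boundary maximizing between-class
    variance.  Deterministic: ties break toward the lowest threshold."""
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for a constant sample")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    total = w.sum()
    omega0 = np.cumsum(w)[:-1]
    omega1 = total - omega0
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    valid = (omega0 > 0) & (omega1 > 0)
    mu0 = np.where(valid, mu_cum[:-1] / np.maximum(omega0, 1), 0.0)
    mu1 = np.where(valid, (mu_total - mu_cum[:-1]) / np.maximum(omega1, 1), 0.0)
    sigma_b = np.where(valid, omega0 * omega1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


@dataclass
class LayerEntry:
    """Layer masks of one lobule (all boolean, on the lobule's grid)."""

    granular: np.ndarray
    molecular: np.ndarray
    purkinje: np.ndarray | None = None
    threshold: float = np.nan
    flagged: bool = False

    def validate(self, lobule_mask=None):
        if (self.granular & self.molecular).any():
            raise ValueError("granular and molecular masks overlap")
        if self.purkinje is not None:
            if ((self.purkinje & self.granular).any()
                    or (self.purkinje & self.molecular).any()):
                raise ValueError("purkinje mask overlaps a source layer")
        if lobule_mask is not None:
            union = self.granular | self.molecular
            if self.purkinje is not None:
                union = union | self.purkinje
            if (union & ~np.asarray(lobule_mask, bool)).any():
                raise ValueError("layer masks leak outside the lobule")


@dataclass
class LayerLabeling:
    """Per-lobule layer masks plus the grid resolution they live on (µm)."""

    entries: dict = dfield(default_factory=dict)  # lobule id -> LayerEntry
    resolution_um: float = 25.0


def segment_lobule_layers(nissl, lobule_mask, granular_id=None,
                          molecular_id=None, island_min: int = 10,
                          unimodal_fraction: float = 0.01) -> LayerEntry:
    """Otsu split of one lobule into granular (bright) and molecular (dark)
    layers, with small isolated islands reassigned to the surrounding class.

    A lobule whose threshold puts fewer than ``unimodal_fraction`` of voxels
    into either class is flagged for review rather than rejected.
    """
    mask = np.asarray(lobule_mask, bool)
    if not mask.any():
        raise ValueError("empty lobule mask")
    vals = (nissl.values if hasattr(nissl, "values") else np.asarray(nissl))
    thr = otsu_threshold(vals[mask])
    granular = mask & (vals > thr)
    molecular = mask & ~granular
    granular, molecular = _clean_islands(granular, molecular, island_min)
    molecular, granular = _clean_islands(molecular, granular, island_min)
    n = mask.sum()
    flagged = (granular.sum() < unimodal_fraction * n
               or molecular.sum() < unimodal_fraction * n)
    if granular.sum() == 0:  # keep both classes non-empty
        flagged = True
        pick = np.unravel_index(np.argmax(np.where(molecular, vals, -np.inf)),
                                vals.shape)
        granular, molecular = granular.copy(), molecular.copy()
        granular[pick], molecular[pick] = True, False
    elif molecular.sum() == 0:
        flagged = True
        pick = np.unravel_index(np.argmin(np.where(granular, vals, np.inf)),
                                vals.shape)
        granular, molecular = granular.copy(), molecular.copy()
        molecular[pick], granular[pick] = True, False
    return LayerEntry(granular, molecular, threshold=thr, flagged=bool(flagged))


def _clean_islands(cls_mask, other_mask, island_min):
    """Reassign connected components of ``cls_mask`` smaller than
    ``island_min`` to the other class."""
    if island_min <= 1:
        return cls_mask, other_mask
    comp, n = ndimage.label(cls_mask)
    if n <= 1:
        return cls_mask, other_mask
    sizes = np.bincount(comp.ravel())
    small = np.isin(comp, [i for i in range(1, n + 1) if sizes[i] < island_min])
    return cls_mask & ~small, other_mask | (cls_mask & small)


def segment_all_lobules(nissl, ann: LabeledVolume, graph, lobule_ids,
                        island_min: int = 10) -> LayerLabeling:
    """Independent per-lobule Otsu segmentation (order-invariant)."""
    from .ontology import region_mask

    labeling = LayerLabeling(resolution_um=ann.meta.voxel_size[0])
    for rid in sorted(lobule_ids):
        mask = region_mask(ann, graph, rid, include_descendants=True)
        labeling.entries[rid] = segment_lobule_layers(nissl, mask,
                                                      island_min=island_min)
    return labeling


def insert_purkinje(labeling: LayerLabeling) -> LayerLabeling:
    """Synthesize the two-voxel Purkinje layer at fine resolution.

    The layer takes the granular voxels 6-adjacent to molecular ones plus the
    molecular voxels 6-adjacent to granular ones — one voxel from each side
    of the interface — and removes them from their source masks.
    """
    face = ndimage.generate_binary_structure(3, 1)
    out = LayerLabeling(resolution_um=labeling.resolution_um)
    for rid, entry in labeling.entries.items():
        g, m = entry.granular, entry.molecular
        near_m = ndimage.binary_dilation(m, structure=face)
        near_g = ndimage.binary_dilation(g, structure=face)
        purkinje = (g & near_m) | (m & near_g)
        if not purkinje.any():
            raise ValueError(f"lobule {rid}: granular/molecular interface is empty")
        out.entries[rid] = LayerEntry(g & ~purkinje, m & ~purkinje, purkinje,
                                      threshold=entry.threshold,
                                      flagged=entry.flagged)
    return out


def upsample_annotation(ann: LabeledVolume, factor: int,
                        smooth: bool = True) -> LabeledVolume:
    """Block-replicate labels onto a finer grid, optionally followed by one
    3×3×3 modal (majority) filter pass for spatial continuity.

    The modal filter keeps label ids exact integers and can move a label
    interface by at most one fine voxel; it never invents new ids.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    fine = ann.labels
    for ax in range(fine.ndim):
        fine = np.repeat(fine, factor, axis=ax)
    if smooth and factor > 1:
        fine = _modal_filter(fine)
    meta = ann.meta.__class__(
        tuple(v / factor for v in ann.meta.voxel_size),
        ann.meta.origin, ann.meta.axis_roles)
    return LabeledVolume(fine, meta)


def _modal_filter(labels):
    """3×3×3 majority vote per voxel; ties break toward the smallest id."""
    ids = np.unique(labels)
    counts = np.stack([ndimage.uniform_filter((labels == i).astype(np.float32),
                                              size=3, mode="nearest")
                       for i in ids], axis=0)
    return ids[np.argmax(counts, axis=0)]
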