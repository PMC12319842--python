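"""Region-by-region alignment orchestration.

The moving pair (a textured Nissl volume and its old-version annotation) is
aligned into the space of the fixed pair (a smooth average-template volume
and the new-version annotation) in three stages:

1. *Global label initialization* — a label-driven affine + nonlinear
   registration between the two annotation volumes; the transforms are
   applied to the Nissl volume (linear interpolation) and its annotation
   (nearest).
2. *Region-wise registration* — each comparable leaf region is cropped,
   masked and independently registered (affine, then multimodal nonlinear)
   from the Nissl to the template; warped regions are mosaicked into a
   reconstruction, gaps filled from parent-level registrations and finally
   from the globally initialized volume.  A dedicated per-lobule pass with
   aggressive settings handles the cerebellum.
3. *Final whole-brain pass* — one monomodal nonlinear registration of the
   initialized Nissl onto the mosaic restores tissue continuity across
   region seams.

Normalized mutual information is tracked per stage at whole-brain, region
and slice level, alongside fiducial-based target registration error.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional

import json

import numpy as np
from scipy import ndimage as _ndi
import pandas as pd

from .metrics import nmi, per_region_nmi, per_slice_nmi, tre
from .ontology import (LevelAssignment, StructureGraph, assign_levels,
                       descendants)
from .register import (RegistrationParams, apply_transform, register_affine,
                       register_labels, register_nonlinear)
from .transforms import AffineTransform, DeformationField
from .volio import IntensityVolume, LabeledVolume, bounding_box, crop

DEFAULT_MIN_REGION_VOXELS = 50
DEFAULT_MARGIN = 5


@dataclass
class RegionTransform:
    level: str  # 'leaf' | 'parent' | 'lobule'
    affine: Optional[AffineTransform]
    field: Optional[DeformationField]
    metric_after: float
    nmi_before: float = np.nan
    nmi_after: float = np.nan
    skipped: bool = False


@dataclass
class AlignmentReport:
    """Multi-scale evaluation of an alignment run."""

    nmi_whole_before: float = np.nan
    nmi_whole_after: float = np.nan
    per_region: Optional[pd.DataFrame] = None
    per_slice: dict = dfield(default_factory=dict)  # incidence -> DataFrame
    tre_before: Optional[pd.DataFrame] = None
    tre_after: Optional[pd.DataFrame] = None
    conflicts: int = 0
    fill_counts: dict = dfield(default_factory=dict)

    def to_json(self, path):
        doc = {
            "nmi_whole_before": self.nmi_whole_before,
            "nmi_whole_after": self.nmi_whole_after,
            "conflicts": self.conflicts,
            "fill_counts": self.fill_counts,
        }
        if self.per_region is not None:
            doc["per_region"] = self.per_region.to_dict(orient="records")
        for inc, df in self.per_slice.items():
            doc[f"per_slice_{inc}"] = df.to_dict(orient="records")
        for name, df in (("tre_before", self.tre_before),
                         ("tre_after", self.tre_after)):
            if df is not None:
                doc[name] = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            doc = json.load(fh)
        rep = cls(nmi_whole_before=doc["nmi_whole_before"],
                  nmi_whole_after=doc["nmi_whole_after"],
                  conflicts=doc.get("conflicts", 0),
                  fill_counts=doc.get("fill_counts", {}))
        if "per_region" in doc:
            rep.per_region = pd.DataFrame(doc["per_region"])
        for key, val in doc.items():
            if key.startswith("per_slice_"):
                rep.per_slice[key[len("per_slice_"):]] = pd.DataFrame(val)
        if "tre_before" in doc:
            rep.tre_before = pd.DataFrame(doc["tre_before"])
        if "tre_after" in doc:
            rep.tre_after = pd.DataFrame(doc["tre_after"])
        return rep


# ---------------------------------------------------------------------------
# Stage 1: global label-driven initialization
# ---------------------------------------------------------------------------

def global_label_init(nissl: IntensityVolume, ann_v2: LabeledVolume,
                      ann_v3: LabeledVolume,
                      params: RegistrationParams | None = None):
    """Annotation-to-annotation affine + nonlinear registration, applied to
    the Nissl volume (linear) and its annotation (nearest).

    Returns ``(nissl_init, ann_v2_init, {'affine', 'field'})``.
    """
    params = params or RegistrationParams(metric="ssd")
    aff, fld = register_labels(ann_v2, ann_v3, params)
    chain = [fld, aff]
    nissl_init = apply_transform(nissl, chain, interpolation="linear",
                                 out_meta=ann_v3.meta)
    ann_v2_init = apply_transform(ann_v2, chain, interpolation="nearest",
                                  out_meta=ann_v3.meta)
    return nissl_init, ann_v2_init, {"affine": aff, "field": fld}


# ---------------------------------------------------------------------------
# Stage 2: region-wise registration and reconstruction
# ---------------------------------------------------------------------------

def _masked_crop(vol, mask, box):
    sub = crop(vol, box)
    data = np.where(mask[box], sub.data, 0)
    return type(vol)(data, sub.meta)


def _register_one_region(nissl_init, template_vol, mov_mask, fix_mask, params,
                         margin, min_voxels):
    """Affine + multimodal nonlinear registration of one masked region.

    Returns ``(warped crop, box, affine, field)`` or None when the region is
    too small to register.
    """
    if mov_mask.sum() < min_voxels or fix_mask.sum() < min_voxels:
        return None
    box = bounding_box(mov_mask | fix_mask, margin=margin,
                       shape=nissl_init.values.shape)
    # a slightly dilated moving mask keeps real tissue at the region rim, so
    # warped boundary voxels are not attenuated by interpolation against zeros
    mov_mask = _ndi.binary_dilation(mov_mask, iterations=2)
    mov = _masked_crop(nissl_init, mov_mask, box)
    fix = _masked_crop(template_vol, fix_mask, box)
    if np.ptp(mov.values) == 0 or np.ptp(fix.values) == 0:
        return None
    aff = register_affine(mov, fix, params, dof="similarity")
    fld = register_nonlinear(mov, fix, params, initial=aff)
    warped = apply_transform(mov, [fld, aff], interpolation="linear",
                             out_meta=fix.meta)
    return warped, box, aff, fld


def regionwise_register(nissl_init: IntensityVolume,
                        template_vol: IntensityVolume,
                        ann_v2_init: LabeledVolume, ann_v3: LabeledVolume,
                        graph: StructureGraph,
                        assignment: LevelAssignment | None = None,
                        params: RegistrationParams | None = None,
                        min_voxels: int = DEFAULT_MIN_REGION_VOXELS,
                        margin: int = DEFAULT_MARGIN):
    """Independent masked registration of every leaf region, then parent-level
    gap filling, then global fill.

    Reconstruction policy: leaf-level content is written only inside the
    region's fixed-space mask, in ascending region-id order with conflicts
    counted; still-empty fixed-annotation voxels are filled from parent-level
    registrations, and finally from the globally initialized volume.
    """
    params = params or RegistrationParams(metric="nmi")
    if assignment is None:
        assignment = assign_levels(graph, ann_v2_init, ann_v3)
    recon = np.zeros_like(template_vol.values)
    written = np.zeros(recon.shape, dtype=bool)
    transforms: dict = {}
    conflicts = 0
    fill_counts = {"leaf": 0, "parent": 0, "global": 0}

    def region_nmi(mask):
        try:
            return nmi(nissl_init, template_vol, mask=mask)
        except ValueError:
            return np.nan

    for rid in sorted(assignment.leaf_ids):
        mov_mask = ann_v2_init.labels == rid
        fix_mask = ann_v3.labels == rid
        before = region_nmi(fix_mask)
        result = _register_one_region(nissl_init, template_vol, mov_mask,
                                      fix_mask, params, margin, min_voxels)
        if result is None:
            transforms[rid] = RegionTransform("leaf", None, None, np.nan,
                                              before, np.nan, skipped=True)
            continue
        warped, box, aff, fld = result
        # claim the region interior only: the outermost voxel shell is left
        # to the continuous global fill so mosaic seams join similar tissue
        claim_mask = _ndi.binary_erosion(fix_mask, border_value=0)
        target = claim_mask[box] & (warped.values != 0)
        conflicts += int((written[box] & target).sum())
        sub_written = written[box]
        claim = target & ~sub_written
        sub = recon[box]
        sub[claim] = warped.values[claim]
        recon[box] = sub
        sub_written[claim] = True
        written[box] = sub_written
        fill_counts["leaf"] += int(claim.sum())
        transforms[rid] = RegionTransform(
            "leaf", aff, fld, getattr(fld, "final_metric", np.nan), before)

    # parent-level registrations cover leaves missing from one version
    for pid in sorted(assignment.parent_levels()):
        agg = {pid} | descendants(graph, pid)
        mov_mask = np.isin(ann_v2_init.labels, sorted(agg))
        fix_mask = np.isin(ann_v3.labels, sorted(agg))
        before = region_nmi(fix_mask)
        result = _register_one_region(nissl_init, template_vol, mov_mask,
                                      fix_mask, params, margin, min_voxels)
        if result is None:
            transforms[pid] = RegionTransform("parent", None, None, np.nan,
                                              before, np.nan, skipped=True)
            continue
        warped, box, aff, fld = result
        claim_mask = _ndi.binary_erosion(fix_mask, border_value=0)
        target = claim_mask[box] & ~written[box] & (warped.values != 0)
        sub = recon[box]
        sub[target] = warped.values[target]
        recon[box] = sub
        w = written[box]
        w[target] = True
        written[box] = w
        fill_counts["parent"] += int(target.sum())
        transforms[pid] = RegionTransform(
            "parent", aff, fld, getattr(fld, "final_metric", np.nan), before)

    # global fill: the initialized volume everywhere no region claimed —
    # keeps the reconstruction whole-brain tissue, not a bare region mosaic
    recon[~written] = nissl_init.values[~written]
    fill_counts["global"] = int(((ann_v3.labels != 0) & ~written).sum())

    recon_vol = IntensityVolume(recon, template_vol.meta)
    for rid, rt in transforms.items():
        if rt.skipped:
            continue
        mask = (ann_v3.labels == rid if rt.level == "leaf"
                else np.isin(ann_v3.labels, sorted({rid} | descendants(graph, rid))))
        try:
            rt.nmi_after = nmi(recon_vol, template_vol, mask=mask)
        except ValueError:
            pass
    labeled = ann_v3.labels != 0
    covered = written | (nissl_init.values != 0)
    stats = {"conflicts": conflicts, "fill_counts": fill_counts,
             "region_coverage": float(written[labeled].mean()) if labeled.any() else 1.0,
             "coverage": float(covered[labeled].mean()) if labeled.any() else 1.0}
    return recon_vol, transforms, stats


# ---------------------------------------------------------------------------
# Dedicated cerebellar path
# ---------------------------------------------------------------------------

def cerebellum_align(nissl: IntensityVolume, ann_v2: LabeledVolume,
                     ann_v3: LabeledVolume, lobule_ids, graph: StructureGraph,
                     params: RegistrationParams | None = None,
                     margin: int = DEFAULT_MARGIN):
    """Per-lobule annotation-mask registration with aggressive settings.

    Each lobule's mask is registered (affine + aggressive nonlinear) between
    the two annotation versions; the transforms carry the Nissl lobule into
    fixed space.  The mosaic claims only voxels inside the fixed lobule
    masks.  Returns ``(mosaic, mosaic_mask, transforms)``.
    """
    params = params or RegistrationParams(metric="ssd", aggressive=True)
    mosaic = np.zeros_like(nissl.values)
    mosaic_mask = np.zeros(mosaic.shape, dtype=bool)
    transforms = {}
    for rid in sorted(lobule_ids):
        agg = sorted({rid} | descendants(graph, rid))
        mov_mask = np.isin(ann_v2.labels, agg)
        fix_mask = np.isin(ann_v3.labels, agg)
        if not mov_mask.any() or not fix_mask.any():
            missing = "moving" if not mov_mask.any() else "fixed"
            raise ValueError(f"lobule {rid} missing from the {missing} annotation")
        box = bounding_box(mov_mask | fix_mask, margin=margin,
                           shape=mosaic.shape)
        mov_ann = _masked_crop(ann_v2, mov_mask, box)
        fix_ann = _masked_crop(ann_v3, fix_mask, box)
        aff, fld = register_labels(mov_ann, fix_ann, params)
        mov_nissl = _masked_crop(nissl, _ndi.binary_dilation(mov_mask, iterations=2), box)
        warped = apply_transform(mov_nissl, [fld, aff], interpolation="linear",
                                 out_meta=fix_ann.meta)
        target = _ndi.binary_erosion(fix_mask, border_value=0)[box] & (warped.values != 0)
        sub = mosaic[box]
        sub[target] = warped.values[target]
        mosaic[box] = sub
        mm = mosaic_mask[box]
        mm[target] = True
        mosaic_mask[box] = mm
        transforms[rid] = RegionTransform(
            "lobule", aff, fld, getattr(fld, "final_metric", np.nan))
    return IntensityVolume(mosaic, nissl.meta), mosaic_mask, transforms


# ---------------------------------------------------------------------------
# Stage 3: final whole-brain pass
# ---------------------------------------------------------------------------

def final_whole_brain(nissl_raw: IntensityVolume,
                      reconstructed: IntensityVolume,
                      params: RegistrationParams | None = None):
    """One monomodal nonlinear whole-brain registration of the continuous
    raw volume onto the mosaic: preserves tissue integrity (no seams) while
    adopting the mosaic's geometry.  Returns ``(aligned volume, field)``."""
    if nissl_raw.values.shape != reconstructed.values.shape:
        raise ValueError("volumes must share a grid")
    params = params or RegistrationParams(metric="ssd")
    fld = register_nonlinear(nissl_raw, reconstructed, params)
    aligned = apply_transform(nissl_raw, fld, interpolation="linear",
                              out_meta=reconstructed.meta)
    return aligned, fld


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_alignment(before: IntensityVolume, after: IntensityVolume,
                       template_vol: IntensityVolume, ann_v3: LabeledVolume,
                       graph: StructureGraph, region_ids=None,
                       fiducials_before: pd.DataFrame | None = None,
                       fiducials_after: pd.DataFrame | None = None,
                       bins: int = 64) -> AlignmentReport:
    """Multi-scale report: whole-brain, per-region and per-slice NMI against
    the template before/after, plus TRE when fiducial tables are given."""
    rep = AlignmentReport()
    rep.nmi_whole_before = nmi(before, template_vol, bins=bins)
    rep.nmi_whole_after = nmi(after, template_vol, bins=bins)
    if region_ids:
        pr_before = per_region_nmi(before, template_vol, ann_v3, graph,
                                   region_ids, bins=bins)
        pr_after = per_region_nmi(after, template_vol, ann_v3, graph,
                                  region_ids, bins=bins)
        merged = pr_before.merge(pr_after, on="region_id",
                                 suffixes=("_before", "_after"))
        merged["delta"] = merged["nmi_after"] - merged["nmi_before"]
        rep.per_region = merged
    for incidence in ("coronal", "sagittal", "horizontal"):
        b = per_slice_nmi(before, template_vol, incidence, bins=bins)
        a = per_slice_nmi(after, template_vol, incidence, bins=bins)
        m = b.merge(a, on="plane", suffixes=("_before", "_after"))
        rep.per_slice[incidence] = m
    if fiducials_before is not None:
        rep.tre_before = tre(fiducials_before)
    if fiducials_after is not None:
        rep.tre_after = tre(fiducials_after)
    return rep


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    nissl_init: IntensityVolume
    ann_v2_init: LabeledVolume
    reconstruction: IntensityVolume
    aligned: IntensityVolume
    global_transforms: dict
    region_transforms: dict
    lobule_transforms: dict
    final_field: DeformationField
    stats: dict
    report: Optional[AlignmentReport] = None

    def map_fixed_points_to_moving(self, pts_um: np.ndarray) -> np.ndarray:
        """Estimated total point map from fixed space into the original
        moving (Nissl) space, for fiducial evaluation."""
        pts = np.asarray(pts_um, float)
        pts = self.final_field.apply_points(pts)
        pts = self.global_transforms["field"].apply_points(pts)
        return self.global_transforms["affine"].apply_points(pts)


def run_full_pipeline(nissl, ann_v2, template_vol, ann_v3, graph,
                      params: RegistrationParams | None = None,
                      lobule_ids=(), fiducials: pd.DataFrame | None = None,
                      min_voxels: int = DEFAULT_MIN_REGION_VOXELS,
                      evaluate: bool = True) -> PipelineResult:
    """Run init → region-wise (+ cerebellar path) → final pass and evaluate.

    ``fiducials`` needs columns ``x_ref..z_ref`` (fixed space, µm) and
    ``x_mov..z_mov`` (the points' true coordinates in the moving volume).
    """
    params = params or RegistrationParams(metric="nmi")
    nissl_init, ann_v2_init, gtrans = global_label_init(nissl, ann_v2, ann_v3)
    assignment = assign_levels(graph, ann_v2_init, ann_v3)
    # the dedicated cerebellar path replaces generic leaf handling of lobules
    generic = LevelAssignment(assignment.leaf_ids - set(lobule_ids),
                              {k: v for k, v in assignment.parent_map.items()
                               if k not in lobule_ids})
    recon, rtrans, stats = regionwise_register(
        nissl_init, template_vol, ann_v2_init, ann_v3, graph, generic, params,
        min_voxels=min_voxels)
    ltrans = {}
    if lobule_ids:
        mosaic, mosaic_mask, ltrans = cerebellum_align(
            nissl_init, ann_v2_init, ann_v3, lobule_ids, graph)
        vals = recon.values.copy()
        vals[mosaic_mask] = mosaic.values[mosaic_mask]
        recon = IntensityVolume(vals, recon.meta)
    aligned, final_field = final_whole_brain(nissl_init, recon)

    result = PipelineResult(nissl_init, ann_v2_init, recon, aligned, gtrans,
                            rtrans, ltrans, final_field, stats)
    if evaluate:
        fb = fa = None
        if fiducials is not None:
            ref = fiducials[["x_ref", "y_ref", "z_ref"]].to_numpy()
            mov = fiducials[["x_mov", "y_mov", "z_mov"]].to_numpy()
            est = result.map_fixed_points_to_moving(ref)
            fb = fiducials.copy()
            fb[["x_reg", "y_reg", "z_reg"]] = mov  # unaligned: anatomy sits at its moving-space position
            fa = fiducials.copy()
            fa[["x_reg", "y_reg", "z_reg"]] = ref + (est - mov)
        leaf_ids = sorted(assignment.leaf_ids)
        result.report = evaluate_alignment(
            nissl, aligned, template_vol, ann_v3, graph, region_ids=leaf_ids,
            fiducials_before=fb, fiducials_after=fa)
        result.report.conflicts = stats["conflicts"]
        result.report.fill_counts = stats["fill_counts"]
    return result
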