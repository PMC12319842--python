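"""Evaluation metrics: normalized mutual information, target registration
error, Dice overlap, multi-scale NMI reports, and per-region voxel/volume
accounting.

NMI is ``2·I(A;B) / (H(A)+H(B))`` computed from a joint intensity histogram;
entropies are in bits internally (the ratio is base-invariant).  TRE is the
Euclidean distance (µm) between a fiducial's reference coordinates and its
coordinates estimated after registration.  Dice is ``2|A∩B| / (|A|+|B|)`` on
voxel counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import StructureGraph, region_mask
from .volio import IntensityVolume, LabeledVolume


# ---------------------------------------------------------------------------
# Joint histogram and NMI
# ---------------------------------------------------------------------------

@dataclass
class JointHistogram:
    counts: np.ndarray  # (bins, bins)
    edges_a: np.ndarray
    edges_b: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginals(self):
        return self.counts.sum(axis=1), self.counts.sum(axis=0)


def _as_array(vol):
    return vol.data if isinstance(vol, (IntensityVolume, LabeledVolume)) else np.asarray(vol)


def _default_mask(a, b, mask):
    if mask is None:
        mask = (a != 0) | (b != 0)
    else:
        mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask for histogram")
    return mask


def joint_histogram(A, B, bins: int = 64, mask=None) -> JointHistogram:
    """Joint intensity histogram over a mask (default: union of nonzero
    supports), with per-image min–max bin edges."""
    a, b = _as_array(A).astype(float), _as_array(B).astype(float)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    m = _default_mask(a, b, mask)
    av, bv = a[m], b[m]
    counts, ea, eb = np.histogram2d(av, bv, bins=bins)
    return JointHistogram(counts, ea, eb)


def _entropy(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nmi(A, B, bins: int = 64, mask=None) -> float:
    """Normalized mutual information ``2·I(A;B)/(H(A)+H(B))`` in [0, 1]."""
    jh = joint_histogram(A, B, bins=bins, mask=mask)
    p = jh.counts / jh.total
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    ha, hb = _entropy(pa), _entropy(pb)
    if ha == 0 or hb == 0:
        raise ValueError("NMI undefined for a constant image over the mask")
    hab = _entropy(p.ravel())
    mi = ha + hb - hab
    return float(2.0 * mi / (ha + hb))


# ---------------------------------------------------------------------------
# TRE
# ---------------------------------------------------------------------------

FIDUCIAL_COLUMNS = ["name", "operator", "region_group",
                    "x_ref", "y_ref", "z_ref", "x_reg", "y_reg", "z_reg"]


def tre(points: pd.DataFrame) -> pd.DataFrame:
    """Per-fiducial Euclidean distance (µm) between reference and estimated
    coordinates, with the input columns preserved.

    ``points`` needs columns ``x_ref..z_ref`` and ``x_reg..z_reg`` (µm);
    optional ``region_group``/``operator`` enable grouped summaries via
    :func:`tre_summary`.
    """
    for col in ("x_ref", "y_ref", "z_ref", "x_reg", "y_reg", "z_reg"):
        if col not in points.columns:
            raise ValueError(f"fiducial table missing column {col!r}")
        if points[col].isna().any():
            raise ValueError(f"missing coordinate in column {col!r}")
    d = np.sqrt((points["x_ref"] - points["x_reg"]) ** 2
                + (points["y_ref"] - points["y_reg"]) ** 2
                + (points["z_ref"] - points["z_reg"]) ** 2)
    out = points.copy()
    out["tre_um"] = d
    return out


def tre_summary(points: pd.DataFrame, by=("region_group", "operator")) -> pd.DataFrame:
    """Mean/median TRE per grouping column present in the table."""
    scored = tre(points)
    frames = []
    for col in by:
        if col in scored.columns:
            g = scored.groupby(col)["tre_um"].agg(["mean", "median", "count"])
            g.insert(0, "group_by", col)
            frames.append(g.reset_index(names="group"))
    overall = pd.DataFrame({"group_by": ["all"], "group": ["all"],
                            "mean": [scored["tre_um"].mean()],
                            "median": [scored["tre_um"].median()],
                            "count": [len(scored)]})
    return pd.concat(frames + [overall], ignore_index=True)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dice(A, B) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` on boolean masks."""
    a, b = np.asarray(_as_array(A), bool), np.asarray(_as_array(B), bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def mean_label_dice(annA: LabeledVolume, annB: LabeledVolume, ids) -> float:
    """Mean Dice over a set of label ids (labels absent from both skipped)."""
    scores = []
    for rid in sorted(ids):
        a, b = annA.labels == rid, annB.labels == rid
        if a.any() or b.any():
            scores.append(dice(a, b))
    if not scores:
        raise ValueError("no scored labels")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Multi-scale NMI reports
# ---------------------------------------------------------------------------

def per_region_nmi(A, B, ann: LabeledVolume, graph: StructureGraph,
                   region_ids, bins: int = 64, min_voxels: int = 50) -> pd.DataFrame:
    """NMI inside each region mask (descendant-aggregated); regions below
    ``min_voxels`` are flagged and not scored."""
    rows = []
    for rid in sorted(region_ids):
        mask = region_mask(ann, graph, rid, include_descendants=True)
        n = int(mask.sum())
        score, flagged = np.nan, True
        if n >= min_voxels:
            try:
                score, flagged = nmi(A, B, bins=bins, mask=mask), False
            except ValueError:
                pass
        rows.append({"region_id": rid, "voxels": n, "nmi": score,
                     "flagged": flagged})
    return pd.DataFrame(rows)


INCIDENCE_ROLE = {"coronal": "rostrocaudal", "horizontal": "dorsoventral",
                  "sagittal": "leftright"}


def per_slice_nmi(A, B, incidence: str, bins: int = 64,
                  min_voxels: int = 50) -> pd.DataFrame:
    """NMI per 2D plane perpendicular to the given incidence axis; near-empty
    planes are flagged rather than scored."""
    a, b = _as_array(A), _as_array(B)
    meta = A.meta if isinstance(A, (IntensityVolume, LabeledVolume)) else None
    if incidence not in INCIDENCE_ROLE:
        raise ValueError(f"unknown incidence {incidence!r}")
    axis = meta.axis_of(INCIDENCE_ROLE[incidence]) if meta is not None else 0
    rows = []
    for i in range(a.shape[axis]):
        sa = np.take(a, i, axis=axis)
        sb = np.take(b, i, axis=axis)
        support = int(((sa != 0) | (sb != 0)).sum())
        score, flagged = np.nan, True
        if support >= min_voxels:
            try:
                score, flagged = nmi(sa, sb, bins=bins), False
            except ValueError:
                pass
        rows.append({"plane": i, "support": support, "nmi": score,
                     "flagged": flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Voxel/volume accounting
# ---------------------------------------------------------------------------

def voxels_to_mm3(n_voxels: int, voxel_size_um: float) -> float:
    """Volume in mm³ of ``n_voxels`` isotropic voxels of the given edge (µm)."""
    return float(n_voxels) * (voxel_size_um / 1000.0) ** 3


def relative_increase_percent(before: float, after: float) -> float:
    """Relative growth from ``before`` to ``after``, in percent."""
    return 100.0 * (after - before) / before


def volume_report(ann_before: LabeledVolume, ann_after: LabeledVolume,
                  graph: StructureGraph, region_ids) -> pd.DataFrame:
    """Per-region accounting of annotation changes.

    For each region (descendant-aggregated in the *after* volume): an *added*
    voxel was background before and labelled after; a *modified* voxel was
    labelled before but carries a different label after.  Totals are
    added + modified; mm³ uses the voxel edge length exactly.
    """
    if ann_before.labels.shape != ann_after.labels.shape:
        raise ValueError("annotation volumes must share a grid")
    vs = ann_after.meta.voxel_size[0]
    before, after = ann_before.labels, ann_after.labels
    added_mask = (before == 0) & (after != 0)
    modified_mask = (before != 0) & (after != 0) & (before != after)
    rows = []
    for rid in sorted(region_ids):
        mask = region_mask(ann_after, graph, rid, include_descendants=True)
        added = int((added_mask & mask).sum())
        modified = int((modified_mask & mask).sum())
        rows.append(_report_row(rid, added, modified, int(mask.sum()), vs))
    total_added = int(added_mask.sum())
    total_modified = int(modified_mask.sum())
    rows.append(_report_row("TOTAL", total_added, total_modified,
                            int((after != 0).sum()), vs))
    return pd.DataFrame(rows)


def _report_row(region, added, modified, region_voxels, vs):
    total = added + modified
    return {
        "region": region,
        "added_voxels": added,
        "modified_voxels": modified,
        "total_voxels": total,
        "added_mm3": voxels_to_mm3(added, vs),
        "modified_mm3": voxels_to_mm3(modified, vs),
        "total_mm3": voxels_to_mm3(total, vs),
        "region_voxels": region_voxels,
        "fraction_of_region": total / region_voxels if region_voxels else 0.0,
    }
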