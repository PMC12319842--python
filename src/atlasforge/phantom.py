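"""Synthetic phantom brains with recorded ground truth.

The generator emulates the data situation the toolkit is built for: two
annotation versions of the same anatomy sharing one ontology but with some
leaf labels merged into their parents in the older version; a high-contrast
textured Nissl-like intensity volume aligned with the old annotation; a
smooth, low-contrast average-template-like volume aligned with the new one; a
known smooth deformation between the two spaces; truncated variants; 2D
sections with known plane positions and in-plane warps; and fiducial points
with ground-truth coordinates in both spaces.

The standard "mouse-64" phantom is a 64×80×56 grid at 25 µm with a 15-node
ontology (root → 2 branches → 4 parents → 8 leaves, four of which form a
four-lobule "cerebellum" whose lobules carry a bimodal inner/outer intensity
shell), two leaves dropped from the old annotation, and a sinusoidal warp of
3-voxel amplitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .ontology import StructureGraph
from .register import apply_transform
from .transforms import DeformationField
from .volio import GridMeta, IntensityVolume, LabeledVolume

# -- fixed 15-node ontology of the standard phantom -------------------------
ROOT_ID = 997
BRANCH_IDS = (100, 200)
PARENT_IDS = (110, 120, 210, 220)
CEREBELLUM_ID = 220
LEAF_IDS = (111, 112, 121, 211, 221, 222, 223, 224)
LOBULE_IDS = (221, 222, 223, 224)
DEFAULT_DROPPED = (112, 121)  # merged into parents 110, 120 in the V2-like volume

_ONTOLOGY_RECORDS = [
    {"id": ROOT_ID, "acronym": "root", "name": "root", "parent_id": None},
    {"id": 100, "acronym": "FB", "name": "forebrain-like", "parent_id": ROOT_ID},
    {"id": 200, "acronym": "HB", "name": "hindbrain-like", "parent_id": ROOT_ID},
    {"id": 110, "acronym": "P1", "name": "parent 1", "parent_id": 100},
    {"id": 120, "acronym": "P2", "name": "parent 2", "parent_id": 100},
    {"id": 210, "acronym": "P3", "name": "parent 3", "parent_id": 200},
    {"id": 220, "acronym": "CB", "name": "cerebellum-like", "parent_id": 200},
    {"id": 111, "acronym": "L1", "name": "leaf 1", "parent_id": 110},
    {"id": 112, "acronym": "L2", "name": "leaf 2", "parent_id": 110},
    {"id": 121, "acronym": "L3", "name": "leaf 3", "parent_id": 120},
    {"id": 211, "acronym": "L4", "name": "leaf 4", "parent_id": 210},
    {"id": 221, "acronym": "CB1", "name": "lobule 1", "parent_id": 220},
    {"id": 222, "acronym": "CB2", "name": "lobule 2", "parent_id": 220},
    {"id": 223, "acronym": "CB3", "name": "lobule 3", "parent_id": 220},
    {"id": 224, "acronym": "CB4", "name": "lobule 4", "parent_id": 220},
]

# ellipsoids: id -> (centre, radii) in voxel index coordinates
_REGION_GEOMETRY = {
    111: ((14, 28, 18), (8, 12, 10)),
    112: ((14, 28, 38), (8, 12, 10)),
    121: ((16, 56, 28), (9, 13, 12)),
    211: ((34, 40, 28), (12, 16, 14)),
    221: ((52, 24, 18), (8, 10, 9)),
    222: ((52, 24, 38), (8, 10, 9)),
    223: ((52, 56, 18), (8, 10, 9)),
    224: ((52, 56, 38), (8, 10, 9)),
}

_REGION_INTENSITY = {111: 120.0, 112: 90.0, 121: 150.0, 211: 110.0}
LOBULE_INNER_INTENSITY = 200.0  # granular-like (dense somata)
LOBULE_OUTER_INTENSITY = 50.0   # molecular-like
TISSUE_INTENSITY = 60.0         # unlabeled brain tissue
_BRAIN = ((32, 40, 28), (29, 36, 25))


def phantom_graph() -> StructureGraph:
    """The fixed 15-node ontology of the standard phantom."""
    return StructureGraph.from_records(_ONTOLOGY_RECORDS)


@dataclass
class PhantomSpec:
    """Generating conditions of a phantom bundle (all lengths in voxels
    unless noted)."""

    shape: tuple = (64, 80, 56)
    voxel_size_um: float = 25.0
    warp_amplitude: float = 3.0  # voxels
    warp_wavelength: float = 36.0  # voxels
    speckle_sigma: float = 5.0  # intensity units, Nissl-like voxel noise
    texture_amplitude: float = 0.15  # relative smooth anatomical texture
    texture_sigma: float = 3.0  # voxels, texture correlation length
    template_blur_sigma: float = 1.5  # voxels
    contrast_gamma: float = 0.6  # template contrast compression exponent
    dropped_leaves: tuple = DEFAULT_DROPPED
    lobule_shell_fraction: float = 0.55  # inner (granular) radius fraction
    fiducials_per_region: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.warp_amplitude < 0 or self.speckle_sigma < 0:
            raise ValueError("amplitudes must be non-negative")
        unknown = set(self.dropped_leaves) - set(LEAF_IDS)
        if unknown:
            raise ValueError(f"dropped leaves not in the phantom ontology: {unknown}")


@dataclass
class PhantomBundle:
    """Everything the pipeline consumes, plus the generating ground truth."""

    spec: PhantomSpec
    graph: StructureGraph
    ann_v3: LabeledVolume          # new-version annotation (fixed space)
    ann_v2: LabeledVolume          # old-version annotation (moving space)
    nissl: IntensityVolume         # textured modality, aligned with ann_v2
    template: IntensityVolume      # smooth modality, aligned with ann_v3
    intensity_true: IntensityVolume  # pristine intensity in fixed space
    nissl_clean: IntensityVolume   # warped intensity before speckle
    true_field: DeformationField   # moving-grid point map x ↦ x + u(x) → fixed
    dropped_leaves: tuple
    expected_parent_map: dict
    lobule_ids: tuple
    region_voxel_counts: dict      # leaf id -> voxels in ann_v3
    granular_true: dict            # lobule id -> bool mask (fixed space)
    molecular_true: dict
    fiducials: pd.DataFrame        # ref (fixed) and true moving coords, µm

    @property
    def comparable_leaf_ids(self) -> set:
        return set(LEAF_IDS) - set(self.dropped_leaves)


def _ellipsoid_mask(shape, center, radii):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _sinusoid_field(shape, amplitude, wavelength, phases=(0.0, 1.3, 2.1)):
    """Smooth component-wise sinusoidal displacement (voxel units)."""
    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    k = 2.0 * np.pi / wavelength
    comps = [
        amplitude * np.sin(k * idx[1] + phases[0]),
        amplitude * np.sin(k * idx[2] + phases[1]),
        amplitude * np.sin(k * idx[0] + phases[2]),
    ]
    return np.stack(comps, axis=-1)


def make_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Generate the standard phantom bundle, deterministic under ``spec.seed``."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    meta = GridMeta((spec.voxel_size_um,) * 3)

    # -- pristine annotation and intensity in fixed (V3) space -------------
    labels = np.zeros(shape, dtype=np.int64)
    intensity = np.zeros(shape, dtype=float)
    brain = _ellipsoid_mask(shape, *_BRAIN)
    intensity[brain] = TISSUE_INTENSITY
    granular_true, molecular_true = {}, {}
    for rid in LEAF_IDS:
        center, radii = _REGION_GEOMETRY[rid]
        mask = _ellipsoid_mask(shape, center, radii) & (labels == 0)
        labels[mask] = rid
        if rid in LOBULE_IDS:
            inner = _ellipsoid_mask(
                shape, center, tuple(r * spec.lobule_shell_fraction for r in radii))
            granular_true[rid] = mask & inner
            molecular_true[rid] = mask & ~inner
            intensity[granular_true[rid]] = LOBULE_INNER_INTENSITY
            intensity[molecular_true[rid]] = LOBULE_OUTER_INTENSITY
        else:
            intensity[mask] = _REGION_INTENSITY[rid]

    # smooth anatomical texture shared by both modalities: real tissue has
    # structure (cell clusters, fibre bundles) inside every region, which is
    # what drives deformable registration away from region boundaries
    if spec.texture_amplitude > 0:
        noise = rng.standard_normal(shape)
        texture = ndimage.gaussian_filter(noise, spec.texture_sigma)
        texture /= max(np.abs(texture).max(), 1e-9)
        intensity *= 1.0 + spec.texture_amplitude * texture

    ann_v3 = LabeledVolume(labels, meta)
    intensity_true = IntensityVolume(intensity, meta)

    # -- smooth low-contrast modality aligned with ann_v3 ------------------
    vmax = intensity.max()
    compressed = vmax * (intensity / vmax) ** spec.contrast_gamma
    template = ndimage.gaussian_filter(compressed, spec.template_blur_sigma)
    template_vol = IntensityVolume(template, meta)

    # -- known deformation into moving (V2/Nissl) space --------------------
    disp_vox = _sinusoid_field(shape, spec.warp_amplitude, spec.warp_wavelength)
    true_field = DeformationField(disp_vox * spec.voxel_size_um,
                                  meta.with_shape(shape))

    merged = labels.copy()
    for rid in spec.dropped_leaves:
        parent = phantom_graph().nodes[rid].parent_id
        merged[merged == rid] = parent
    ann_merged = LabeledVolume(merged, meta)
    ann_v2 = apply_transform(ann_merged, true_field, interpolation="nearest")

    nissl_clean = apply_transform(intensity_true, true_field,
                                  interpolation="linear")
    speckle = rng.normal(0.0, spec.speckle_sigma, size=shape)
    nissl_vals = np.where(nissl_clean.values != 0,
                          np.maximum(nissl_clean.values + speckle, 1e-3), 0.0)
    nissl = IntensityVolume(nissl_vals, meta)

    graph = phantom_graph()
    expected_parent_map = {rid: graph.nodes[rid].parent_id
                           for rid in spec.dropped_leaves}
    counts = ann_v3.label_counts()

    fiducials = _make_fiducials(spec, ann_v3, disp_vox)

    return PhantomBundle(
        spec=spec, graph=graph, ann_v3=ann_v3, ann_v2=ann_v2, nissl=nissl,
        template=template_vol, intensity_true=intensity_true,
        nissl_clean=nissl_clean, true_field=true_field,
        dropped_leaves=tuple(spec.dropped_leaves),
        expected_parent_map=expected_parent_map, lobule_ids=LOBULE_IDS,
        region_voxel_counts={rid: counts.get(rid, 0) for rid in LEAF_IDS},
        granular_true=granular_true, molecular_true=molecular_true,
        fiducials=fiducials)


def _invert_displacement_at(point_vox, disp_vox, iters=30):
    """Solve m + u(m) = r by fixed-point iteration (voxel coordinates)."""
    ndim = disp_vox.shape[-1]
    m = np.asarray(point_vox, float).copy()
    for _ in range(iters):
        u = np.array([ndimage.map_coordinates(disp_vox[..., c], m[:, None],
                                              order=1, mode="nearest")[0]
                      for c in range(ndim)])
        m = np.asarray(point_vox, float) - u
    return m


def _make_fiducials(spec, ann_v3, disp_vox) -> pd.DataFrame:
    """Fiducial points at comparable-leaf centroids (plus a boundary-ward
    offset point per region): reference coordinates in fixed space and
    ground-truth coordinates in the moving (Nissl) space, µm."""
    vs = spec.voxel_size_um
    rows = []
    usable = [rid for rid in LEAF_IDS if rid not in spec.dropped_leaves]
    for rid in usable:
        mask = ann_v3.labels == rid
        if not mask.any():
            continue
        centroid = np.array(ndimage.center_of_mass(mask))
        pts = [centroid]
        if spec.fiducials_per_region > 1:
            center, radii = _REGION_GEOMETRY[rid]
            pts.append(centroid + np.array([0.6 * radii[0], 0.0, 0.0]))
        for j, r_vox in enumerate(pts[: spec.fiducials_per_region]):
            m_vox = _invert_displacement_at(r_vox, disp_vox)
            r_um, m_um = r_vox * vs, m_vox * vs
            rows.append({
                "name": f"{rid}_{j}", "region_group": rid, "operator": "truth",
                "x_ref": r_um[0], "y_ref": r_um[1], "z_ref": r_um[2],
                "x_mov": m_um[0], "y_mov": m_um[1], "z_mov": m_um[2],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sections, truncation, defect injection
# ---------------------------------------------------------------------------

def make_sections(volume: IntensityVolume, axis: int = 0, spacing: int = 4,
                  warp_amplitude: float = 0.0, noise_sigma: float = 0.0,
                  seed: int = 0, source_id: str = "phantom"):
    """Extract every ``spacing``-th plane as a 2D section, independently
    warped in-plane by a recorded sinusoidal field with noise added.

    Returns a list of :class:`atlasforge.template.SectionRecord`.
    """
    from .template import SectionRecord  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    sections = []
    n = volume.values.shape[axis]
    for pos, plane in enumerate(range(0, n, spacing)):
        img = np.take(volume.values, plane, axis=axis).astype(float)
        warp = None
        if warp_amplitude > 0:
            phases = rng.uniform(0, 2 * np.pi, size=3)
            warp = _sinusoid_field_2d(img.shape, warp_amplitude, 24.0, phases)
            idx = np.meshgrid(*[np.arange(s, dtype=float) for s in img.shape],
                              indexing="ij")
            img = ndimage.map_coordinates(
                img, [idx[c] + warp[..., c] for c in range(2)],
                order=1, mode="constant", cval=0.0)
        if noise_sigma > 0:
            img = np.where(img != 0, img + rng.normal(0, noise_sigma, img.shape),
                           0.0)
        sections.append(SectionRecord(image=img, plane_axis=axis,
                                      plane_index=plane, source_id=source_id,
                                      true_warp=warp))
    return sections


def _sinusoid_field_2d(shape, amplitude, wavelength, phases):
    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    k = 2.0 * np.pi / wavelength
    return np.stack([amplitude * np.sin(k * idx[1] + phases[0]),
                     amplitude * np.sin(k * idx[0] + phases[1])], axis=-1)


def truncate(volume, axis: int, fraction: float, end: str = "rostral"):
    """Zero out a fraction of planes at one end of an axis.

    ``end='rostral'`` removes low-index planes, ``'caudal'`` high-index ones.
    Returns ``(truncated volume, record)`` where the record restores the
    original exactly via :func:`restore_truncation`.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = volume.data.shape[axis]
    k = int(round(fraction * n))
    sl = [slice(None)] * volume.data.ndim
    sl[axis] = slice(0, k) if end == "rostral" else slice(n - k, n)
    sl = tuple(sl)
    data = volume.data.copy()
    record = {"axis": axis, "slices": sl, "removed": volume.data[sl].copy(),
              "end": end, "n_planes": k}
    data[sl] = 0
    return type(volume)(data, volume.meta), record


def restore_truncation(volume, record):
    data = volume.data.copy()
    data[record["slices"]] = record["removed"]
    return type(volume)(data, volume.meta)


def inject_stray_voxels(ann: LabeledVolume, k: int, seed: int = 0,
                        min_distance: int = 4) -> tuple:
    """Scatter ``k`` isolated single-voxel islands of existing labels well
    away from any labelled tissue; returns (volume, list of indices)."""
    rng = np.random.default_rng(seed)
    labels = ann.labels.copy()
    fg = labels != 0
    far = ndimage.distance_transform_edt(~fg) > min_distance
    candidates = np.argwhere(far)
    ids = sorted(np.unique(labels[fg]))
    placed = []
    order = rng.permutation(len(candidates))
    for i in order:
        if len(placed) >= k:
            break
        pos = tuple(candidates[i])
        if any(max(abs(p - q) for p, q in zip(pos, prev)) <= 2 for prev in placed):
            continue
        labels[pos] = ids[len(placed) % len(ids)]
        placed.append(pos)
    return LabeledVolume(labels, ann.meta), placed


def inject_asymmetry(ann: LabeledVolume, n_voxels: int = 433,
                     seed: int = 0) -> tuple:
    """Add ``n_voxels`` labelled voxels on the left hemisphere only (adjacent
    to existing tissue), emulating a one-sided annotation defect."""
    rng = np.random.default_rng(seed)
    labels = ann.labels.copy()
    axis = ann.meta.axis_of("leftright")
    half = labels.shape[axis] // 2
    fg = labels != 0
    shell = ndimage.binary_dilation(fg) & ~fg
    left = np.zeros_like(fg)
    sl = [slice(None)] * labels.ndim
    sl[axis] = slice(0, half)
    left[tuple(sl)] = True
    candidates = np.argwhere(shell & left)
    take = rng.permutation(len(candidates))[:n_voxels]
    lab = int(np.unique(labels[fg])[0])
    for i in take:
        labels[tuple(candidates[i])] = lab
    return LabeledVolume(labels, ann.meta), len(take)
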