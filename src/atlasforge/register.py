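"""Internal registration engine: multi-resolution affine alignment and a
demons-style free-form nonlinear aligner with Gaussian field regularization.

The nonlinear model keeps a per-voxel displacement field on the fixed grid and
iterates: warp the moving image, compute a force field from the similarity
metric, smooth the update (fluid-like) and the accumulated field (diffusion-
like), and accept the step only if the configured metric does not decrease —
so the optimized metric is monotone over accepted iterations.  Multimodal
pairs are handled by computing forces on a masked-histogram-matched copy of
the moving image while judging steps on normalized mutual information.

All public transforms are expressed in world µm; internally each pyramid
level works in voxel units of its own grid.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize

from .metrics import nmi as _nmi
from .transforms import AffineTransform, DeformationField, compose
from .volio import GridMeta, IntensityVolume, LabeledVolume

__all__ = ["RegistrationParams", "register_affine", "register_nonlinear",
           "register_labels", "apply_transform", "compose",
           "AffineTransform", "DeformationField"]


@dataclass
class RegistrationParams:
    """Tunables of the engine.

    pyramid_levels are coarse→fine integer downsampling factors; iterations
    matches them one-to-one.  ``smoothing_sigma`` (µm) regularizes the field;
    the fluid sigma applied to each update is half of it.  ``aggressive``
    halves the smoothing, doubles iterations and switches to local-correlation
    forces (fine-scale matching with enhanced deformation).
    """

    pyramid_levels: tuple = (4, 2, 1)
    iterations: tuple = (100, 50, 20)
    metric: str = "nmi"  # nmi | ssd | local-correlation
    smoothing_sigma: float = 150.0  # µm; suits smooth anatomical deformation
    step_size: float = 2.0  # voxels, max update magnitude scale
    bins: int = 64
    aggressive: bool = False
    min_overlap: int = 32
    seed: int = 0

    def __post_init__(self):
        if len(self.pyramid_levels) != len(self.iterations):
            raise ValueError("pyramid_levels and iterations must align")
        if list(self.pyramid_levels) != sorted(self.pyramid_levels, reverse=True):
            raise ValueError("pyramid levels must be coarse→fine")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.bins < 8:
            raise ValueError("bins must be >= 8")
        if self.metric not in ("nmi", "ssd", "local-correlation"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def effective(self) -> "RegistrationParams":
        if not self.aggressive:
            return self
        return replace(self, smoothing_sigma=self.smoothing_sigma / 2.0,
                       iterations=tuple(2 * i for i in self.iterations),
                       metric="local-correlation", aggressive=False)


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _check_images(moving, fixed):
    for name, vol in (("moving", moving), ("fixed", fixed)):
        arr = vol.values if isinstance(vol, IntensityVolume) else np.asarray(vol)
        if np.ptp(arr) == 0:
            raise RegistrationError(f"{name} image is constant")


def _downsample_level(arr, factor):
    if factor == 1:
        return np.asarray(arr, float)
    pads = [(0, (-s) % factor) for s in arr.shape]
    a = np.pad(np.asarray(arr, float), pads, mode="edge")
    sh = []
    for s in a.shape:
        sh.extend([s // factor, factor])
    view = a.reshape(sh)
    return view.mean(axis=tuple(range(1, 2 * arr.ndim, 2)))


def _normalize(arr, mask):
    vals = arr[mask] if mask.any() else arr
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def _match_histogram(src, ref, mask, nbins=256):
    """Monotone CDF matching of src to ref over the mask (array version)."""
    s, r = src[mask], ref[mask]
    s_sorted = np.sort(s)
    r_sorted = np.sort(r)
    q = np.linspace(0, 1, nbins)
    s_q = np.quantile(s_sorted, q)
    r_q = np.quantile(r_sorted, q)
    s_q, idx = np.unique(s_q, return_index=True)
    return np.interp(src, s_q, r_q[idx])


def _local_normalize(arr, sigma_vox=3.0):
    mean = ndimage.gaussian_filter(arr, sigma_vox)
    var = ndimage.gaussian_filter(arr * arr, sigma_vox) - mean ** 2
    return (arr - mean) / np.sqrt(np.maximum(var, 1e-8))


def _warp_voxels(arr, disp_vox, order=1):
    """Sample ``arr`` at identity+displacement (voxel units, fixed grid)."""
    ndim = arr.ndim
    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in arr.shape],
                      indexing="ij")
    coords = [idx[c] + disp_vox[..., c] for c in range(ndim)]
    return ndimage.map_coordinates(arr, coords, order=order, mode="constant",
                                   cval=0.0)


def _eval_metric(metric, warped, fixed, mask, bins):
    if not mask.any():
        return -np.inf
    if metric == "ssd":
        return -float(((warped - fixed) ** 2)[mask].mean())
    if metric == "local-correlation":
        return -float(((_local_normalize(warped) - _local_normalize(fixed)) ** 2)[mask].mean())
    try:
        return _nmi(warped, fixed, bins=bins, mask=mask)
    except ValueError:
        return -np.inf


def _metric_mask(moving_like, fixed, min_overlap):
    mask = (moving_like != 0) | (fixed != 0)
    if mask.sum() < min_overlap:
        raise RegistrationError("insufficient overlap between images")
    return mask


# ---------------------------------------------------------------------------
# Affine registration
# ---------------------------------------------------------------------------

def _euler_matrix(angles):
    rx, ry, rz = angles
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


_DOF_SIZES = {"rigid": 6, "similarity": 7, "affine": 12}


def _params_to_affine(p, dof, center):
    t = np.asarray(p[:3], float)
    R = _euler_matrix(p[3:6])
    if dof == "rigid":
        M = R
    elif dof == "similarity":
        M = R * np.exp(p[6])
    else:
        S = np.diag(np.exp(p[6:9]))
        Sh = np.eye(3)
        Sh[0, 1], Sh[0, 2], Sh[1, 2] = p[9], p[10], p[11]
        M = R @ S @ Sh
    # centred map: y = M (x - c) + c + t
    return AffineTransform(M, center - M @ center + t)


def _resample_affine(mov_arr, mov_meta, aff, fix_meta, order=1):
    pts = fix_meta.world_grid()
    mapped = aff.apply_points(pts.reshape(-1, 3))
    coords = ((mapped - np.asarray(mov_meta.origin))
              / np.asarray(mov_meta.voxel_size)).T
    out = ndimage.map_coordinates(mov_arr, coords, order=order, mode="constant",
                                  cval=0.0)
    return out.reshape(fix_meta.shape)


def register_affine(moving: IntensityVolume, fixed: IntensityVolume,
                    params: RegistrationParams | None = None,
                    dof: str = "affine") -> AffineTransform:
    """Multi-resolution affine alignment (rigid / similarity / full affine).

    A coarse exhaustive translation search at the lowest resolution seeds a
    Nelder–Mead refinement of the full parameter vector at every level.
    Deterministic for fixed params.
    """
    if dof not in _DOF_SIZES:
        raise ValueError(f"unknown dof {dof!r}")
    params = (params or RegistrationParams()).effective()
    _check_images(moving, fixed)
    center = np.asarray(fixed.meta.world(np.asarray(fixed.meta.shape) / 2.0))
    nparams = _DOF_SIZES[dof]
    p = np.zeros(nparams)

    for li, (factor, iters) in enumerate(zip(params.pyramid_levels,
                                             params.iterations)):
        mov_arr = _downsample_level(moving.values, factor)
        fix_arr = _downsample_level(fixed.values, factor)
        vs_m = tuple(v * factor for v in moving.meta.voxel_size)
        vs_f = tuple(v * factor for v in fixed.meta.voxel_size)
        mov_meta = GridMeta(vs_m, moving.meta.origin, moving.meta.axis_roles,
                            mov_arr.shape)
        fix_meta = GridMeta(vs_f, fixed.meta.origin, fixed.meta.axis_roles,
                            fix_arr.shape)

        def score(vec):
            aff = _params_to_affine(vec, dof, center)
            warped = _resample_affine(mov_arr, mov_meta, aff, fix_meta)
            mask = (warped != 0) | (fix_arr != 0)
            if mask.sum() < params.min_overlap:
                return np.inf
            return -_eval_metric(params.metric, warped, fix_arr, mask,
                                 params.bins)

        if li == 0:
            # exhaustive translation seed on the coarsest grid
            step = 2 * vs_f[0]
            offsets = np.arange(-4, 5) * step
            best = (score(p), p.copy())
            for dx in offsets:
                for dy in offsets:
                    for dz in offsets:
                        cand = p.copy()
                        cand[:3] = [dx, dy, dz]
                        s = score(cand)
                        if s < best[0]:
                            best = (s, cand)
            p = best[1]

        scale = np.ones(nparams)
        scale[:3] = vs_f[0]  # translations step one voxel
        scale[3:6] = 0.05  # radians
        if nparams > 6:
            scale[6:] = 0.05
        res = optimize.minimize(
            score, p, method="Nelder-Mead",
            options={"maxiter": max(20, min(iters * 3, 240)),
                     "xatol": 1e-3, "fatol": 1e-9,
                     "initial_simplex": _simplex(p, scale)})
        p = res.x
    final = _params_to_affine(p, dof, center)
    return final


def _simplex(p, scale):
    n = len(p)
    simplex = np.tile(p, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += scale[i]
    return simplex


# ---------------------------------------------------------------------------
# Demons nonlinear registration
# ---------------------------------------------------------------------------

def demons_displacement(mov_arr, fix_arr, spacing, params: RegistrationParams,
                        channels=None):
    """Core demons loop on raw arrays; returns displacement in voxel units on
    the fixed grid, plus the final metric value.

    ``channels`` optionally provides matched multi-channel images
    ``(mov_channels, fix_channels)`` — forces are then averaged over channels
    while the acceptance metric is still evaluated on the scalar pair.
    """
    params = params.effective()
    ndim = np.asarray(fix_arr).ndim
    spacing = np.broadcast_to(np.asarray(spacing, float), (ndim,))
    disp = None
    metric_value = -np.inf

    for factor, iters in zip(params.pyramid_levels, params.iterations):
        fix_l = _downsample_level(fix_arr, factor)
        mov_l = _downsample_level(mov_arr, factor)
        if channels is not None:
            mov_ch = [_downsample_level(c, factor) for c in channels[0]]
            fix_ch = [_downsample_level(c, factor) for c in channels[1]]
        # regularization: every increment is Gaussian-smoothed before being
        # composed into the running field, so the accumulated field is a sum
        # of smooth updates (fluid-like regularization)
        fluid_sigma = max(params.smoothing_sigma / (spacing[0] * factor), 0.5)

        if disp is None:
            disp = np.zeros(fix_l.shape + (ndim,))
        else:
            disp = _rescale_disp(disp, fix_l.shape)

        mask = (mov_l != 0) | (fix_l != 0)
        # working images for force computation
        if channels is not None:
            force_pairs = list(zip(mov_ch, fix_ch))
        elif params.metric == "nmi":
            matched = (_match_histogram(mov_l, fix_l, mask)
                       if mask.any() else mov_l)
            force_pairs = [(_normalize(matched, mask), _normalize(fix_l, mask))]
        elif params.metric == "local-correlation":
            force_pairs = [(_local_normalize(mov_l), _local_normalize(fix_l))]
        else:
            force_pairs = [(_normalize(mov_l, mask), _normalize(fix_l, mask))]

        warped = _warp_voxels(mov_l, disp)
        mval = _eval_metric(params.metric, warped, fix_l, mask, params.bins)
        step = params.step_size
        rejects = 0
        for _ in range(iters):
            force = np.zeros_like(disp)
            for mov_f, fix_f in force_pairs:
                w = _warp_voxels(mov_f, disp)
                diff = fix_f - w
                grads = np.gradient(w)
                if ndim == 1:  # pragma: no cover
                    grads = [grads]
                gmag2 = sum(g * g for g in grads)
                denom = gmag2 + diff * diff + 1e-9
                for c in range(ndim):
                    force[..., c] += diff * grads[c] / denom
            force /= len(force_pairs)
            update = np.stack([ndimage.gaussian_filter(force[..., c], fluid_sigma)
                               for c in range(ndim)], axis=-1)
            update *= step
            mag = np.sqrt((update ** 2).sum(axis=-1)).max()
            if mag > step:  # cap the largest voxel motion at `step` voxels
                update *= step / mag
            cand = disp + update
            warped = _warp_voxels(mov_l, cand)
            cand_val = _eval_metric(params.metric, warped, fix_l, mask,
                                    params.bins)
            if cand_val >= mval - 1e-12:
                disp, mval = cand, max(mval, cand_val)
                step = min(step * 1.2, params.step_size)
                rejects = 0
            else:
                step *= 0.5
                rejects += 1
                if rejects >= 6:
                    break
        metric_value = mval

    return disp, metric_value


def _rescale_disp(disp, new_shape):
    """Resample a voxel-unit displacement field onto a new grid shape,
    rescaling vector magnitudes with the grid ratio."""
    ndim = disp.shape[-1]
    old_shape = disp.shape[:-1]
    ratio = [n / o for n, o in zip(new_shape, old_shape)]
    grids = [np.arange(n) / r for n, r in zip(new_shape, ratio)]
    mesh = np.meshgrid(*grids, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    comps = []
    for c in range(ndim):
        v = ndimage.map_coordinates(disp[..., c], coords, order=1,
                                    mode="nearest").reshape(new_shape)
        comps.append(v * ratio[c])
    return np.stack(comps, axis=-1)


def register_nonlinear(moving: IntensityVolume, fixed: IntensityVolume,
                       params: RegistrationParams | None = None,
                       initial: AffineTransform | None = None
                       ) -> DeformationField:
    """Demons-style nonlinear registration; returns the displacement field on
    the fixed grid (µm).

    With ``initial`` set, the moving image is first resampled through the
    affine and the returned field is the residual: apply both via
    ``apply_transform(vol, [field, affine])``.
    """
    params = params or RegistrationParams()
    _check_images(moving, fixed)
    mov = moving
    if initial is not None and not initial.is_identity():
        arr = _resample_affine(moving.values, moving.meta, initial, fixed.meta)
        mov = IntensityVolume(arr, fixed.meta)
    disp_vox, metric_value = demons_displacement(
        mov.values, fixed.values, fixed.meta.voxel_size, params)
    disp_um = disp_vox * np.asarray(fixed.meta.voxel_size)
    fld = DeformationField(disp_um, fixed.meta)
    fld.final_metric = metric_value
    return fld


def register_labels(moving_ann: LabeledVolume, fixed_ann: LabeledVolume,
                    params: RegistrationParams | None = None,
                    label_sigma_vox: float = 1.0):
    """Label-driven registration via smoothed per-label indicator channels.

    Shared labels become Gaussian-blurred soft masks; an affine stage on the
    summed channels is followed by multi-channel SSD demons.  Returns
    ``(affine, field)``.
    """
    params = params or RegistrationParams(metric="ssd")
    shared = sorted(set(np.unique(moving_ann.labels))
                    & set(np.unique(fixed_ann.labels)) - {0})
    if not shared:
        raise RegistrationError("annotations share no labels")

    def soft(ann):
        chans = [ndimage.gaussian_filter((ann.labels == lab).astype(float),
                                         label_sigma_vox) for lab in shared]
        return chans

    mov_ch, fix_ch = soft(moving_ann), soft(fixed_ann)
    # scalar encodings for the affine stage: weighted channel sum keeps
    # distinct labels distinguishable
    weights = np.linspace(1.0, 2.0, len(shared))
    mov_sum = sum(w * c for w, c in zip(weights, mov_ch))
    fix_sum = sum(w * c for w, c in zip(weights, fix_ch))
    aff_params = replace(params.effective(), metric="ssd")
    aff = register_affine(IntensityVolume(mov_sum, moving_ann.meta),
                          IntensityVolume(fix_sum, fixed_ann.meta),
                          aff_params, dof="affine")
    mov_ch_res = [_resample_affine(c, moving_ann.meta, aff, fixed_ann.meta)
                  for c in mov_ch]
    mov_sum_res = _resample_affine(mov_sum, moving_ann.meta, aff,
                                   fixed_ann.meta)
    nl_params = replace(params.effective(), metric="ssd")
    disp_vox, metric_value = demons_displacement(
        mov_sum_res, fix_sum, fixed_ann.meta.voxel_size, nl_params,
        channels=(mov_ch_res, fix_ch))
    disp_um = disp_vox * np.asarray(fixed_ann.meta.voxel_size)
    fld = DeformationField(disp_um, fixed_ann.meta.with_shape(fixed_ann.labels.shape))
    fld.final_metric = metric_value
    return aff, fld


# ---------------------------------------------------------------------------
# Application of transforms
# ---------------------------------------------------------------------------

def apply_transform(vol, transform, interpolation: str | None = None,
                    out_meta: GridMeta | None = None):
    """Resample a volume through a transform (or a sequence applied to points
    in listed order) onto ``out_meta`` (default: the fixed grid of the first
    field, else the volume's own grid).

    Labels require nearest-neighbour interpolation; intensities default to
    linear.  Out-of-domain voxels become background/0.
    """
    transforms = transform if isinstance(transform, (list, tuple)) else [transform]
    transforms = [t for t in transforms if t is not None]
    is_labels = isinstance(vol, LabeledVolume)
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    if is_labels and interpolation != "nearest":
        raise ValueError("labelled volumes must use nearest interpolation")
    order = 0 if interpolation == "nearest" else 1
    if out_meta is None:
        for t in transforms:
            if isinstance(t, DeformationField):
                out_meta = t.meta
                break
        else:
            out_meta = vol.meta
    out_meta = out_meta.with_shape(out_meta.shape or vol.data.shape)
    pts = out_meta.world_grid().reshape(-1, out_meta.ndim)
    for t in transforms:
        pts = t.apply_points(pts)
    coords = ((pts - np.asarray(vol.meta.origin))
              / np.asarray(vol.meta.voxel_size)).T
    src = vol.labels if is_labels else vol.values
    out = ndimage.map_coordinates(src.astype(float), coords, order=order,
                                  mode="constant", cval=0.0)
    out = out.reshape(out_meta.shape)
    if is_labels:
        return LabeledVolume(np.round(out).astype(np.int64), out_meta)
    return IntensityVolume(out, out_meta)
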