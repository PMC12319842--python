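# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic phantom does and does not emulate,
and the design choices made where the design was genuinely open.

## Coordinate and grid conventions

Voxel indices are 0-based; the world coordinate (µm) of voxel `i` along an
axis is `origin + i × voxel_size` (voxel-centre convention). Axis roles name
the anatomical direction of each array axis (`rostrocaudal`, `dorsoventral`,
`leftright`; index 0 on the left-right axis is the left side) and travel with
the volume through I/O: NIfTI headers carry spacing in mm (converted to µm)
and the roles in the description field; the built-in NRRD codec stores
spacing in µm with a custom `axis roles` key. Padding a volume shifts its
origin by `−before × voxel_size` per axis so world coordinates of existing
content never move — e.g. 14 rostral slabs at 25 µm shift the origin by
−350 µm. Transforms map fixed-space world points into moving-space points
(the resampling convention); composing transforms chains the point maps so
that warping through the composition equals sequential warping.

## Registration engine

The nonlinear model is a multi-resolution demons-style free-form displacement
field, not a geodesic/symmetric diffeomorphism: the pipeline's contract only
needs a monotone aligner, and a displacement field with Gaussian-smoothed
updates is simpler, fast in pure numpy/scipy, and easy to reason about.

Per pyramid level (default factors ×4/×2/×1 with 100/50/20 iterations) the
loop: warps the moving image through the current field, computes per-voxel
demons forces `(f − m∘u)·∇(m∘u) / (|∇|² + diff²)`, Gaussian-smooths the
update (σ = `smoothing_sigma` converted to level voxels, default 150 µm),
scales it by an adaptive step (start 2 voxels, capped at that magnitude),
and **accepts the step only if the configured metric does not decrease** —
rejected steps halve the step size and six consecutive rejections end the
level. The accumulated field is therefore a sum of smooth increments
(fluid-like regularization) and the optimized metric is monotone over
accepted iterations by construction. Everything is deterministic: no
stochastic sampling is used, so fixed parameters reproduce fields bit-for-bit.

Metric variants: `ssd` (monomodal), `nmi` (64-bin joint histogram over the
union-foreground mask; forces are computed on a masked-histogram-matched copy
of the moving image, which is monotone and brings the pair into a common
intensity frame, while acceptance is judged on NMI itself), and
`local-correlation` (forces on locally mean/variance-normalized images,
σ = 3 voxels). The `aggressive` flag — used for the cerebellar path — halves
the smoothing, doubles iterations and switches to local-correlation forces.

The default smoothing of 150 µm (6 voxels at 25 µm) reflects the smooth,
large-wavelength anatomical deformations the toolkit targets; piecewise
uniform tissue carries registration signal mostly at boundaries and interior
motion is recovered by propagation, so substantially smaller kernels
under-displace region interiors.

Affine registration parameterizes rigid (6), similarity (7) or full affine
(12) degrees of freedom about the fixed-volume centre, seeds translation by
an exhaustive ±8-voxel grid search at the coarsest level, and refines with
Nelder–Mead per level. Label-driven registration converts each shared label
into a Gaussian-blurred indicator channel (σ = 1 voxel), runs the affine
stage on a weighted channel sum and the demons stage on summed multi-channel
SSD forces.

## Alignment pipeline

Stage order and reconstruction policy:

1. **Global label initialization** registers `annV2 → annV3` (labels only)
   and applies both stages to the Nissl volume (linear) and annotation
   (nearest).
2. **Region-wise registration** processes comparable leaves in ascending-id
   order. Crops take the union bounding box of the moving and fixed masks
   plus a 5-voxel margin. The moving mask is dilated by 2 voxels before
   masking so warped boundary voxels interpolate real tissue rather than
   zeros. Regions under 50 voxels on either side are skipped (flagged) and
   fall through to the next fill level. Warped content claims only the
   *eroded* fixed-space region mask (the outermost voxel shell is left to
   the continuous global fill) and only where the warp delivered tissue;
   conflicts are counted, first writer wins. Parent-level registrations run
   on descendant-aggregated masks and fill still-empty voxels; the global
   fill then copies the initialized volume everywhere unclaimed, keeping the
   reconstruction whole-brain tissue rather than a bare mosaic. The
   one-voxel seam rim and the fill ordering are what make whole-brain NMI
   non-decreasing from the initialization to the mosaic on the phantom.
3. **Cerebellar path**: each lobule's annotation mask is registered
   independently (affine + aggressive nonlinear on the mask channels), the
   transforms carry the Nissl lobule, and the mosaic claims only fixed-space
   lobule voxels. It merges after the generic leaves and before the final
   pass.
4. **Final whole-brain pass**: one monomodal nonlinear registration of the
   initialized (continuous) volume onto the reconstruction; the output is
   the warped continuous volume, so region seams disappear while the refined
   geometry is kept.

Fiducial evaluation: the composed estimated point map (final field → global
field → global affine) sends a reference point `r` to a predicted moving
position; TRE-after is its distance to the point's true moving-space
position, TRE-before the distance `|r − m|` itself. For smooth transforms
this forward-mapped error agrees with the warped-image reading error to
first order and avoids numerically inverting the estimated field.

## Tissue extension

`extend_region` follows a fixed eight-step sequence (each logged): global
similarity registration of the donor; crop to the full-region bounding box
(+4 voxels); mask *both* sides with the truncated annotation (dilated by 2
voxels) so only mutually present tissue drives a nonlinear registration with
no linear stage; apply the field to the unmasked donor; histogram-match the
donor over the overlap (256 quantile bins, monotone by construction,
background stays zero); copy donor tissue where the region is missing; and
average a three-voxel junction slab along the rostro-caudal axis, centred on
the first originally-populated target plane. Donor voxels never overwrite
original tissue, and nothing outside the full mask changes except the
junction slab.

`merge_annotations` integrates label volumes by overlay (shared grid or an
affine placement) or slab concatenation; label id spaces must be disjoint
unless an explicit remap is given, and overlaps resolve by a declared
precedence with the overlap count reported.

## Cerebellar layers

Otsu's threshold is computed over a 256-bin histogram of the in-mask
intensities by direct maximization of between-class variance; ties (the
variance is exactly flat across empty bins between well-separated modes)
break toward the lowest boundary, which leaves the induced classification
unchanged. Each lobule is processed independently (order-invariant); voxels
above threshold become the granular layer. Isolated islands under 10 voxels
are reassigned to the surrounding class — an automatic stand-in for manual
review — and lobules whose split puts under 1 % of voxels in either class
are flagged rather than rejected. The Purkinje layer at fine resolution
takes one voxel from each side of the granular/molecular interface
(6-adjacency): symmetric, parameter-free, and exactly two voxels thick
across a locally planar interface. Annotation upsampling is nearest-neighbour
block replication followed by one 3×3×3 modal-filter pass, which keeps label
ids exact and moves interfaces by at most one fine voxel.

## Average template

Sections register to their planes of the *fixed* initialization, never a
progressively updated average — this makes the build order-independent and
deterministic. Contribution counts increment only where a warped section has
tissue, so partial sections do not dilute uncovered voxels. Normalization is
`(init + Σ) / (1 + count)` where any section contributed — the
initialization counts as one dataset (configurable off) — and the
initialization value elsewhere. With registration pinned off (pre-aligned
sections), output error variance follows the i.i.d. averaging law σ²/(n+1).

## The phantom and what it does not show

The standard bundle is a 64×80×56 grid at 25 µm: a brain-shaped ellipsoid
holding 8 ellipsoidal leaf regions under a 15-node ontology, including a
four-lobule "cerebellum" whose lobules carry a bright inner (granular-like,
intensity 200) and dark outer (molecular-like, 50) shell. The Nissl-like
modality adds i.i.d. Gaussian speckle (σ = 5) on top of a smooth
multiplicative anatomical texture (±15 %, 3-voxel correlation length) shared
by both modalities — real tissue has cytoarchitectural structure inside
every region, and that texture is what lets deformable registration recover
motion away from boundaries. The template-like modality is the same anatomy
gamma-compressed (exponent 0.6) and blurred (σ = 1.5 voxels): smooth and
low-contrast. The old-version annotation and the Nissl volume are produced
by a recorded component-wise sinusoidal displacement (amplitude 3 voxels,
wavelength 36 voxels — smooth and invertible), with two leaves merged into
their parents; fiducials are comparable-leaf centroids plus one offset point
each, with exact moving-space positions obtained by fixed-point inversion of
the recorded field.

Passing the phantom battery shows the machinery is correct and monotone
under known, smooth, moderate deformations with idealized geometry. It does
not show performance on real histology: tears and folds, staining gradients,
non-smooth inter-specimen variability, hundreds of regions with thin or
disconnected shapes, and genuinely different contrast mechanisms are all
outside what the generator emulates, and the published real-data figures
(whole-brain NMI gains, operator TRE reductions, expert-comparison Dice)
are not reproducible from synthetic data.

## Numerical choices and degenerate inputs

* Joint histograms: 64 bins, per-image min–max edges over the mask; entropy
  in bits (NMI is base-invariant). Constant images make NMI undefined — an
  explicit error, never silently 0 or 1.
* The default NMI mask is the union of the two foregrounds; both-background
  voxels would otherwise dominate the histogram.
* Majority-vote ties in label downsampling and in the modal filter break
  toward the smallest label id.
* `clean_border_voxels` defaults: 26-connectivity, minimum component 5
  voxels at 25 µm; a small component face-adjacent to a larger same-label
  component is never removed.
* Dice of two empty masks and Otsu of a constant sample are errors;
  empty sections are skipped with a log entry; a region with no ancestor
  supported in both annotation volumes is an ontology error (the root always
  qualifies on non-empty brains).
* Problem sizes: the suite and the acceptance script run the full pipeline
  once on the standard 64×80×56 phantom and the template averaging at up to
  40 synthetic specimens — sizes chosen so a complete run stays within a few
  minutes on a single CPU core while every property remains measurable.

## Known limitations

* The demons engine is a stand-in for production tools (symmetric
  diffeomorphic or block-matching registration); it matches their contracts
  (monotone metric, deterministic, bounded recovery error on smooth warps),
  not their numerics.
* Integer block factors only for resampling (matching the 10↔25 µm usage);
  no DICOM/OME-Zarr, no streaming I/O, no GPU.
* Only single-axis (coronal-style) sections are supported by the template
  builder; sagittal handling would need hemisphere logic the data model does
  not carry.
* The two-voxel Purkinje interpretation (one voxel per side) is one of
  several defensible readings of a "two-voxel layer at the interface";
  it was chosen for symmetry and testability.
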