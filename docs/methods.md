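# Methods

## Problem and approach

Two MR acquisitions of the same head — a clinical-field "reference" and a
high-field "test" scan — differ geometrically through scanner-level
distortion (gradient nonlinearity, B0 inhomogeneity, shimming residuals)
and subject-dependent susceptibility effects near air–tissue interfaces.
warpgauge quantifies that distortion the way it is done in stereotactic
practice: register the test scan to the reference with an intensity-based
affine registration, then read the distortion off the recovered transform
and off held-out anatomical landmarks. The affine registration is not a
correction method here but a *measurement instrument*: the non-rigid part
of the matrix (scales, shears, determinant) is a first-order estimate of
the distortion the hardware imposed, and piecewise re-registration of
sub-regions maps where it is concentrated.

Because no paired patient scans ship with the package, every stage is
validated on a digital phantom whose ground-truth distortion is known to
machine precision. Passing these tests shows the *instrument* works: that
the pipeline recovers affine distortion of the stated magnitude and
localizes a confined nonlinear warp under controlled degradations. It does
not by itself certify performance on clinical data, whose anatomy, noise
structure and artifact spectrum are richer than the phantom's.

## The phantom

The head analogue is an analytic sum of ellipsoids on a RAS-mm grid: one
brain envelope, a handful of named internal structures
(ventricle/thalamus/midbrain/cortical analogues), and two dozen scattered
small "gyrus" blobs placed by a seeded RNG so that **every** parcel of the
brain carries intensity structure — a region of uniform intensity is
invisible to any intensity cost, and a warp inside it would be
undetectable by construction. An optional Gaussian point-spread blur
(default 0.8 mm) emulates acquisition smoothing so intensities vary at
sub-voxel scale. Landmarks are the analytic centres of the internal
structures plus points on the brain envelope's principal axes, all
strictly interior.

Geometry comes in two sizes, chosen by `anatomy_scale`:

* scale 1.0 — a 56 mm brain on a 64³ 1 mm grid. Fast; used for the rigid
  and affine global-recovery experiments and the slab path.
* scale 2.4 — near-life-size (135 mm brain) on a 144×152×128 1 mm grid;
  used for regional mapping. The reason is resolution, not realism: a
  scale deviation of 0.005 over a parcel displaces content by
  `0.005 × parcel half-width`. At scale 1.0 that is ~0.05 mm (1/20 voxel),
  below what any intensity cost can resolve; at scale 2.4 it is a
  resolvable ~0.15 mm. Tolerances phrased in absolute units implicitly
  assume life-size anatomy.

### Ground-truth distortion chain

The forward map from reference space to test space is

    f(p) = A (p + d(p))

with `A` a 12-parameter affine (translations, rotations, scales, shear
tangents, applied about the volume centre) and `d` a Gaussian-bump
displacement field `a·exp(−r²/2σ²)` along a fixed direction — a
one-parameter stand-in for susceptibility warping; nothing in the package
infers or assumes a physical susceptibility model. The test volume is the
reference pulled back through `f` (the warp inverse solved by fixed-point
iteration, convergent because the displacement gradient is bounded below 1
by spec validation), then degraded in order:

1. multiplicative bias `exp(P(x))`, `P` a random polynomial of given order
   scaled to a peak log-magnitude;
2. Gaussian-profile signal dropout centred on a simulated air cavity
   (fraction `dropout_strength` at the centre);
3. Rician noise `|(I + n₁) + i·n₂|`, `n ~ N(0, σ²)` — the standard
   magnitude-MR model; background therefore follows Rayleigh(σ), which a
   KS test in the suite checks.

Landmark pairs are mapped through `f` exactly (no resampling), so landmark
recovery errors measure the registration, not the simulator. Two presets
("PS", smaller scale/shear residuals; "AS", larger, dominated by
through-plane scale and sagittal shear) emulate the contrast between a
passively and an actively shielded high-field system; their values are
illustrative magnitudes, not measurements.

Default degradation levels for the shipped experiments: noise σ = 3
intensity units against a ~60-unit brain (SNR ≈ 20), bias amplitude 0.2
(log units) where bias is exercised, marking-error jitter σ = 0.5 mm.

## Preprocessing

*Bias correction* estimates the log-domain field by mask-restricted
Gaussian smoothing (normalized convolution; default σ = 25 mm), iterated
to convergence because a single pass attenuates fields whose extent is
comparable to the object. The converged estimate contains everything the
smoother can see, which makes the operation idempotent (second pass
changes intensities ≪ 1%) and preserves the in-mask mean exactly. When no
mask is given, a crude foreground (10% of the 98th percentile) is used —
a Rician background floor must not enter the estimate, or the
brain/background step masquerades as shading. This is a deliberately
transparent estimator, not a reimplementation of any clinical tool; the
pipeline only needs non-uniformity flattened enough not to disturb the
registration.

*Brain extraction* is Otsu thresholding → largest connected component →
morphological closing (ball radius 2) → hole filling. Its product is the
**mask**. The registration uses the mask only to restrict cost sampling —
the intensities stay intact. We measured that registering hard-zeroed
("extracted") volumes is actively harmful on the phantom: the thresholded
cut surface is an artificial high-gradient edge whose position depends on
the threshold, and with two independently thresholded images the cost
aligns the two artificial edges instead of anatomy (observed as a
catastrophic ~6% scale error). The sampling mask is additionally dilated
by 4 voxels so the true boundary and a thin background ring anchoring it
stay inside the cost.

## Registration

Staged schedule, mirroring clinical affine co-registration practice:

1. centre-of-mass translation initialization;
2. exhaustive rotation grid search at the coarsest pyramid level
   (default ±30° per axis at 3° steps; the step is the method's defining
   parameter, the range a package default), best three candidates locally
   polished, best kept;
3. 6-DOF (rigid) Nelder–Mead refinement through a Gaussian dyadic pyramid
   (default 3 levels; axes shorter than 16 voxels are not decimated, so
   thin slabs never collapse through-plane);
4. if 12 DOF requested, scales and shears released at the two finest
   levels.

The cost is mutual information in bits from a joint histogram of fixed
intensities and trilinearly interpolated moving intensities over the
overlap, robust intensity range the 2nd–98th percentile; correlation ratio
is available as a fallback. The optimizer is derivative-free
(Nelder–Mead, adaptive, parameters scaled to characteristic magnitudes of
1 mm / 1° / 0.01) terminating when the cost change falls below
`convergence_tol` (default 1e-5 bits). When an initial transform is
supplied, the result is guaranteed not to score below it.

Three numerical choices matter for sub-voxel accuracy and were set by
measurement on the phantom (they are defaults, all exposed in
`RegistrationConfig`):

* **Jittered off-grid sampling.** Cost samples sit at mask voxel centres
  plus a uniform sub-voxel offset, with the fixed image interpolated
  there. Sampling exactly on the grid makes histogram MI prefer
  grid-commensurate geometry; we measured a ~1% scale displacement of the
  optimum for near-unity scales, which off-grid sampling removes.
* **32 histogram bins** (not 64): with SNR-20 noise, a bin narrower than
  the noise σ smears the joint histogram and biases the optimum by
  ~0.5% in scale. Bin width should be at least the noise scale.
* **Symmetric 0.5-voxel pre-smoothing** of both images during cost
  evaluation: interpolating a noisy moving image rewards contraction
  (interpolation averages noise, so sampling "inside" the grid looks
  cleaner), again a ~0.5% uniform scale bias; smoothing both sides
  symmetrically re-centres it. Smoothing only the moving side
  over-corrects.

With these, on the compact phantom at SNR 20 the 12-DOF registration
recovers 1% scales and 0.01 shears to ~0.002–0.003 and rigid parameters to
~0.01 mm / 0.05°.

## Transform metrics

The world-mm 3×3 block is factored `A₃ = R·S·H` (rotation, positive
diagonal scales, unit-upper-triangular shear) by QR with the diagonal
forced positive — the avscale-style convention. Shears are reported as the
tangents of the skew angles, i.e. the off-diagonal entries of `H` (three
of them; the factorization order is fixed and documented because shear
values are order-dependent). Headline metrics: `max_scale_dev = max|sᵢ−1|`,
`max_skew = max|hᵢⱼ|`, `volume_dev = |det−1|` (= `|Πsᵢ − 1|` exactly).
Reflections (negative determinant) raise — a same-subject registration
that mirrors is pathological. Metrics always come from the world-mm
matrix, so anisotropic voxels cannot masquerade as scaling.

## Landmark validation

Registration is landmark-free; named landmark pairs are held out and used
only to score it. Distances are 3D Euclidean in mm; the boxplot convention
is linear-interpolation quartiles, whiskers at the most extreme datum
within 1.5·IQR, outliers beyond. (The convention is configurable in code;
a "quintile" reading of box bounds was considered and rejected as a likely
typo in the source tradition.) Voxel-equivalent distances divide by the
reference voxel diagonal — the conservative one-voxel yardstick. Missing
names are dropped pairwise with a warning, mirroring landmarks that are
unmarkable in one acquisition. The marking-error model is isotropic
Gaussian jitter (σ = 0.5 mm default); the suite checks the observed mean
pair distance against a Monte-Carlo simulation of the same model.

## Regional mapping

The brain-mask bounding box is split into equal thirds along the
anterior–posterior axis and (for the 3×3 scheme) superior–inferior axis,
full left–right extent, remainder voxels to the last third; the slab
scheme uses anterior–posterior thirds only. The test volume is resampled
once through the global transform; each region is then re-registered to
the corresponding reference region with a bounded 12-DOF fit
(|scale−1| ≤ 0.1, |shear| ≤ 0.1) starting at identity, and the total
per-region transform is `local ∘ global` (global applied first — the local
fit acts in fixed space because the moving volume was globally resampled;
the order is verified by landmark mapping in the suite). Local fits use a
single pyramid level (the global transform already aligns crops to within
~1 mm, and coarse levels of a small crop have too few samples for a stable
histogram), a 20k-sample cap with two jitter replicates per voxel, and a
tighter 1e-6 convergence tolerance.

A local registration "succeeds" when its in-region cost at least matches
the global transform's; on failure the fallback ladder is restricted
rotation search (±5°), correlation-ratio cost, then perturbed
initializations, and only if everything fails is the region excluded.
Regions are also excluded *before* registration when signal loss leaves
nothing to register: fewer than 50% of in-mask region voxels above 10% of
the volume's robust maximum (98th percentile in-mask). Both thresholds are
configurable.

Two facts about detectability shaped the shipped regional experiment and
are worth knowing when interpreting real maps:

* A Gaussian warp *centred* in a region is mostly translation to an affine
  observer: the displacement gradient vanishes at the bump centre, so the
  region-level skew signature comes from the bump being cut
  *asymmetrically* by the region. The experiment therefore places the
  2 mm bump at the region's outer (brain-surface) corner — which is also
  the physically typical geometry, susceptibility bumps living at
  air–tissue interfaces. The induced regional mean gradient scales as
  `a·2πσ²/V_region`, which fixes the bump width (σ = 12 mm at life size)
  needed for the skew to clear the fit noise floor.
* The warped voxels also participate in the *global* fit and drag it
  slightly; distant regions then show small compensating locals. Keeping
  the bump volume a small fraction of the brain keeps that leakage below
  the 0.005 identity band.

## Orchestration, formats, CLI

`run_pipeline` executes bias correction → brain extraction → global
registration (6 then 12 DOF staged internally) → landmark assessment →
decomposition → regional analysis → edge-overlay QC, logging START/END per
stage with input hashes; a stage error skips dependents but the partial
report is still written. All numbers in the report come from module calls.
Formats: NIfTI-1 volumes (nibabel), landmark TSV (`name\tx\ty\tz`, world
mm), 4×4 whitespace text transforms in world-mm convention with a header
comment (converters to/from the scaled-voxel FLIRT-style convention are
provided, given both image geometries), JSON reports, CSV regional tables,
PNG overlays. The `warpgauge` CLI exposes each stage
(`simulate`, `preprocess`, `register`, `decompose`, `assess`, `regional`,
`overlay`, `run`) as a thin wrapper over the library.

Edge-overlay QC draws the registered volume's gradient-magnitude edges
(Sobel, 90th-percentile threshold of nonzero gradients) in red over the
grayscale reference at the three mid-slices — deterministic defaults so
the images are testable, where interactive inspection is the clinical
habit.

## Determinism

Every stochastic element (phantom blobs, noise, bias coefficients, cost
sampling, jitter, perturbed fallback inits) draws from
`numpy.random.default_rng` seeded from the caller; identical seeds give
bit-identical volumes and numerically identical pipeline outputs.
Nelder–Mead is deterministic given its start.

## Known limitations

* The phantom's ellipsoid anatomy has far less texture than a real brain;
  MI accuracy on real data depends on anatomy-driven histogram structure
  the phantom only sketches. Absolute recovery errors here are best-case.
* The through-plane scale of a 20-slice slab is weakly constrained
  (~1% recovery error against ~0.2–0.3% in-plane) — the anisotropic-voxel
  limitation that also caps landmark accuracy at one slice thickness
  through-plane.
* Regional skew below ~0.003–0.004 is indistinguishable from the fit noise
  floor even at life-size scale; the maps should be read with that floor
  in mind.
* No deformable registration: a nonlinear warp is *detected and localized*
  but only its affine shadow is quantified.
* The signal-loss rule is intensity-based only; pathological contrast
  changes that preserve brightness would not trigger exclusion.
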