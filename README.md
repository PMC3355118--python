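# warpgauge

Quantify the geometric distortion between two MR acquisitions of the same
brain — e.g. an ultra-high-field scan against the clinical-field scan used
for stereotactic surgical planning — by using an affine registration as a
measuring instrument.

Whether high-field images can be trusted for millimetre-accurate targeting
(deep brain stimulation of the STN, VIM or GPi) hinges on how much
geometric distortion the stronger field and gradients add. warpgauge
implements the standard clinical assessment loop as a reusable, tested
pipeline:

1. **Preprocess** — non-uniformity (bias field) correction and brain
   extraction, so only brain tissue drives the registration.
2. **Staged affine registration** — coarse 6-DOF rotation search (3° grid)
   → rigid refinement through a multi-resolution pyramid → 12-DOF affine
   polish, maximizing mutual information (correlation ratio as fallback).
3. **Landmark validation** — the registration is landmark-free; held-out
   anatomical landmark pairs score it via their 3D Euclidean distances
   (target registration error) and boxplot statistics.
4. **Transform decomposition** — the world-mm matrix is factored
   `A = R·S·H` (rotation · scales · shear); the distortion metrics are
   `max_scale_dev = max|sᵢ−1|`, `max_skew = max|hᵢⱼ|` (tangent of the skew
   angle) and `volume_dev = |det−1|`. Rigid content is not distortion;
   scaling is a weak form of it; shear is the real thing.
5. **Regional mapping** — the brain is parceled into 9 sub-regions (3
   anterior–posterior × 3 superior–inferior thirds; 3 slabs for thin
   axial acquisitions), each re-registered independently seeded by the
   global transform; per-region metrics of `local ∘ global` map where
   distortion concentrates. Regions with susceptibility signal loss are
   excluded automatically.

No patient data ships with the package. A **digital head phantom** with
fully parameterized ground truth (affine distortion, localized Gaussian
susceptibility warp, signal dropout, polynomial bias field, Rician noise,
exact landmark pairs) stands in for the scan pairs, so every stage is
validated by parameter recovery. See `docs/methods.md` for the models and
the numerical choices.

## Worked example

```python
import warpgauge as wg

# a reference head and its distorted "high-field" counterpart, truth known
spec = wg.default_head_spec(seed=0)
reference, landmarks = wg.generate_phantom(spec)
distortion = wg.DistortionSpec(
    translation_mm=(2.0, -1.5, 1.0), rotation_deg=(1.0, -1.0, 2.0),
    scales=(1.01, 0.99, 1.0), shears=(0.01, 0.0, -0.008),
    noise_sigma=3.0,                      # SNR ~ 20
)
test, truth = wg.apply_ground_truth_distortion(
    reference, distortion, seed=1, landmarks=landmarks,
    cavity_center_mm=spec.cavity_center_mm,
)

# register and read the distortion off the recovered transform
mask, _ = wg.extract_brain(reference)
xfm, cost, _ = wg.register(reference, test,
                           wg.RegistrationConfig(dof=12, seed=0),
                           fixed_mask=mask)
report = wg.decompose_affine(xfm)
print(f"max scaling change {report.max_scale_dev:.4f}, "
      f"max skew {report.max_skew:.4f}, volume change {report.volume_dev:.4f}")

# validate on the held-out landmarks
mapped = wg.transform_points(xfm, truth.landmarks_test)
stats = wg.landmark_distances(truth.landmarks_ref, mapped,
                              voxel_size_mm=reference.voxel_size)
print(f"landmark error: mean {stats.mean:.3f} mm, "
      f"max {stats.distances_mm.max():.3f} mm")
```

Output (seed 0):

```
max scaling change 0.0117, max skew 0.0108, volume change 0.0056
landmark error: mean 0.038 mm, max 0.054 mm
```

The applied distortion has true max scaling change 0.0096 and max skew
0.0117 (the values of the *inverse* map that registration recovers), so
both metrics come back to within ~0.002, and every landmark lands within
a tenth of a voxel — the registration measures ~1% scaling and ~0.01 skew
reliably at SNR 20.

The same stages are scripted as a narrative analysis under `analysis/`
(`01_simulate_phantoms.py` … `05_slab_analysis.py`, each writing tables
under `results/`), and exposed as a CLI:

```bash
warpgauge simulate --out pair/ --seed 0
warpgauge register pair/reference.nii.gz pair/test.nii.gz --dof 12 --out xfm.mat
warpgauge decompose xfm.mat
warpgauge assess --ref-lm pair/landmarks_reference.tsv \
    --test-lm pair/landmarks_test.tsv --xfm xfm.mat
warpgauge run --config pipeline.yaml        # full workflow from YAML
```

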