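"""Generate the synthetic study data: paired reference/test head volumes.

The reference volume stands in for a 1 mm isotropic T1-like clinical
acquisition; the test volume is the same head after a known geometric
distortion (the "PS" and "AS" scanner-hardware presets: nearly rigid
residuals vs. ~1% scales and ~0.01 shears), plus bias field and Rician
noise at SNR ~20. Ground-truth transforms and landmark pairs are written
alongside so every later stage can be scored by parameter recovery.

Writes results/phantoms/{ps,as}/ with reference.nii.gz, test.nii.gz,
landmark TSVs and a truth.json sidecar.
"""

import json
import sys
from pathlib import Path

import warpgauge as wg
from warpgauge.io_report import write_volume
from warpgauge.landmarks import write_landmarks_tsv

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    spec = wg.default_head_spec(seed=SEED)
    reference, landmarks = wg.generate_phantom(spec)
    for preset in ("PS", "AS"):
        out = ROOT / "results" / "phantoms" / preset.lower()
        out.mkdir(parents=True, exist_ok=True)
        distortion = wg.preset_distortion(
            preset, noise_sigma=3.0, bias_amplitude=0.2, bias_order=2
        )
        test, truth = wg.apply_ground_truth_distortion(
            reference, distortion, seed=SEED + 1,
            landmarks=landmarks, cavity_center_mm=spec.cavity_center_mm,
        )
        write_volume(reference, out / "reference.nii.gz")
        write_volume(test, out / "test.nii.gz")
        write_landmarks_tsv(truth.landmarks_ref, out / "landmarks_reference.tsv")
        write_landmarks_tsv(truth.landmarks_test, out / "landmarks_test.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "true_affine_ref_to_test": truth.true_affine.matrix.tolist(),
                    "expected_registration_affine":
                        truth.registration_affine.matrix.tolist(),
                    "degradation": truth.degradation.to_dict(),
                    "seed": SEED,
                },
                fh, indent=2,
            )
        print(f"{preset}: wrote phantom pair to {out}")
        print(f"  shape {test.shape}, noise sigma "
              f"{distortion.noise_sigma}, shears {distortion.shears}")


if __name__ == "__main__":
    main()
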