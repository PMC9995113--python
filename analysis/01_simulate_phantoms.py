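#!/usr/bin/env python
"""Generate one synthetic phantom per imaging modality with known ground truth.

Writes NIfTI volumes with JSON ground-truth sidecars (and a CSV curve table
for the DCE cohort) under results/phantoms/.  These are the inputs every
later analysis stage regenerates or reloads.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from glymphokit.image import save_nifti
from glymphokit.synthetic import (
    DCEParams,
    PhantomSpec,
    default_dwi_truth,
    gen_beads_phantom,
    gen_ciss_phantom,
    gen_dce_dataset,
    gen_dwi_series,
    gen_vtr_series,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "phantoms"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # CISS-like cisternography phantom at the acquisition-typical SNR 3.5
    spec = PhantomSpec(seed=SEED, snr=3.5)
    vol, truth = gen_ciss_phantom(spec)
    save_nifti(vol, OUT / "ciss_snr35.nii.gz")
    save_nifti(truth.csf_mask.astype(np.uint8), OUT / "ciss_csf_truth.nii.gz",
               spec.voxel_size)
    save_nifti(truth.compartment_labels, OUT / "ciss_labels_truth.nii.gz",
               spec.voxel_size)
    (OUT / "ciss_truth.json").write_text(json.dumps({
        "seed": SEED, "snr": 3.5, "grid": spec.grid_shape,
        "csf_voxels": int(truth.csf_mask.sum()),
        "brain_voxels": int(truth.brain_mask.sum()),
        "csf_fraction_of_brain": float(truth.csf_mask.sum() / truth.brain_mask.sum()),
    }, indent=2))
    print(f"CISS phantom: CSF {truth.csf_mask.sum()} voxels "
          f"({truth.csf_mask.sum() / truth.brain_mask.sum():.1%} of brain)")

    # multi-b DWI stack over the 17-value scheme, blockwise IVIM truth
    dwi_truth = default_dwi_truth(shape=(10, 10, 4), n_regions=4)
    series, _ = gen_dwi_series(SEED, dwi_truth, noise_sd=30.0)
    save_nifti(series["avg"].data, OUT / "dwi_avg.nii.gz", (0.15, 0.15, 0.5))
    (OUT / "dwi_truth.json").write_text(json.dumps({
        "b_values": list(series["avg"].b_values),
        "region_params": {
            str(r): {
                "fp": float(dwi_truth["fp"][dwi_truth["regions"] == r][0]),
                "d": float(dwi_truth["d"][dwi_truth["regions"] == r][0]),
                "d_star": float(dwi_truth["d_star"][dwi_truth["regions"] == r][0]),
            } for r in (1, 2, 3, 4)
        },
    }, indent=2))
    print(f"DWI stack: {series['avg'].data.shape} over {len(series['avg'].b_values)} b-values")

    # DCE cohort: 6 subjects, 90 one-minute scans, hippocampus-like kinetics
    p = DCEParams(arrival=5, time_to_peak=40, peak=100, duration=60)
    dce, _ = gen_dce_dataset(SEED, 6, 90, {"hippocampus": p}, noise_sd=5.0)
    rows = []
    for roi, s in dce.items():
        for subj in range(s.n_subjects):
            for t, v in zip(s.time_min, s.values[subj]):
                rows.append({"subject": f"s{subj}", "roi": roi,
                             "time_min": t, "value": v})
    pd.DataFrame(rows).to_csv(OUT / "dce_curves.csv", index=False)
    print(f"DCE cohort: {len(rows)} samples -> dce_curves.csv")

    # variable-TR saturation-recovery stack with a smooth flip-angle field
    t1_map = np.full((8, 8, 1), 1500.0)
    kappa = 0.85 + 0.2 * np.linspace(0, 1, 8)[:, None, None] * np.ones((8, 8, 1))
    stack, s45, s90, t1_truth = gen_vtr_series(SEED, t1_map, kappa_map=kappa)
    save_nifti(stack, OUT / "vtr_stack.nii.gz", (0.1, 0.1, 3.0))
    (OUT / "vtr_truth.json").write_text(json.dumps({
        "t1_ms": 1500.0, "tr_list_ms": list(t1_truth.extras["tr_list"]),
        "kappa_range": [float(kappa.min()), float(kappa.max())],
    }, indent=2))
    print(f"VTR stack: {stack.shape[-1]} TRs, kappa {kappa.min():.2f}-{kappa.max():.2f}")

    # microbead phantom (microCT-like)
    beads, bead_truth = gen_beads_phantom(SEED, (48, 48, 48), 4.0, 0.3)
    save_nifti(beads, OUT / "beads_uct.nii.gz")
    (OUT / "beads_truth.json").write_text(json.dumps({
        "true_free_fluid_fraction": bead_truth.free_fluid_fraction,
    }, indent=2))
    print(f"Bead phantom: true free-fluid fraction "
          f"{bead_truth.free_fluid_fraction:.3f}")


if __name__ == "__main__":
    main()
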