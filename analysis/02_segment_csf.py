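#!/usr/bin/env python
"""Segment the CSF space of CISS-like phantoms and report volumetry.

Runs the full adaptive chain (bounding box, solitary-region removal,
percentile seeding, contrast-driven region growing in three planes, median
filtering) on a noiseless and an SNR-3.5 phantom, compares against ground
truth, and writes the compartment volumetry table under results/volumetry/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from glymphokit.ciss import compartment_report, dice, segment_csf
from glymphokit.image import save_nifti
from glymphokit.synthetic import PhantomSpec, gen_ciss_phantom

OUT = Path(__file__).resolve().parent.parent / "results" / "volumetry"
SEED = 1


def run_one(snr, tag):
    spec = PhantomSpec(seed=SEED, snr=snr)
    vol, truth = gen_ciss_phantom(spec)
    seg = segment_csf(vol, truth.brain_mask)
    d = dice(seg.final_mask, truth.csf_mask)
    volumes, ratios = compartment_report(seg, truth.compartment_labels, spec.voxel_size)
    rows = [
        {"compartment": name, "volume_mm3": volumes[name],
         "ratio_pct": ratios.get(name, np.nan)}
        for name in volumes
    ]
    pd.DataFrame(rows).to_csv(OUT / f"volumetry_{tag}.csv", index=False)
    save_nifti(seg.final_mask.astype(np.uint8), OUT / f"final_mask_{tag}.nii.gz",
               spec.voxel_size)
    log = dict(seg.thresholds)
    log.update({"dice_vs_truth": float(d), "snr_requested": float(snr) if np.isfinite(snr) else "inf"})
    (OUT / f"runlog_{tag}.json").write_text(json.dumps(log, indent=2, default=str))
    print(f"{tag}: Dice {d:.3f}, whole-CSF ratio "
          f"{ratios['whole_csf']:.2f}% of brain-minus-CSF")
    return d


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    d_clean = run_one(np.inf, "noiseless")
    d_noisy = run_one(3.5, "snr35")
    print(f"Segmentation recovered ground truth at Dice {d_clean:.3f} "
          f"(noiseless) and {d_noisy:.3f} (SNR 3.5).")


if __name__ == "__main__":
    main()
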