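#!/usr/bin/env python
"""Fit the monoexponential ADC and segmented IVIM models to DWI phantoms.

Recovers (S0, ADC) and (Fp, D, D*) from noiseless and Rician-noisy (SNR 30)
stacks generated over the 17-b-value scheme, tabulates per-region recovery
against ground truth, and writes parameter maps and ROI statistics under
results/diffusion/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glymphokit.dwi import fit_adc, fit_ivim_segmented, roi_statistics, select_ivim_threshold
from glymphokit.image import save_nifti
from glymphokit.synthetic import B_VALUES, default_dwi_truth, gen_dwi_series, ivim_signal

OUT = Path(__file__).resolve().parent.parent / "results" / "diffusion"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    b_thr = select_ivim_threshold(B_VALUES)
    print(f"IVIM threshold b-value: {b_thr:.0f} s/mm^2 (closest to 250)")

    truth = default_dwi_truth(shape=(10, 10, 4), n_regions=4)
    s_b0 = float(ivim_signal(B_VALUES[0], 1000.0, 0.10, 7e-4, 1e-2))

    rows = []
    for tag, noise_sd in (("noiseless", 0.0), ("snr30", s_b0 / 30.0)):
        series, _ = gen_dwi_series(SEED, truth, noise_sd=noise_sd)
        adc = fit_adc(series["avg"])
        ivim = fit_ivim_segmented(series["avg"], b_threshold=b_thr)
        save_nifti(ivim.d_slow, OUT / f"d_map_{tag}.nii.gz", (0.15, 0.15, 0.5))
        save_nifti(ivim.fp, OUT / f"fp_map_{tag}.nii.gz", (0.15, 0.15, 0.5))
        for region in (1, 2, 3, 4):
            sel = truth["regions"] == region
            fp_t = float(truth["fp"][sel][0])
            d_t = float(truth["d"][sel][0])
            adc_mean, adc_sd, n = roi_statistics(adc.adc, sel)
            d_med = float(np.nanmedian(ivim.d_slow[sel]))
            fp_med = float(np.nanmedian(ivim.fp[sel]))
            rows.append({
                "condition": tag, "region": region, "n_voxels": int(sel.sum()),
                "fp_true": fp_t, "fp_median": fp_med,
                "d_true": d_t, "d_median": d_med,
                "d_error_pct": abs(d_med - d_t) / d_t * 100.0,
                "adc_roi_mean": adc_mean, "adc_roi_sd": adc_sd,
            })
            print(f"  {tag} region {region}: D {d_med:.2e} "
                  f"(true {d_t:.2e}), Fp {fp_med:.3f} (true {fp_t:.2f})")
    pd.DataFrame(rows).to_csv(OUT / "recovery_table.csv", index=False)
    print("Per-region recovery written to recovery_table.csv")


if __name__ == "__main__":
    main()
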