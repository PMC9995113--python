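#!/usr/bin/env python
"""T1-map the bead phantoms and estimate their free-fluid fractions.

Fits the saturation-recovery model over the 13-TR scheme with dual-angle B1
correction, then applies the percentile free-fluid estimator to microCT-like
bead phantoms of three particle sizes (coarser beads leave more free fluid).
Writes the phantom summary under results/t1_phantom/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glymphokit.relaxometry import apply_b1, b1_correction, fit_t1, free_fluid_fraction
from glymphokit.synthetic import gen_beads_phantom, gen_vtr_series

OUT = Path(__file__).resolve().parent.parent / "results" / "t1_phantom"
SEED = 1

# (bead radius px, nominal packing, expected T1 ms): finer beads pack denser,
# leave less free gadobutrol solution, hence shorter T1
PHANTOMS = {
    "coarse": (6.0, 0.25, 2200.0),
    "medium": (4.0, 0.35, 1900.0),
    "fine": (3.0, 0.45, 1600.0),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (name, (radius, packing, t1_ms)) in enumerate(PHANTOMS.items()):
        t1_map = np.full((6, 6, 1), t1_ms)
        kappa = np.full((6, 6, 1), 0.9)
        stack, s45, s90, truth = gen_vtr_series(
            SEED + i, t1_map, kappa_map=kappa, noise_sd=1000.0 / 80.0
        )
        fit = fit_t1(stack, truth.extras["tr_list"])
        kmap, _ = b1_correction(s45, s90)
        corr = apply_b1(fit, kmap)
        vol, bead_truth = gen_beads_phantom(
            SEED + 10 + i, (48, 48, 48), radius, packing
        )
        roi = np.ones(vol.data.shape, bool)
        est = free_fluid_fraction(vol, roi)
        rows.append({
            "phantom": name,
            "t1_fit_ms": float(np.nanmedian(corr.t1)),
            "t1_true_ms": t1_ms,
            "kappa_fit": float(np.nanmedian(kmap)),
            "true_free_fraction": bead_truth.free_fluid_fraction,
            "free_fraction_p75": est.fractions_at[75],
            "free_fraction_p80": est.fractions_at[80],
            "free_fraction_p85": est.fractions_at[85],
            "free_fraction_mean": est.mean_fraction,
        })
        print(f"{name}: T1 {rows[-1]['t1_fit_ms']:.0f} ms (true {t1_ms:.0f}), "
              f"free fluid {est.mean_fraction:.3f} "
              f"(true {bead_truth.free_fluid_fraction:.3f})")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "phantom_summary.csv", index=False)
    r = np.corrcoef(df["t1_fit_ms"], df["true_free_fraction"])[0, 1]
    print(f"T1 vs true free-fluid fraction across phantoms: r = {r:.3f}")


if __name__ == "__main__":
    main()
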