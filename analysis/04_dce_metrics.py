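#!/usr/bin/env python
"""Score DCE tracer kinetics per genotype group and compare the groups.

Builds two synthetic cohorts whose kinetics mirror the qualitative in-vivo
pattern (the knockout group shows later arrival, lower peak, smaller AUC),
derives the rank-sum metrics per ROI and group, and writes the metric and
per-time significance tables under results/dce/.
"""

from pathlib import Path

import pandas as pd

from glymphokit.dce import compare_groups, dce_metrics, friedman_ranksum_scores
from glymphokit.synthetic import DCEParams, gen_dce_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "dce"
SEED = 1

# per-ROI kinetics (minutes from infusion start); KO delayed and attenuated
ROIS = {
    "hippocampus": (DCEParams(5, 45, 46, 60), DCEParams(7, 60, 22, 45)),
    "thalamus": (DCEParams(2, 40, 61, 60), DCEParams(3, 48, 45, 55)),
    "circle_of_willis": (DCEParams(1, 24, 397, 70), DCEParams(1, 24, 339, 65)),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metric_rows, sig_rows = [], []
    for roi, (p_wt, p_ko) in ROIS.items():
        wt, _ = gen_dce_dataset(SEED, 6, 90, {roi: p_wt}, noise_sd=2.0)
        ko, _ = gen_dce_dataset(SEED + 1, 5, 90, {roi: p_ko}, noise_sd=2.0)
        for group, series in (("WT", wt[roi]), ("KO", ko[roi])):
            m = dce_metrics(series)
            metric_rows.append({
                "roi": roi, "group": group,
                "arrival_min": m.arrival_time, "time_to_peak_min": m.time_to_peak,
                "peak_intensity": m.peak_intensity, "duration_min": m.duration,
                "auc": m.auc,
            })
            curve = friedman_ranksum_scores(series)
            for t, s, sig in zip(curve.time_min, curve.score, curve.significant):
                sig_rows.append({"roi": roi, "group": group, "time_min": t,
                                 "score": s, "significant": bool(sig)})
        res = compare_groups(wt[roi], ko[roi])
        n_sig = int(res["significant"].sum())
        print(f"{roi}: {n_sig} time points differ between groups "
              f"(Bonferroni-corrected)")
    pd.DataFrame(metric_rows).to_csv(OUT / "dce_metrics_by_group.csv", index=False)
    pd.DataFrame(sig_rows).to_csv(OUT / "rank_scores.csv", index=False)
    print("Group kinetic metrics written to dce_metrics_by_group.csv")


if __name__ == "__main__":
    main()
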