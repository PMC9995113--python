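"""DCE-MRI tracer-kinetic scoring via Friedman mean ranks and Dunn contrasts.

Within one genotype group, each subject's ROI enhancement curve is ranked
across time (subjects are blocks, time points are treatments, midranks on
ties).  The per-time score is the baseline mean rank minus the mean rank at
that time — enhancement above baseline yields a *negative* score, matching
the convention that the "maximum negative rank-sum score" marks the peak.
Dunn's z statistics compare each time point against the baseline reference
only, Bonferroni-corrected over the number of compared time points.

Derived metrics: arrival time (score at least ``arrival_mult`` times the
baseline reference level), time-to-peak (most negative score), peak intensity
(group-mean enhancement at the peak), duration (span of significant time
points), and AUC (plain sum of amplitudes over time points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps


@dataclass
class DCESeries:
    """Subject x time enhancement matrix for one ROI."""

    values: np.ndarray                      # (n_subjects, n_time)
    time_min: np.ndarray                    # acquisition times in minutes
    baseline_indices: tuple[int, ...] = (0, 1, 2)
    infusion_start_min: float = 3.0
    infusion_duration_min: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.values.shape[1] != self.time_min.size:
            raise ValueError("values and time_min disagree on time points")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if max(self.baseline_indices) >= np.searchsorted(
            self.time_min, self.infusion_start_min, side="right"
        ):
            raise ValueError("baseline indices must precede the infusion start")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class RankScoreCurve:
    """Per-time Friedman rank-sum scores versus the baseline reference."""

    score: np.ndarray           # baseline mean rank - mean rank at t (signed)
    significant: np.ndarray     # after Bonferroni over compared time points
    z: np.ndarray
    baseline_ref: int           # reference time index
    time_min: np.ndarray
    alpha: float = 0.05


@dataclass
class DCEMetrics:
    arrival_time: float | None = None
    time_to_peak: float | None = None
    peak_intensity: float | None = None
    duration: float = 0.0
    auc: float = 0.0
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess_dce(series_4d: np.ndarray, baseline_index: int = 0) -> np.ndarray:
    """Baseline subtraction, Gaussian (z) normalization, separable smoothing.

    The volume at ``baseline_index`` (the first post-dummy scan) is subtracted
    voxel-wise from every frame and supplies the normalization mean/SD; each
    frame is then smoothed with the separable 1-D kernel [0.2, 1, 0.2]
    (normalized to unit sum) applied along each spatial axis.  The reference
    frame itself is excluded from the output.
    """
    data = np.asarray(series_4d, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) array")
    ref = data[..., baseline_index]
    sd = ref.std()
    if sd == 0:
        raise ValueError("reference volume has zero SD; normalization undefined")
    out = (data - ref[..., None]) / sd
    w = np.array([0.2, 1.0, 0.2])
    w = w / w.sum()
    for axis in range(3):
        out = ndimage.convolve1d(out, w, axis=axis, mode="reflect")
    keep = [t for t in range(data.shape[-1]) if t != baseline_index]
    return out[..., keep]


# --------------------------------------------------------------------------
# rank scoring
# --------------------------------------------------------------------------

def friedman_ranksum_scores(
    dce: DCESeries, baseline_ref: int | None = None, alpha: float = 0.05
) -> RankScoreCurve:
    """Friedman mean-rank scores and Dunn baseline-vs-time significance.

    ``score(t) = mean_rank(baseline_ref) - mean_rank(t)`` so that enhancement
    above baseline gives a negative score.  Dunn's
    ``z = |diff| / sqrt(k (k+1) / (6 n))`` with Bonferroni over the k-1
    non-reference time points at level ``alpha``.
    """
    if baseline_ref is None:
        baseline_ref = dce.baseline_indices[0]
    values = dce.values
    n, k = values.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, values)  # midranks on ties
    mean_ranks = ranks.mean(axis=0)
    score = mean_ranks[baseline_ref] - mean_ranks

    se = np.sqrt(k * (k + 1) / (6.0 * n))
    z = np.abs(score) / se
    if n < 3:
        warnings.warn("fewer than 3 subjects; significance undefined")
        significant = np.zeros(k, dtype=bool)
    else:
        z_crit = sps.norm.ppf(1.0 - alpha / (2.0 * (k - 1)))
        significant = z > z_crit
        significant[baseline_ref] = False
    return RankScoreCurve(
        score=score, significant=significant, z=z,
        baseline_ref=baseline_ref, time_min=dce.time_min, alpha=alpha,
    )


def baseline_reference_level(curve: RankScoreCurve, baseline_indices) -> float:
    """Max |score| over the baseline time points, floored at one midrank unit."""
    b = np.abs(curve.score[list(baseline_indices)])
    return float(max(b.max(), 1.0))


def arrival_time(
    curve: RankScoreCurve,
    baseline_indices=(0, 1, 2),
    arrival_mult: float = 3.0,
) -> float | None:
    """First post-baseline time where ``-score`` reaches ``arrival_mult`` times
    the baseline reference level, expressed in minutes from the baseline
    (last pre-infusion) time point.  None when never reached."""
    ref_level = baseline_reference_level(curve, baseline_indices)
    t_baseline = curve.time_min[max(baseline_indices)]
    after = np.arange(curve.score.size) > max(baseline_indices)
    hits = after & (-curve.score >= arrival_mult * ref_level)
    if not hits.any():
        return None
    return float(curve.time_min[np.argmax(hits)] - t_baseline)


def time_to_peak(curve: RankScoreCurve, infusion_start_min: float = 3.0):
    """Minutes from infusion start to the most negative score (earliest tie).
    None when no score is negative (flat curve)."""
    s = curve.score
    if np.all(s >= 0):
        return None
    idx = int(np.argmin(s))
    return float(curve.time_min[idx] - infusion_start_min)


def peak_intensity(mean_curve: np.ndarray, curve: RankScoreCurve) -> float | None:
    """Group-mean enhancement at the time-to-peak sample."""
    s = curve.score
    if np.all(s >= 0):
        return None
    return float(np.asarray(mean_curve)[int(np.argmin(s))])


def accumulation_duration(curve: RankScoreCurve) -> float:
    """(last significant time) - (first significant time); 0 when fewer than
    two significant time points."""
    idx = np.nonzero(curve.significant)[0]
    if idx.size < 2:
        return 0.0
    return float(curve.time_min[idx[-1]] - curve.time_min[idx[0]])


def dce_auc(mean_curve: np.ndarray) -> float:
    """Plain sum of DCE amplitudes over all measured time points."""
    return float(np.sum(np.asarray(mean_curve, dtype=float)))


def dce_metrics(dce: DCESeries, arrival_mult: float = 3.0, alpha: float = 0.05) -> DCEMetrics:
    """All rank-derived kinetic metrics for one ROI of one group."""
    curve = friedman_ranksum_scores(dce, alpha=alpha)
    mean_curve = dce.mean_curve
    return DCEMetrics(
        arrival_time=arrival_time(curve, dce.baseline_indices, arrival_mult),
        time_to_peak=time_to_peak(curve, dce.infusion_start_min),
        peak_intensity=peak_intensity(mean_curve, curve),
        duration=accumulation_duration(curve),
        auc=dce_auc(mean_curve),
        extras={"curve": curve},
    )


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

def compare_groups(group_a: DCESeries, group_b: DCESeries, alpha: float = 0.05):
    """Per-time-point group comparison with Bonferroni correction.

    Implements the per-time contrasts of a repeated-measures two-group design
    as two-sample t-tests at each time point, Bonferroni-corrected over the
    number of time points.  Returns a dict with per-time differences,
    corrected p-values, significance flags, and per-group metric summaries.
    """
    if group_a.values.shape[0] < 2 or group_b.values.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if not np.array_equal(group_a.time_min, group_b.time_min):
        raise ValueError("groups must share the time grid")
    k = group_a.time_min.size
    diff = group_a.mean_curve - group_b.mean_curve
    p = np.ones(k)
    for t in range(k):
        a, bb = group_a.values[:, t], group_b.values[:, t]
        if np.allclose(a, a[0]) and np.allclose(bb, bb[0]) and np.isclose(a[0], bb[0]):
            p[t] = 1.0
            continue
        p[t] = sps.ttest_ind(a, bb, equal_var=True).pvalue
    p_corr = np.minimum(p * k, 1.0)
    return {
        "time_min": group_a.time_min,
        "difference": diff,
        "p_corrected": p_corr,
        "significant": p_corr < alpha,
        "metrics_a": dce_metrics(group_a),
        "metrics_b": dce_metrics(group_b),
    }
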