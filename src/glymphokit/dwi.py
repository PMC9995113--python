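"""Noise normalization, brain masking, ADC and segmented IVIM fitting.

The monoexponential model ``S(b) = S0 exp(-b ADC)`` is fitted over all
b-values; the IVIM biexponential
``S(b) = S0 (Fp exp(-b D*) + (1-Fp) exp(-b D))`` is fitted with the segmented
two-step approach: the slow component (D) from a log-linear regression above
the threshold b-value (the acquired value closest to 250 s/mm^2), then D*
by nonlinear least squares with Fp and D held fixed.

Note "b0" throughout means the lowest *acquired* b-value (40 s/mm^2 in the
default scheme), not b = 0; the perfusion fraction estimated by comparing
S(b0) with the extrapolated slow-component intercept therefore carries a
downward bias that the optional iterative correction (default on) removes —
see ``fit_ivim_segmented``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import morphology

from glymphokit.image import ImageVolume


@dataclass
class DWISeries:
    """4-D multi-b stack for one diffusion-encoding direction."""

    data: np.ndarray                       # (x, y, z, b)
    b_values: tuple[float, ...]
    averages_per_b: tuple[int, ...] = ()
    voxel_size: tuple[float, float, float] = (0.15, 0.15, 0.5)
    direction: str = "avg"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        b = np.asarray(self.b_values, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != b.size:
            raise ValueError("data must be (x, y, z, n_b)")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")

    @property
    def b0_volume(self) -> np.ndarray:
        return self.data[..., 0]


@dataclass
class BackgroundStats:
    """Per-b background-noise statistics from a VOI outside the tissue."""

    mu_noise: np.ndarray     # per b-value
    sigma_noise: np.ndarray  # per b-value
    voi_voxels: np.ndarray   # (n, 3) index array


@dataclass
class DiffusionMaps:
    """Voxel-wise diffusion parameter maps (units mm^2/s where applicable)."""

    adc: np.ndarray | None = None
    s0_mono: np.ndarray | None = None
    d_slow: np.ndarray | None = None
    s0_lin: np.ndarray | None = None
    fp: np.ndarray | None = None
    fp_raw: np.ndarray | None = None
    d_star: np.ndarray | None = None
    valid: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def fp_dstar(self) -> np.ndarray:
        return np.where(np.isfinite(self.d_star), self.fp * self.d_star, np.nan)


# --------------------------------------------------------------------------
# background VOI and normalization
# --------------------------------------------------------------------------

def half_ball_voi(shape, center=None, n_voxels: int = 704) -> np.ndarray:
    """Indices of a half-ball VOI of ~``n_voxels`` voxels, default placed in a
    corner of the FOV (outside any centred phantom/brain)."""
    shape = tuple(shape)
    if center is None:
        center = (0, 0, shape[2] // 2)
    grids = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
    d2 = np.sum((grids - np.asarray(center)) ** 2, axis=-1).ravel()
    order = np.argsort(d2, kind="stable")[:n_voxels]
    return np.stack(np.unravel_index(order, shape), axis=1)


def background_stats(series: DWISeries, voi_voxels: np.ndarray) -> BackgroundStats:
    idx = tuple(np.asarray(voi_voxels).T)
    mu, sd = [], []
    for i in range(len(series.b_values)):
        vals = series.data[..., i][idx]
        mu.append(float(vals.mean()))
        sd.append(float(vals.std()))
    return BackgroundStats(np.array(mu), np.array(sd), np.asarray(voi_voxels))


def normalize_series(series: DWISeries, bg: BackgroundStats, clamp: bool = False) -> DWISeries:
    """Subtract the Rician noise floor per b-volume:
    ``DWI_norm = DWI - (mu_noise - 6 sigma_noise)``.

    A per-volume constant shift — within-volume voxel differences are
    preserved exactly.  Values may go negative unless ``clamp``.
    """
    if len(bg.mu_noise) != len(series.b_values):
        raise ValueError("background stats do not match the series b-values")
    offset = bg.mu_noise - 6.0 * bg.sigma_noise
    out = series.data - offset[None, None, None, :]
    if clamp:
        out = np.maximum(out, 0.0)
    return DWISeries(out, series.b_values, series.averages_per_b,
                     series.voxel_size, series.direction)


def compute_brain_mask(b0_volume: np.ndarray) -> np.ndarray:
    """Threshold the b0 image at mean + 0.5 SD, dilate with a 2-pixel diamond,
    and fill holes slice-wise."""
    b0 = np.asarray(b0_volume, dtype=float)
    thr = b0.mean() + 0.5 * b0.std()
    mask = b0 >= thr
    if not mask.any():
        raise ValueError("empty brain mask at mean + 0.5 SD threshold")
    diamond = morphology.diamond(1)  # 2-pixel diameter diamond kernel
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):  # axial slices
        sl = ndimage.binary_dilation(mask[..., k], structure=diamond)
        out[..., k] = ndimage.binary_fill_holes(sl)
    return out


def smooth_slices(volume: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Slice-wise 3x3 Gaussian smoothing (sigma in pixels, reflective edges)."""
    vol = np.asarray(volume, dtype=float)
    out = np.empty_like(vol)
    for k in range(vol.shape[2]):
        out[..., k] = ndimage.gaussian_filter(
            vol[..., k], sigma=sigma, radius=1, mode="reflect"
        )
    return out


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

def _loglinear(b: np.ndarray, s: np.ndarray, weights: np.ndarray | None = None):
    """Least-squares line through (b, ln s); returns (intercept_value, slope).

    With ``weights`` (typically ``s**2``) this is the standard log-domain
    approximation of nonlinear least squares on the untransformed signals;
    unweighted, the log transform over-weights the noisiest high-b points.
    """
    ln = np.log(s)
    if weights is None:
        slope, intercept = np.polyfit(b, ln, 1)
    else:
        slope, intercept = np.polyfit(b, ln, 1, w=np.sqrt(weights))
    return float(np.exp(intercept)), float(slope)


def fit_adc(series: DWISeries, mask: np.ndarray | None = None) -> DiffusionMaps:
    """Voxel-wise monoexponential least-squares fit of S0 and ADC.

    Initialized from the log-linear solution and refined by nonlinear least
    squares on the untransformed signals.  Voxels with no positive signal at
    any b are flagged invalid.
    """
    b = np.asarray(series.b_values, dtype=float)
    if b.size < 3:
        raise ValueError("need at least 3 b-values")
    shape = series.data.shape[:3]
    mask = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    adc = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for ijk in zip(*np.nonzero(mask)):
        s = series.data[ijk]
        pos = s > 0
        if pos.sum() < 2:
            continue
        s0_i, slope = _loglinear(b[pos], s[pos])
        x0 = np.array([s0_i, max(-slope, 0.0)])
        res = optimize.least_squares(
            lambda p: p[0] * np.exp(-b * p[1]) - s,
            x0,
            bounds=([0.0, 0.0], [np.inf, 1.0]),
            method="trf",
        )
        s0[ijk], adc[ijk] = res.x
        valid[ijk] = True
    return DiffusionMaps(adc=adc, s0_mono=s0, valid=valid)


def select_ivim_threshold(b_values, target: float = 250.0) -> float:
    """The acquired b-value closest to ``target``; ties break toward lower b."""
    b = np.asarray(b_values, dtype=float)
    if b.size == 0:
        raise ValueError("empty b-value list")
    dist = np.abs(b - target)
    candidates = b[dist == dist.min()]
    return float(candidates.min())


def _fp_corrected(s_b0, s0_lin, b0, d, d_star):
    """Closed-form Fp at b0 != 0 given the slow-component intercept and D*.

    Solves S(b0) = S0 [Fp e^(-b0 D*) + (1-Fp) e^(-b0 D)] with
    S0 = S0_lin / (1 - Fp); exact on noiseless biexponential data and
    reduces to (S_b0 - S0_lin)/S_b0 as b0 -> 0.
    """
    ec = np.exp(-b0 * d)
    ea = np.exp(-b0 * d_star)
    denom = s_b0 + s0_lin * (ea - ec)
    if denom <= 0:
        return np.nan
    return (s_b0 - s0_lin * ec) / denom


def fit_ivim_segmented(
    series: DWISeries,
    mask: np.ndarray | None = None,
    b_threshold: float | None = None,
    refit_s0: bool = True,
    correct_b0_offset: bool = True,
    weighted_loglinear: bool = True,
    n_iter: int = 3,
    d_star_max: float = 1.0,
) -> DiffusionMaps:
    """Two-step segmented IVIM fit.

    Step 1: log-linear regression over b >= ``b_threshold`` gives D (negative
    slope) and the extrapolated intercept S0_lin; the raw perfusion fraction
    is ``Fp = (S_b0 - S0_lin) / S_b0``.  The regression is signal^2-weighted
    by default (``weighted_loglinear``) so it approximates least squares on
    the untransformed signals; the unweighted log fit over-weights the
    floor-dominated highest b-values and biases D downward.  Step 2: where Fp > 0, nonlinear least
    squares of the biexponential with Fp and D fixed estimates D* (S0 is
    refined when ``refit_s0``, else held at S_b0).  Voxels with Fp <= 0 get
    Fp = 0 and undefined D* (NaN).

    With ``correct_b0_offset`` (default) Fp is re-derived after each D* fit
    from the closed-form correction for the nonzero minimum b-value, and
    step 2 repeated ``n_iter`` times; this removes the bias from "b0" being
    40 s/mm^2 rather than 0.
    """
    b = np.asarray(series.b_values, dtype=float)
    if b_threshold is None:
        b_threshold = select_ivim_threshold(b)
    if b_threshold not in b:
        raise ValueError("b_threshold must be one of the acquired b-values")
    high = b >= b_threshold
    if high.sum() < 2:
        raise ValueError("fewer than 2 b-values at/above the threshold")
    b0 = b[0]

    shape = series.data.shape[:3]
    mask = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    d_map = np.full(shape, np.nan)
    s0_lin_map = np.full(shape, np.nan)
    fp_map = np.full(shape, np.nan)
    fp_raw_map = np.full(shape, np.nan)
    ds_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    for ijk in zip(*np.nonzero(mask)):
        s = series.data[ijk]
        s_high = s[high]
        if np.any(s_high <= 0):
            continue  # log-regression undefined; voxel flagged
        s0_lin, slope = _loglinear(
            b[high], s_high, weights=s_high**2 if weighted_loglinear else None
        )
        d = max(-slope, 0.0)
        s_b0 = s[0]
        if s_b0 <= 0:
            continue
        fp_raw = (s_b0 - s0_lin) / s_b0
        d_map[ijk], s0_lin_map[ijk] = d, s0_lin
        fp_raw_map[ijk] = fp_raw
        valid[ijk] = True
        if fp_raw <= 0:
            fp_map[ijk] = 0.0
            continue

        fp = fp_raw
        d_star = np.nan
        ds_lo = max(d, 1e-12)
        for _ in range(max(n_iter, 1) if correct_b0_offset else 1):
            ds0 = min(max(10.0 * d, ds_lo * 1.01), d_star_max * 0.5)
            if refit_s0:
                def resid(p, fp=fp):
                    s0_, ds_ = p
                    return s0_ * (fp * np.exp(-b * ds_) + (1 - fp) * np.exp(-b * d)) - s
                x0 = np.array([s_b0, ds0])
                lb, ub = [0.0, ds_lo], [np.inf, d_star_max]
            else:
                def resid(p, fp=fp):
                    return s_b0 * (fp * np.exp(-b * p[0]) + (1 - fp) * np.exp(-b * d)) - s
                x0 = np.array([ds0])
                lb, ub = [ds_lo], [d_star_max]
            try:
                res = optimize.least_squares(resid, x0, bounds=(lb, ub), method="trf")
            except Exception:
                break
            d_star = float(res.x[-1])
            if not correct_b0_offset:
                break
            fp_new = _fp_corrected(s_b0, s0_lin, b0, d, d_star)
            if not np.isfinite(fp_new) or fp_new <= 0:
                break
            fp_new = min(fp_new, 0.999)
            if abs(fp_new - fp) < 1e-10:
                fp = fp_new
                break
            fp = fp_new
        fp_map[ijk] = fp
        ds_map[ijk] = d_star

    return DiffusionMaps(
        d_slow=d_map, s0_lin=s0_lin_map, fp=fp_map, fp_raw=fp_raw_map,
        d_star=ds_map, valid=valid,
        extras={"b_threshold": float(b_threshold)},
    )


def roi_statistics(param_map: np.ndarray, roi_mask: np.ndarray):
    """ROI mean/SD excluding negative values and values above the 99th
    percentile of the within-ROI distribution."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    vals = np.asarray(param_map, dtype=float)[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size:
        p99 = np.percentile(vals, 99)
        vals = vals[(vals >= 0) & (vals <= p99)]
    if vals.size == 0:
        warnings.warn("ROI empty after exclusions; statistics undefined")
        return np.nan, np.nan, 0
    return float(vals.mean()), float(vals.std()), int(vals.size)
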