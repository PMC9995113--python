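"""Synthetic phantom generators with known ground truth.

Every downstream stage of the pipeline (CSF segmentation, diffusion fitting,
DCE scoring, T1 mapping, bead-phantom porosity) is testable against phantoms
generated here.  Generators are pure functions of their seed and spec: the same
call with the same seed is bit-reproducible, and all randomness comes from one
`numpy.random.Generator` created per call.

Conventions
-----------
* Rician noise is the magnitude of a complex Gaussian with per-channel SD
  ``sigma``; the phantom "SNR" is foreground (parenchyma) mean divided by
  ``sigma``, matching the magnitude-MRI convention of measuring noise in a
  background VOI.
* The CISS-like phantom mimics heavily T2-weighted cisternography: bright CSF
  compartments (ventricles, perivascular tubes) over darker parenchyma at
  SNR around 3-5, modulated by a smooth low-order polynomial bias field.
* The DWI forward model is the IVIM biexponential
  ``S(b) = S0 * (Fp * exp(-b D*) + (1-Fp) * exp(-b D))`` evaluated over the
  17-b-value scheme used in the acquisition protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from glymphokit.image import ImageVolume

# 17-b-value diffusion scheme (s/mm^2); the lowest value (40) is the "b0".
B_VALUES: tuple[float, ...] = (
    40, 50, 59, 70, 92, 113, 165, 197, 238, 342, 445, 649, 854,
    1057, 1564, 2071, 3081,
)
# number of averages per b-value (>=1000 s/mm^2 acquired twice)
AVERAGES_PER_B: tuple[int, ...] = (1,) * 13 + (2,) * 4

# variable-TR scheme for saturation-recovery T1 mapping (ms)
TR_LIST_MS: tuple[float, ...] = (
    12000, 9000, 6500, 4000, 2000, 1000, 800, 500, 300, 100, 80, 50, 15,
)

# CSF compartment labels
COMPARTMENTS = {
    1: "lateral_ventricles",
    2: "third_ventricle",
    3: "fourth_ventricle",
    4: "basilar_artery",
    5: "basal_pvs_circle_of_willis",
    6: "parietal_pvs_cisterns",
    7: "remaining_pvs",
}


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    label: int = 1


@dataclass
class Tube:
    """Cylinder given by endpoints (voxel coords) and radius (voxels)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    label: int = 7


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _tube_mask(shape, p0, p1, radius) -> np.ndarray:
    grids = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length2 = float(axis @ axis)
    rel = grids - p0
    t = np.clip((rel @ axis) / length2, 0.0, 1.0)
    nearest = p0 + t[..., None] * axis
    dist2 = np.sum((grids - nearest) ** 2, axis=-1)
    return dist2 <= radius**2


# --------------------------------------------------------------------------
# specs and ground truth containers
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the CISS-like cisternography phantom.

    ``snr`` may be ``numpy.inf`` for a noiseless phantom.  ``bias_field`` holds
    polynomial coefficients for (1, x, y, z, x^2, y^2, z^2) with coordinates
    normalized to [-1, 1]; the field multiplies the noiseless image and is
    rescaled to unit mean over the brain.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    snr: float = 3.5
    parenchyma_mean: float = 3.0
    csf_mean: float = 9.0
    bias_field: tuple[float, ...] = (1.0, 0.03, -0.025, 0.02, -0.015, 0.012, -0.018)
    brain: Ellipsoid | None = None
    compartments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.csf_mean <= self.parenchyma_mean:
            raise ValueError("CSF mean must exceed parenchyma mean")
        if self.brain is None:
            self.brain = _default_brain(self.grid_shape)
        if not self.compartments:
            self.compartments = default_csf_geometry(self.grid_shape)
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        shape = np.asarray(self.grid_shape, dtype=float)
        for comp in [self.brain, *self.compartments]:
            if isinstance(comp, Ellipsoid):
                lo = np.asarray(comp.center) - np.asarray(comp.semi_axes)
                hi = np.asarray(comp.center) + np.asarray(comp.semi_axes)
            else:
                r = comp.radius
                lo = np.minimum(comp.p0, comp.p1) - r
                hi = np.maximum(comp.p0, comp.p1) + r
            if np.any(lo < -0.5) or np.any(hi > shape - 0.5):
                raise ValueError(f"geometry element {comp} extends outside the grid")


def _default_brain(shape) -> Ellipsoid:
    c = tuple((s - 1) / 2 for s in shape)
    axes = tuple(0.38 * s for s in shape)
    return Ellipsoid(center=c, semi_axes=axes, label=0)


def default_csf_geometry(shape=(64, 64, 64)) -> list:
    """Ventricles + perivascular tubes for the 7-compartment scheme.

    Sized so the whole CSF space is ~5% of the brain volume: the adaptive
    segmentation's premise is that CSF intensities occupy roughly the top
    5% of the aggregated brain distribution, and the in-vivo CSF/brain
    ratio is a few percent.
    """
    cx, cy, cz = ((s - 1) / 2 for s in shape)
    sx, sy, sz = (s / 64 for s in shape)  # scale factors for non-64 grids
    return [
        # paired lateral ventricles
        Ellipsoid((cx - 8 * sx, cy + 4 * sy, cz + 4 * sz), (8 * sx, 4.2 * sy, 4.2 * sz), 1),
        Ellipsoid((cx + 8 * sx, cy + 4 * sy, cz + 4 * sz), (8 * sx, 4.2 * sy, 4.2 * sz), 1),
        # third ventricle: midline slab
        Ellipsoid((cx, cy - 1 * sy, cz + 2 * sz), (2.4 * sx, 3.5 * sy, 7.0 * sz), 2),
        # fourth ventricle
        Ellipsoid((cx, cy - 9 * sy, cz - 8 * sz), (3.5 * sx, 3.0 * sy, 3.5 * sz), 3),
        # basilar artery PVS: thin ventral tube
        Tube((cx, cy - 15 * sy, cz - 10 * sz), (cx, cy - 15 * sy, cz + 8 * sz), 2.0 * sx, 4),
        # Circle of Willis / basal PVS
        Tube((cx - 10 * sx, cy - 13 * sy, cz), (cx + 10 * sx, cy - 13 * sy, cz), 2.2 * sy, 5),
        # parietal PVS and cisterns: dorsal tube
        Tube((cx - 11 * sx, cy + 13 * sy, cz - 2 * sz), (cx + 11 * sx, cy + 13 * sy, cz - 2 * sz), 2.2 * sy, 6),
        # remaining PVS: anterior and posterior thin tubes
        Tube((cx - 8 * sx, cy, cz + 13 * sz), (cx + 8 * sx, cy, cz + 13 * sz), 1.8 * sy, 7),
        Tube((cx, cy + 2 * sy, cz - 13 * sz), (cx, cy - 6 * sy, cz - 13 * sz), 1.8 * sx, 7),
    ]


@dataclass
class GroundTruth:
    """Container for per-phantom ground truth (masks, maps, parameters)."""

    csf_mask: np.ndarray | None = None
    compartment_labels: np.ndarray | None = None
    brain_mask: np.ndarray | None = None
    param_maps: dict | None = None
    dce_params: dict | None = None
    t1_map: np.ndarray | None = None
    kappa_map: np.ndarray | None = None
    free_fluid_fraction: float | None = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

def rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Magnitude of (signal + g1) + i g2 with per-channel SD ``sigma``."""
    if sigma < 0:
        raise ValueError("noise SD must be nonnegative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, np.shape(signal))
    im = rng.normal(0.0, sigma, np.shape(signal))
    return np.hypot(re, im)


#: SD of the Rayleigh background of a Rician image, in units of sigma
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


# --------------------------------------------------------------------------
# CISS phantom
# --------------------------------------------------------------------------

def _bias_field(shape, coeffs) -> np.ndarray:
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    c = list(coeffs) + [0.0] * (7 - len(coeffs))
    return c[0] + c[1] * x + c[2] * y + c[3] * z + c[4] * x**2 + c[5] * y**2 + c[6] * z**2


def gen_ciss_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """CISS-like brain phantom: bright CSF compartments over darker parenchyma.

    Returns the noisy magnitude volume and the exact CSF mask / compartment
    labels.  Outside the brain the signal is zero (pure Rayleigh background).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape

    brain = _ellipsoid_mask(shape, spec.brain.center, spec.brain.semi_axes)
    labels = np.zeros(shape, dtype=np.int32)
    for comp in spec.compartments:
        if isinstance(comp, Ellipsoid):
            m = _ellipsoid_mask(shape, comp.center, comp.semi_axes)
        else:
            m = _tube_mask(shape, comp.p0, comp.p1, comp.radius)
        labels[m & brain] = comp.label
    csf = labels > 0

    clean = np.zeros(shape, dtype=float)
    clean[brain] = spec.parenchyma_mean
    clean[csf] = spec.csf_mean

    bias = _bias_field(shape, spec.bias_field)
    bias = bias / bias[brain].mean()
    clean *= bias
    clean[~brain] = 0.0

    if np.isinf(spec.snr):
        noisy = clean
    else:
        sigma = spec.parenchyma_mean / spec.snr
        noisy = rician(rng, clean, sigma)

    truth = GroundTruth(
        csf_mask=csf,
        compartment_labels=labels,
        brain_mask=brain,
        extras={"bias_field": bias, "clean": clean,
                "sigma": 0.0 if np.isinf(spec.snr) else spec.parenchyma_mean / spec.snr},
    )
    return ImageVolume(noisy, spec.voxel_size), truth


# --------------------------------------------------------------------------
# DWI phantom
# --------------------------------------------------------------------------

def ivim_signal(b, s0, fp, d, d_star) -> np.ndarray:
    """IVIM biexponential forward model."""
    b = np.asarray(b, dtype=float)
    return s0 * (fp * np.exp(-b * d_star) + (1.0 - fp) * np.exp(-b * d))


def default_dwi_truth(shape=(16, 16, 4), n_regions: int = 4) -> dict:
    """Blockwise-constant (S0, Fp, D, D*) maps over ``n_regions`` x-bands.

    Parameter levels span physiologically plausible mouse-brain values; the
    blockwise layout gives ROI statistics a known truth.
    """
    if not 3 <= n_regions <= 5:
        raise ValueError("n_regions must be in 3..5")
    s0 = np.full(shape, 1000.0)
    fp = np.zeros(shape)
    d = np.zeros(shape)
    ds = np.zeros(shape)
    levels = [
        (0.05, 6.0e-4, 8.0e-3),
        (0.10, 7.0e-4, 1.0e-2),
        (0.15, 9.0e-4, 1.5e-2),
        (0.0, 7.0e-4, 1.0e-2),   # pure monoexponential region
        (0.08, 1.2e-3, 2.0e-2),
    ][:n_regions]
    edges = np.linspace(0, shape[0], n_regions + 1).astype(int)
    region_labels = np.zeros(shape, dtype=np.int32)
    for i, (fpi, di, dsi) in enumerate(levels):
        sl = slice(edges[i], edges[i + 1])
        fp[sl], d[sl], ds[sl] = fpi, di, dsi
        region_labels[sl] = i + 1
    return {"s0": s0, "fp": fp, "d": d, "d_star": ds, "regions": region_labels}


def gen_dwi_series(
    seed: int,
    truth_maps: dict | None = None,
    b_values=B_VALUES,
    directions=("X", "Y", "Z"),
    noise_sd: float = 0.0,
    voxel_size=(0.15, 0.15, 0.5),
):
    """Multi-b multi-direction DWI stack from known IVIM parameter maps.

    ``truth_maps`` is either a single dict of (s0, fp, d, d_star) arrays used
    isotropically for every encoding direction, or a dict keyed by direction.
    Returns ``(series, truth)`` where ``series`` maps each direction plus
    ``"avg"`` (direction mean) to a :class:`glymphokit.dwi.DWISeries`.
    """
    from glymphokit.dwi import DWISeries  # local import to avoid cycle

    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    b = np.asarray(b_values, dtype=float)
    if b.size == 0 or np.any(np.diff(b) <= 0):
        raise ValueError("b_values must be nonempty and strictly increasing")

    if truth_maps is None:
        truth_maps = default_dwi_truth()
    per_direction = all(k in truth_maps for k in directions)
    maps_by_dir = truth_maps if per_direction else {d_: truth_maps for d_ in directions}

    for m in maps_by_dir.values():
        fp = np.asarray(m["fp"])
        if np.any(fp < 0) or np.any(fp >= 1):
            raise ValueError("Fp must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    averages = AVERAGES_PER_B[: b.size] if b.size <= len(AVERAGES_PER_B) else (1,) * b.size
    series: dict[str, DWISeries] = {}
    stacks = []
    for d_ in directions:
        m = maps_by_dir[d_]
        shape = np.shape(m["s0"])
        sig = np.empty(shape + (b.size,), dtype=float)
        for i, bi in enumerate(b):
            sig[..., i] = ivim_signal(bi, m["s0"], m["fp"], m["d"], m["d_star"])
        if noise_sd > 0:
            # per-b averaging as acquired: each average is an independent
            # Rician magnitude; high-b volumes are acquired twice
            noisy = np.empty_like(sig)
            for i, n_av in enumerate(averages):
                draws = [rician(rng, sig[..., i], noise_sd) for _ in range(n_av)]
                noisy[..., i] = np.mean(draws, axis=0)
        else:
            noisy = sig
        stacks.append(noisy)
        series[d_] = DWISeries(noisy, tuple(b), averages, voxel_size, direction=d_)
    series["avg"] = DWISeries(
        np.mean(stacks, axis=0), tuple(b), AVERAGES_PER_B[: b.size], voxel_size, direction="avg"
    )
    truth = GroundTruth(param_maps=maps_by_dir if per_direction else truth_maps)
    return series, truth


# --------------------------------------------------------------------------
# DCE cohort
# --------------------------------------------------------------------------

@dataclass
class DCEParams:
    """Ground-truth uptake/washout parameters of one ROI curve.

    All times are minutes *relative to the infusion start* (the last baseline
    scan), matching the reporting convention of the tracer-kinetic metrics:
    ``arrival`` is when the first above-baseline sample occurs, ``time_to_peak``
    when the curve maximum occurs, and ``duration`` the support length (the
    curve is exactly 0 beyond ``arrival + duration``).
    """

    arrival: float = 5.0
    time_to_peak: float = 40.0
    peak: float = 100.0
    duration: float = 60.0
    plateau: float = 0.0         # minutes held at peak before washout
    shape: float = 2.0           # gamma-variate shape parameter


def gamma_variate_curve(
    t, p: DCEParams, infusion_start_min: float = 3.0, onset_lead: float = 0.5
) -> np.ndarray:
    """Piecewise gamma-variate with explicit plateau and hard return to baseline.

    The onset is placed ``onset_lead`` minutes before the arrival sample so
    the sample *at* the ground-truth arrival time is already (slightly)
    enhanced; the maximum falls exactly on the time-to-peak sample.
    """
    t = np.asarray(t, dtype=float)
    t_arr = infusion_start_min + p.arrival
    t_peak = infusion_start_min + p.time_to_peak
    t0 = t_arr - onset_lead
    tp = max(t_peak - t0, 1e-9)
    out = np.zeros_like(t)
    tau = (t - t0) / tp
    gv = np.where(tau > 0, p.peak * np.power(np.maximum(tau, 1e-12), p.shape)
                  * np.exp(p.shape * (1.0 - tau)), 0.0)
    out = np.where((t >= t_arr) & (t <= t_peak), gv, out)
    out = np.where((t > t_peak) & (t <= t_peak + p.plateau), p.peak, out)
    tau2 = (t - t0 - p.plateau) / tp
    gv2 = np.where(tau2 > 0, p.peak * np.power(np.maximum(tau2, 1e-12), p.shape)
                   * np.exp(p.shape * (1.0 - tau2)), 0.0)
    out = np.where(t > t_peak + p.plateau, gv2, out)
    out = np.where(t > t_arr + p.duration, 0.0, out)
    return out


def gen_dce_dataset(
    seed: int,
    n_subjects: int,
    time_points: int,
    roi_params: dict[str, DCEParams] | None = None,
    noise_sd: float = 0.0,
    time_step: float = 1.0,
    n_baseline: int = 3,
    infusion_start_min: float = 3.0,
    infusion_duration_min: float = 10.0,
):
    """Per-ROI, per-subject DCE enhancement curves with known kinetics.

    Time axis: scan ``i`` (0-based) is acquired at ``(i + 1) * time_step``
    minutes; the first ``n_baseline`` scans precede the infusion.  Additive
    Gaussian noise of SD ``noise_sd``.
    """
    from glymphokit.dce import DCESeries  # local import to avoid cycle

    if time_points < 10:
        raise ValueError("time_points must be >= 10")
    if n_baseline < 3:
        raise ValueError("need at least 3 baseline scans")
    if roi_params is None:
        roi_params = {"parenchyma": DCEParams()}
    for name, p in roi_params.items():
        if p.peak != 0 and p.arrival <= 0:
            raise ValueError(f"ROI {name!r}: arrival precedes the infusion start")

    rng = np.random.default_rng(seed)
    t = (np.arange(time_points) + 1) * time_step
    series = {}
    for name, p in roi_params.items():
        clean = gamma_variate_curve(t, p, infusion_start_min, onset_lead=time_step / 2)
        values = np.tile(clean, (n_subjects, 1))
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, values.shape)
        series[name] = DCESeries(
            values=values,
            time_min=t,
            baseline_indices=tuple(range(n_baseline)),
            infusion_start_min=infusion_start_min,
            infusion_duration_min=infusion_duration_min,
        )
    truth = GroundTruth(dce_params=dict(roi_params))
    return series, truth


# --------------------------------------------------------------------------
# variable-TR T1 stack
# --------------------------------------------------------------------------

def gen_vtr_series(
    seed: int,
    t1_map: np.ndarray,
    tr_list=TR_LIST_MS,
    kappa_map: np.ndarray | None = None,
    noise_sd: float = 0.0,
    s0: float = 1000.0,
):
    """Saturation-recovery stack ``S(TR) = S0 sin(kappa*90deg) (1 - e^(-TR/T1))``.

    Also emits the dual-angle pair acquired at the maximal TR with nominal
    flip angles 45 and 90 degrees: ``S(alpha) = S0 (1-e^(-TRmax/T1)) sin(kappa*alpha)``.
    Returns ``(stack, s45, s90, truth)``.
    """
    t1 = np.asarray(t1_map, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive everywhere")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    tr = np.asarray(sorted(tr_list), dtype=float)
    kappa = np.ones_like(t1) if kappa_map is None else np.asarray(kappa_map, dtype=float)

    rng = np.random.default_rng(seed)
    amp = s0 * np.sin(kappa * np.pi / 2)
    stack = amp[..., None] * (1.0 - np.exp(-tr / t1[..., None]))
    sat_max = s0 * (1.0 - np.exp(-tr.max() / t1))
    s45 = sat_max * np.sin(kappa * np.pi / 4)
    s90 = sat_max * np.sin(kappa * np.pi / 2)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
        s45 = s45 + rng.normal(0.0, noise_sd, s45.shape)
        s90 = s90 + rng.normal(0.0, noise_sd, s90.shape)
    truth = GroundTruth(t1_map=t1, kappa_map=kappa, extras={"s0": s0, "tr_list": tuple(tr)})
    return stack, s45, s90, truth


# --------------------------------------------------------------------------
# microbead phantom
# --------------------------------------------------------------------------

def gen_beads_phantom(
    seed: int,
    grid_shape=(64, 64, 64),
    bead_radius_px: float = 4.0,
    packing_fraction: float = 0.3,
    hu_levels: tuple[float, float] = (60.0, 200.0),
    hu_spread: float = 3.0,
    max_attempts: int = 200_000,
):
    """Bead phantom: low-HU non-overlapping spheres in a high-HU contrast bath.

    Below ~0.25 nominal packing the spheres are placed by random sequential
    adsorption; denser packs use a jittered cubic lattice (geometric limit
    ~0.52 for a simple cubic arrangement).  The exact voxel fraction outside
    the beads is recorded as ground truth.
    """
    if not 0 <= packing_fraction < 1:
        raise ValueError("packing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in grid_shape)
    total = int(np.prod(shape))
    beads = np.zeros(shape, dtype=bool)
    r = float(bead_radius_px)
    sphere_vol = 4.0 / 3.0 * math.pi * r**3

    centers: list[np.ndarray] = []
    if packing_fraction > 0:
        if packing_fraction <= 0.25:
            n_target = int(round(packing_fraction * total / sphere_vol))
            attempts = 0
            while len(centers) < n_target and attempts < max_attempts:
                attempts += 1
                c = rng.uniform(r, np.asarray(shape, dtype=float) - r)
                if all(np.sum((c - c0) ** 2) >= (2 * r) ** 2 for c0 in centers):
                    centers.append(c)
            if len(centers) < n_target:
                achieved = len(centers) * sphere_vol / total
                raise RuntimeError(
                    f"could not reach packing {packing_fraction:.3f}; "
                    f"achieved {achieved:.3f} after {max_attempts} attempts"
                )
        else:
            cell = r * (4.0 * math.pi / (3.0 * packing_fraction)) ** (1.0 / 3.0)
            if cell < 2 * r:
                achieved = sphere_vol / (2 * r) ** 3
                raise RuntimeError(
                    f"packing {packing_fraction:.3f} exceeds the cubic-lattice limit; "
                    f"max achievable ~{achieved:.3f}"
                )
            jitter = (cell - 2 * r) / 2.0
            grid_axes = [np.arange(r + jitter, s - r - jitter + 1e-9, cell) for s in shape]
            for cx in grid_axes[0]:
                for cy in grid_axes[1]:
                    for cz in grid_axes[2]:
                        c = np.array([cx, cy, cz]) + rng.uniform(-jitter, jitter, 3)
                        centers.append(c)

        grids = np.stack(
            np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
        ).astype(float)
        for c in centers:
            lo = np.maximum(np.floor(c - r - 1).astype(int), 0)
            hi = np.minimum(np.ceil(c + r + 2).astype(int), shape)
            sub = grids[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            d2 = np.sum((sub - c) ** 2, axis=-1)
            beads[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r**2

    free_fraction = 1.0 - beads.sum() / total
    achieved_packing = 1.0 - free_fraction
    if packing_fraction > 0 and abs(achieved_packing - packing_fraction) > 0.05:
        import warnings

        warnings.warn(
            f"achieved packing {achieved_packing:.3f} deviates from the nominal "
            f"{packing_fraction:.3f} (edge margins and voxelization); the exact "
            "free fraction is recorded in the ground truth"
        )
    hu = np.where(beads, hu_levels[0], hu_levels[1]).astype(float)
    if hu_spread > 0:
        hu = hu + rng.normal(0.0, hu_spread, shape)
    truth = GroundTruth(
        free_fluid_fraction=float(free_fraction),
        extras={"bead_mask": beads, "centers": np.array(centers) if centers else np.empty((0, 3))},
    )
    return ImageVolume(hu, (0.015, 0.015, 0.015)), truth
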