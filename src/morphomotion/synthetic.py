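"""Synthetic inputs at desk scale: phantoms, motion traces, and cohorts.

Everything the pipeline consumes can be generated here with known ground
truth: binary solids with analytic box-counting dimension (cube, sphere,
shell, Menger sponge), realignment traces with the stylised features of
real fMRI runs (elevated initial frames, stimulus-locked spikes), and a
cohort table whose statistical structure emulates a lifespan ageing
study: age uniform on 18-88, BMI weakly age-correlated, lognormal motion
rates with rest > movie and a shared subject trait, and three morphology
outcomes (cortical thickness, fractal dimensionality, gyrification)
declining linearly with age and with movie-scan motion.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CohortRecord, RealignmentTrace, VoxelVolume

HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # E|N(0,1)|


# ---------------------------------------------------------------------------
# Geometric phantoms


def _padded(shape_occ: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(shape_occ.astype(np.uint8), pad)


def make_cube(edge: int, pad: int = 2) -> VoxelVolume:
    """Filled cube of the given edge, centred in a padded array."""
    if edge < 1:
        raise ValueError(f"edge must be positive, got {edge}")
    return VoxelVolume(data=_padded(np.ones((edge,) * 3, dtype=bool), pad))


def make_sphere(radius: int, pad: int = 2) -> VoxelVolume:
    """Filled ball: voxels whose centre lies within ``radius`` of the middle.

    The occupied count approaches (4/3) pi r^3 as the radius grows (within
    2% for r >= 10).
    """
    if radius < 1:
        raise ValueError(f"radius must be positive, got {radius}")
    n = 2 * radius + 1
    c = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[:n, :n, :n]
    occ = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return VoxelVolume(data=_padded(occ, pad))


def make_shell(radius: int, thickness: int, pad: int = 2) -> VoxelVolume:
    """Hollow spherical shell: ball(radius) minus the concentric
    ball(radius - thickness)."""
    if thickness < 1 or thickness > radius:
        raise ValueError(f"need 1 <= thickness <= radius, got {thickness}, {radius}")
    n = 2 * radius + 1
    c = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[:n, :n, :n]
    d2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
    occ = (d2 <= radius**2) & (d2 > (radius - thickness) ** 2)
    return VoxelVolume(data=_padded(occ, pad))


def make_menger(level: int, pad: int = 0) -> VoxelVolume:
    """Menger sponge of the given construction level on a 3^level grid.

    Each 3x3x3 block keeps the 20 subcubes that are not part of the
    centre cross, so the sponge has exactly 20^level occupied voxels and
    box-counting dimension log(20)/log(3).
    """
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    if level > 4:
        raise ValueError("levels above 4 exceed desk-scale arrays")
    n = 3**level
    idx = np.arange(n)
    # digit d of each coordinate in base 3, per level
    keep = np.ones((n, n, n), dtype=bool)
    for lv in range(level):
        d = (idx // 3**lv) % 3
        is_mid = d == 1
        mz = is_mid[:, None, None]
        my = is_mid[None, :, None]
        mx = is_mid[None, None, :]
        # removed where >= 2 of the 3 digits are the middle digit
        removed = (mz & my) | (mz & mx) | (my & mx)
        keep &= ~removed
    return VoxelVolume(data=_padded(keep, pad) if pad else keep.astype(np.uint8))


# ---------------------------------------------------------------------------
# Realignment traces


def base_scale_for_rate(rate_mm_min: float, tr_seconds: float) -> float:
    """Increment scale giving an expected motion rate of ``rate_mm_min``.

    Each transition sums six half-normal |increments| of scale ``s``, so
    the expected displacement per transition is ``6 s sqrt(2/pi)`` and
    the expected rate ``that / TR * 60``.
    """
    return rate_mm_min * tr_seconds / 60.0 / (6.0 * HALF_NORMAL_MEAN)


def simulate_trace(duration_s: float, tr_seconds: float, base_scale_mm: float,
                   spike_times_s: tuple[float, ...] = (), seed: int = 0,
                   label: str = "", initial_boost: float = 5.0,
                   spike_boost: float = 10.0,
                   radius_mm: float = 50.0) -> RealignmentTrace:
    """Random-walk realignment trace with scan-start and stimulus artefacts.

    Per-parameter increments have half-normal magnitude scaled by
    ``base_scale_mm`` (rotations are generated in radians, scaled so
    their arc length on the ``radius_mm`` sphere matches the
    translations).  The first five transitions are inflated
    ``initial_boost``-fold, emulating the settling frames excluded by the
    drop rule; each spike time inflates its single transition
    ``spike_boost``-fold.  Angle unit of the result is radians.
    """
    if duration_s < 10 * tr_seconds:
        raise ValueError("duration must cover at least 10 repetition times")
    if base_scale_mm < 0:
        raise ValueError("base_scale_mm must be >= 0")
    n_frames = int(round(duration_s / tr_seconds))
    rng = np.random.default_rng(seed)
    mags = np.abs(rng.standard_normal((n_frames - 1, 6))) * base_scale_mm
    signs = rng.choice((-1.0, 1.0), size=(n_frames - 1, 6))
    inc = mags * signs
    inc[: min(5, n_frames - 1)] *= initial_boost
    for t_spike in spike_times_s:
        if not 0 < t_spike <= duration_s:
            raise ValueError(f"spike time {t_spike}s outside the {duration_s}s run")
        k = min(max(int(round(t_spike / tr_seconds)) - 1, 0), n_frames - 2)
        inc[k] *= spike_boost
    inc[:, 3:] /= radius_mm  # radians whose arc length matches the mm scale
    params = np.vstack([np.zeros(6), np.cumsum(inc, axis=0)])
    return RealignmentTrace(params=params, angle_unit="radians",
                            tr_seconds=tr_seconds, label=label)


# ---------------------------------------------------------------------------
# Cohort generator


@dataclass
class SimulationParams:
    """Generating parameters of the synthetic ageing cohort.

    Slopes and the rest-vs-movie contrast use the study-condition values;
    the motion distribution is lognormal with raw-scale correlation
    targets hit by analytic calibration of the latent Gaussian loadings.
    Outcome noise SDs are set so the generating morphology model
    (age + movie motion) is identifiable by BIC at the default n.
    """

    n_subjects: int = 640
    seed: int = 0
    age_range: tuple[float, float] = (18.0, 88.0)

    # morphology: outcome = intercept + slope*age + motion_effect*movie + noise
    slope_thickness_per_year: float = -0.00432   # mm/yr  (-0.0432 mm/decade)
    slope_fd_per_year: float = -0.00097          # FD_f/yr
    slope_gi_per_year: float = -0.00372          # GI/yr
    motion_effect_thickness: float = -0.0135     # mm per mm/min of movie motion
    motion_effect_fd: float = -0.003
    motion_effect_gi: float = -0.012
    intercept_thickness: float = 2.75
    intercept_fd: float = 2.66
    intercept_gi: float = 3.00
    sd_thickness: float = 0.05
    sd_fd: float = 0.012
    sd_gi: float = 0.05

    # motion (lognormal, mm/min) and its correlation targets (raw scale)
    mean_rest_mm_min: float = 3.1
    movie_rest_mean_diff_mm_min: float = 1.528
    paired_cohen_d: float = 0.99
    r_age_rest: float = 0.351
    r_age_movie: float = 0.430
    r_rest_movie: float = 0.484

    # BMI
    bmi_mean: float = 26.5
    bmi_sd: float = 4.4
    r_age_bmi: float = 0.274
    r_bmi_rest: float = 0.456
    r_bmi_movie: float = 0.335
    bmi_missing_frac: float = 81.0 / 640.0

    # AES (arbitrary normalized-gradient units), age-loaded, motion-free
    aes_means: tuple[float, float, float] = (0.22, 0.18, 0.21)  # axial, coronal, sagittal
    aes_sd: float = 0.02
    r_age_aes_axial: float = 0.493
    r_age_aes_coronal: float = -0.131
    r_age_aes_sagittal: float = 0.525
    r_aes_axial_sagittal: float = 0.702

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        for name in ("sd_thickness", "sd_fd", "sd_gi", "bmi_sd", "aes_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _motion_log_sd(p: SimulationParams) -> float:
    """Log-scale SD solving SD(rest - movie) = M_diff / d for lognormal
    marginals with the requested means and raw inter-scan correlation."""
    m_r = p.mean_rest_mm_min
    m_m = m_r - p.movie_rest_mean_diff_mm_min
    if m_m <= 0:
        raise ValueError("movie mean motion must stay positive")
    sd_diff = p.movie_rest_mean_diff_mm_min / p.paired_cohen_d
    denom = m_r**2 + m_m**2 - 2 * p.r_rest_movie * m_r * m_m
    v = sd_diff**2 / denom  # = exp(sigma^2) - 1
    if v <= 0:
        raise ValueError("inconsistent contrast/effect-size targets")
    return math.sqrt(math.log1p(v))


def _latent_loadings(p: SimulationParams, sigma: float):
    """Latent-Gaussian loadings hitting the raw-scale correlation targets.

    A Gaussian variable correlated rho with the log of a lognormal shows
    raw correlation rho*sigma/sqrt(e^{sigma^2}-1); two lognormals with
    latent correlation rho show (e^{rho sigma^2}-1)/(e^{sigma^2}-1).
    Both maps are inverted here so the *raw* correlations land on target.
    """
    ev = math.expm1(sigma**2)
    infl = math.sqrt(ev) / sigma  # Gaussian-lognormal inflation factor
    rho_ar = p.r_age_rest * infl
    rho_am = p.r_age_movie * infl
    rho_br = p.r_bmi_rest * infl
    rho_bm = p.r_bmi_movie * infl
    rho_rm = math.log1p(p.r_rest_movie * ev) / sigma**2
    ba = p.r_age_bmi
    root = math.sqrt(1 - ba**2)
    c1, d1 = rho_ar, rho_am
    c2 = (rho_br - c1 * ba) / root
    d2 = (rho_bm - d1 * ba) / root
    g2 = rho_rm - c1 * d1 - c2 * d2
    c4sq = 1 - c1**2 - c2**2 - g2
    d4sq = 1 - d1**2 - d2**2 - g2
    if g2 < 0 or c4sq < 0 or d4sq < 0:
        raise ValueError("requested correlation structure is infeasible")
    return c1, c2, d1, d2, math.sqrt(g2), math.sqrt(c4sq), math.sqrt(d4sq)


def simulate_cohort(params: SimulationParams | None = None) -> list[CohortRecord]:
    """Draw a synthetic cohort with the configured statistical structure.

    Age is uniform on the configured range; BMI is Gaussian with an age
    loading; rest and movie motion are lognormal sharing a subject trait
    plus age and BMI loadings; AES is age-loaded and independent of
    motion given age; the three morphology outcomes are linear in age and
    movie motion plus Gaussian noise.  A configurable fraction of BMI
    values is set missing.  Fully reproducible from ``params.seed``.
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_subjects

    lo, hi = p.age_range
    age = rng.uniform(lo, hi, n)
    z_age = (age - (lo + hi) / 2.0) / math.sqrt((hi - lo) ** 2 / 12.0)

    e_bmi = rng.standard_normal(n)
    trait = rng.standard_normal(n)
    e_rest = rng.standard_normal(n)
    e_movie = rng.standard_normal(n)

    ba = p.r_age_bmi
    z_bmi = ba * z_age + math.sqrt(1 - ba**2) * e_bmi
    bmi = p.bmi_mean + p.bmi_sd * z_bmi

    sigma = _motion_log_sd(p)
    c1, c2, d1, d2, g, c4, d4 = _latent_loadings(p, sigma)
    z_rest = c1 * z_age + c2 * e_bmi + g * trait + c4 * e_rest
    z_movie = d1 * z_age + d2 * e_bmi + g * trait + d4 * e_movie
    mean_movie = p.mean_rest_mm_min - p.movie_rest_mean_diff_mm_min
    rest = p.mean_rest_mm_min * np.exp(sigma * z_rest - sigma**2 / 2)
    movie = mean_movie * np.exp(sigma * z_movie - sigma**2 / 2)

    # AES: axial and sagittal share an age-independent factor; coronal only
    # weakly (negatively) tracks age.  No motion loading (given age).
    r_ax, r_sg, r_co = p.r_age_aes_axial, p.r_age_aes_sagittal, p.r_age_aes_coronal
    lam2 = p.r_aes_axial_sagittal - r_ax * r_sg
    if lam2 < 0 or r_ax**2 + lam2 > 1 or r_sg**2 + lam2 > 1:
        raise ValueError("requested AES correlation structure is infeasible")
    lam = math.sqrt(lam2)
    f_aes = rng.standard_normal(n)
    z_ax = r_ax * z_age + lam * f_aes + math.sqrt(1 - r_ax**2 - lam2) * rng.standard_normal(n)
    z_sg = r_sg * z_age + lam * f_aes + math.sqrt(1 - r_sg**2 - lam2) * rng.standard_normal(n)
    z_co = r_co * z_age + math.sqrt(1 - r_co**2) * rng.standard_normal(n)
    aes_ax = p.aes_means[0] + p.aes_sd * z_ax
    aes_co = p.aes_means[1] + p.aes_sd * z_co
    aes_sg = p.aes_means[2] + p.aes_sd * z_sg

    thickness = (p.intercept_thickness + p.slope_thickness_per_year * age
                 + p.motion_effect_thickness * movie
                 + p.sd_thickness * rng.standard_normal(n))
    fd_cort = (p.intercept_fd + p.slope_fd_per_year * age
               + p.motion_effect_fd * movie
               + p.sd_fd * rng.standard_normal(n))
    gyrif = (p.intercept_gi + p.slope_gi_per_year * age
             + p.motion_effect_gi * movie
             + p.sd_gi * rng.standard_normal(n))

    sex = rng.choice(("F", "M"), size=n)
    n_missing = int(round(p.bmi_missing_frac * n))
    missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist())

    records = []
    for i in range(n):
        records.append(CohortRecord(
            id=f"sub-{i + 1:04d}",
            age_years=float(age[i]),
            sex=str(sex[i]),
            bmi_kg_m2=math.nan if i in missing_idx else float(bmi[i]),
            motion_rest_mm_min=float(rest[i]),
            motion_movie_mm_min=float(movie[i]),
            thickness_mm=float(thickness[i]),
            fd_cortical=float(fd_cort[i]),
            gyrification=float(gyrif[i]),
            aes_axial=float(aes_ax[i]),
            aes_coronal=float(aes_co[i]),
            aes_sagittal=float(aes_sg[i]),
        ))
    return records
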