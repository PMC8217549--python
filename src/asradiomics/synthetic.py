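"""Synthetic two-arm active-surveillance cohort: phantoms, masks, clinical table.

The real study cohort (73 MR-visible lesions: 35 progressors, 38 stable,
imaged on a single 3T scanner) is not publicly deposited, so this module
generates a fully synthetic stand-in with controllable planted effects:

* Lesions are superellipsoids with randomised semi-axes on an anisotropic
  voxel grid; progressors receive a configurable mean-size shift (lesion
  size is a known correlate of progression on AS).
* Intratumoural texture is a smoothed Gaussian random field whose
  correlation length differs between groups, which shifts many texture
  features at once without hand-tuning 107 of them.
* PSA is log-normal with a configurable standardised group shift; gland
  volume is log-normal and (by default) group-independent, so PSA density
  (= PSA / gland volume, an enforced invariant) inherits its group effect
  mostly from PSA — matching the observation that PSA density tracks PSA in
  a homogeneous surveillance cohort.  An excess PSA-density effect beyond
  the PSA effect is realised as a downward gland-volume shift in
  progressors.
* Acquisition parameters are drawn from a single narrow distribution
  (single-scanner cohort); slice thickness and spacing-between-slices are
  exactly constant, exercising the degenerate-parameter path of the
  decoupling stage.  ``acquisition_confound`` optionally couples TE to the
  texture correlation length for testing that stage's power.

Both sequences (T2WI-like and ADC-like) share one lesion mask.  Everything
is deterministic given the config seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ACQUISITION_PARAMS, ImageVolume, LesionImages, RoiMask

COHORT_COLUMNS = [
    "lesion_id",
    "patient_id",
    "label",
    "psa",
    "gland_volume",
    "psa_density",
    "likert",
    "grade_group",
    "zone",
    *ACQUISITION_PARAMS,
]


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the target cohort: 35 progressors vs 38 stable lesions,
    moderate planted clinical effects (PSA and PSA density higher in
    progressors), and planted texture/size effects large enough for the
    combined model to beat the clinical-only model.  Effect sizes are
    standardised (units of the between-lesion SD of the shifted quantity).
    """

    n_progressors: int = 35
    n_stable: int = 38
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)  # mm, semi-axis
    texture_effect: dict = field(
        default_factory=lambda: {"texture": 1.0, "size": 0.6}
    )
    clinical_effect: dict = field(
        default_factory=lambda: {"psa": 0.6, "psa_density": 0.8}
    )
    noise_sd: float = 5.0  # intensity units, on a base of 100
    acquisition_confound: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progressors < 2 or self.n_stable < 2:
            raise ValueError("need >= 2 lesions per group")
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("degenerate grid: every axis needs >= 8 voxels")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid lesion_radius_range")
        extent = [s * sp for s, sp in zip(self.grid_shape, self.voxel_spacing)]
        if 2 * hi >= min(extent) - 4 * max(self.voxel_spacing):
            raise ValueError("lesion_radius_range does not fit inside the grid")
        for d in (self.texture_effect, self.clinical_effect):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("effect sizes must be finite")


def synthesize_lesion(
    shape_params: dict,
    texture_params: dict,
    seed: int,
) -> tuple[ImageVolume, RoiMask]:
    """One superellipsoid lesion with Gaussian-random-field texture.

    ``shape_params``: grid_shape, spacing, semi_axes (mm, 3), exponent.
    ``texture_params``: base, amplitude, corr_len_mm, noise_sd, sequence.
    The mask must not touch a 2-voxel border margin (morphological closing
    downstream would otherwise be truncated) and must be a single connected
    component of >= 30 voxels.
    """
    rng = np.random.default_rng(seed)
    grid_shape = tuple(shape_params["grid_shape"])
    spacing = tuple(shape_params["spacing"])
    semi = np.asarray(shape_params["semi_axes"], dtype=float)
    p = float(shape_params.get("exponent", 2.0))
    if np.any(semi / np.asarray(spacing) < 2):
        raise ValueError("lesion radius must span >= 2 voxels along each axis")

    centre = (np.asarray(grid_shape) - 1) / 2.0
    coords = [
        (np.arange(n) - c) * s for n, c, s in zip(grid_shape, centre, spacing)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    mask = (
        np.abs(X / semi[0]) ** p + np.abs(Y / semi[1]) ** p + np.abs(Z / semi[2]) ** p
    ) <= 1.0

    border = np.zeros(grid_shape, dtype=bool)
    border[:2], border[-2:] = True, True
    border[:, :2], border[:, -2:] = True, True
    border[:, :, :2], border[:, :, -2:] = True, True
    if (mask & border).any():
        raise ValueError("lesion mask touches the volume border margin")
    if mask.sum() < 30:
        raise ValueError("lesion mask has fewer than 30 voxels")
    _, ncomp = ndimage.label(mask)
    if ncomp != 1:
        raise ValueError("lesion mask is not a single connected component")

    base = float(texture_params.get("base", 100.0))
    amp = float(texture_params.get("amplitude", 20.0))
    corr = float(texture_params.get("corr_len_mm", 2.0))
    noise_sd = float(texture_params.get("noise_sd", 5.0))
    sequence = texture_params.get("sequence", "T2W")

    field_ = rng.standard_normal(grid_shape)
    sigma_vox = [corr / s for s in spacing]
    smooth = ndimage.gaussian_filter(field_, sigma=sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    data = base + amp * smooth
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, grid_shape)
    return ImageVolume(data, spacing, sequence=sequence), RoiMask(mask, spacing)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def generate_cohort(config: PhantomConfig) -> tuple[list[LesionImages], pd.DataFrame]:
    """Generate the full synthetic cohort: images+masks and the clinical table."""
    n = config.n_progressors + config.n_stable
    ss = np.random.SeedSequence(config.seed)
    lesion_seeds = ss.spawn(n)

    d_tex = float(config.texture_effect.get("texture", 0.0))
    d_size = float(config.texture_effect.get("size", 0.0))
    d_psa = float(config.clinical_effect.get("psa", 0.0))
    d_psad = float(config.clinical_effect.get("psa_density", d_psa))

    lo, hi = config.lesion_radius_range
    mean_r = (lo + hi) / 2.0
    sd_r = (hi - lo) / 5.0

    labels = np.array([1] * config.n_progressors + [0] * config.n_stable)
    lesions: list[LesionImages] = []
    rows = []
    for i, lab in enumerate(labels):
        lrng = np.random.default_rng(lesion_seeds[i])
        # size effect: progressors get a mean semi-axis shift of d_size * sd_r
        mu_r = mean_r + (d_size * sd_r if lab else 0.0)
        semi = np.array(
            [_truncnorm(lrng, mu_r, sd_r, lo, hi) * lrng.uniform(0.8, 1.2) for _ in range(3)]
        )
        semi = np.clip(semi, lo, hi)
        exponent = lrng.uniform(1.8, 2.6)
        # texture effect: group shift of log-correlation-length (sd 0.15)
        log_corr = np.log(2.0) + lrng.normal(0.0, 0.15) + (d_tex * 0.15 if lab else 0.0)
        corr_len = float(np.exp(log_corr))

        shape_params = dict(
            grid_shape=config.grid_shape,
            spacing=config.voxel_spacing,
            semi_axes=semi,
            exponent=exponent,
        )
        sub = lesion_seeds[i].spawn(2)
        t2w, mask = synthesize_lesion(
            shape_params,
            dict(base=100.0, amplitude=20.0, corr_len_mm=corr_len,
                 noise_sd=config.noise_sd, sequence="T2W"),
            seed=sub[0],
        )
        adc, _ = synthesize_lesion(
            shape_params,
            dict(base=1200.0, amplitude=150.0, corr_len_mm=corr_len,
                 noise_sd=config.noise_sd * 10.0, sequence="ADC"),
            seed=sub[1],
        )
        lid = f"L{i + 1:03d}"
        lesions.append(LesionImages(lid, {"T2W": t2w, "ADC": adc}, mask))

        # clinical covariates
        log_psa = np.log(5.0) + lrng.normal(0.0, 0.45) + (d_psa * 0.45 if lab else 0.0)
        vol_shift = -(d_psad - d_psa) * 0.35 if lab else 0.0
        log_vol = np.log(45.0) + lrng.normal(0.0, 0.35) + vol_shift
        psa = float(np.exp(log_psa))
        vol = float(np.exp(log_vol))
        likert = int(lrng.choice([3, 4, 5], p=[0.16, 0.40, 0.44]))
        gg = int(lrng.choice([1, 2], p=[0.74, 0.26]))
        zone = str(lrng.choice(["PZ", "TZ"], p=[0.70, 0.30]))

        te = float(lrng.normal(100.0, 2.0))
        if config.acquisition_confound:
            te += config.acquisition_confound * (corr_len - 2.0) * 10.0
        rows.append(
            dict(
                lesion_id=lid,
                patient_id=f"P{i + 1:03d}",
                label="progressor" if lab else "stable",
                psa=psa,
                gland_volume=vol,
                psa_density=psa / vol,
                likert=likert,
                grade_group=gg,
                zone=zone,
                te=te,
                tr=float(lrng.normal(4500.0, 150.0)),
                flip_angle=float(lrng.normal(140.0, 2.0)),
                slice_thickness=3.0,
                spacing_between_slices=3.0,
                pixel_spacing=float(lrng.normal(0.35, 0.005)),
            )
        )

    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return lesions, cohort


def null_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A no-effect cohort (all planted effects zero) for null controls."""
    cfg = PhantomConfig(
        texture_effect={"texture": 0.0, "size": 0.0},
        clinical_effect={"psa": 0.0, "psa_density": 0.0},
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def clinical_feature_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric clinical candidate table (zone encoded as TZ indicator)."""
    return pd.DataFrame(
        {
            "psa": cohort.psa,
            "gland_volume": cohort.gland_volume,
            "psa_density": cohort.psa_density,
            "likert": cohort.likert.astype(float),
            "grade_group": cohort.grade_group.astype(float),
            "zone_tz": (cohort.zone == "TZ").astype(float),
        },
        index=cohort.index,
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df[COHORT_COLUMNS]


def cohort_csv_roundtrip(cohort: pd.DataFrame) -> pd.DataFrame:
    buf = io.StringIO()
    cohort.to_csv(buf, index=False)
    buf.seek(0)
    return pd.read_csv(buf)
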