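"""Seeded synthetic prostate-phantom cohorts with ground-truth lesions.

Each case is a T2W-like magnitude volume: a bright ellipsoidal peripheral
zone (PZ) shell around a darker transition-zone (TZ) core, embedded in dim
background tissue, with optional hypointense lesion blobs, an oriented
high-spatial-frequency texture (so that k-space undersampling visibly blurs
one axis), a smooth multiplicative bias field, and Rician noise (the
magnitude-MR noise model).  The ground-truth labelmap is voxel-aligned with
the image and every lesion lies fully inside the prostate.

Cohort generation is a pure function of (config, n): per-case generators are
derived from the master seed by a counter-based scheme, so prefixes of a
cohort are stable under changes of n.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, LesionSet

__all__ = ["PhantomConfig", "PhantomCase", "generate_case", "generate_cohort", "save_cohort"]

# Three-site cohort composition mirrored by the generator (patients per site).
DEFAULT_SITE_SIZES = {"site_a": 305, "site_b": 384, "site_c": 846}

_BACKGROUND = 0.20  # periprostatic tissue intensity
_PZ_INTENSITY = 0.85  # bright peripheral zone on T2W
_TZ_INTENSITY = 0.60  # darker, heterogeneous transition zone
_EDGE_WIDTH = 0.06  # logistic margin width in normalised ellipsoid radius


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the grid of the detection stage — shape (160, 160, 16)
    at (0.5, 0.5, 3.0) mm — with a lesion prevalence of 0.48 (roughly half
    the patients in the emulated multicentre cohort carry likely-csPCa
    lesions), one to three lesions per positive patient, lesion radii of
    3.5-7 mm and a 40% relative T2W signal drop inside lesions.
    """

    volume_shape: tuple[int, int, int] = (160, 160, 16)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    lesion_prevalence: float = 0.48
    lesions_per_positive: tuple[int, int] = (1, 3)
    lesion_radius: tuple[float, float] = (3.5, 7.0)  # mm
    lesion_contrast: float = 0.40  # relative intensity drop
    noise_sigma: float = 0.03  # Rician scale, fraction of PZ intensity
    texture_strength: float = 0.08
    bias_strength: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.volume_shape):
            raise ValueError(f"volume_shape must be positive, got {self.volume_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if not 0.0 <= self.lesion_prevalence <= 1.0:
            raise ValueError("lesion_prevalence must be in [0, 1]")
        if self.lesion_radius[0] <= 0 or self.lesion_radius[1] < self.lesion_radius[0]:
            raise ValueError("lesion_radius must be a positive (lo, hi) range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.lesions_per_positive
        if lo < 1 or hi < lo:
            raise ValueError("lesions_per_positive must be an integer range >= 1")


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic patient: image, ground truth, and cohort metadata.

    ``lesion_geometry`` records the sampled (centre_mm, semi_axes_mm) of
    each lesion ellipsoid, in labelmap order, for geometry checks.
    """

    image: ImageVolume
    lesions: LesionSet
    patient_id: str
    site: str = "site_a"
    lesion_geometry: tuple[tuple[tuple[float, ...], tuple[float, ...]], ...] = ()

    @property
    def patient_label(self) -> int:
        """1 iff the patient has any ground-truth lesion."""
        return int(self.lesions.n_lesions > 0)


def _physical_grid(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(config.volume_shape, config.voxel_spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_rho(
    grid: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    """Normalised ellipsoid radius: <= 1 inside."""
    return np.sqrt(
        sum(((g - c) / a) ** 2 for g, c, a in zip(grid, center, semi_axes))
    )


def _soft_inside(rho: np.ndarray, width: float = _EDGE_WIDTH) -> np.ndarray:
    """Smooth indicator of the ellipsoid interior (1 inside, 0 outside)."""
    return 1.0 / (1.0 + np.exp((rho - 1.0) / width))


def _case_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based sub-seeding: prefix-stable across cohort sizes
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _draw_site(rng: np.random.Generator) -> str:
    names = list(DEFAULT_SITE_SIZES)
    weights = np.array([DEFAULT_SITE_SIZES[n] for n in names], dtype=float)
    return str(rng.choice(names, p=weights / weights.sum()))


def _place_lesions(
    rng: np.random.Generator,
    config: PhantomConfig,
    prostate_center: np.ndarray,
    prostate_axes: np.ndarray,
    n_lesions: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample lesion (center, semi_axes) fully inside the prostate."""
    min_z_semi = 1.5 * config.voxel_spacing[2]  # span >= 2-3 slices
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_lesions):
        for _attempt in range(60):
            r = rng.uniform(*config.lesion_radius)
            semi = np.array(
                [r, r * rng.uniform(0.8, 1.1), max(r * rng.uniform(0.8, 1.2), min_z_semi)]
            )
            # Keep the whole lesion ellipsoid inside the prostate: the centre
            # must sit where the normalised prostate radius leaves room for
            # the lesion's largest semi-axis along every prostate axis.
            margin = np.max(semi / prostate_axes)
            if margin >= 0.85:
                continue
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rho_c = (0.85 - margin) * rng.uniform() ** (1 / 3)
            center = prostate_center + u * rho_c * prostate_axes
            if any(
                np.linalg.norm((center - c0) / (semi + s0)) < 1.0
                for c0, s0 in placed
            ):
                continue  # overlapping a previous lesion; retry
            placed.append((center, semi))
            break
    return placed


def generate_case(config: PhantomConfig, index: int) -> PhantomCase:
    """Generate one synthetic patient, deterministically from (config, index)."""
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = _case_rng(config.seed, index)
    grid = _physical_grid(config)
    extent = np.array(
        [n * s for n, s in zip(config.volume_shape, config.voxel_spacing)]
    )

    # anatomy: prostate ellipsoid with a darker transition-zone core
    prostate_center = rng.normal(scale=0.02, size=3) * extent
    prostate_axes = extent * np.array([0.32, 0.30, 0.38]) * rng.uniform(0.9, 1.1, 3)
    tz_axes = prostate_axes * rng.uniform(0.55, 0.65, 3)
    rho_prostate = _ellipsoid_rho(grid, prostate_center, prostate_axes)
    rho_tz = _ellipsoid_rho(grid, prostate_center, tz_axes)
    in_prostate = _soft_inside(rho_prostate)
    in_tz = _soft_inside(rho_tz)
    image = (
        _BACKGROUND
        + (_PZ_INTENSITY - _BACKGROUND) * in_prostate
        + (_TZ_INTENSITY - _PZ_INTENSITY) * in_tz
    )

    # lesions: hypointense ellipsoids with smooth margins, hard-edged labels
    positive = rng.random() < config.lesion_prevalence
    n_lesions = (
        int(rng.integers(config.lesions_per_positive[0], config.lesions_per_positive[1] + 1))
        if positive
        else 0
    )
    lesion_geoms = _place_lesions(
        rng, config, prostate_center, prostate_axes, n_lesions
    )
    labelmap = np.zeros(config.volume_shape, dtype=np.int16)
    grades: dict[int, int] = {}
    for k, (center, semi) in enumerate(lesion_geoms, start=1):
        rho = _ellipsoid_rho(grid, center, semi)
        image *= 1.0 - config.lesion_contrast * _soft_inside(rho, width=0.10)
        labelmap[rho <= 1.0] = k
        grades[k] = int(rng.choice([4, 5]))

    # oriented high-frequency texture: sharp along axis 0, smooth along 1/2,
    # so undersampling the phase-encoding axis visibly blurs it
    if config.texture_strength > 0:
        white = rng.standard_normal(config.volume_shape)
        texture = ndimage.gaussian_filter(white, sigma=(0.0, 2.0, 0.0))
        texture /= max(texture.std(), 1e-12)
        image += config.texture_strength * texture * in_prostate

    # smooth multiplicative bias field (coil-profile-like)
    if config.bias_strength > 0:
        gdir = rng.normal(size=3)
        gdir /= np.linalg.norm(gdir)
        ramp = sum(g * d for g, d in zip(grid, gdir)) / np.linalg.norm(extent)
        image *= 1.0 + config.bias_strength * ramp

    image = np.clip(image, 0.0, None)

    # Rician noise: magnitude of a complex Gaussian perturbation
    if config.noise_sigma > 0:
        sigma = config.noise_sigma * _PZ_INTENSITY
        re = image + rng.normal(scale=sigma, size=image.shape)
        im = rng.normal(scale=sigma, size=image.shape)
        image = np.sqrt(re**2 + im**2)

    vol = ImageVolume(image, spacing=config.voxel_spacing)
    lesions = LesionSet(labelmap, spacing=config.voxel_spacing, grades=grades)
    return PhantomCase(
        image=vol,
        lesions=lesions,
        patient_id=f"case_{index:05d}",
        site=_draw_site(rng),
        lesion_geometry=tuple(
            (tuple(float(v) for v in c), tuple(float(v) for v in s))
            for c, s in lesion_geoms
        ),
    )


def generate_cohort(config: PhantomConfig, n_cases: int) -> list[PhantomCase]:
    """Generate ``n_cases`` independent patients (prefix-stable in n)."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    return [generate_case(config, i) for i in range(n_cases)]


def save_cohort(cases: list[PhantomCase], out_dir: str | Path) -> Path:
    """Write images/labelmaps as NIfTI plus a cohort manifest CSV."""
    from .io import save_labelmap, save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "site", "label", "n_lesions", "image", "labelmap"])
        for case in cases:
            img_path = out / f"{case.patient_id}_t2w.nii.gz"
            lab_path = out / f"{case.patient_id}_lesions.nii.gz"
            save_volume(case.image, img_path)
            save_labelmap(case.lesions, lab_path)
            writer.writerow(
                [
                    case.patient_id,
                    case.site,
                    case.patient_label,
                    case.lesions.n_lesions,
                    img_path.name,
                    lab_path.name,
                ]
            )
    return manifest
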