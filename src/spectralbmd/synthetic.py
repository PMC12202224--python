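"""Seeded synthetic spectral-CT volumes of the phantom and simplified subjects.

Each generated scan holds three co-registered channels — a conventional
image (120 kVp surrogate, modelled as a 64 keV monoenergetic image) and
virtual monoenergetic images at 50 and 200 keV — plus an integer
ground-truth label grid. Subjects are deliberately simplified anatomy: a
soft-tissue body cylinder containing 18 spherical trabecular sites with
site-specific HA density and marrow fat fraction, one cortical-bone
cylinder, and the calibration phantom placed beside the body in the field
of view. Voxel spacing is body-weight dependent (heavier subjects are
scanned coarser), which reproduces the voxel-count mechanisms the analysis
layer studies.

Conventions: world coordinates in mm; arrays indexed ``[ix, iy, iz]``;
``origin`` is the world position of the first voxel's *center*; a voxel
belongs to a region iff its center lies inside the region's geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .materials import (
    ENERGY_CONVENTIONAL_KEV,
    ENERGY_HIGH_KEV,
    ENERGY_LOW_KEV,
    MaterialModel,
    default_material_model,
    mixture_hu,
)
from .phantom import PhantomSpec, default_phantom
from .sites import (
    INSERT_LABELS,
    LABEL_AIR,
    LABEL_PHANTOM_BODY,
    LABEL_SOFT_TISSUE,
    SiteRegistry,
    default_registry,
)

__all__ = [
    "NoiseSpec",
    "SpectralVolume",
    "SubjectSpec",
    "spacing_for_weight",
    "rasterize_phantom",
    "rasterize_subject",
    "make_subject",
    "simulate_cohort",
    "iter_cohort",
]

HU_AIR = -1000.0
CHANNEL_ENERGIES = {
    "conventional": ENERGY_CONVENTIONAL_KEV,
    "mono_low": ENERGY_LOW_KEV,
    "mono_high": ENERGY_HIGH_KEV,
}
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian HU noise per channel plus an isotropic PSF blur.

    Noise is white in the reconstructed image; the blur (given as a full
    width at half maximum, mm) stands in for the reconstruction point
    spread and produces partial-volume mixing at region boundaries. All
    zeros gives a bit-reproducible noiseless volume. The low-energy
    channel is the noisiest, as in dual-layer spectral reconstructions.
    """

    sd_conventional: float = 15.0
    sd_mono_low: float = 25.0
    sd_mono_high: float = 10.0
    blur_fwhm_mm: float = 0.7

    def __post_init__(self):
        for name in ("sd_conventional", "sd_mono_low", "sd_mono_high", "blur_fwhm_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)

    @classmethod
    def preset(cls, name: str) -> "NoiseSpec":
        if name == "none":
            return cls.none()
        if name == "default":
            return cls()
        raise ValueError(f"unknown noise preset {name!r}")

    def sd_for(self, channel: str) -> float:
        return {
            "conventional": self.sd_conventional,
            "mono_low": self.sd_mono_low,
            "mono_high": self.sd_mono_high,
        }[channel]


@dataclass
class SpectralVolume:
    """Three co-registered HU grids plus the ground-truth label grid."""

    channels: dict  # name -> float ndarray, shapes identical
    labels: np.ndarray  # int16 ndarray, same shape
    spacing_mm: tuple  # (sx, sy, sz), strictly positive
    origin_mm: tuple  # world position of voxel (0,0,0) center
    seed: int
    truth: dict = field(default_factory=dict)  # label -> (density, fat_fraction)
    subject_id: str = "phantom"
    weight_kg: float | None = None

    def __post_init__(self):
        shapes = {c.shape for c in self.channels.values()} | {self.labels.shape}
        if len(shapes) != 1:
            raise ValueError("channel and label grids must share one shape")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def voxel_centers(self):
        """Per-axis 1-D arrays of voxel-center world coordinates."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )


def spacing_for_weight(weight_kg: float) -> tuple[float, float, float]:
    """Weight-dependent voxel spacing (mm): heavier -> coarser.

    In-plane spacing runs linearly from 0.4 mm at 2 kg to 1.2 mm at 55 kg;
    slice thickness from 1 mm to 3 mm over the same range (clamped to the
    clinically used 1-3 mm band). Monotone non-decreasing in weight.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    t = np.clip((weight_kg - 2.0) / (55.0 - 2.0), 0.0, 1.0)
    s_xy = 0.4 + 0.8 * t
    s_z = float(np.clip(1.0 + 2.0 * t, 1.0, 3.0))
    return (float(s_xy), float(s_xy), s_z)


@dataclass(frozen=True)
class SubjectSpec:
    """Ground truth for one synthetic subject.

    ``site_truth`` maps site name -> (HA density mg/cm3, fat fraction).
    ``phantom_offset_mm`` positions the phantom axis mid-point in world
    coordinates (the body axis passes through the world origin).
    """

    subject_id: str
    weight_kg: float
    site_truth: dict
    phantom_offset_mm: tuple = None  # default: beside the body, derived
    body_length_mm: float = 40.0
    spacing_override_mm: tuple | None = None

    def __post_init__(self):
        for name, (dens, fat) in self.site_truth.items():
            if dens < 0 or not 0.0 <= fat <= 1.0:
                raise ValueError(f"invalid ground truth for site {name!r}")
        if self.phantom_offset_mm is None:
            object.__setattr__(
                self,
                "phantom_offset_mm",
                (self.body_radius_mm + 8.0 + 32.5, 0.0, 0.0),
            )

    @property
    def body_radius_mm(self) -> float:
        # body cross-section grows with weight; ~20 mm for a toy breed,
        # ~78 mm for a giant breed
        return 18.0 + 1.1 * self.weight_kg

    @property
    def site_radius_mm(self) -> float:
        return 3.0 + 0.08 * min(self.weight_kg, 60.0)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        if self.spacing_override_mm is not None:
            return self.spacing_override_mm
        return spacing_for_weight(self.weight_kg)

    def site_centers(self, registry: SiteRegistry | None = None) -> dict:
        """World-coordinate centers of the anatomical sites.

        Trabecular sites sit on three z-layers (z = -12, 0, +12 mm), six
        per layer on a ring at 55% of the body radius, with a per-layer
        angular offset so neighbouring layers interleave. The cortical
        cylinder sits on an outer ring between trabecular positions.
        """
        registry = registry or default_registry()
        ring = 0.55 * self.body_radius_mm
        centers = {}
        trab = registry.trabecular
        for i, site in enumerate(trab):
            layer, pos = divmod(i, 6)
            angle = np.deg2rad(60.0 * pos + 20.0 * layer)
            z = (layer - 1) * 12.0
            centers[site.name] = (
                ring * np.cos(angle),
                ring * np.sin(angle),
                z,
            )
        cort_ring = 0.8 * self.body_radius_mm
        ang = np.deg2rad(30.0)
        for site in registry.cortical:
            centers[site.name] = (cort_ring * np.cos(ang), cort_ring * np.sin(ang), 0.0)
        return centers


def _grid_axes(lo, hi, spacing):
    """Voxel-center coordinates covering [lo, hi] per axis."""
    axes = []
    for a in range(3):
        n = int(np.ceil((hi[a] - lo[a]) / spacing[a]))
        axes.append(lo[a] + spacing[a] * (np.arange(n) + 0.5))
    return axes


def _paint_cylinder_z(labels, axes, center, radius, length, label):
    """Assign ``label`` to voxels whose centers lie in a z-aligned cylinder."""
    xs, ys, zs = axes
    inx = np.flatnonzero(np.abs(xs - center[0]) <= radius)
    iny = np.flatnonzero(np.abs(ys - center[1]) <= radius)
    inz = np.flatnonzero(np.abs(zs - center[2]) <= length / 2.0)
    if inx.size == 0 or iny.size == 0 or inz.size == 0:
        return
    sub = np.ix_(inx, iny, inz)
    r2 = (xs[inx, None] - center[0]) ** 2 + (ys[None, iny] - center[1]) ** 2
    mask2d = r2 <= radius**2
    labels[sub] = np.where(mask2d[:, :, None], label, labels[sub])


def _paint_sphere(labels, axes, center, radius, label):
    xs, ys, zs = axes
    inx = np.flatnonzero(np.abs(xs - center[0]) <= radius)
    iny = np.flatnonzero(np.abs(ys - center[1]) <= radius)
    inz = np.flatnonzero(np.abs(zs - center[2]) <= radius)
    if inx.size == 0 or iny.size == 0 or inz.size == 0:
        return
    sub = np.ix_(inx, iny, inz)
    d2 = (
        (xs[inx, None, None] - center[0]) ** 2
        + (ys[None, iny, None] - center[1]) ** 2
        + (zs[None, None, inz] - center[2]) ** 2
    )
    labels[sub] = np.where(d2 <= radius**2, label, labels[sub])


def _paint_phantom(labels, axes, phantom: PhantomSpec, offset):
    ox, oy, oz = offset
    _paint_cylinder_z(
        labels,
        axes,
        (ox, oy, oz),
        phantom.radius_mm,
        phantom.length_mm,
        LABEL_PHANTOM_BODY,
    )
    for ins in phantom.inserts:
        _paint_cylinder_z(
            labels,
            axes,
            (ox + ins.center_xy_mm[0], oy + ins.center_xy_mm[1], oz),
            ins.radius_mm,
            ins.length_mm,
            INSERT_LABELS[ins.density_mg_cm3],
        )


def _render_channels(labels, truth, spacing, noise: NoiseSpec, seed,
                     model: MaterialModel, soft_tissue_labels=()):
    """Map labels to per-channel HU, then apply blur and noise.

    ``truth`` maps label -> (HA density, fat fraction); labels listed in
    ``soft_tissue_labels`` use the bulk soft-tissue material instead of the
    HA/fat/water mixture; unlisted labels (air) get -1000 HU.
    """
    n_labels = int(labels.max()) + 1
    channels = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(CHANNEL_ENERGIES))
    for (name, energy), child in zip(CHANNEL_ENERGIES.items(), child_seeds):
        lut = np.full(n_labels, HU_AIR)
        mu_w = model.mu_water(energy)
        for label, (dens, fat) in truth.items():
            lut[label] = mixture_hu(dens, fat, energy, model)
        for label in soft_tissue_labels:
            lut[label] = 1000.0 * (model.mu("soft_tissue", energy) - mu_w) / mu_w
        hu = lut[labels]
        if noise.blur_fwhm_mm > 0:
            sigma = [noise.blur_fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing]
            hu = gaussian_filter(hu, sigma=sigma, mode="nearest")
        sd = noise.sd_for(name)
        if sd > 0:
            rng = np.random.default_rng(child)
            hu = hu + rng.normal(0.0, sd, size=hu.shape)
        channels[name] = hu
    return channels


def rasterize_phantom(
    spec: PhantomSpec | None = None,
    spacing_mm: float | tuple = 0.5,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    padding_mm: float = 4.0,
    model: MaterialModel | None = None,
) -> SpectralVolume:
    """Rasterize the calibration phantom alone (reference-standard scan).

    The phantom axis is the z axis through the grid center. Identical
    ``spec``, ``spacing_mm``, ``noise`` and ``seed`` give a bit-identical
    volume.
    """
    spec = spec or default_phantom()
    noise = noise or NoiseSpec.none()
    model = model or default_material_model()
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    min_insert_r = min(ins.radius_mm for ins in spec.inserts)
    if max(spacing) > min_insert_r:
        warnings.warn(
            "voxel spacing exceeds the smallest insert radius; inserts may "
            "contain no voxel centers",
            stacklevel=2,
        )
    half = (
        spec.radius_mm + padding_mm,
        spec.radius_mm + padding_mm,
        spec.length_mm / 2.0 + padding_mm,
    )
    axes = _grid_axes([-h for h in half], half, spacing)
    labels = np.full([len(a) for a in axes], LABEL_AIR, dtype=np.int16)
    _paint_phantom(labels, axes, spec, (0.0, 0.0, 0.0))
    truth = {LABEL_PHANTOM_BODY: (0.0, 0.0)}
    for ins in spec.inserts:
        truth[INSERT_LABELS[ins.density_mg_cm3]] = (ins.density_mg_cm3, 0.0)
    channels = _render_channels(labels, truth, spacing, noise, seed, model)
    return SpectralVolume(
        channels=channels,
        labels=labels,
        spacing_mm=spacing,
        origin_mm=tuple(float(a[0]) for a in axes),
        seed=seed,
        truth=truth,
        subject_id="phantom",
    )


def rasterize_subject(
    subject: SubjectSpec,
    phantom: PhantomSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    registry: SiteRegistry | None = None,
    padding_mm: float = 4.0,
    model: MaterialModel | None = None,
) -> SpectralVolume:
    """One scan containing both the subject anatomy and the phantom.

    Raises ``ValueError`` if the phantom placement overlaps the body
    cylinder. A phantom placed partially outside the grid is rendered
    clipped (the downstream validation stage excludes such scans).
    """
    phantom = phantom or default_phantom()
    noise = noise or NoiseSpec.none()
    model = model or default_material_model()
    registry = registry or default_registry()
    spacing = subject.spacing_mm

    ox, oy, oz = subject.phantom_offset_mm
    if np.hypot(ox, oy) < subject.body_radius_mm + phantom.radius_mm:
        # lateral separation too small -> cylinders intersect in-plane
        if abs(oz) < (subject.body_length_mm + phantom.length_mm) / 2.0:
            raise ValueError("phantom placement overlaps the subject anatomy")

    r_body = subject.body_radius_mm
    lo = [
        -(r_body + padding_mm),
        -max(r_body, abs(oy) + phantom.radius_mm) - padding_mm,
        -max(subject.body_length_mm / 2.0, abs(oz) + phantom.length_mm / 2.0)
        - padding_mm,
    ]
    hi = [
        max(r_body, ox + phantom.radius_mm) + padding_mm,
        max(r_body, abs(oy) + phantom.radius_mm) + padding_mm,
        -lo[2],
    ]
    axes = _grid_axes(lo, hi, spacing)
    labels = np.full([len(a) for a in axes], LABEL_AIR, dtype=np.int16)

    _paint_cylinder_z(
        labels, axes, (0.0, 0.0, 0.0), r_body, subject.body_length_mm,
        LABEL_SOFT_TISSUE,
    )
    centers = subject.site_centers(registry)
    truth = {}
    for site in registry.trabecular:
        dens, fat = subject.site_truth[site.name]
        _paint_sphere(labels, axes, centers[site.name], subject.site_radius_mm,
                      site.label)
        truth[site.label] = (dens, fat)
    for site in registry.cortical:
        dens, fat = subject.site_truth[site.name]
        _paint_cylinder_z(
            labels, axes, centers[site.name], 0.9 * subject.site_radius_mm,
            8.0, site.label,
        )
        truth[site.label] = (dens, fat)
    _paint_phantom(labels, axes, phantom, subject.phantom_offset_mm)
    truth[LABEL_PHANTOM_BODY] = (0.0, 0.0)
    for ins in phantom.inserts:
        truth[INSERT_LABELS[ins.density_mg_cm3]] = (ins.density_mg_cm3, 0.0)

    channels = _render_channels(
        labels, truth, spacing, noise, seed, model,
        soft_tissue_labels=(LABEL_SOFT_TISSUE,),
    )
    return SpectralVolume(
        channels=channels,
        labels=labels,
        spacing_mm=spacing,
        origin_mm=tuple(float(a[0]) for a in axes),
        seed=seed,
        truth=truth,
        subject_id=subject.subject_id,
        weight_kg=subject.weight_kg,
    )


def _subject_seed(master_seed: int, index: int) -> int:
    child = np.random.SeedSequence(master_seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def make_subject(
    subject_id: str,
    weight_kg: float,
    rng: np.random.Generator,
    registry: SiteRegistry | None = None,
    phantom_jitter_mm: float = 2.0,
) -> SubjectSpec:
    """Sample one subject's ground truth around the registry defaults.

    Site densities get a lognormal multiplier (sigma 0.12, between-subject
    biological variation); fat fractions a clipped Gaussian jitter (sd
    0.05); the phantom position a small placement jitter in y and z.
    """
    registry = registry or default_registry()
    truth = {}
    for site in registry.cortical + registry.trabecular:
        dens = site.density_mg_cm3 * float(rng.lognormal(0.0, 0.12))
        fat = float(np.clip(site.fat_fraction + rng.normal(0.0, 0.05), 0.0, 1.0))
        if site.kind == "cortical":
            fat = 0.0
        truth[site.name] = (dens, fat)
    body_radius = 18.0 + 1.1 * weight_kg
    jitter = rng.normal(0.0, phantom_jitter_mm, size=2) if phantom_jitter_mm else (0, 0)
    offset = (body_radius + 8.0 + 32.5, float(jitter[0]), float(jitter[1]))
    return SubjectSpec(
        subject_id=subject_id,
        weight_kg=float(weight_kg),
        site_truth=truth,
        phantom_offset_mm=offset,
    )


def iter_cohort(
    n_subjects: int,
    weight_range: tuple = (2.2, 54.7),
    seed: int = 0,
    noise: NoiseSpec | None = None,
    phantom: PhantomSpec | None = None,
    registry: SiteRegistry | None = None,
):
    """Lazily yield ``(SubjectSpec, SpectralVolume)`` for a seeded cohort.

    Weights are log-uniform over ``weight_range`` (small dogs outnumber
    large ones, matching a right-skewed clinical weight distribution).
    Per-subject seeds are derived deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    noise = NoiseSpec() if noise is None else noise
    registry = registry or default_registry()
    phantom = phantom or default_phantom()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    lo, hi = weight_range
    weights = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_subjects))
    for i in range(n_subjects):
        spec = make_subject(f"subject_{i + 1:03d}", weights[i], rng, registry)
        vol = rasterize_subject(
            spec, phantom, noise, seed=_subject_seed(seed, i), registry=registry
        )
        yield spec, vol


def cohort_truth_table(specs_and_volumes) -> pd.DataFrame:
    """Long-format ground-truth table: one row per subject x site."""
    rows = []
    for spec, vol in specs_and_volumes:
        spacing_str = "x".join(f"{s:.4f}" for s in vol.spacing_mm)
        for name, (dens, fat) in sorted(spec.site_truth.items()):
            rows.append(
                {
                    "subject_id": spec.subject_id,
                    "weight_kg": spec.weight_kg,
                    "site": name,
                    "true_density_mg_cm3": dens,
                    "fat_fraction": fat,
                    "spacing_mm": spacing_str,
                    "seed": vol.seed,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    n_subjects: int,
    weight_range: tuple = (2.2, 54.7),
    seed: int = 0,
    noise: NoiseSpec | None = None,
    phantom: PhantomSpec | None = None,
    registry: SiteRegistry | None = None,
):
    """Materialize a cohort: list of volumes plus the ground-truth table.

    For large cohorts prefer :func:`iter_cohort`, which streams volumes.
    """
    pairs = list(iter_cohort(n_subjects, weight_range, seed, noise, phantom, registry))
    table = cohort_truth_table(pairs)
    return [vol for _, vol in pairs], table
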