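"""Volume-of-interest definition and extraction.

Implements the measurement protocol: a sphere centrally inscribed in each
phantom insert, cylindrical insert VOIs whose lengths are adjusted per scan
to hit a common voxel-count target, the "largest possible" sphere inside
each trabecular site (its ground-truth label eroded by one voxel), and a
single transverse planar disc for the cortical site. Membership is by
voxel center; repeated extraction at an identical placement is strictly
deterministic, which is what drives the test-retest ICC of 1.0 downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .phantom import PhantomSpec, default_phantom
from .sites import INSERT_LABELS, SiteRegistry, default_registry

__all__ = [
    "VOIShape",
    "MeasurementRecord",
    "voxel_mask",
    "voxels_in_shape",
    "measure_voi",
    "largest_inscribed_sphere",
    "insert_sphere_voi",
    "cortical_disc_roi",
    "cylindrical_insert_vois",
    "protocol_vois",
]

_EPS = 1e-9


@dataclass(frozen=True)
class VOIShape:
    """A sphere, z-aligned cylinder or single-slice planar disc."""

    kind: str  # "sphere" | "cylinder" | "planar-disc"
    center_mm: tuple
    radius_mm: float
    length_mm: float | None = None  # cylinders only

    def __post_init__(self):
        if self.kind not in ("sphere", "cylinder", "planar-disc"):
            raise ValueError(f"unknown VOI kind {self.kind!r}")
        if self.radius_mm <= 0:
            raise ValueError("radius must be > 0")
        if self.kind == "cylinder" and (self.length_mm is None or self.length_mm <= 0):
            raise ValueError("cylinder requires a positive length")


@dataclass(frozen=True)
class MeasurementRecord:
    """One VOI x method x repeat observation."""

    subject_id: str
    site: str
    method: str  # "qct" | "sdct"
    repeat: int
    shape_kind: str
    mean_value: float  # raw channel mean (HU for QCT stage, mg/cm3 for map)
    bmd_mg_cm3: float
    voxel_count: int
    volume_mm3: float

    def __post_init__(self):
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")

    def to_dict(self):
        return asdict(self)


def _axes(geometry):
    return tuple(
        geometry.origin_mm[a] + geometry.spacing_mm[a] * np.arange(geometry.shape[a])
        for a in range(3)
    )


def voxel_mask(geometry, shape: VOIShape) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside ``shape``.

    ``geometry`` is any object with ``shape``, ``spacing_mm`` and
    ``origin_mm`` (a SpectralVolume or BMDMap). Raises ``ValueError`` if
    the shape captures no voxel centers.
    """
    xs, ys, zs = _axes(geometry)
    cx, cy, cz = shape.center_mm
    mask = np.zeros(geometry.shape, dtype=bool)
    if shape.kind == "sphere":
        d2 = (
            (xs[:, None, None] - cx) ** 2
            + (ys[None, :, None] - cy) ** 2
            + (zs[None, None, :] - cz) ** 2
        )
        mask = d2 <= shape.radius_mm**2
    elif shape.kind == "cylinder":
        r2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
        in_plane = r2 <= shape.radius_mm**2
        in_z = np.abs(zs - cz) <= shape.length_mm / 2.0
        mask = in_plane[:, :, None] & in_z[None, None, :]
    else:  # planar-disc: exactly one slice, the one nearest the center
        iz = int(np.argmin(np.abs(zs - cz)))
        r2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
        mask[:, :, iz] = r2 <= shape.radius_mm**2
    if not mask.any():
        raise ValueError(f"VOI contains no voxel centers: {shape}")
    return mask


def voxels_in_shape(geometry, shape: VOIShape) -> np.ndarray:
    """Index array (k, 3) of voxels inside ``shape`` (center-in test)."""
    return np.argwhere(voxel_mask(geometry, shape))


def measure_voi(
    geometry,
    values: np.ndarray,
    shape: VOIShape,
    site: str,
    method: str,
    repeat: int = 1,
    subject_id: str = "",
    bmd: float | None = None,
) -> MeasurementRecord:
    """Mean of ``values`` over the VOI, with voxel count and volume.

    ``bmd`` defaults to the mean itself (appropriate when ``values`` is
    already a BMD map); the QCT path passes the calibrated value instead.
    """
    mask = voxel_mask(geometry, shape)
    mean = float(values[mask].mean())
    count = int(mask.sum())
    return MeasurementRecord(
        subject_id=subject_id or getattr(geometry, "subject_id", ""),
        site=site,
        method=method,
        repeat=repeat,
        shape_kind=shape.kind,
        mean_value=mean,
        bmd_mg_cm3=mean if bmd is None else float(bmd),
        voxel_count=count,
        volume_mm3=count * float(np.prod(geometry.spacing_mm)),
    )


def _label_bbox(labels: np.ndarray, label: int, pad: int = 1):
    idx = np.argwhere(labels == label)
    if idx.size == 0:
        raise ValueError(f"label {label} absent from volume")
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, labels.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def largest_inscribed_sphere(geometry, label: int) -> VOIShape:
    """Largest sphere inside a label region eroded by one voxel.

    Operationalizes "the largest possible circular VOI ... avoiding the
    cortical bone": the ground-truth region is shrunk by a one-voxel
    safety margin, then the sphere is centered at the interior point
    deepest from the region surface (anisotropy-aware Euclidean distance
    transform). Falls back to the uneroded region when erosion empties it
    (very coarse scans).
    """
    labels = geometry.labels
    box = _label_bbox(labels, label)
    mask = labels[box] == label
    eroded = ndimage.binary_erosion(mask)
    if not eroded.any():
        eroded = mask
    dist = ndimage.distance_transform_edt(eroded, sampling=geometry.spacing_mm)
    ijk = np.unravel_index(int(np.argmax(dist)), dist.shape)
    radius = float(dist[ijk]) * (1.0 - _EPS)
    center = tuple(
        geometry.origin_mm[a] + geometry.spacing_mm[a] * (box[a].start + ijk[a])
        for a in range(3)
    )
    return VOIShape(kind="sphere", center_mm=center, radius_mm=radius)


def insert_sphere_voi(geometry, label: int) -> VOIShape:
    """Spherical VOI placed centrally in a phantom insert."""
    return largest_inscribed_sphere(geometry, label)


def cortical_disc_roi(geometry, label: int) -> VOIShape:
    """Planar 2D disc inside the cortical label, one transverse slice."""
    labels = geometry.labels
    box = _label_bbox(labels, label)
    mask = labels[box] == label
    iz = mask.shape[2] // 2  # mid-slice of the cortical segment
    sl = mask[:, :, iz]
    eroded = ndimage.binary_erosion(sl)
    if not eroded.any():
        eroded = sl
    dist = ndimage.distance_transform_edt(
        eroded, sampling=geometry.spacing_mm[:2]
    )
    ij = np.unravel_index(int(np.argmax(dist)), dist.shape)
    radius = float(dist[ij]) * (1.0 - _EPS)
    center = (
        geometry.origin_mm[0] + geometry.spacing_mm[0] * (box[0].start + ij[0]),
        geometry.origin_mm[1] + geometry.spacing_mm[1] * (box[1].start + ij[1]),
        geometry.origin_mm[2] + geometry.spacing_mm[2] * (box[2].start + iz),
    )
    return VOIShape(kind="planar-disc", center_mm=center, radius_mm=radius)


def _label_centroid(geometry, label: int):
    idx = np.argwhere(geometry.labels == label)
    if idx.size == 0:
        raise ValueError(f"label {label} absent from volume")
    c = idx.mean(axis=0)
    return tuple(
        geometry.origin_mm[a] + geometry.spacing_mm[a] * c[a] for a in range(3)
    )


def cylindrical_insert_vois(
    geometry,
    phantom: PhantomSpec | None = None,
    target_voxel_count: int = 1800,
    radius_mm: float = 6.5,
) -> dict:
    """Length-adjusted cylindrical VOIs, one per insert.

    The cylinder radius is fixed; its length (a whole number of slices) is
    chosen per scan so the voxel count is as close as possible to
    ``target_voxel_count``, emulating the voxel-count-controlled second
    measurement pass. Raises if the closest achievable count is more than
    50% away from the target (insert too short at this spacing).

    Returns a dict: insert density -> VOIShape.
    """
    phantom = phantom or default_phantom()
    xs, ys, zs = _axes(geometry)
    s_z = geometry.spacing_mm[2]
    out = {}
    for ins in phantom.inserts:
        label = INSERT_LABELS[ins.density_mg_cm3]
        cx, cy, cz = _label_centroid(geometry, label)
        n_disc = int(
            np.sum((xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= radius_mm**2)
        )
        if n_disc == 0:
            raise ValueError(
                f"cylindrical VOI disc empty for insert {ins.density_mg_cm3:g}"
            )
        k_max = max(int(np.floor(ins.length_mm / s_z)), 1)
        k_best = min(max(int(round(target_voxel_count / n_disc)), 1), k_max)
        k_best = min(
            (k for k in {k_best - 1, k_best, k_best + 1} if 1 <= k <= k_max),
            key=lambda k: abs(k * n_disc - target_voxel_count),
        )
        count = k_best * n_disc
        if abs(count - target_voxel_count) > 0.5 * target_voxel_count:
            raise ValueError(
                f"insert {ins.density_mg_cm3:g}: achievable voxel count "
                f"{count} is outside +/-50% of target {target_voxel_count}"
            )
        iz0 = int(np.argmin(np.abs(zs - cz)))
        center_z = zs[iz0] if k_best % 2 == 1 else zs[iz0] + s_z / 2.0
        out[ins.density_mg_cm3] = VOIShape(
            kind="cylinder",
            center_mm=(cx, cy, float(center_z)),
            radius_mm=radius_mm,
            length_mm=k_best * s_z * (1.0 - _EPS),
        )
    return out


def insert_vois(geometry, registry: SiteRegistry | None = None) -> dict:
    """Spherical insert VOIs only (phantom-only scans): name -> VOIShape."""
    registry = registry or default_registry()
    return {s.name: insert_sphere_voi(geometry, s.label) for s in registry.inserts}


def protocol_vois(geometry, registry: SiteRegistry | None = None) -> dict:
    """The standard per-subject VOI set: site name -> VOIShape.

    18 trabecular spheres, 1 cortical planar disc and 4 spherical insert
    VOIs — 23 shapes per subject.
    """
    registry = registry or default_registry()
    shapes = {}
    for site in registry.trabecular:
        shapes[site.name] = largest_inscribed_sphere(geometry, site.label)
    for site in registry.cortical:
        shapes[site.name] = cortical_disc_roi(geometry, site.label)
    for site in registry.inserts:
        shapes[site.name] = insert_sphere_voi(geometry, site.label)
    return shapes
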