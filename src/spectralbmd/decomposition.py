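"""Regression-line material decomposition: 50/200 keV HU -> BMD map.

Calibration: mean 50 keV and 200 keV HU are sampled inside each phantom
insert over a calibration sample of scans (default ten), the per-insert
means are plotted against each other in (HU50, HU200) space, and a line is
fitted through them — by total least squares by default, since both
coordinates are equally noisy measurements. Every voxel of a scan is then
orthogonally projected onto that line; the projected coordinate is mapped
affinely to a bone volume fraction and on to mg HA/cm3, anchored so that
the projected water point (0, 0) maps to exactly 0 and scaled by a
least-squares fit against the four known insert densities. Negative
densities are clamped to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .phantom import PhantomSpec, default_phantom
from .sites import INSERT_LABELS

__all__ = [
    "InsertSample",
    "DecompositionModel",
    "BMDMap",
    "collect_insert_samples",
    "fit_decomposition",
    "project_voxel",
    "apply_decomposition",
]

# fraction scale: bone volume fraction 1.0 at the reference insert density
REFERENCE_DENSITY = 800.0


@dataclass(frozen=True)
class InsertSample:
    """Mean dual-energy HU of one insert in one calibration scan."""

    density_mg_cm3: float
    hu50: float
    hu200: float
    scan_id: str
    voxel_count: int

    def __post_init__(self):
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")


@dataclass(frozen=True)
class DecompositionModel:
    """The fitted calibration line and its density anchoring.

    ``base_point`` and unit ``direction`` define the line in (HU50, HU200)
    space. ``t_water`` is the projected coordinate of the water point
    (0, 0); ``density_per_t`` converts the water-anchored projected
    coordinate directly to mg HA/cm3.
    """

    base_point: tuple  # (hu50, hu200)
    direction: tuple  # unit vector, oriented toward increasing density
    t_water: float
    density_per_t: float  # mg/cm3 per unit projected coordinate, > 0
    calibration_n: int = 0
    fit_method: str = "tls"
    scan_ids: tuple = ()

    def __post_init__(self):
        norm = float(np.hypot(*self.direction))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("direction must be unit length")
        if self.density_per_t <= 0:
            raise ValueError("density must increase along the line direction")

    def project(self, hu50, hu200):
        """Projected line coordinate of (hu50, hu200); arrays broadcast."""
        dx = np.asarray(hu50, dtype=float) - self.base_point[0]
        dy = np.asarray(hu200, dtype=float) - self.base_point[1]
        t = dx * self.direction[0] + dy * self.direction[1]
        return float(t) if t.ndim == 0 else t

    def fraction(self, t):
        """Bone volume fraction (1.0 at the reference insert density)."""
        return self.density(t) / REFERENCE_DENSITY

    def density(self, t):
        """Signed density (mg/cm3) at projected coordinate ``t``."""
        return self.density_per_t * (np.asarray(t, dtype=float) - self.t_water)

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_point": list(self.base_point),
                "direction": list(self.direction),
                "t_water": self.t_water,
                "density_per_t": self.density_per_t,
                "calibration_n": self.calibration_n,
                "fit_method": self.fit_method,
                "scan_ids": list(self.scan_ids),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DecompositionModel":
        d = json.loads(text)
        return cls(
            base_point=tuple(d["base_point"]),
            direction=tuple(d["direction"]),
            t_water=float(d["t_water"]),
            density_per_t=float(d["density_per_t"]),
            calibration_n=int(d["calibration_n"]),
            fit_method=d.get("fit_method", "tls"),
            scan_ids=tuple(d.get("scan_ids", ())),
        )

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "DecompositionModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class BMDMap:
    """Voxel-wise BMD (mg HA/cm3), co-registered with its source scan."""

    values: np.ndarray
    spacing_mm: tuple
    origin_mm: tuple
    model: DecompositionModel
    subject_id: str = ""

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def collect_insert_samples(
    volumes,
    phantom: PhantomSpec | None = None,
    n_calibration: int = 10,
) -> list[InsertSample]:
    """Mean (HU50, HU200) per insert over the first ``n_calibration`` scans.

    Each sample uses the largest sphere inscribed in the insert's
    ground-truth label region (eroded by one voxel). Raises if a scan's
    insert VOI contains no voxels.
    """
    from .voi import insert_sphere_voi, voxel_mask

    phantom = phantom or default_phantom()
    if n_calibration < 1:
        raise ValueError("n_calibration must be >= 1")
    samples = []
    for vol in volumes[:n_calibration]:
        for ins in phantom.inserts:
            label = INSERT_LABELS[ins.density_mg_cm3]
            try:
                shape = insert_sphere_voi(vol, label)
                mask = voxel_mask(vol, shape)
            except ValueError as exc:
                raise ValueError(
                    f"empty insert VOI: scan {vol.subject_id!r}, insert "
                    f"{ins.density_mg_cm3:g} mg/cm3"
                ) from exc
            samples.append(
                InsertSample(
                    density_mg_cm3=ins.density_mg_cm3,
                    hu50=float(vol.channel("mono_low")[mask].mean()),
                    hu200=float(vol.channel("mono_high")[mask].mean()),
                    scan_id=vol.subject_id,
                    voxel_count=int(mask.sum()),
                )
            )
    return samples


def _insert_means(samples: list[InsertSample]) -> tuple[np.ndarray, np.ndarray]:
    """Average per-insert (HU50, HU200) over the calibration scans."""
    densities = sorted({s.density_mg_cm3 for s in samples})
    pts = []
    for d in densities:
        sub = [s for s in samples if s.density_mg_cm3 == d]
        pts.append([np.mean([s.hu50 for s in sub]), np.mean([s.hu200 for s in sub])])
    return np.array(pts), np.array(densities)


def fit_decomposition(
    samples,
    densities=None,
    fit_method: str = "tls",
) -> DecompositionModel:
    """Fit the calibration line and its density anchoring.

    ``samples`` is either a list of :class:`InsertSample` (averaged per
    insert first) or an (k, 2) array of per-insert mean (HU50, HU200)
    points with ``densities`` the matching mg/cm3 values.

    ``fit_method`` "tls" (default) fits the line by total least squares
    (principal axis of the 2x2 scatter); "ols" regresses HU200 on HU50.
    """
    if densities is None:
        samples = list(samples)
        pts, dens = _insert_means(samples)
        scan_ids = tuple(dict.fromkeys(s.scan_id for s in samples))
        n_cal = max(
            sum(1 for s in samples if s.density_mg_cm3 == d)
            for d in {s.density_mg_cm3 for s in samples}
        )
    else:
        pts = np.asarray(samples, dtype=float)
        dens = np.asarray(densities, dtype=float)
        scan_ids, n_cal = (), 0
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 insert points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate fit: all insert points coincide")
    if fit_method == "tls":
        scatter = centered.T @ centered
        eigval, eigvec = np.linalg.eigh(scatter)
        direction = eigvec[:, np.argmax(eigval)]
    elif fit_method == "ols":
        slope = float(
            np.sum(centered[:, 0] * centered[:, 1]) / np.sum(centered[:, 0] ** 2)
        )
        direction = np.array([1.0, slope]) / np.hypot(1.0, slope)
    else:
        raise ValueError(f"unknown fit_method {fit_method!r}")
    t = centered @ direction
    # orient the line so projected coordinate increases with density
    if np.sum((t - t.mean()) * (dens - dens.mean())) < 0:
        direction = -direction
        t = -t
    t_water = float(-(centroid @ direction))
    dt = t - t_water
    denom = float(np.sum(dt**2))
    if denom == 0:
        raise ValueError("degenerate fit: inserts project onto the water point")
    density_per_t = float(np.sum(dt * dens) / denom)
    return DecompositionModel(
        base_point=tuple(centroid),
        direction=tuple(direction),
        t_water=t_water,
        density_per_t=density_per_t,
        calibration_n=n_cal,
        fit_method=fit_method,
        scan_ids=scan_ids,
    )


def project_voxel(hu50, hu200, model: DecompositionModel):
    """Orthogonal projection of (hu50, hu200) onto the calibration line."""
    return model.project(hu50, hu200)


def apply_decomposition(volume, model: DecompositionModel) -> BMDMap:
    """Voxel-wise project -> fraction -> density; negatives clamped to 0."""
    try:
        hu50 = volume.channel("mono_low")
        hu200 = volume.channel("mono_high")
    except KeyError as exc:
        raise ValueError("volume lacks the 50/200 keV channels") from exc
    if hu50.shape != hu200.shape:
        raise ValueError("channel shape mismatch")
    t = model.project(hu50, hu200)
    bmd = np.maximum(model.density(t), 0.0)
    return BMDMap(
        values=bmd,
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
        model=model,
        subject_id=volume.subject_id,
    )
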