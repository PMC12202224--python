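"""Measurement-site registry and label-map conventions.

The measurement protocol places 18 trabecular volumes of interest, one
planar cortical region of interest (right femoral mid-diaphysis) and one
VOI per calibration-phantom insert on every subject. Each site carries a
default ground-truth hydroxyapatite density and marrow fat volume fraction
used by the synthetic-subject generator; per-subject values are sampled
around these defaults.

Label-volume conventions (integer voxel labels, ITK-SNAP compatible):
0 air, 1 soft tissue, 2 phantom body, 3-6 phantom inserts (100/200/400/800
mg HA/cm3), 7 cortical site, 10+ trabecular sites.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SiteDef",
    "SiteRegistry",
    "default_registry",
    "LABEL_AIR",
    "LABEL_SOFT_TISSUE",
    "LABEL_PHANTOM_BODY",
    "INSERT_LABELS",
    "LABEL_CORTICAL",
]

LABEL_AIR = 0
LABEL_SOFT_TISSUE = 1
LABEL_PHANTOM_BODY = 2
# insert density (mg HA/cm3) -> voxel label
INSERT_LABELS = {100.0: 3, 200.0: 4, 400.0: 5, 800.0: 6}
LABEL_CORTICAL = 7
_FIRST_TRABECULAR_LABEL = 10


@dataclass(frozen=True)
class SiteDef:
    """One named measurement site."""

    name: str
    kind: str  # "trabecular" | "cortical" | "insert"
    label: int
    density_mg_cm3: float  # default ground-truth HA density
    fat_fraction: float  # default marrow fat volume fraction

    def __post_init__(self):
        if self.kind not in ("trabecular", "cortical", "insert"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must be in [0, 1]")


# (name, density, fat fraction); densities are typical canine trabecular
# values, fat fractions reflect the yellow-marrow gradient: low in
# vertebral bodies, highest in long-bone diaphyses.
_TRABECULAR_DEFAULTS = [
    ("t5_cranial", 300.0, 0.15),
    ("t5_caudal", 300.0, 0.15),
    ("t12_cranial", 320.0, 0.15),
    ("t12_caudal", 305.0, 0.15),
    ("l5_cranial", 300.0, 0.15),
    ("l5_caudal", 305.0, 0.15),
    ("scapula_left", 375.0, 0.25),
    ("scapula_right", 375.0, 0.25),
    ("ilium_left", 355.0, 0.25),
    ("ilium_right", 355.0, 0.25),
    ("humerus_metaphysis_left", 180.0, 0.45),
    ("humerus_metaphysis_right", 180.0, 0.45),
    ("femur_neck_left", 250.0, 0.40),
    ("femur_neck_right", 250.0, 0.40),
    ("femur_diaphysis_left", 140.0, 0.70),
    ("femur_diaphysis_right", 140.0, 0.70),
    ("humerus_diaphysis_left", 170.0, 0.70),
    ("humerus_diaphysis_right", 170.0, 0.70),
]


class SiteRegistry:
    """Ordered collection of measurement sites with unique names/labels."""

    def __init__(self, sites: list[SiteDef]):
        names = [s.name for s in sites]
        labels = [s.label for s in sites]
        if len(set(names)) != len(names):
            raise ValueError("site names must be unique")
        if len(set(labels)) != len(labels):
            raise ValueError("site labels must be unique")
        self.sites = list(sites)
        self._by_name = {s.name: s for s in sites}

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)

    def __getitem__(self, name: str) -> SiteDef:
        return self._by_name[name]

    @property
    def trabecular(self) -> list[SiteDef]:
        return [s for s in self.sites if s.kind == "trabecular"]

    @property
    def cortical(self) -> list[SiteDef]:
        return [s for s in self.sites if s.kind == "cortical"]

    @property
    def inserts(self) -> list[SiteDef]:
        return [s for s in self.sites if s.kind == "insert"]

    @property
    def comparison_sites(self) -> list[SiteDef]:
        """The 19 anatomical rows of the method-comparison table."""
        return self.cortical + self.trabecular


def default_registry() -> SiteRegistry:
    """The standard protocol: 18 trabecular + 1 cortical + 4 inserts."""
    sites = [
        SiteDef("cortical_femur_right", "cortical", LABEL_CORTICAL, 1100.0, 0.0)
    ]
    for i, (name, dens, fat) in enumerate(_TRABECULAR_DEFAULTS):
        sites.append(
            SiteDef(name, "trabecular", _FIRST_TRABECULAR_LABEL + i, dens, fat)
        )
    for dens, label in INSERT_LABELS.items():
        sites.append(SiteDef(f"insert_{int(dens)}", "insert", label, dens, 0.0))
    return SiteRegistry(sites)
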