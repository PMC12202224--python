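"""Two-basis X-ray attenuation model for the materials in the synthetic scans.

Photon attenuation in the diagnostic energy range is dominated by two
interactions: the photoelectric effect (steeply decreasing with energy,
roughly as E^-3, and strong for high-Z constituents such as calcium) and
Compton scattering (slowly varying, following the Klein-Nishina cross
section). Each material's linear attenuation coefficient is therefore
modelled as

    mu(E) = a_p * f_p(E) + a_c * f_c(E)

where ``f_p(E) = (E / 100 keV)^-3`` and ``f_c`` is the Klein-Nishina total
cross-section shape, normalised to 1 at 100 keV. The per-material
amplitudes ``(a_p, a_c)`` are fitted once, by unweighted least squares over
40-200 keV, to tabulated photon mass-attenuation values for water, adipose
tissue, soft tissue and hydroxyapatite, and embedded here as module data so
the model carries no runtime data dependency.

CT numbers follow the Hounsfield convention: ``HU = 1000 * (mu - mu_w) /
mu_w`` with water fixed at 0 HU at every energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialModel",
    "klein_nishina",
    "mixture_hu",
    "HA_SOLID_DENSITY_MG_CM3",
    "ENERGY_CONVENTIONAL_KEV",
    "ENERGY_LOW_KEV",
    "ENERGY_HIGH_KEV",
]

# Effective monoenergetic surrogate for the 120 kVp polychromatic image,
# and the two virtual monoenergetic channels used for decomposition.
ENERGY_CONVENTIONAL_KEV = 64.0
ENERGY_LOW_KEV = 50.0
ENERGY_HIGH_KEV = 200.0

# Density of solid (crystalline) hydroxyapatite, g/cm3, expressed in
# mg/cm3 for consistency with BMD units. A voxel holding d mg HA/cm3
# occupies a HA volume fraction d / HA_SOLID_DENSITY_MG_CM3.
HA_SOLID_DENSITY_MG_CM3 = 3160.0

# Tabulated mass-attenuation values (cm^2/g) over the diagnostic range,
# compiled from standard photon cross-section tabulations. Hydroxyapatite
# is a mass-fraction-weighted elemental mixture (Ca 39.9%, P 18.5%,
# O 41.4%, H 0.2%).
_TAB_ENERGIES_KEV = np.array([40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0])
_TAB_MU_RHO = {
    "water": np.array([0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505, 0.1370]),
    "fat": np.array([0.2396, 0.2123, 0.1974, 0.1800, 0.1688, 0.1500, 0.1368]),
    "soft_tissue": np.array([0.2685, 0.2264, 0.2048, 0.1823, 0.1693, 0.1492, 0.1358]),
    "ha": np.array([0.6440, 0.4380, 0.3300, 0.2380, 0.2000, 0.1590, 0.1410]),
}
# Bulk densities (g/cm3) converting mass attenuation into linear attenuation.
_BULK_DENSITY = {"water": 1.000, "fat": 0.950, "soft_tissue": 1.060, "ha": 3.160}

_ELECTRON_REST_KEV = 511.0


def klein_nishina(energy_kev: np.ndarray | float) -> np.ndarray | float:
    """Total Klein-Nishina cross-section shape, normalised to 1 at 100 keV.

    Parameters
    ----------
    energy_kev
        Photon energy in keV (scalar or array).
    """

    def _kn(a):
        t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log1p(2.0 * a) / a)
        t2 = np.log1p(2.0 * a) / (2.0 * a)
        t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
        return t1 + t2 - t3

    a = np.asarray(energy_kev, dtype=float) / _ELECTRON_REST_KEV
    ref = _kn(100.0 / _ELECTRON_REST_KEV)
    out = _kn(a) / ref
    return out if out.ndim else float(out)


def _photoelectric(energy_kev):
    return (np.asarray(energy_kev, dtype=float) / 100.0) ** -3


def _fit_basis(mu_linear: np.ndarray) -> tuple[float, float]:
    """Least-squares (a_p, a_c) reproducing tabulated linear attenuation."""
    design = np.column_stack(
        [_photoelectric(_TAB_ENERGIES_KEV), klein_nishina(_TAB_ENERGIES_KEV)]
    )
    coef, *_ = np.linalg.lstsq(design, mu_linear, rcond=None)
    return float(coef[0]), float(coef[1])


@dataclass(frozen=True)
class MaterialModel:
    """Fitted basis amplitudes for water, hydroxyapatite, fat and soft tissue.

    ``coefficients[material]`` holds ``(a_p, a_c)`` such that the linear
    attenuation (1/cm) of the bulk material is ``a_p*f_p(E) + a_c*f_c(E)``.
    Construction uses the embedded tabulation; the default instance is the
    one used throughout the package.
    """

    coefficients: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.coefficients:
            coeffs = {
                name: _fit_basis(_BULK_DENSITY[name] * mu_rho)
                for name, mu_rho in _TAB_MU_RHO.items()
            }
            object.__setattr__(self, "coefficients", coeffs)

    def mu(self, material: str, energy_kev) -> np.ndarray | float:
        """Linear attenuation (1/cm) of a bulk material at ``energy_kev``."""
        a_p, a_c = self.coefficients[material]
        out = a_p * _photoelectric(energy_kev) + a_c * klein_nishina(energy_kev)
        return out

    def mu_water(self, energy_kev):
        return self.mu("water", energy_kev)


_DEFAULT_MODEL: MaterialModel | None = None


def default_material_model() -> MaterialModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = MaterialModel()
    return _DEFAULT_MODEL


def mixture_hu(
    ha_density: float,
    fat_fraction: float,
    energy_kev: float,
    model: MaterialModel | None = None,
) -> float:
    """CT number of a hydroxyapatite / marrow mixture at one energy.

    The voxel is a volume mixture: a HA fraction ``ha_density / 3160``
    (solid-HA partial volume) plus a marrow remainder split between fat
    (``fat_fraction``) and water. By construction the result is affine in
    ``ha_density`` at fixed fat fraction, and pure water maps to exactly
    0 HU at every energy.

    Parameters
    ----------
    ha_density
        Hydroxyapatite partial density in mg/cm3 (>= 0).
    fat_fraction
        Fat volume fraction of the non-mineral compartment, in [0, 1].
    energy_kev
        Photon energy in keV, within [40, 200].
    model
        Material model; defaults to the embedded tabulation fit.
    """
    ha_density = float(ha_density)
    fat_fraction = float(fat_fraction)
    energy_kev = float(energy_kev)
    if ha_density < 0:
        raise ValueError(f"ha_density must be >= 0, got {ha_density}")
    if not 0.0 <= fat_fraction <= 1.0:
        raise ValueError(f"fat_fraction must be in [0, 1], got {fat_fraction}")
    if not 40.0 <= energy_kev <= 200.0:
        raise ValueError(f"energy_kev must be in [40, 200], got {energy_kev}")
    model = model or default_material_model()
    v_ha = ha_density / HA_SOLID_DENSITY_MG_CM3
    mu_marrow = fat_fraction * model.mu("fat", energy_kev) + (
        1.0 - fat_fraction
    ) * model.mu("water", energy_kev)
    mu_mix = v_ha * model.mu("ha", energy_kev) + (1.0 - v_ha) * mu_marrow
    mu_w = model.mu_water(energy_kev)
    return float(1000.0 * (mu_mix - mu_w) / mu_w)
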