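"""Per-subject phantom calibration of conventional-image HU to BMD.

For each subject the four insert VOI means on the conventional image give
(HU, known density) pairs; ordinary least squares of density on HU (density
is the error-free known) yields a per-subject affine HU -> mg HA/cm3 map.
Calibrated values are deliberately not clamped at zero so that calibration
failures remain visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QCTCalibration", "fit_qct_calibration", "hu_to_bmd"]


@dataclass(frozen=True)
class QCTCalibration:
    """Linear HU -> density model for one subject."""

    subject_id: str
    slope: float  # mg/cm3 per HU
    intercept: float  # mg/cm3
    r2: float
    residuals: dict  # insert density -> fitted-minus-known residual (mg/cm3)

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(
                f"calibration slope must be positive, got {self.slope:g} "
                f"(subject {self.subject_id!r})"
            )


def fit_qct_calibration(
    insert_means,
    subject_id: str = "",
    force_zero_intercept: bool = False,
) -> QCTCalibration:
    """OLS fit of insert density on insert mean HU.

    Parameters
    ----------
    insert_means
        Sequence of (mean_hu, density_mg_cm3) pairs, one per insert.
    force_zero_intercept
        Fit ``density = slope * hu`` through the origin instead of the
        default free-intercept model.
    """
    pairs = np.asarray(list(insert_means), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least two (hu, density) pairs")
    hu, dens = pairs[:, 0], pairs[:, 1]
    if np.allclose(hu, hu[0]):
        raise ValueError("degenerate fit: identical HU across inserts")
    if force_zero_intercept:
        slope = float(np.sum(hu * dens) / np.sum(hu**2))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(hu, dens, 1))
    fitted = slope * hu + intercept
    ss_res = float(np.sum((dens - fitted) ** 2))
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    residuals = {float(d): float(f - d) for d, f in zip(dens, fitted)}
    return QCTCalibration(
        subject_id=subject_id,
        slope=slope,
        intercept=intercept,
        r2=r2,
        residuals=residuals,
    )


def hu_to_bmd(hu, cal: QCTCalibration):
    """Affine HU -> mg HA/cm3; scalar or elementwise on arrays."""
    out = cal.slope * np.asarray(hu, dtype=float) + cal.intercept
    return float(out) if out.ndim == 0 else out
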