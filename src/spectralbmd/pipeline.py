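"""End-to-end orchestration: simulate -> decompose -> calibrate -> measure
-> compare, reproducibly from a single configuration.

The run streams subjects to keep memory flat: a first pass over the
calibration subsample collects the insert samples for the decomposition
model, a second pass regenerates each subject deterministically (same
per-subject seeds), builds its BMD map, fits its QCT calibration and
extracts every protocol VOI. Identical config and seed give identical CSV
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decomposition import (
    DecompositionModel,
    apply_decomposition,
    collect_insert_samples,
    fit_decomposition,
)
from .io import save_spectral_volume, write_table
from .phantom import default_phantom
from .qct import fit_qct_calibration, hu_to_bmd
from .sites import INSERT_LABELS, LABEL_PHANTOM_BODY, SiteRegistry, default_registry
from .stats import (
    PairedSample,
    deviation_analysis,
    icc_repeatability,
    pearson,
    site_comparison_table,
)
from .synthetic import NoiseSpec, iter_cohort
from .voi import cylindrical_insert_vois, measure_voi, protocol_vois

__all__ = ["RunConfig", "run_all", "measure_subject", "validate_inputs"]

log = logging.getLogger("spectralbmd")


@dataclass(frozen=True)
class RunConfig:
    """Flat, serializable configuration of a full analysis run."""

    seed: int = 0
    n_subjects: int = 49
    weight_min_kg: float = 2.2
    weight_max_kg: float = 54.7
    noise_preset: str = "default"
    calibration_scans: int = 10
    voi_pass: str = "both"  # "spherical" | "cylindrical" | "both"
    family_size: int = 19
    cylinder_target_voxels: int = 1800
    save_volumes: bool = False
    out_dir: str = "run_output"

    def __post_init__(self):
        if self.n_subjects < 1 or self.calibration_scans < 1:
            raise ValueError("sizes must be positive")
        if self.voi_pass not in ("spherical", "cylindrical", "both"):
            raise ValueError(f"unknown voi_pass {self.voi_pass!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec.preset(self.noise_preset)


def measure_subject(
    spec,
    vol,
    model: DecompositionModel,
    registry: SiteRegistry | None = None,
    voi_pass: str = "both",
    cylinder_target: int = 1800,
    phantom=None,
):
    """All protocol measurements for one subject.

    Returns ``(records, qct_rows, warnings)``: MeasurementRecord dicts
    (with extra ``voi_pass``, ``weight_kg``, ``true_density``,
    ``fat_fraction`` columns), per-pass QCT calibration rows, and any
    warnings raised (e.g. an unachievable cylindrical target).
    """
    registry = registry or default_registry()
    phantom = phantom or default_phantom()
    warnings_out = []
    records = []
    qct_rows = []
    conv = vol.channel("conventional")
    bmd_map = apply_decomposition(vol, model)

    shapes = protocol_vois(vol, registry)
    insert_sites = registry.inserts

    def qct_calibration_from(shape_by_site):
        pairs = []
        for site in insert_sites:
            mask_mean = measure_voi(
                vol, conv, shape_by_site[site.name], site.name, "qct"
            ).mean_value
            pairs.append((mask_mean, site.density_mg_cm3))
        return fit_qct_calibration(pairs, subject_id=spec.subject_id)

    def add_records(site, shape, cal, pass_name, repeats):
        dens, fat = spec.site_truth.get(
            site.name, (site.density_mg_cm3, site.fat_fraction)
        )
        for rep in repeats:
            rec_q = measure_voi(
                vol, conv, shape, site.name, "qct", repeat=rep,
                subject_id=spec.subject_id,
            )
            rec_q = {
                **rec_q.to_dict(),
                "bmd_mg_cm3": float(hu_to_bmd(rec_q.mean_value, cal)),
            }
            rec_s = measure_voi(
                bmd_map, bmd_map.values, shape, site.name, "sdct", repeat=rep,
                subject_id=spec.subject_id,
            ).to_dict()
            for rec in (rec_q, rec_s):
                rec.update(
                    voi_pass=pass_name,
                    weight_kg=spec.weight_kg,
                    true_density=dens,
                    fat_fraction=fat,
                )
                records.append(rec)

    if voi_pass in ("spherical", "both"):
        cal_sph = qct_calibration_from(shapes)
        qct_rows.append(_qct_row(cal_sph, "spherical"))
        for site in registry.trabecular:
            add_records(site, shapes[site.name], cal_sph, "spherical", (1, 2))
        for site in registry.cortical:
            add_records(site, shapes[site.name], cal_sph, "spherical", (1,))
        for site in insert_sites:
            add_records(site, shapes[site.name], cal_sph, "spherical", (1, 2))

    if voi_pass in ("cylindrical", "both"):
        try:
            cyl_shapes = cylindrical_insert_vois(
                vol, phantom, target_voxel_count=cylinder_target
            )
        except ValueError as exc:
            warnings_out.append(f"{spec.subject_id}: {exc}")
        else:
            by_site = {
                f"insert_{int(d)}": shp for d, shp in cyl_shapes.items()
            }
            cal_cyl = qct_calibration_from(by_site)
            qct_rows.append(_qct_row(cal_cyl, "cylindrical"))
            for site in insert_sites:
                add_records(site, by_site[site.name], cal_cyl, "cylindrical", (1,))
    return records, qct_rows, warnings_out


def _qct_row(cal, pass_name):
    row = {
        "subject_id": cal.subject_id,
        "voi_pass": pass_name,
        "slope": cal.slope,
        "intercept": cal.intercept,
        "r2": cal.r2,
    }
    for dens, res in sorted(cal.residuals.items()):
        row[f"residual_{int(dens)}"] = res
    return row


def validate_inputs(specs_and_volumes, registry: SiteRegistry | None = None) -> pd.DataFrame:
    """Technical inclusion screening of a set of scans.

    A scan is excluded when the phantom is not fully displayed (phantom
    body or any insert label touches the grid boundary, or is absent) or
    when a required measurement-site label is missing from the field of
    view. Report-only: returns one row per scan with the reason.
    """
    registry = registry or default_registry()
    rows = []
    phantom_labels = [LABEL_PHANTOM_BODY, *INSERT_LABELS.values()]
    for item in specs_and_volumes:
        spec, vol = item if isinstance(item, tuple) else (None, item)
        subject_id = vol.subject_id
        reason = ""
        for lab in phantom_labels:
            mask = vol.labels == lab
            if not mask.any():
                reason = "phantom not fully displayed"
                break
            idx = np.argwhere(mask)
            if (idx.min(axis=0) == 0).any() or (
                idx.max(axis=0) == np.array(vol.shape) - 1
            ).any():
                reason = "phantom not fully displayed"
                break
        if not reason and spec is not None:
            for site in registry.trabecular + registry.cortical:
                if not (vol.labels == site.label).any():
                    reason = f"FOV did not include site {site.name}"
                    break
        rows.append(
            {"subject_id": subject_id, "included": reason == "", "reason": reason}
        )
    return pd.DataFrame(rows)


def _correlation_row(analysis, method, x, y, extra=None):
    try:
        r, p = pearson(x, y)
        ok = True
    except ValueError:
        r, p, ok = float("nan"), float("nan"), False
    row = {
        "analysis": analysis,
        "method": method,
        "r": r,
        "p": p,
        "n": len(x),
        "computable": ok,
    }
    row.update(extra or {})
    return row


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes truth.csv, decomposition_model.json, qct_calibration.csv,
    measurements.csv, site_comparison.csv, phantom_deviation.csv,
    correlations.csv, repeatability.csv and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash, "seed": config.seed}
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash,
        "stages": [],
        "warnings": [],
    }
    registry = default_registry()
    phantom = default_phantom()
    noise = config.noise
    weight_range = (config.weight_min_kg, config.weight_max_kg)

    def cohort():
        return iter_cohort(
            config.n_subjects, weight_range, config.seed, noise, phantom, registry
        )

    # stage 1: decomposition calibration on the first scans
    log.info("stage calibrate-decomposition: %d scans", config.calibration_scans)
    n_cal = min(config.calibration_scans, config.n_subjects)
    cal_volumes = []
    for i, (_, vol) in enumerate(cohort()):
        cal_volumes.append(vol)
        if i + 1 >= n_cal:
            break
    samples = collect_insert_samples(cal_volumes, phantom, n_calibration=n_cal)
    model = fit_decomposition(samples)
    del cal_volumes
    model.save(out / "decomposition_model.json")
    manifest["stages"].append({"stage": "fit-decomposition", "n_scans": n_cal})

    # stage 2: per-subject measurement
    log.info("stage measure: %d subjects", config.n_subjects)
    all_records, all_qct, truth_rows = [], [], []
    validation_items = []
    for spec, vol in cohort():
        log.info("  subject %s (%.1f kg)", spec.subject_id, spec.weight_kg)
        recs, qct_rows, warns = measure_subject(
            spec,
            vol,
            model,
            registry,
            voi_pass=config.voi_pass,
            cylinder_target=config.cylinder_target_voxels,
            phantom=phantom,
        )
        all_records.extend(recs)
        all_qct.extend(qct_rows)
        manifest["warnings"].extend(warns)
        validation_items.append((spec, _GeometryOnly(vol)))
        spacing_str = "x".join(f"{s:.4f}" for s in vol.spacing_mm)
        for name, (dens, fat) in sorted(spec.site_truth.items()):
            truth_rows.append(
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
        if config.save_volumes:
            save_spectral_volume(vol, out / "volumes", spec.subject_id)
    measurements = pd.DataFrame(all_records)
    write_table(measurements, out / "measurements.csv", meta)
    write_table(pd.DataFrame(truth_rows), out / "truth.csv", meta)
    write_table(pd.DataFrame(all_qct), out / "qct_calibration.csv", meta)
    manifest["stages"].append(
        {"stage": "measure", "n_records": len(measurements)}
    )

    # stage 3: inclusion screening (label-based, geometry retained only)
    inclusion = validate_inputs(validation_items, registry)
    write_table(inclusion, out / "inclusion.csv", meta)

    # stage 4: statistics
    log.info("stage compare")
    stats_outputs = compare_measurements(
        measurements, registry, family_size=config.family_size
    )
    for name, df in stats_outputs.items():
        write_table(df, out / f"{name}.csv", meta)
    manifest["stages"].append({"stage": "compare", "tables": sorted(stats_outputs)})

    (out / "config.yaml").write_text(config.to_yaml())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


class _GeometryOnly:
    """Labels + geometry of a volume, without the channel data."""

    def __init__(self, vol):
        self.labels = vol.labels
        self.shape = vol.shape
        self.spacing_mm = vol.spacing_mm
        self.origin_mm = vol.origin_mm
        self.subject_id = vol.subject_id


def compare_measurements(
    measurements: pd.DataFrame,
    registry: SiteRegistry | None = None,
    family_size: int = 19,
) -> dict:
    """Statistical layer over a measurement table.

    Returns DataFrames: ``site_comparison`` (median/IQR/Wilcoxon per
    anatomical site, QCT vs spectral map), ``repeatability`` (test-retest
    ICC per method), ``phantom_deviation`` (per insert x method deviation
    summaries) and ``correlations`` (accuracy vs voxel count / weight,
    voxel count vs weight, deviation vs weight).
    """
    registry = registry or default_registry()
    df = measurements
    sph = df[df["voi_pass"] == "spherical"]

    # paired site-wise comparison, repeat 1, spherical pass
    paired = []
    for site in registry.comparison_sites:
        sub = sph[(sph["site"] == site.name) & (sph["repeat"] == 1)]
        piv = sub.pivot_table(
            index="subject_id", columns="method", values="bmd_mg_cm3"
        ).dropna()
        if len(piv) >= 2:
            paired.append(
                PairedSample(
                    site=site.name,
                    values_a=tuple(piv["qct"]),
                    values_b=tuple(piv["sdct"]),
                )
            )
    comparison = site_comparison_table(paired, m=family_size)

    # test-retest ICC per method over all twice-measured VOIs
    icc_rows = []
    repeated = sph[sph["site"].isin([s.name for s in registry.trabecular + registry.inserts])]
    for method, grp in repeated.groupby("method"):
        piv = grp.pivot_table(
            index=["subject_id", "site"], columns="repeat", values="bmd_mg_cm3"
        ).dropna()
        icc = icc_repeatability(piv[1].to_numpy(), piv[2].to_numpy())
        icc_rows.append({"method": method, "icc": icc, "n_pairs": len(piv)})
    repeatability = pd.DataFrame(icc_rows)

    # phantom deviations (repeat 1) per pass
    insert_names = {f"insert_{int(d)}": d for d in INSERT_LABELS}
    dev = df[(df["site"].isin(insert_names)) & (df["repeat"] == 1)].copy()
    dev["insert_density"] = dev["site"].map(insert_names)
    dev["deviation"] = dev["bmd_mg_cm3"] - dev["insert_density"]
    dev["abs_deviation"] = dev["deviation"].abs()

    deviation_frames, corr_rows = [], []
    for pass_name, grp in dev.groupby("voi_pass"):
        res = deviation_analysis(
            grp[
                [
                    "subject_id",
                    "insert_density",
                    "method",
                    "deviation",
                    "voxel_count",
                    "weight_kg",
                ]
            ]
        )
        summary = res["summary"].copy()
        summary.insert(0, "voi_pass", pass_name)
        deviation_frames.append(summary)
        cors = res["correlations"].copy()
        cors.insert(0, "voi_pass", pass_name)
        corr_rows.append(cors)
        # pooled accuracy vs voxel count per method (all inserts together)
        for method, g in grp.groupby("method"):
            corr_rows.append(
                pd.DataFrame(
                    [
                        _correlation_row(
                            "abs_deviation_vs_voxel_count_pooled",
                            method,
                            g["voxel_count"],
                            g["abs_deviation"],
                            {"voi_pass": pass_name},
                        )
                    ]
                )
            )
    deviation_table = pd.concat(deviation_frames, ignore_index=True)

    # voxel count vs body weight; mean deviation vs weight per method
    sph_dev = dev[dev["voi_pass"] == "spherical"]
    extra = [
        _correlation_row(
            "voxel_count_vs_weight",
            "all",
            sph_dev["weight_kg"],
            sph_dev["voxel_count"],
            {"voi_pass": "spherical"},
        )
    ]
    for method, g in sph_dev.groupby("method"):
        per_subj = g.groupby("subject_id").agg(
            weight_kg=("weight_kg", "first"), deviation=("deviation", "mean")
        )
        extra.append(
            _correlation_row(
                "mean_deviation_vs_weight",
                method,
                per_subj["weight_kg"],
                per_subj["deviation"],
                {"voi_pass": "spherical"},
            )
        )
    corr_rows.append(pd.DataFrame(extra))
    correlations = pd.concat(corr_rows, ignore_index=True)

    return {
        "site_comparison": comparison,
        "repeatability": repeatability,
        "phantom_deviation": deviation_table,
        "correlations": correlations,
    }
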