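# spectralbmd

Tools for studying how two CT-based bone mineral density (BMD) estimates
compare: classic phantom-calibrated quantitative CT (QCT) and voxel-wise
BMD maps derived from dual-layer spectral CT by a two-energy material
decomposition. Because clinical spectral scans of this kind are rarely
shared, the package ships a seeded synthetic data generator — a
hydroxyapatite (HA) calibration phantom plus simplified canine anatomy,
rendered as co-registered conventional / 50 keV / 200 keV volumes — so the
entire analysis chain is reproducible end to end. It is aimed at
researchers in quantitative imaging who want a tested, scriptable
reference implementation of both BMD pathways and of the statistical
comparison between them.

## The two methods

**QCT.** A cylindrical phantom with four HA inserts (100, 200, 400,
800 mg/cm³) is scanned with each subject. For subject *s*, ordinary least
squares of the known densities ρᵢ on the measured insert HU means gives a
per-subject affine map

&nbsp;&nbsp;&nbsp;&nbsp;ρ̂ = a·HU + b,

applied to every volume of interest (VOI) on the conventional image.

**Spectral BMD map.** Virtual monoenergetic images at 50 and 200 keV
separate the photoelectric- and Compton-dominated parts of attenuation.
The insert means of a calibration sample of scans (default ten) are
plotted in (HU₅₀, HU₂₀₀) space and a regression line is fitted through
them by total least squares. Each voxel is projected orthogonally onto
this line; the projected coordinate *t* maps affinely to bone volume
fraction and density,

&nbsp;&nbsp;&nbsp;&nbsp;ρ̂(t) = c·(t − t_water),&nbsp;&nbsp;ρ̂ ← max(ρ̂, 0),

anchored so the water point (0, 0) maps to exactly 0 mg/cm³ and scaled by
a least-squares fit against the four known insert densities.

Both methods are measured with an identical VOI protocol — spherical and
length-adjusted cylindrical insert VOIs, 18 trabecular sites, one planar
cortical region — and compared with a paired Wilcoxon signed-rank test
(Bonferroni-corrected across the 19 anatomical sites), Pearson
correlations of measurement error against voxel count and body weight,
Jarque–Bera normality screening and a test–retest intraclass correlation
coefficient, ICC(1,1).

## Worked example

Noiseless phantom scan, both pathways calibrated and evaluated on it:

```python
import spectralbmd as sb
from spectralbmd.qct import fit_qct_calibration, hu_to_bmd
from spectralbmd.voi import insert_vois, measure_voi

vol = sb.rasterize_phantom(spacing_mm=0.5, noise=sb.NoiseSpec.none(), seed=1)
registry = sb.default_registry()
shapes = insert_vois(vol, registry)
conv = vol.channel("conventional")
pairs = [(measure_voi(vol, conv, shapes[s.name], s.name, "qct").mean_value,
          s.density_mg_cm3) for s in registry.inserts]
cal = fit_qct_calibration(pairs, subject_id="phantom")
print(f"QCT calibration: slope={cal.slope:.4f} mg/cm3 per HU, "
      f"intercept={cal.intercept:.2e}, R2={cal.r2:.6f}")

model = sb.fit_decomposition(sb.collect_insert_samples([vol], n_calibration=1))
bmd = sb.apply_decomposition(vol, model)
for s in registry.inserts:
    q = hu_to_bmd(measure_voi(vol, conv, shapes[s.name], s.name, "qct").mean_value, cal)
    m = measure_voi(bmd, bmd.values, shapes[s.name], s.name, "sdct").bmd_mg_cm3
    print(f"{s.name}: QCT {q:8.3f}  map {m:8.3f}  (nominal {s.density_mg_cm3:g})")
```

prints

```
QCT calibration: slope=0.8471 mg/cm3 per HU, intercept=-1.31e-13, R2=1.000000
insert_100: QCT  100.000  map  100.000  (nominal 100)
insert_200: QCT  200.000  map  200.000  (nominal 200)
insert_400: QCT  400.000  map  400.000  (nominal 400)
insert_800: QCT  800.000  map  800.000  (nominal 800)
```

i.e. without noise both calibrations recover the insert densities exactly
(the slope is the per-subject HU→density factor; the intercept and the
residuals are zero because the synthetic mixture model is affine in HA
density). With the default noise model and a weight-dependent voxel
spacing, a full cohort run reproduces the characteristic error structure:
QCT accuracy improves with the number of voxels averaged, and the
voxel-count-controlled cylindrical pass attenuates that dependence.

A full pipeline run (cohort → decomposition → calibration → measurement →
statistics) from one config:

```sh
spectralbmd run-all --n 10 --seed 7 --out my_run
```

writes `measurements.csv`, `site_comparison.csv` (median/IQR and adjusted
p per anatomical site), `phantom_deviation.csv`, `correlations.csv`,
`repeatability.csv`, the fitted decomposition model and a manifest. The
other CLI verbs (`simulate-cohort`, `fit-decomposition`,
`apply-decomposition`, `calibrate-qct`, `measure`, `compare`, `validate`)
expose the individual stages over NIfTI volumes and CSV tables.

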