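# Methods

## Attenuation model

All three image channels come from one physical model. A material's
linear attenuation is a two-basis expansion

    mu(E) = a_p (E/100 keV)^-3 + a_c f_KN(E),

with the photoelectric term falling as E^-3 and `f_KN` the total
Klein–Nishina cross-section shape (normalised to 1 at 100 keV). The
amplitudes (a_p, a_c) for water, adipose tissue, soft tissue and
hydroxyapatite are fitted once, by unweighted least squares over
40–200 keV, to tabulated photon mass-attenuation values embedded in
`materials.py`, so the package carries no runtime data dependency. The
fit reproduces the tables to ≲0.4% for the soft materials and ≲4% for
hydroxyapatite (whose strong photoelectric component is hardest for a
two-term model); the properties the analysis relies on — water at exactly
0 HU at every energy, fat negative, HA HU strictly decreasing from 50 to
200 keV, HU affine in HA partial density — hold exactly by construction
and are property-tested.

A voxel is a volume mixture: HA fraction d/3160 (d in mg/cm³, 3160 mg/cm³
the solid-HA density) plus a marrow remainder split between fat and water
by the site's fat volume fraction. The conventional 120 kVp image is
modelled as a monoenergetic image at an effective energy of 64 keV —
the standard effective-energy approximation — so one attenuation model
serves all channels. No polychromatic spectrum, beam hardening, scatter
or projection-domain physics is simulated.

## Synthetic scans

The phantom is a 6.5 cm water-equivalent cylinder holding four parallel
HA inserts (100/200/400/800 mg/cm³). Insert radius 7.5 mm and length
60 mm are the package's own sizing: with a fixed 6.5 mm cylindrical-VOI
radius, a full-length cylinder at the coarsest cohort spacing then
contains ≈1,800 voxels, so the length-adjusted VOI pass has a common
achievable target across the whole spacing range.

Subjects are deliberately simplified geometry, not anatomy: a soft-tissue
body cylinder whose radius grows with body weight, 18 spherical
trabecular sites on three axial rings, one cortical-bone cylinder, and
the phantom beside the body in the same field of view. Each trabecular
site carries a ground-truth HA density and marrow fat fraction; defaults
are typical canine trabecular values with a marrow-fat gradient (≈0.15 in
vertebral bodies up to 0.7 in long-bone diaphyses, reflecting the high
fat content of diaphyseal yellow marrow). Per-subject values are sampled
around the defaults (lognormal density multiplier, sigma 0.12; clipped
Gaussian fat jitter, sd 0.05). Cohort weights are log-uniform over
2.2–54.7 kg, giving the right-skewed weight distribution of a clinical
sample.

Voxel spacing is weight-dependent: in-plane 0.4→1.2 mm and slice
thickness 1→3 mm, linear between 2 and 55 kg (slice thickness clamped to
the clinically used 1–3 mm band). This single rule produces the two
voxel-count mechanisms the statistics layer studies: heavier subjects
have fewer voxels per fixed-size VOI, and VOI means average away less
noise.

Noise is additive white Gaussian in HU, independent per channel, default
SD 15 (conventional), 25 (50 keV) and 10 HU (200 keV) — the low-energy
channel is noisiest, as in dual-layer reconstructions. A Gaussian PSF
blur (default FWHM 0.7 mm) is applied to the ideal image before noise and
produces partial-volume mixing at boundaries. All randomness flows from
one master seed through deterministic per-subject, per-channel child
seeds; zero noise gives bit-reproducible volumes.

What the generator does **not** emulate: real trabecular microstructure
and its partial-volume statistics, beam-hardening and position-dependent
CT-number errors, patient motion, scanner reconstruction kernels, or
anatomically realistic site shapes. Passing tests therefore demonstrate
the correctness and internal consistency of the analysis chain and the
direction of the studied mechanisms (noise averaging, fat bias), not
clinical accuracy on real scans.

## Decomposition details

The calibration line is fitted by total least squares (principal axis of
the 2×2 scatter of the per-insert mean points) because both coordinates
are equally noisy measurements; an ordinary-regression variant (HU200 on
HU50) is available via `fit_method="ols"` for sensitivity analysis.
Projection is orthogonal (Euclidean) in raw HU units. The projected
coordinate maps to density through a single free slope fitted over all
four inserts, constrained so the projected water point maps to exactly
0 mg/cm³; bone volume fraction is that density divided by the 800 mg/cm³
reference insert. Negative mapped densities are clamped to 0 in the map
(sub-water voxels such as fat); the per-subject QCT calibration is *not*
clamped, so calibration failures stay visible.

The direction of the fat-induced bias of the spectral map is an empirical
outcome, not an assertion: fat moves a voxel off the calibration line and
the signed change equals the closed-form projection prediction, which the
tests check without fixing a sign. For QCT the sign is forced — fat's
negative HU contribution at 64 keV makes calibrated BMD strictly
decreasing in fat fraction — and is asserted.

## VOI protocol

"Largest possible" trabecular VOIs are operationalized as the largest
sphere inscribed in the site's ground-truth label eroded by one voxel
(anisotropy-aware distance transform), which avoids neighbouring tissue
without manual interaction. The cortical region of interest is a single
transverse-plane disc inside the cortical label. Insert VOIs exist in two
variants: a centrally inscribed sphere, and a fixed-radius (6.5 mm)
cylinder whose whole-slice length is chosen per scan to bring the voxel
count as close as possible to a common target (default 1,800), mirroring
a second, voxel-count-controlled measurement pass; the choice errs if the
achievable count misses the target by more than 50%. Voxel membership is
by voxel center throughout, making repeated extraction at an identical
placement exactly deterministic — the mechanism behind the test–retest
ICC of exactly 1.0.

## Statistics

The paired Wilcoxon signed-rank test drops zero differences (Wilcoxon's
original rule) and uses the exact permutation null for up to 25 nonzero
differences — the distribution of the positive-rank sum over all 2^n
equally likely sign assignments, computed by convolution over (doubled)
midranks, which is identical to literal enumeration — and a normal
approximation with tie and continuity corrections above. Two-sided
p-values are twice the smaller tail, capped at 1. Bonferroni adjustment
uses the family of the 19 anatomical comparison sites by default.
Jarque–Bera uses the moment-based statistic n/6·(S² + (K−3)²/4) against
χ²(2). The repeatability coefficient is ICC(1,1) (one-way random,
single-measure) from the two-repeat ANOVA decomposition. The relative
method difference uses the symmetric pairwise-mean denominator,
(a−b)/mean(a,b), undefined (reported missing) when the mean is zero.
Deviation-vs-voxel-count and deviation-vs-weight relations are Pearson
correlations of |measured − nominal| per insert and method; when a
noiseless cohort makes the deviations numerically zero (spread below
1e-9 mg/cm³, pure floating-point residue), the correlation is reported
as not computable rather than as a spurious value.

## Pipeline and problem sizes

`run_all` streams subjects in two deterministic passes (decomposition
calibration on the first ten scans, then measurement), so memory stays
flat for large cohorts; identical config and seed give byte-identical
CSVs. The configuration hash embedded in every output covers the
scientific parameters only (not the output path). Default cohort size is
49 subjects with both VOI passes, which completes in about a minute on a
single core; the test suite uses 3–10 subjects for orchestration checks
and the full 49-subject default for the mechanism checks. The acceptance
script uses the 0.5 mm noiseless reference phantom (≈10,000 voxels per
insert VOI) and a ten-subject noisy cohort (220 duplicate VOI pairs per
method).

## Known limitations

- The two-basis fit underrepresents hydroxyapatite's photoelectric
  structure by a few percent; this affects only the realism of absolute
  HU values, not the calibration-based recoveries (both methods calibrate
  on the same rendered values).
- Anatomical sites are homogeneous spheres; partial-volume effects at
  trabecular interfaces are represented only through the Gaussian PSF.
- The inclusion screening translates only the technical exclusion rules
  (phantom fully displayed, required sites in the field of view);
  clinical exclusions have no synthetic counterpart.
- Tukey post hoc comparisons and three-material (fat-corrected)
  decomposition are out of scope.
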