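"""Volume generator: construction fidelity, determinism, blur, cohort."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

import spectralbmd as sb
from spectralbmd.materials import mixture_hu
from spectralbmd.sites import INSERT_LABELS, LABEL_AIR
from spectralbmd.synthetic import _FWHM_TO_SIGMA, CHANNEL_ENERGIES


def test_noiseless_insert_means_match_mixture_hu(noiseless_phantom):
    vol = noiseless_phantom
    for density, label in INSERT_LABELS.items():
        mask = vol.labels == label
        for channel, energy in CHANNEL_ENERGIES.items():
            got = vol.channel(channel)[mask].mean()
            assert got == pytest.approx(mixture_hu(density, 0.0, energy), abs=1e-9)


def test_phantom_body_is_water_and_outside_is_air(noiseless_phantom):
    vol = noiseless_phantom
    assert np.all(vol.channel("mono_low")[vol.labels == 2] == 0.0)
    assert np.all(vol.channel("mono_low")[vol.labels == LABEL_AIR] == -1000.0)


def test_same_seed_bit_identical():
    kw = dict(spacing_mm=(1.0, 1.0, 1.5), noise=sb.NoiseSpec(), seed=9)
    a = sb.rasterize_phantom(**kw)
    b = sb.rasterize_phantom(**kw)
    for ch in a.channels:
        np.testing.assert_array_equal(a.channel(ch), b.channel(ch))
    np.testing.assert_array_equal(a.labels, b.labels)


def test_different_seed_changes_noise():
    kw = dict(spacing_mm=(1.0, 1.0, 1.5), noise=sb.NoiseSpec())
    a = sb.rasterize_phantom(seed=1, **kw)
    b = sb.rasterize_phantom(seed=2, **kw)
    assert not np.array_equal(a.channel("mono_low"), b.channel("mono_low"))


def test_blur_matches_direct_convolution_oracle():
    """Gaussian PSF blur equals explicit kernel convolution away from the
    grid boundary, leaves deep-interior means unchanged, and creates
    intermediate values at insert boundaries."""
    spacing = (1.0, 1.0, 1.0)
    sharp = sb.rasterize_phantom(spacing_mm=spacing, noise=sb.NoiseSpec.none(), seed=0)
    fwhm = 2.0
    blurred = sb.rasterize_phantom(
        spacing_mm=spacing,
        noise=sb.NoiseSpec(0.0, 0.0, 0.0, blur_fwhm_mm=fwhm),
        seed=0,
    )
    # oracle: separable truncated-Gaussian kernel convolution
    sigma = fwhm * _FWHM_TO_SIGMA
    half = 6
    x = np.arange(-half, half + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    oracle = fftconvolve(sharp.channel("mono_low"), kernel, mode="same")
    core = (slice(half, -half),) * 3
    # sub-0.05 HU agreement; the implementation truncates the kernel tails
    np.testing.assert_allclose(
        blurred.channel("mono_low")[core], oracle[core], atol=0.05
    )
    # interior of the largest insert unchanged, boundary intermediate
    from scipy.ndimage import binary_erosion

    mask800 = sharp.labels == INSERT_LABELS[800.0]
    interior = binary_erosion(mask800, iterations=4)
    hu800 = mixture_hu(800.0, 0.0, 50.0)
    assert blurred.channel("mono_low")[interior].mean() == pytest.approx(hu800, rel=1e-6)
    shell = mask800 & ~binary_erosion(mask800)
    shell_vals = blurred.channel("mono_low")[shell]
    assert np.all(shell_vals < hu800 - 1.0)
    assert np.all(shell_vals > 0.0)


def test_blur_conserves_total_hu():
    """Partial-volume blur redistributes but does not create signal."""
    spacing = (1.0, 1.0, 1.0)
    sharp = sb.rasterize_phantom(
        spacing_mm=spacing, noise=sb.NoiseSpec.none(), seed=0, padding_mm=8.0
    )
    blurred = sb.rasterize_phantom(
        spacing_mm=spacing,
        noise=sb.NoiseSpec(0.0, 0.0, 0.0, blur_fwhm_mm=1.5),
        seed=0,
        padding_mm=8.0,
    )
    # measure relative to the uniform air background
    a = sharp.channel("mono_low") + 1000.0
    b = blurred.channel("mono_low") + 1000.0
    assert b.sum() == pytest.approx(a.sum(), rel=1e-6)


def test_spacing_rule_monotone_and_clamped():
    weights = np.linspace(2.0, 60.0, 30)
    spacings = np.array([sb.spacing_for_weight(w) for w in weights])
    assert np.all(np.diff(spacings[:, 0]) >= 0)
    assert np.all(np.diff(spacings[:, 2]) >= 0)
    assert spacings[:, 2].min() >= 1.0 and spacings[:, 2].max() <= 3.0
    with pytest.raises(ValueError):
        sb.spacing_for_weight(0.0)


def test_subject_sites_match_ground_truth(noiseless_subject, registry):
    spec, vol = noiseless_subject
    for site in registry.trabecular:
        dens, fat = spec.site_truth[site.name]
        mask = vol.labels == site.label
        got = vol.channel("mono_low")[mask].mean()
        assert got == pytest.approx(mixture_hu(dens, fat, 50.0), abs=1e-9)


def test_heavier_subject_fewer_voxels_per_fixed_radius_voi(registry):
    """Coarser spacing in heavy subjects -> fewer voxels in the same
    physical VOI (the voxel-count/weight mechanism)."""
    shape = sb.VOIShape(kind="sphere", center_mm=(0.0, 0.0, 0.0), radius_mm=6.0)
    counts = {}
    for w in (2.2, 54.7):
        spec = sb.SubjectSpec(f"w{w}", w, {s.name: (s.density_mg_cm3, s.fat_fraction)
                                           for s in registry.trabecular + registry.cortical})
        vol = sb.rasterize_subject(spec, noise=sb.NoiseSpec.none(), seed=0)
        counts[w] = int(sb.voxel_mask(vol, shape).sum())
    assert counts[54.7] < counts[2.2]


def test_phantom_offset_does_not_change_insert_means(registry):
    """Spatially homogeneous noiseless model: phantom position is
    irrelevant to insert interior values."""
    truth = {s.name: (s.density_mg_cm3, s.fat_fraction)
             for s in registry.trabecular + registry.cortical}
    means = []
    for dy in (0.0, 6.0):
        spec = sb.SubjectSpec("s", 20.0, truth,
                              phantom_offset_mm=(18.0 + 1.1 * 20.0 + 40.5, dy, 3.0))
        vol = sb.rasterize_subject(spec, noise=sb.NoiseSpec.none(), seed=0)
        means.append([
            vol.channel("conventional")[vol.labels == lab].mean()
            for lab in INSERT_LABELS.values()
        ])
    np.testing.assert_allclose(means[0], means[1], atol=1e-9)


def test_phantom_overlapping_anatomy_rejected(registry):
    truth = {s.name: (s.density_mg_cm3, s.fat_fraction)
             for s in registry.trabecular + registry.cortical}
    spec = sb.SubjectSpec("s", 20.0, truth, phantom_offset_mm=(0.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="overlaps"):
        sb.rasterize_subject(spec, noise=sb.NoiseSpec.none(), seed=0)


def test_coarse_spacing_warns_when_inserts_may_vanish():
    with pytest.warns(UserWarning, match="spacing exceeds"):
        sb.rasterize_phantom(spacing_mm=8.0, noise=sb.NoiseSpec.none(), seed=0)


def test_cohort_shapes_and_determinism():
    vols, table = sb.simulate_cohort(3, seed=123, noise=sb.NoiseSpec.none())
    assert len(vols) == 3
    # one row per subject x site (18 trabecular + 1 cortical)
    assert len(table) == 3 * 19
    assert table["subject_id"].nunique() == 3
    vols2, table2 = sb.simulate_cohort(3, seed=123, noise=sb.NoiseSpec.none())
    for a, b in zip(vols, vols2):
        np.testing.assert_array_equal(a.channel("mono_low"), b.channel("mono_low"))
    assert table.equals(table2)
    with pytest.raises(ValueError):
        sb.simulate_cohort(0, seed=1)


def test_single_subject_cohort():
    vols, table = sb.simulate_cohort(1, seed=5, noise=sb.NoiseSpec.none())
    assert len(vols) == 1 and table["subject_id"].nunique() == 1
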