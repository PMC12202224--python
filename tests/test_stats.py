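"""Statistics layer: exact oracles, references, table construction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from spectralbmd.stats import (
    PairedSample,
    bonferroni,
    deviation_analysis,
    icc_repeatability,
    jarque_bera,
    pearson,
    relative_difference,
    site_comparison_table,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(diffs):
    """Literal enumeration over all 2^n equally likely sign patterns."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(ranks)
    ws = np.array(
        [np.sum(ranks[list(signs)]) for signs in itertools.product([False, True], repeat=n)]
    )
    tol = 1e-9
    p_le = np.mean(ws <= w_obs + tol)
    p_ge = np.mean(ws >= w_obs - tol)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------- Jarque-Bera

def test_jarque_bera_hand_computed_value():
    # S = 0, K = 1 -> JB = 4/6 * (0 + 4/4) = 2/3
    jb, p = jarque_bera([-1.0, -1.0, 1.0, 1.0])
    assert jb == pytest.approx(2.0 / 3.0, rel=1e-12)
    assert p == pytest.approx(float(sps.chi2.sf(2.0 / 3.0, 2)), rel=1e-12)


def test_jarque_bera_matches_scipy_reference():
    rng = np.random.default_rng(1)
    for x in (rng.normal(size=300), rng.exponential(size=120)):
        jb, p = jarque_bera(x)
        ref = sps.jarque_bera(x)
        assert jb == pytest.approx(float(ref.statistic), rel=1e-10)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-10)


def test_jarque_bera_separates_normal_from_heavy_tails():
    rng = np.random.default_rng(7)
    n = 400
    jb_normal = np.median([jarque_bera(rng.normal(size=n))[0] for _ in range(20)])
    jb_heavy = np.median([jarque_bera(rng.standard_t(2, size=n))[0] for _ in range(20)])
    assert jb_heavy > jb_normal


def test_jarque_bera_invalid_inputs():
    with pytest.raises(ValueError):
        jarque_bera([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        jarque_bera([2.0, 2.0, 2.0, 2.0])


# ------------------------------------------------------------------- Wilcoxon

def test_wilcoxon_all_positive_three():
    # all-positive {1,2,3}: W+ = 6, exact two-sided p = 2/8
    w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0])
    assert w == 6.0
    assert p == pytest.approx(0.25, rel=1e-12)


def test_wilcoxon_antisymmetric_center_of_null():
    _, p = wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0])
    assert p == pytest.approx(1.0)
    _, p_oracle = wilcoxon_enumeration_oracle([-2.0, -1.0, 1.0, 2.0])
    assert p == pytest.approx(p_oracle, rel=1e-12)


@pytest.mark.parametrize("trial", range(20))
def test_wilcoxon_matches_enumeration_oracle(trial):
    """Exact equality with brute-force sign enumeration, ties included."""
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(4, 13))
    diffs = rng.normal(0.2, 1.0, size=n)
    if trial % 3 == 0:  # force ties in |d|
        diffs = np.round(diffs, 0)
        diffs = diffs[diffs != 0]
        if len(diffs) == 0:
            diffs = np.array([1.0, 1.0, -1.0])
    w, p = wilcoxon_signed_rank(diffs)
    w_o, p_o = wilcoxon_enumeration_oracle(diffs)
    assert w == pytest.approx(w_o)
    assert p == pytest.approx(p_o, rel=1e-12)


def test_wilcoxon_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(5)
    d = rng.normal(0.3, 1.0, size=14)
    _, p = wilcoxon_signed_rank(d)
    assert p == pytest.approx(float(sps.wilcoxon(d, method="exact").pvalue), rel=1e-12)


def test_wilcoxon_normal_approximation_matches_scipy():
    rng = np.random.default_rng(6)
    d = rng.normal(0.2, 1.0, size=40)
    _, p = wilcoxon_signed_rank(d)
    ref = sps.wilcoxon(d, method="approx", correction=True)
    assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_wilcoxon_zero_differences_dropped_and_all_zero_errors():
    w1, p1 = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 0.0])
    w2, p2 = wilcoxon_signed_rank([1.0, 2.0, 3.0])
    assert (w1, p1) == (w2, p2)
    with pytest.raises(ValueError, match="zero"):
        wilcoxon_signed_rank([0.0, 0.0])


def test_wilcoxon_paired_forms_agree():
    a = np.array([3.0, 5.0, 2.0, 8.0])
    b = np.array([1.0, 6.0, 1.0, 4.0])
    assert wilcoxon_signed_rank(a, b) == wilcoxon_signed_rank(a - b)
    ps = PairedSample("x", tuple(a), tuple(b))
    assert wilcoxon_signed_rank(ps) == wilcoxon_signed_rank(a - b)


# ----------------------------------------------------------------- Bonferroni

def test_bonferroni_values():
    assert bonferroni(0.01, 19) == pytest.approx(0.19)
    assert bonferroni(0.2, 19) == 1.0
    assert bonferroni(0.3, 1) == 0.3


@given(p=st.floats(0.0, 1.0), m=st.integers(1, 100))
def test_bonferroni_never_decreases_and_bounded(p, m):
    adj = bonferroni(p, m)
    assert p <= adj <= 1.0


# -------------------------------------------------------------------- Pearson

def test_pearson_perfect_and_formula_oracle():
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson(x, -x)[0] == pytest.approx(-1.0)
    rng = np.random.default_rng(3)
    y = rng.normal(size=10)
    r, _ = pearson(x, y)
    r_oracle = np.mean((x - x.mean()) * (y - y.mean())) / (np.std(x) * np.std(y))
    assert r == pytest.approx(r_oracle, abs=1e-12)


def test_pearson_affine_invariance_and_errors():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=20), rng.normal(size=20)
    r0, _ = pearson(x, y)
    r1, _ = pearson(3.0 * x + 7.0, y)
    assert r1 == pytest.approx(r0, abs=1e-12)
    assert -1.0 <= r0 <= 1.0
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [1.0, 2.0])


# ------------------------------------------------------------------------ ICC

def test_icc_duplicate_vectors_exactly_one():
    x = np.array([1.0, 4.0, 2.0, 9.0, 5.0])
    assert icc_repeatability(x, x.copy()) == 1.0


def test_icc_two_subject_zero_within_variance():
    assert icc_repeatability([0.0, 1.0], [0.0, 1.0]) == 1.0


def test_icc_matches_pingouin_reference():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    r1 = rng.normal(size=15)
    r2 = r1 + rng.normal(0, 0.3, size=15)
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(15), 2),
            "raters": np.tile([1, 2], 15),
            "y": np.stack([r1, r2], axis=1).ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="y")
    icc1 = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
    assert icc_repeatability(r1, r2) == pytest.approx(icc1, rel=1e-9)


def test_icc_shuffled_repeats_near_zero():
    rng = np.random.default_rng(12)
    vals = []
    for _ in range(200):
        x = rng.normal(size=30)
        vals.append(icc_repeatability(x, rng.permutation(x)))
    assert abs(np.mean(vals)) < 0.05


def test_icc_affine_invariance_and_errors():
    rng = np.random.default_rng(13)
    r1, r2 = rng.normal(size=10), rng.normal(size=10)
    base = icc_repeatability(r1, r2)
    assert icc_repeatability(5 * r1 - 2, 5 * r2 - 2) == pytest.approx(base, rel=1e-9)
    with pytest.raises(ValueError):
        icc_repeatability([1.0, 1.0], [1.0, 1.0])


# ------------------------------------------------------- relative difference

def test_relative_difference():
    assert relative_difference(3.0, 1.0) == pytest.approx(1.0)
    assert relative_difference(2.0, 2.0) == 0.0
    out = relative_difference([3.0, 1.0, 1.0], [1.0, 1.0, -1.0])
    np.testing.assert_allclose(out[:2], [1.0, 0.0])
    assert np.isnan(out[2])


# ------------------------------------------------------------ comparison table

def _paired(site, a, b):
    return PairedSample(site, tuple(a), tuple(b))


def test_comparison_table_identical_methods_all_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    table = site_comparison_table([_paired(f"s{i}", x, x) for i in range(19)])
    assert len(table) == 19
    assert (table["p_adjusted"] == 1.0).all()
    assert (table["significance"] == "ns").all()


def test_comparison_table_shifted_site_matches_enumeration():
    rng = np.random.default_rng(21)
    x = rng.normal(300, 40, size=10)
    samples = [_paired("shifted", x + 5.0, x), _paired("equal", x, x)]
    table = site_comparison_table(samples, m=19)
    _, p_oracle = wilcoxon_enumeration_oracle((x + 5.0) - x)
    row = table.set_index("site").loc["shifted"]
    assert row["p_raw"] == pytest.approx(p_oracle, rel=1e-12)
    assert row["p_adjusted"] == pytest.approx(min(1.0, 19 * p_oracle), rel=1e-12)
    assert row["median_a"] == pytest.approx(np.median(x + 5.0))
    assert row["iqr_b"] == pytest.approx(np.subtract(*np.percentile(x, [75, 25])))


# ---------------------------------------------------------- deviation analysis

def _dev_frame(noise_sd, rng):
    rows = []
    for subj in range(12):
        weight = 2.0 + 4.0 * subj
        voxels = int(8000 / (1 + subj))
        for dens in (100.0, 200.0, 400.0, 800.0):
            dev = rng.normal(0, noise_sd / np.sqrt(voxels)) if noise_sd else 0.0
            rows.append(
                {
                    "subject_id": f"s{subj}",
                    "insert_density": dens,
                    "method": "qct",
                    "deviation": dev,
                    "voxel_count": voxels,
                    "weight_kg": weight,
                }
            )
    return pd.DataFrame(rows)


def test_deviation_analysis_noiseless_reports_not_computable():
    df = _dev_frame(0.0, np.random.default_rng(0))
    res = deviation_analysis(df)
    assert (res["summary"]["mean_deviation"] == 0.0).all()
    assert not res["correlations"]["computable"].any()
    assert res["correlations"]["r"].isna().all()


def test_deviation_analysis_noisy_negative_voxel_correlation():
    res = deviation_analysis(_dev_frame(500.0, np.random.default_rng(8)))
    cors = res["correlations"]
    voxel_r = cors[cors["predictor"] == "voxel_count"]["r"]
    assert (voxel_r < 0).mean() >= 0.75  # averaging noise over more voxels helps


def test_deviation_analysis_requires_three_subjects():
    df = _dev_frame(1.0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        deviation_analysis(df[df["subject_id"].isin(["s0", "s1"])])
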