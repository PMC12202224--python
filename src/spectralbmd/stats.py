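"""Statistical comparison layer.

Normality screening (Jarque-Bera), test-retest repeatability (one-way
single-measure ICC), paired site-wise method comparison (Wilcoxon
signed-rank with Bonferroni correction and median/IQR summaries), Pearson
correlations, and the phantom-deviation analysis relating measurement
error to voxel count and body weight.

The Wilcoxon test uses the exact permutation null (all 2^n equally likely
sign assignments of the absolute-difference ranks, midranks for ties) for
up to 25 nonzero differences, computed by convolution over the rank
distribution; larger samples use the normal approximation with tie and
continuity corrections. Zero differences are dropped (Wilcoxon's original
rule).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "ComparisonRow",
    "jarque_bera",
    "wilcoxon_signed_rank",
    "bonferroni",
    "pearson",
    "icc_repeatability",
    "relative_difference",
    "site_comparison_table",
    "deviation_analysis",
]

EXACT_WILCOXON_LIMIT = 25


@dataclass(frozen=True)
class PairedSample:
    """Index-aligned per-subject values for two methods at one site."""

    site: str
    values_a: tuple
    values_b: tuple

    def __post_init__(self):
        if len(self.values_a) != len(self.values_b):
            raise ValueError("paired vectors must have equal length")
        if len(self.values_a) < 2:
            raise ValueError("need at least 2 pairs")


@dataclass(frozen=True)
class ComparisonRow:
    """One row of the site-wise method-comparison table."""

    site: str
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    p_raw: float
    p_adjusted: float
    significance: str


def jarque_bera(x) -> tuple[float, float]:
    """Jarque-Bera normality statistic and its chi-square(2) p-value.

    JB = n/6 * (S^2 + (K - 3)^2 / 4) with moment-based sample skewness S
    and kurtosis K.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        raise ValueError("zero variance sample")
    s = np.mean((x - m) ** 3) / m2**1.5
    k = np.mean((x - m) ** 4) / m2**2
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    return float(jb), float(sps.chi2.sf(jb, df=2))


def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    return sps.rankdata(np.abs(diffs))


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments, via rank convolution.

    Midranks are doubled so all rank sums are integers; the distribution
    of W+ is built by successive convolution (equivalent to enumerating
    the 2^n sign patterns).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    upper = 0
    for r in r2:
        counts[r : upper + r + 1] += counts[: upper + 1]
        upper += r
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b=None) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Call with paired vectors ``(a, b)`` (differences ``a - b``) or a
    single vector of differences. Returns ``(W+, p)`` where W+ is the sum
    of ranks of the positive differences. Raises if every difference is
    zero.
    """
    if isinstance(a, PairedSample):
        diffs = np.asarray(a.values_a, float) - np.asarray(a.values_b, float)
    elif b is not None:
        diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    else:
        diffs = np.asarray(a, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences are zero; no test possible")
    ranks = _signed_ranks(diffs)
    w_plus = float(ranks[diffs > 0].sum())
    if n <= EXACT_WILCOXON_LIMIT:
        return w_plus, _exact_wilcoxon_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    shift = np.sign(w_plus - mean) * 0.5  # continuity correction toward the mean
    z = (w_plus - mean - shift) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m*p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return min(1.0, m * p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def icc_repeatability(repeat1, repeat2) -> float:
    """One-way random, single-measure ICC(1,1) for two repeats.

    From the one-way ANOVA decomposition with k = 2 measurements per
    subject: ICC = (MSB - MSW) / (MSB + MSW). Identical repeats on a
    non-constant sample give exactly 1.0.
    """
    r1 = np.asarray(repeat1, dtype=float)
    r2 = np.asarray(repeat2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("repeats must be equal-length vectors")
    n = r1.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    data = np.stack([r1, r2], axis=1)
    if np.allclose(data, data.flat[0]):
        raise ValueError("zero total variance; ICC undefined")
    k = 2
    subject_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * np.sum((subject_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subject_means[:, None]) ** 2) / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


def relative_difference(a, b):
    """Symmetric relative difference (a - b) / mean(a, b); NaN when the
    pairwise mean is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return float(out) if out.ndim == 0 else out


def _significance_label(p_adj: float) -> str:
    if p_adj <= 0.001:
        return "***"
    if p_adj <= 0.01:
        return "**"
    if p_adj <= 0.05:
        return "*"
    return "ns"


def _iqr(x) -> float:
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def site_comparison_table(paired_samples, m: int | None = None) -> pd.DataFrame:
    """Median/IQR and Bonferroni-adjusted Wilcoxon p per site.

    ``paired_samples`` is an iterable of :class:`PairedSample`; the family
    size ``m`` defaults to the number of sites. Identical methods at a
    site (all differences zero) are reported with p = 1.
    """
    samples = list(paired_samples)
    m = m or len(samples)
    rows = []
    for s in samples:
        a = np.asarray(s.values_a, float)
        b = np.asarray(s.values_b, float)
        try:
            _, p = wilcoxon_signed_rank(a, b)
        except ValueError:
            p = 1.0  # methods identical at this site
        p_adj = bonferroni(p, m)
        rows.append(
            ComparisonRow(
                site=s.site,
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
                iqr_a=_iqr(a),
                iqr_b=_iqr(b),
                p_raw=float(p),
                p_adjusted=p_adj,
                significance=_significance_label(p_adj),
            )
        )
    return pd.DataFrame([asdict(r) for r in rows])


def deviation_analysis(records: pd.DataFrame) -> dict:
    """Phantom-deviation summaries and accuracy correlations.

    ``records`` needs columns: subject_id, insert_density, method,
    deviation (measured - nominal, mg/cm3), voxel_count, weight_kg.

    Returns ``{"summary": DataFrame, "correlations": DataFrame}``:
    per insert x method mean +/- SD of the deviation, and the Pearson
    correlation of |deviation| against voxel count and against body
    weight. Correlations that cannot be computed (fewer than 3 subjects
    or zero variance, e.g. a noiseless cohort) are reported as NaN with
    ``computable = False``.
    """
    df = records.copy()
    if df["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    df["abs_deviation"] = df["deviation"].abs()
    summary = (
        df.groupby(["insert_density", "method"], as_index=False)
        .agg(
            mean_deviation=("deviation", "mean"),
            sd_deviation=("deviation", "std"),
            mean_abs_deviation=("abs_deviation", "mean"),
            n=("deviation", "size"),
        )
    )
    corr_rows = []
    for (dens, method), grp in df.groupby(["insert_density", "method"]):
        for predictor in ("voxel_count", "weight_kg"):
            try:
                # sub-nano-mg/cm3 spread is floating-point residue, not
                # signal (a noiseless cohort): report as not computable
                if grp["abs_deviation"].std() < 1e-9:
                    raise ValueError("deviations are numerically zero")
                r, p = pearson(grp[predictor], grp["abs_deviation"])
                ok = True
            except ValueError:
                r, p, ok = float("nan"), float("nan"), False
            corr_rows.append(
                {
                    "insert_density": dens,
                    "method": method,
                    "predictor": predictor,
                    "r": r,
                    "p": p,
                    "n": len(grp),
                    "computable": ok,
                }
            )
    return {"summary": summary, "correlations": pd.DataFrame(corr_rows)}
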