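"""Statistical layer: normality, paired comparisons, correlation, and
noncentral-t power machinery for the paired t-test.

The power computations follow the standard two-sided paired design: with
effect size d (mean of paired differences over their SD), n pairs and
level alpha, the test statistic under the alternative follows a
noncentral t-distribution with df = n - 1 and noncentrality d * sqrt(n);
power is the probability mass of that distribution beyond the central-t
critical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "PowerAnalysisResult",
    "paired_t",
    "cohens_d_from_stats",
    "cohens_d_from_p",
    "power_paired_t",
    "min_n_for_power",
    "pearson",
    "ks_normality",
]


@dataclass(frozen=True)
class PairedSample:
    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple = ("a", "b")

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.shape != b.shape or a.ndim != 1 or a.size < 2:
            raise ValueError("paired sample needs two equal-length vectors, n >= 2")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return self.values_a.size

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass(frozen=True)
class PowerAnalysisResult:
    d: float
    n: int
    alpha: float
    power: float

    @property
    def df(self) -> int:
        return self.n - 1

    @property
    def noncentrality(self) -> float:
        return self.d * np.sqrt(self.n)


def paired_t(sample: PairedSample) -> dict:
    """Two-tailed paired Student's t-test.

    Returns t, df, the two-tailed p, the mean and SD of the differences
    and Cohen's d (mean/SD of differences).  Zero-variance differences are
    an error rather than an infinite statistic.
    """
    diffs = sample.differences
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        if np.allclose(diffs, 0):
            return {
                "t": 0.0, "df": sample.n - 1, "p": 1.0,
                "mean_diff": 0.0, "sd_diff": 0.0, "d": 0.0,
            }
        raise ValueError("paired differences have zero variance")
    res = sps.ttest_rel(sample.values_a, sample.values_b)
    mean = float(diffs.mean())
    return {
        "t": float(res.statistic),
        "df": sample.n - 1,
        "p": float(res.pvalue),
        "mean_diff": mean,
        "sd_diff": sd,
        "d": mean / sd,
    }


def cohens_d_from_stats(mean_diff: float, sd_diff: float) -> float:
    """Cohen's d for paired data: mean difference over SD of differences."""
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    return mean_diff / sd_diff


def cohens_d_from_p(p_two_tailed: float, n: int) -> float:
    """Back-calculate |d| from a two-tailed p-value and the number of pairs.

    Inverts the central t-distribution: t = t_{1 - p/2, n-1}, d = t/sqrt(n).
    """
    if not (0.0 < p_two_tailed < 1.0):
        raise ValueError("p must lie strictly between 0 and 1")
    if n < 2:
        raise ValueError("need at least two pairs")
    # isf keeps full precision for very small p, where ppf(1 - p/2) cannot
    t = sps.t.isf(p_two_tailed / 2.0, df=n - 1)
    return float(t / np.sqrt(n))


def power_paired_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Post hoc power of the two-tailed paired t-test via the noncentral t."""
    if n < 2:
        raise ValueError("need at least two pairs")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = d * np.sqrt(n)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(power):
        # scipy's noncentral t loses accuracy at extreme noncentrality;
        # fall back to the large-df normal limit T' ~ N(ncp, 1)
        power = sps.norm.sf(t_crit - ncp) + sps.norm.cdf(-t_crit - ncp)
    return float(min(max(power, 0.0), 1.0))


def min_n_for_power(d: float, target_power: float, alpha: float = 0.05,
                    n_max: int = 10**6) -> int:
    """Smallest n >= 2 with power_paired_t(d, n, alpha) >= target_power."""
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0.0 < target_power < 1.0):
        raise ValueError("target_power must lie in (0, 1)")
    n = 2
    while n <= n_max:
        if power_paired_t(d, n, alpha) >= target_power:
            return n
        n += 1
    raise RuntimeError(f"no n <= {n_max} reaches the requested power")


def power_analysis(d: float, n: int, alpha: float = 0.05) -> PowerAnalysisResult:
    return PowerAnalysisResult(d=d, n=n, alpha=alpha, power=power_paired_t(d, n, alpha))


def pearson(sample: PairedSample) -> tuple:
    """Pearson correlation with its two-tailed t-based p-value."""
    if sample.n < 3:
        raise ValueError("Pearson correlation needs at least three pairs")
    if sample.values_a.std() == 0 or sample.values_b.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = sps.pearsonr(sample.values_a, sample.values_b)
    return float(r), float(p)


def ks_normality(values, mean: float | None = None, sd: float | None = None) -> tuple:
    """One-sample Kolmogorov-Smirnov test against a normal distribution.

    By default the reference normal's parameters are estimated from the
    sample (a Lilliefors-style usage whose p-value is then conservative
    only in the classical-KS sense); fixed parameters may be supplied.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least five observations")
    if values.std(ddof=1) == 0:
        raise ValueError("constant sample; normality test is degenerate")
    mu = values.mean() if mean is None else mean
    sigma = values.std(ddof=1) if sd is None else sd
    stat, p = sps.kstest(values, "norm", args=(mu, sigma))
    return float(stat), float(p)
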