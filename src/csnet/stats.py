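"""Statistical battery for paired CS-word vs. translation-equivalent comparisons.

The unit of analysis is the CS-TE *pair*: each item carries one value for
the CS word and one for its translation equivalent, plus a between-item
direction label (which language switched into which).  The battery covers
z-standardization, covariate residualization, Pearson correlation, the
paired t-test with Cohen's d, the split-plot (mixed-design) 2x2 ANOVA with
the item as the random unit, the two-cell goodness-of-fit sign test, and a
logistic regression with Cox–Snell R².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """A single test statistic with its degrees of freedom and p-value.

    ``effect`` holds Cohen's d for t-tests, r for correlations, and the
    Cox–Snell R² for logistic fits; anything extra (slope, SE, counts,
    convergence flags) goes into ``extra``.
    """

    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect: float | None = None
    n: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")

    def to_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": df,
            "p": self.p,
            "effect": self.effect,
            "n": self.n,
            **self.extra,
        }


@dataclass
class ZScoreSpec:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("standard deviation must be positive")

    def apply(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


@dataclass
class PairedSample:
    """Per-item CS and TE values with a between-item direction label."""

    value_cs: np.ndarray
    value_te: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.value_cs = np.asarray(self.value_cs, dtype=float)
        self.value_te = np.asarray(self.value_te, dtype=float)
        self.direction = np.asarray(self.direction)
        if not (len(self.value_cs) == len(self.value_te) == len(self.direction)):
            raise ValueError("value_cs, value_te and direction must align")
        if not (np.all(np.isfinite(self.value_cs)) and np.all(np.isfinite(self.value_te))):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.value_cs)

    def directions(self) -> list:
        seen: list = []
        for d in self.direction:
            if d not in seen:
                seen.append(d)
        return seen

    def subset(self, direction) -> "PairedSample":
        mask = self.direction == direction
        return PairedSample(self.value_cs[mask], self.value_te[mask], self.direction[mask])


def zscore(values: Sequence[float]) -> tuple[np.ndarray, ZScoreSpec]:
    """Standardize to mean 0, sample (ddof=1) standard deviation 1."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least 2 values to standardize")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot z-score a constant sequence")
    spec = ZScoreSpec(mean=mean, sd=sd)
    return spec.apply(arr), spec


def residualize(y: Sequence[float], x: Sequence[float]) -> np.ndarray:
    """Residuals of the OLS fit y ~ intercept + x.

    Removes the linear effect of ``x`` from ``y``; the output is orthogonal
    to ``x`` and sums to zero.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("y and x must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor is constant")
    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the t-transform p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return TestResult(
        name="pearson",
        statistic=float(res.statistic),
        df=len(x) - 2,
        p=float(res.pvalue),
        effect=float(res.statistic),
        n=len(x),
    )


def paired_t(sample: PairedSample | tuple, direction=None) -> TestResult:
    """Paired-sample t-test on CS − TE differences with Cohen's d.

    ``sample`` is a :class:`PairedSample` (optionally restricted to one
    ``direction``) or a plain (cs_values, te_values) tuple.  t is
    mean(d)/(sd(d)/sqrt(n)) with df = n − 1 and d = mean(d)/sd(d); the sign
    convention is CS minus TE.
    """
    if isinstance(sample, PairedSample):
        if direction is not None:
            sample = sample.subset(direction)
        cs, te = sample.value_cs, sample.value_te
    else:
        cs, te = (np.asarray(v, dtype=float) for v in sample)
    if len(cs) < 2:
        raise ValueError("need at least 2 pairs")
    diff = cs - te
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences")
    n = len(diff)
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(
        name="paired_t",
        statistic=float(t),
        df=n - 1,
        p=float(p),
        effect=float(diff.mean() / sd),
        n=n,
    )


def mixed_anova_2x2(sample: PairedSample) -> dict[str, TestResult]:
    """Split-plot ANOVA: within-item switching x between-item direction.

    The item (CS-TE pair) is the random unit.  With two within levels the
    decomposition reduces to two one-way analyses: the between-item part on
    item means (direction effect against item-within-direction error) and
    the within-item part on item differences (switching and the
    switching-by-direction interaction against the residual).  The
    interaction F therefore equals the square of the pooled two-sample t
    comparing per-item CS − TE differences across the two directions, with
    df (1, N − 2).  Group sizes may be unbalanced (weighted, Type-I-style
    sums of squares).
    """
    dirs = sample.directions()
    if len(dirs) != 2:
        raise ValueError(f"exactly 2 directions required, got {len(dirs)}")
    groups = [sample.subset(d) for d in dirs]
    sizes = [len(g) for g in groups]
    if min(sizes) < 2:
        raise ValueError("each direction needs at least 2 items")
    n_total = sum(sizes)
    df_err = n_total - 2

    # within-item part: differences d_i = cs_i - te_i
    d_all = sample.value_cs - sample.value_te
    d_groups = [g.value_cs - g.value_te for g in groups]
    grand_d = d_all.mean()
    ss_switch = n_total * grand_d**2 / 2.0
    ss_inter = sum(len(d) * (d.mean() - grand_d) ** 2 for d in d_groups) / 2.0
    ss_err_w = sum(((d - d.mean()) ** 2).sum() for d in d_groups) / 2.0
    ms_err_w = ss_err_w / df_err

    # between-item part: item means s_i = (cs_i + te_i)/2, each counted twice
    s_all = (sample.value_cs + sample.value_te) / 2.0
    s_groups = [(g.value_cs + g.value_te) / 2.0 for g in groups]
    grand_s = s_all.mean()
    ss_dir = 2.0 * sum(len(s) * (s.mean() - grand_s) ** 2 for s in s_groups)
    ss_err_b = 2.0 * sum(((s - s.mean()) ** 2).sum() for s in s_groups)
    ms_err_b = ss_err_b / df_err

    def f_result(name: str, ss: float, ms_err: float) -> TestResult:
        f = ss / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(f, 1, df_err))
        return TestResult(name=name, statistic=float(f), df=(1, df_err), p=p, n=n_total)

    return {
        "switching": f_result("anova_switching", ss_switch, ms_err_w),
        "direction": f_result("anova_direction", ss_dir, ms_err_b),
        "interaction": f_result("anova_interaction", ss_inter, ms_err_w),
    }


def sign_test(a: int, b: int) -> TestResult:
    """Two-cell goodness-of-fit chi-square on direction-of-difference counts.

    ``a`` pairs had the lower value for the CS word, ``b`` the higher; ties
    must be excluded by the caller.  chi2 = (a − b)^2 / (a + b), df = 1, no
    continuity correction.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be nonnegative")
    if a + b == 0:
        raise ValueError("no untied pairs to test")
    chi2 = (a - b) ** 2 / (a + b)
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(
        name="sign_test",
        statistic=float(chi2),
        df=1,
        p=p,
        n=a + b,
        extra={"count_lower": int(a), "count_higher": int(b)},
    )


def logistic_fit(y: Sequence[int], x: Sequence[float]) -> TestResult:
    """Logistic regression of a binary outcome on one predictor.

    Maximum-likelihood fit (iteratively reweighted least squares / Newton).
    Reports the slope B, its standard error, the Wald statistic (B/SE)^2
    with its two-sided p, and the Cox–Snell R² = 1 − (L0/L1)^(2/n)
    (Nagelkerke's rescaling is included in ``extra``).  Perfect separation
    is flagged via ``extra["converged"]``, never silently ignored.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x) or len(y) < 4:
        raise ValueError("need equal-length sequences of at least 4 values")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise ValueError("y must contain both classes coded 0/1")
    design = sm.add_constant(x)
    model = sm.Logit(y, design)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # perfect separation raises in some versions
            res = model.fit(disp=False, maxiter=100, method="bfgs")
            converged = False
    b = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se == 0.0 or abs(b) > 1e3:
        converged = False
    wald = (b / se) ** 2 if (np.isfinite(se) and se > 0) else np.inf
    p = float(2.0 * sps.norm.sf(abs(b / se))) if np.isfinite(wald) else 0.0
    n = len(y)
    r2_cs = float(1.0 - np.exp((res.llnull - res.llf) * 2.0 / n))
    r2_max = float(1.0 - np.exp(res.llnull * 2.0 / n))
    return TestResult(
        name="logistic",
        statistic=float(wald),
        df=1,
        p=p,
        effect=r2_cs,
        n=n,
        extra={
            "B": b,
            "se": se,
            "intercept": float(res.params[0]),
            "r2_cox_snell": r2_cs,
            "r2_nagelkerke": r2_cs / r2_max if r2_max > 0 else np.nan,
            "converged": converged,
        },
    )
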