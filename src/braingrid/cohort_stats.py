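"""Between-group statistical battery with false-discovery-rate control.

The battery mirrors the conventional comparison of three molecular subgroups
of suspected diffuse low-grade glioma: a Lilliefors-corrected
Kolmogorov-Smirnov normality gate, Kruskal-Wallis for continuous variables,
Pearson chi-square or Fisher's exact test for categorical variables, Mood's
median test for tumour volume and grid-voxel count, and Benjamini-Hochberg
step-up adjustment across the whole battery.  All p-values are two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSampleError, EmptyInputError, InvalidDesignError

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "ks_normality",
    "kruskal_wallis",
    "contingency_test",
    "mood_median_test",
    "bh_fdr",
    "group_comparison_battery",
    "percent",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: float | None = None
    adjusted_p: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidDesignError(f"p-value {self.p_value} outside [0, 1]")


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (table formatting)."""
    if denominator == 0:
        raise EmptyInputError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(numerator) / Decimal(denominator) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def ks_normality(values) -> TestResult:
    """Kolmogorov-Smirnov normality test with sample-estimated parameters.

    Because the normal mean/SD are estimated from the sample, the p-value
    uses the Lilliefors correction rather than the classical KS distribution.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DegenerateSampleError("normality test needs n >= 4")
    if not np.all(np.isfinite(x)):
        raise DegenerateSampleError("sample contains non-finite values")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample: normality undefined")
    d, p = lilliefors(x, dist="norm", pvalmethod="approx")
    return TestResult(test="KS (Lilliefors)", statistic=float(d), p_value=float(min(p, 1.0)))


def kruskal_wallis(values, group_labels) -> TestResult:
    """Kruskal-Wallis H test with tie correction, p from chi-square(k-1)."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    if x.shape != g.shape:
        raise InvalidDesignError("values and group labels must align")
    groups = [x[g == lev] for lev in pd.unique(g)]
    if len(groups) < 2 or any(len(gr) == 0 for gr in groups):
        raise InvalidDesignError("need >= 2 non-empty groups")
    if np.ptp(x) == 0:
        # all observations identical: no evidence of any difference
        return TestResult(test="Kruskal-Wallis", statistic=0.0, p_value=1.0, df=len(groups) - 1)
    h, p = stats.kruskal(*groups)
    return TestResult(test="Kruskal-Wallis", statistic=float(h), p_value=float(p), df=len(groups) - 1)


def _log_table_prob(table: np.ndarray) -> float:
    """Log-probability of an r x c table under fixed margins (generalized
    hypergeometric), used to order tables for the exact test."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _fisher_rxc_montecarlo(table: np.ndarray, n_resamples: int, seed: int) -> float:
    """Monte-Carlo Fisher p for r x c tables via Patefield margin sampling."""
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    rng = np.random.default_rng(seed)
    samples = dist.rvs(n_resamples, random_state=rng)
    lp_obs = _log_table_prob(table)
    lps = np.array([_log_table_prob(t) for t in samples])
    # add-one correction keeps the estimate a valid p-value
    return float((np.sum(lps <= lp_obs + 1e-9) + 1) / (n_resamples + 1))


def contingency_test(
    table, method: str = "auto", n_resamples: int = 20000, seed: int = 0
) -> TestResult:
    """Pearson chi-square or Fisher's exact test on an r x c count table.

    ``auto`` picks Fisher whenever any expected count is below 5 (the usual
    small-sample rule), Pearson otherwise.  Zero-margin rows/columns are
    dropped with a warning before testing.  For tables larger than 2 x 2 the
    exact p is a seeded Monte-Carlo estimate over tables with the observed
    margins.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.round(t)):
        raise InvalidDesignError("table must be 2D nonnegative integers")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape != np.asarray(table).shape:
        warnings.warn("dropped zero-margin rows/columns before testing", stacklevel=2)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise InvalidDesignError("need at least a 2 x 2 table after dropping zero margins")
    if t.sum() == 0:
        raise EmptyInputError("empty contingency table")

    expected = stats.contingency.expected_freq(t)
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "chi2"

    if method == "chi2":
        res = stats.chi2_contingency(t, correction=False)
        return TestResult(
            test="Pearson chi-square",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            df=float(res.dof),
        )
    if method == "fisher":
        if t.shape == (2, 2):
            res = stats.fisher_exact(t.astype(int))
            return TestResult(test="Fisher exact", statistic=float(res.statistic), p_value=float(res.pvalue))
        p = _fisher_rxc_montecarlo(t.astype(int), n_resamples, seed)
        return TestResult(test="Fisher exact (MC)", statistic=float("nan"), p_value=p)
    raise InvalidDesignError(f"unknown method {method!r}")


def mood_median_test(values, group_labels) -> TestResult:
    """Mood's median test: dichotomize at the pooled median, then chi-square.

    Observations equal to the pooled median are counted on the '<= median'
    side, a deterministic tie rule shared with common implementations.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    if np.ptp(x) == 0:
        raise DegenerateSampleError("pooled sample is constant; median test undefined")
    med = np.median(x)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise InvalidDesignError("need >= 2 groups")
    tab = np.array(
        [[(x[g == lev] <= med).sum(), (x[g == lev] > med).sum()] for lev in levels]
    )
    res = contingency_test(tab, method="chi2")
    return TestResult(test="Median test", statistic=res.statistic, p_value=res.p_value, df=res.df)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidDesignError("p_values must be a non-empty 1D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidDesignError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- battery over a cohort table ------------------------------------------

CONTINUOUS_VARS = ["age"]
MEDIAN_VARS = ["volume_ml", "bg_voxel_count"]
CATEGORICAL_VARS = [
    "sex",
    "border",
    "contrast",
    "laterality",
    "location",
    "seizure",
    "cognitive_deficit",
    "motor_deficit",
    "language_deficit",
    "visual_deficit",
    "headache",
    "asymptomatic",
]


def group_comparison_battery(
    cohort: pd.DataFrame, group_col: str = "group", variables: dict | None = None
) -> pd.DataFrame:
    """Run the full between-group battery on a cohort table.

    Returns a results table shaped like the conventional between-group
    summary (variable, test, statistic, p, fdr), with BH adjustment applied
    across every test of the run.
    """
    if group_col not in cohort.columns:
        raise InvalidDesignError(f"missing group column {group_col!r}")
    groups = pd.unique(cohort[group_col])
    if len(groups) < 2:
        raise InvalidDesignError("need >= 2 groups in the cohort")

    if variables is None:
        variables = {
            **{v: "continuous" for v in CONTINUOUS_VARS if v in cohort},
            **{v: "median" for v in MEDIAN_VARS if v in cohort},
            **{v: "categorical" for v in CATEGORICAL_VARS if v in cohort},
        }

    rows = []
    for var, kind in variables.items():
        sub = cohort[[group_col, var]].dropna()
        try:
            if kind == "continuous":
                res = kruskal_wallis(sub[var].to_numpy(float), sub[group_col].to_numpy())
            elif kind == "median":
                res = mood_median_test(sub[var].to_numpy(float), sub[group_col].to_numpy())
            elif kind == "categorical":
                tab = pd.crosstab(sub[group_col], sub[var]).to_numpy()
                res = contingency_test(tab, method="auto")
            else:
                raise InvalidDesignError(f"unknown variable kind {kind!r} for {var}")
        except (DegenerateSampleError, InvalidDesignError) as exc:
            if kind not in ("continuous", "median", "categorical"):
                raise
            logger.warning("skipping degenerate variable %s: %s", var, exc)
            continue
        rows.append(
            {"variable": var, "test": res.test, "statistic": res.statistic, "p": res.p_value}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    logger.info("battery ran %d tests (FDR family size m=%d)", len(out), len(out))
    return out
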