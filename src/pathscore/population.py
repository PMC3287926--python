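"""Population-structure follow-up analyses.

Three questions about a stratified case-control cohort:

1. Does disease prevalence differ across populations?  (chi-square test
   of independence on the population x affection contingency table.)
2. Does a pathway's genetic risk score differ across populations?
   (linear model ``rs ~ population``, overall F test.)
3. Does population still predict disease once the genetic risk score is
   in the model?  (likelihood-ratio test of ``affected ~ rs`` vs
   ``affected ~ rs + population``.)  A non-significant LRT alongside
   significant answers to 1-2 is the signature of prevalence differences
   mediated by genetic differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathscore.regression import add_intercept, fit_logit

log = logging.getLogger(__name__)


@dataclass
class PrevalenceTest:
    prevalence: dict[str, float]
    statistic: float
    df: int
    p: float
    method: str  # "chi2" or "fisher_exact"


def prevalence_test(affected, population) -> PrevalenceTest:
    """Per-population prevalence and a test of prevalence homogeneity.

    Pearson chi-square without continuity correction; for a 2x2 table
    with any expected count below 5 the Fisher exact test is used
    instead (with a warning for larger sparse tables).
    """
    affected = pd.Series(np.asarray(affected, dtype=int), name="affected")
    population = pd.Series(np.asarray(population, dtype=object), name="population")
    if population.nunique() < 2:
        raise ValueError("need at least two populations")
    table = pd.crosstab(population, affected)
    if table.shape[1] < 2:
        raise ValueError("affection status has a single class")
    prev = (table.get(1, 0) / table.sum(axis=1)).to_dict()
    obs = table.to_numpy()
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        if obs.shape == (2, 2):
            log.warning("sparse 2x2 table; switching to Fisher exact test")
            _, p = stats.fisher_exact(obs)
            return PrevalenceTest(prev, np.nan, 1, float(p), "fisher_exact")
        log.warning("expected cell count < 5; chi-square approximation is rough")
    return PrevalenceTest(prev, float(chi2), int(df), float(p), "chi2")


def riskscore_by_population(rs, population) -> float:
    """Overall F-test p for ``rs ~ population`` (dummy-coded linear model,
    largest population as reference)."""
    import statsmodels.api as sm

    rs = np.asarray(rs, dtype=float)
    population = pd.Series(np.asarray(population, dtype=object))
    if population.nunique() < 2:
        raise ValueError("need at least two populations")
    if np.ptp(rs) == 0:
        raise ValueError("risk score is constant")
    ref = population.value_counts().idxmax()
    levels = [g for g in sorted(population.unique()) if g != ref]
    dummies = np.column_stack([(population == g).to_numpy(float) for g in levels])
    res = sm.OLS(rs, add_intercept(dummies)).fit()
    return float(res.f_pvalue)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float
    ok: bool


def lrt_population_given_score(affected, population, rs) -> LrtResult:
    """LRT of population on disease, adjusted for the genetic risk score.

    Compares nested logistic models ``affected ~ rs`` (reduced) and
    ``affected ~ rs + population`` (full); the statistic
    ``2*(llf_full - llf_reduced)`` is chi-square with
    ``n_populations - 1`` degrees of freedom.  A constant risk score
    degenerates to the marginal population test.
    """
    y = np.asarray(affected, dtype=float)
    rs = np.asarray(rs, dtype=float)
    population = pd.Series(np.asarray(population, dtype=object))
    if population.nunique() < 2:
        raise ValueError("need at least two populations")
    ref = population.value_counts().idxmax()
    levels = [g for g in sorted(population.unique()) if g != ref]
    dummies = np.column_stack([(population == g).to_numpy(float) for g in levels])

    score_blocks = () if np.ptp(rs) == 0 else (rs,)
    reduced = fit_logit(y, add_intercept(*score_blocks) if score_blocks
                        else np.ones((len(y), 1)))
    full = fit_logit(y, add_intercept(*score_blocks, dummies))
    ok = reduced.converged and full.converged
    if not ok or not (np.isfinite(reduced.llf) and np.isfinite(full.llf)):
        return LrtResult(np.nan, len(levels), np.nan, False)
    lr = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(lr, df=len(levels)))
    return LrtResult(float(lr), len(levels), p, True)


def population_report(
    covariates: pd.DataFrame, scores: dict[str, np.ndarray]
) -> pd.DataFrame:
    """One row per pathway: prevalence test (repeated), risk-by-population
    F p, and the risk-adjusted population LRT p."""
    prev = prevalence_test(covariates["affected"], covariates["population"])
    rows = []
    for name, rs in scores.items():
        try:
            f_p = riskscore_by_population(rs, covariates["population"])
        except ValueError:
            f_p = np.nan
        lrt = lrt_population_given_score(
            covariates["affected"], covariates["population"], rs
        )
        rows.append(
            {
                "pathway": name,
                "prevalence_p": prev.p,
                "risk_by_population_p": f_p,
                "lrt_population_given_score_p": lrt.p,
                "lrt_statistic": lrt.statistic,
            }
        )
    df = pd.DataFrame(rows)
    for pop, pr in prev.prevalence.items():
        df[f"prevalence_{pop}"] = pr
    return df
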