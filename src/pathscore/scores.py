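"""Per-pathway genetic risk scores.

Three scores are computed for every pathway:

``RS_rare``
    Collapsing (burden) score — the count, or per-allele proportion, of
    minor alleles across the pathway's rare variants.

``RS_common``
    Risk-allele count over the common variants selected by an
    L1-penalized (LASSO) logistic regression in which the clinical
    covariates (age, sex, smoking, population, optional quantitative
    traits) are always present and unpenalized.  Each selected SNP's risk
    allele (minor or major) is fixed by an unadjusted univariate fit, so
    effect directions are aligned before summing.  An empty selection is
    a valid outcome: the pathway then has no common-variant component.

``RS_final``
    OR-weighted combination.  Both component scores are dichotomized at
    their sample medians; the odds ratio of each indicator is estimated
    by unadjusted logistic regression, and a component only contributes
    when its OR exceeds 1 (the sign gate):

        RS_final_i = 1{OR_r>1} * OR_r * 1{RS_rare_i > m_r}
                   + 1{OR_c>1} * OR_c * 1{RS_common_i > m_c}

    ``combine_mode="continuous"`` instead weights the raw scores by the
    same gated ORs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from pathscore.regression import add_intercept, fit_logit

log = logging.getLogger(__name__)

#: multiplier applied to the (standardized) covariate columns inside the
#: liblinear L1 solver so that their coefficients carry a negligible share
#: of the penalty while keeping the problem well conditioned
_COV_SCALE = 1e3


def rare_score(G_rare: np.ndarray, mode: str = "count") -> np.ndarray:
    """Collapsing score over the pathway's rare variants.

    ``count``: sum of minor-allele dosages per sample (missing -> 0).
    ``proportion``: that sum divided by twice the number of *observed*
    rare genotypes for the sample.
    """
    G = np.asarray(G_rare, dtype=float)
    if G.ndim != 2:
        raise ValueError("G_rare must be 2-D (samples x rare SNPs)")
    if G.shape[1] == 0:
        return np.zeros(G.shape[0])
    total = np.nansum(G, axis=1)
    if mode == "count":
        return total
    if mode == "proportion":
        n_obs = (~np.isnan(G)).sum(axis=1)
        out = np.zeros(G.shape[0])
        nz = n_obs > 0
        out[nz] = total[nz] / (2.0 * n_obs[nz])
        return out
    raise ValueError(f"unknown rare score mode {mode!r}")


@dataclass
class LassoFit:
    """Outcome of the penalized common-variant selection for one pathway."""

    snp_ids: list[str]
    gamma: np.ndarray  # per-SNP coefficients on the original dosage scale
    selected: list[str]
    lam: float  # chosen penalty (liblinear scale: 1/C)
    cv_deviance: np.ndarray | None = None
    lam_path: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _l1_fit(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=C,
        solver="liblinear",
        intercept_scaling=100.0,
        max_iter=2000,
        tol=1e-6,
    )
    clf.fit(X, y)
    return clf


def lasso_select_common(
    G_common: np.ndarray,
    snp_ids: list[str],
    affected: np.ndarray,
    covariates: np.ndarray,
    lambda_rule: str = "cv_1se",
    n_folds: int = 10,
    n_lambda: int = 15,
    seed: int = 0,
) -> LassoFit:
    """Select a pathway's common variants by L1-penalized logistic fit.

    SNP columns are standardized before penalization (mean 0, unit SD, as
    glmnet does); the covariate block is kept in every fit and effectively
    unpenalized.  The penalty is chosen on a geometric path by K-fold
    cross-validated deviance (``lambda_rule="cv"``), or by the
    one-standard-error rule (``"cv_1se"``: the strongest penalty whose
    mean CV deviance is within one SE of the minimum).
    """
    y = np.asarray(affected, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("affection status has a single class")
    G = np.asarray(G_common, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("need at least one common SNP")
    if G.shape[1] != len(snp_ids):
        raise ValueError("snp_ids do not match genotype columns")
    G = np.where(np.isnan(G), 0.0, G)  # missing dosage contributes 0

    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    informative = sd > 0
    Xs = np.zeros_like(G)
    Xs[:, informative] = (G[:, informative] - mu[informative]) / sd[informative]

    cov = np.asarray(covariates, dtype=float).reshape(len(y), -1)
    if cov.shape[1]:
        c_mu, c_sd = cov.mean(axis=0), cov.std(axis=0)
        c_sd[c_sd == 0] = 1.0
        cov = (cov - c_mu) / c_sd
    X = np.column_stack([Xs, cov * _COV_SCALE])
    n_snp = G.shape[1]

    # penalty path: lambda_max is where every SNP coefficient is zero
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ resid)))
    if lam_max <= 0:  # no SNP varies; nothing selectable
        return LassoFit(list(snp_ids), np.zeros(n_snp), [], np.inf)
    lam_path = np.geomspace(lam_max * 1.5, lam_max * 0.01, n_lambda)

    n_folds = min(n_folds, int(np.bincount(y.astype(int)).min()))
    if n_folds < 2:
        raise ValueError("too few samples in one class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, len(lam_path)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        for k, lam in enumerate(lam_path):
            try:
                clf = _l1_fit(X[tr], y[tr], C=1.0 / lam)
                eta = X[te] @ clf.coef_[0] + clf.intercept_[0]
                prob = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
                dev[f, k] = -2.0 * float(
                    np.mean(y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob))
                )
            except Exception:  # non-convergence at this knot: fall back
                log.warning("CV fit failed at lambda=%.3g; penalizing knot", lam)
                dev[f, k] = np.inf
    mean_dev = dev.mean(axis=0)
    if not np.isfinite(mean_dev).any():
        raise RuntimeError("no penalty on the path produced a convergent fit")
    best = int(np.argmin(mean_dev))
    if lambda_rule == "cv_1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        limit = mean_dev[best] + se[best]
        # strongest penalty (largest lambda = smallest index) within 1 SE
        best = int(np.nonzero(mean_dev <= limit)[0][0])
    elif lambda_rule != "cv":
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")
    lam = float(lam_path[best])

    clf = _l1_fit(X, y, C=1.0 / lam)
    coef_std = clf.coef_[0][:n_snp]
    gamma = np.zeros(n_snp)
    gamma[informative] = coef_std[informative] / sd[informative]
    selected = [snp_ids[j] for j in range(n_snp) if coef_std[j] != 0.0]
    return LassoFit(list(snp_ids), gamma, selected, lam, mean_dev, lam_path)


def determine_risk_alleles(
    G_selected: np.ndarray, snp_ids: list[str], affected: np.ndarray
) -> dict[str, str]:
    """Fix each selected SNP's risk allele by unadjusted univariate fit.

    ``minor_is_risk`` when the minor-allele OR exceeds 1 (ties and
    degenerate fits default to ``minor_is_risk``).
    """
    from pathscore.qc import univariate_snp_test

    y = np.asarray(affected, dtype=float)
    out: dict[str, str] = {}
    for j, snp in enumerate(snp_ids):
        try:
            res = univariate_snp_test(G_selected[:, j], y)
            beta = res.beta if res.ok and np.isfinite(res.beta) else 0.0
        except ValueError:
            log.warning("degenerate SNP %s; risk allele defaults to minor", snp)
            beta = 0.0
        out[snp] = "major_is_risk" if beta < 0 else "minor_is_risk"
    return out


def common_score(
    G_selected: np.ndarray, snp_ids: list[str], directions: dict[str, str]
) -> np.ndarray:
    """Risk-allele count over the selected common SNPs.

    A SNP whose major allele is the risk allele contributes ``2 - dosage``;
    missing dosages contribute 0 either way.
    """
    G = np.asarray(G_selected, dtype=float)
    score = np.zeros(G.shape[0])
    for j, snp in enumerate(snp_ids):
        d = G[:, j]
        obs = ~np.isnan(d)
        if directions[snp] == "minor_is_risk":
            score[obs] += d[obs]
        elif directions[snp] == "major_is_risk":
            score[obs] += 2.0 - d[obs]
        else:
            raise ValueError(f"unknown direction {directions[snp]!r}")
    return score


@dataclass
class ComponentOR:
    """Dichotomized-score odds ratio used as a combination weight."""

    odds_ratio: float
    median: float
    usable: bool
    note: str = ""


def component_or(rs: np.ndarray, affected: np.ndarray) -> ComponentOR:
    """Median-dichotomize a risk score and estimate its odds ratio.

    Fits an unadjusted logistic regression of affection on the indicator
    ``1{rs > median(rs)}``.  Heavy ties that make the indicator constant,
    or a separated fit, mark the component unusable.
    """
    rs = np.asarray(rs, dtype=float)
    y = np.asarray(affected, dtype=float)
    if np.ptp(rs) == 0:
        return ComponentOR(np.nan, float(rs[0]) if rs.size else np.nan,
                           False, "constant score")
    m = float(np.median(rs))
    ind = (rs > m).astype(float)
    if np.ptp(ind) == 0:
        return ComponentOR(np.nan, m, False, "indicator constant (ties at median)")
    fit = fit_logit(y, add_intercept(ind))
    if not fit.ok:
        return ComponentOR(np.nan, m, False, "non-convergent/separated fit")
    return ComponentOR(float(np.exp(fit.params[1])), m, True)


def combine_scores(
    rs_rare: np.ndarray | None,
    rs_common: np.ndarray | None,
    or_rare: ComponentOR | None,
    or_common: ComponentOR | None,
    combine_mode: str = "indicator",
) -> tuple[np.ndarray, bool]:
    """OR-weighted combined score; returns (RS_final, testable flag).

    A component is gated out (contributes exactly 0 for every sample)
    when it is missing, unusable, or its dichotomized OR is <= 1.  When
    both components are gated the score is identically zero and the
    pathway is flagged untestable.
    """
    if combine_mode not in ("indicator", "continuous"):
        raise ValueError(f"unknown combine mode {combine_mode!r}")
    n = len(rs_rare) if rs_rare is not None else len(rs_common)
    out = np.zeros(n)
    active = False
    for rs, comp in ((rs_rare, or_rare), (rs_common, or_common)):
        if rs is None or comp is None or not comp.usable:
            continue
        if comp.odds_ratio <= 1.0:  # sign gate
            continue
        if combine_mode == "indicator":
            out += comp.odds_ratio * (np.asarray(rs, float) > comp.median)
        else:
            out += comp.odds_ratio * np.asarray(rs, float)
        active = True
    testable = active and np.ptp(out) > 0
    return out, testable


@dataclass
class PathwayScores:
    """Everything the combination step produced for one pathway."""

    pathway: str
    rs_rare: np.ndarray
    rs_common: np.ndarray | None
    rs_final: np.ndarray
    or_rare: ComponentOR
    or_common: ComponentOR | None
    selected_snps: list[str] = field(default_factory=list)
    directions: dict[str, str] = field(default_factory=dict)
    lasso: LassoFit | None = None
    testable: bool = True


def score_pathway(
    gm,
    pathway,
    affected: np.ndarray,
    covariates: np.ndarray,
    rare_score_mode: str = "count",
    combine_mode: str = "indicator",
    lambda_rule: str = "cv_1se",
    n_folds: int = 10,
    n_lambda: int = 15,
    seed: int = 0,
) -> PathwayScores:
    """Run the full three-step scoring for one pathway."""
    y = np.asarray(affected, dtype=float)

    rs_r = rare_score(gm.columns(pathway.rare_snps), mode=rare_score_mode)
    comp_r = component_or(rs_r, y)

    rs_c = None
    comp_c = None
    selected: list[str] = []
    directions: dict[str, str] = {}
    lasso = None
    if pathway.common_snps:
        lasso = lasso_select_common(
            gm.columns(pathway.common_snps),
            pathway.common_snps,
            y,
            covariates,
            lambda_rule=lambda_rule,
            n_folds=n_folds,
            n_lambda=n_lambda,
            seed=seed,
        )
        selected = lasso.selected
        if selected:
            G_sel = gm.columns(selected)
            directions = determine_risk_alleles(G_sel, selected, y)
            rs_c = common_score(G_sel, selected, directions)
            comp_c = component_or(rs_c, y)

    rs_f, testable = combine_scores(rs_r, rs_c, comp_r, comp_c, combine_mode)
    return PathwayScores(
        pathway=pathway.name,
        rs_rare=rs_r,
        rs_common=rs_c,
        rs_final=rs_f,
        or_rare=comp_r,
        or_common=comp_c,
        selected_snps=selected,
        directions=directions,
        lasso=lasso,
        testable=testable,
    )
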