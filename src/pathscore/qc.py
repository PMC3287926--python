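"""Per-SNP quality control.

Minor-allele frequencies, the exact Hardy-Weinberg equilibrium (HWE)
test, per-subpopulation HWE filtering, a univariate logistic screen of
every SNP against affection status, and the Bonferroni threshold helper.

The HWE test is the conditional exact test (probability of the observed
heterozygote count given the allele counts; the p-value sums the
probabilities of all heterozygote counts no more likely than the observed
one).  Pooling across stratified populations would create spurious
heterozygote deficits (Wahlund effect), so the filter always tests within
each subpopulation separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathscore.io import GenotypeMatrix
from pathscore.regression import add_intercept, fit_logit

log = logging.getLogger(__name__)


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one SNP from additive dosages.

    Missing entries (NaN) are excluded; the frequency is folded so the
    result is always the frequency of the *less* common allele.
    """
    d = np.asarray(dosages, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise ValueError("all dosages missing; MAF undefined")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def maf_table(gm: GenotypeMatrix) -> pd.Series:
    """MAF per SNP (vectorised over the matrix)."""
    d = gm.dosages
    obs = (~np.isnan(d)).sum(axis=0)
    if np.any(obs == 0):
        bad = gm.snp_ids[int(np.argmax(obs == 0))]
        raise ValueError(f"SNP {bad} has no observed genotypes")
    f = np.nansum(d, axis=0) / (2.0 * obs)
    return pd.Series(np.minimum(f, 1.0 - f), index=gm.snp_ids, name="maf")


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p-value for one genotype table.

    Implements the standard stable recurrence over heterozygote counts
    (mid-p not applied).  Monomorphic tables return 1 by convention.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("empty genotype table")
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if rare == 0:
        return 1.0

    # unnormalized probabilities over all het counts with the observed parity
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (n-r/2... ))
    curr_hom_r = (rare - mid) // 2
    curr_hom_c = n - mid - curr_hom_r
    h, hr, hc = mid, curr_hom_r, curr_hom_c
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hr + 1.0) * (hc + 1.0))
        h -= 2
        hr += 1
        hc += 1
    h, hr, hc = mid, curr_hom_r, curr_hom_c
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hr * hc / ((h + 2.0) * (h + 1.0))
        h += 2
        hr -= 1
        hc -= 1
    probs /= probs.sum()
    p_obs = probs[n_het]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_hom_major, n_het, n_hom_minor) ignoring missing; folded to minor."""
    d = np.asarray(dosages, dtype=float)
    n0 = int(np.nansum(d == 0))
    n1 = int(np.nansum(d == 1))
    n2 = int(np.nansum(d == 2))
    if n2 > n0:  # dosage counts the major allele; fold
        n0, n2 = n2, n0
    return n0, n1, n2


@dataclass
class HweFilterResult:
    kept: list[str]
    removed: list[str]
    p_values: pd.DataFrame  # SNP x population HWE p


def hwe_filter(
    gm: GenotypeMatrix,
    populations: pd.Series,
    alpha: float = 1e-6,
    rule: str = "all_groups",
) -> HweFilterResult:
    """Remove SNPs out of Hardy-Weinberg equilibrium within subpopulations.

    ``rule="all_groups"`` removes a SNP only when it fails (p < alpha) in
    every subpopulation; ``rule="any_group"`` when it fails in at least
    one.  Populations with fewer than two samples are skipped with a
    warning and do not count toward either rule.
    """
    if rule not in ("all_groups", "any_group"):
        raise ValueError(f"unknown hwe rule {rule!r}")
    populations = pd.Series(populations).astype(str)
    if len(populations) != gm.n_samples:
        raise ValueError("population labels do not match sample count")
    groups = []
    for pop, idx in populations.groupby(populations).groups.items():
        if len(idx) < 2:
            log.warning("population %s has <2 samples; skipped in HWE filter", pop)
            continue
        pos = populations.index.get_indexer(idx)
        groups.append((pop, np.asarray(pos)))
    if not groups:
        raise ValueError("no subpopulation with >=2 samples")

    pvals = {}
    for pop, rows in groups:
        sub = gm.dosages[rows]
        col = np.empty(gm.n_snps)
        for j in range(gm.n_snps):
            col[j] = hwe_exact_test(*genotype_counts(sub[:, j]))
        pvals[pop] = col
    pdf = pd.DataFrame(pvals, index=gm.snp_ids)

    fails = pdf < alpha
    if rule == "all_groups":
        remove = fails.all(axis=1)
    else:
        remove = fails.any(axis=1)
    removed = list(pdf.index[remove])
    kept = list(pdf.index[~remove])
    for snp in removed:
        log.info("HWE removal %s: %s", snp, pdf.loc[snp].to_dict())
    log.info("HWE filter removed %d of %d SNPs (rule=%s, alpha=%g)",
             len(removed), gm.n_snps, rule, alpha)
    return HweFilterResult(kept, removed, pdf)


@dataclass
class SnpTestResult:
    beta: float
    se: float
    z: float
    p: float
    odds_ratio: float
    ok: bool


def univariate_snp_test(
    dosage: np.ndarray,
    affected: np.ndarray,
    covariates: np.ndarray | None = None,
) -> SnpTestResult:
    """Logistic regression of affection on one SNP's dosage.

    With ``covariates`` (a no-intercept design block) the fit is adjusted.
    Non-convergent or separated fits come back flagged (``ok=False``) with
    the p-value missing.  Missing dosages drop the sample from this fit.
    """
    dosage = np.asarray(dosage, dtype=float)
    affected = np.asarray(affected, dtype=float)
    keep = ~np.isnan(dosage)
    dosage, affected = dosage[keep], affected[keep]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)[keep]
    if len(np.unique(affected)) < 2:
        raise ValueError("affection status has a single class")
    if np.ptp(dosage) == 0:
        raise ValueError("degenerate predictor: constant dosage column")
    X = add_intercept(dosage) if covariates is None else add_intercept(dosage, covariates)
    fit = fit_logit(affected, X)
    beta, se, z, p, or_ = fit.wald(1)
    return SnpTestResult(beta, se, z, p, or_, fit.ok)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def qc_report(
    gm: GenotypeMatrix,
    covariates: pd.DataFrame,
    alpha: float = 1e-6,
    rule: str = "all_groups",
    run_univariate: bool = True,
    adjusted: bool = False,
    covariate_design: np.ndarray | None = None,
) -> tuple[pd.DataFrame, HweFilterResult]:
    """Full per-SNP QC table: MAF, genotype counts, HWE p per population,
    keep flag, and (optionally) the univariate screen."""
    maf = maf_table(gm)
    hwe = hwe_filter(gm, covariates["population"], alpha=alpha, rule=rule)
    rows = []
    y = covariates["affected"].to_numpy(dtype=float)
    for j, snp in enumerate(gm.snp_ids):
        d = gm.dosages[:, j]
        n0, n1, n2 = genotype_counts(d)
        rec = {
            "snp": snp,
            "maf": maf[snp],
            "n_hom_major": n0,
            "n_het": n1,
            "n_hom_minor": n2,
            "keep": snp in set(hwe.kept),
        }
        for pop in hwe.p_values.columns:
            rec[f"hwe_p_{pop}"] = hwe.p_values.loc[snp, pop]
        if run_univariate:
            try:
                t = univariate_snp_test(
                    d, y, covariate_design if adjusted else None
                )
                rec.update(uni_beta=t.beta, uni_se=t.se, uni_z=t.z,
                           uni_p=t.p, uni_or=t.odds_ratio, uni_ok=t.ok)
            except ValueError:
                rec.update(uni_beta=np.nan, uni_se=np.nan, uni_z=np.nan,
                           uni_p=np.nan, uni_or=np.nan, uni_ok=False)
        rows.append(rec)
    return pd.DataFrame(rows), hwe
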