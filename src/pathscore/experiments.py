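"""Canned simulation experiments for calibration and power checks.

Each function generates data with :mod:`pathscore.simulate`, runs the
analysis pipeline, and summarizes one operating characteristic of the
method.  The same recipes back the test suite and the reproduction
script, so the study conditions live in one place:

* :func:`null_calibration` — global-null type-I error of the combined
  pathway test (700 samples, 500 overlapping pathways, 3 populations).
* :func:`causal_recovery` — how often the single causal pathway attains
  the smallest combined-test p among 50 pathways (1,000 samples,
  per-allele log-OR 0.4 for the 10 causal rare and 0.5 for the 3 causal
  common variants).
* :func:`mediation_lrt` — whether the score-adjusted likelihood-ratio
  test stays null when population prevalence differences are entirely
  mediated by causal-pathway allele-frequency drift (3,000 samples).

Per-replicate seeds are ``seed + rep``.
"""

from __future__ import annotations

import numpy as np

from pathscore.config import RunConfig
from pathscore.pipeline import analyze_dataset
from pathscore.simulate import (
    CausalPathwaySpec,
    SimulationConfig,
    simulate_dataset,
)

#: causal architecture used by the recovery and mediation experiments
DEFAULT_CAUSAL = CausalPathwaySpec(
    "PW0001", rare_log_or=0.4, common_log_or=0.5,
    n_causal_rare=10, n_causal_common=3,
)


def null_calibration(seed: int = 0, n_pathways: int = 500,
                     n_samples: int = 700, alpha: float = 0.05) -> dict:
    """Rejection rate of the combined unadjusted test under a global null.

    The rate counts a pathway as rejected when its combined score is
    testable and the asymptotic p falls below ``alpha``; pathways whose
    score is gated to a constant are never flagged by the pipeline and
    count as non-rejections.
    """
    cfg = SimulationConfig(
        n_samples=n_samples,
        n_genes=int(1.6 * n_pathways),
        mean_snps_per_gene=3.0,
        n_pathways=n_pathways,
        genes_per_pathway=(5, 12),
        seed=seed,
    )
    ds = simulate_dataset(cfg)
    rc = RunConfig(run_univariate=False)
    res = analyze_dataset(ds.genotypes, ds.annotation, ds.gmt, ds.covariates, rc)
    ps = np.array(
        [r.p for r in res.association
         if r.model == "combined_unadj" and np.isfinite(r.p)]
    )
    n_all = len(res.pathways)
    return {
        "rejections": int((ps < alpha).sum()),
        "n_pathways": n_all,
        "n_tested": int(ps.size),
        "rate": float((ps < alpha).sum() / n_all),
        "rate_among_tested": float((ps < alpha).mean()) if ps.size else np.nan,
        "hwe_removed_fraction": float(
            (~res.qc_table["keep"]).sum() / len(res.qc_table)
        ),
    }


def causal_recovery(seed: int = 1000, n_reps: int = 25) -> dict:
    """Fraction of replicates in which the causal pathway ranks first by
    combined-test p among 50 pathways."""
    wins = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_samples=1000,
            n_genes=350,
            mean_snps_per_gene=3.5,
            n_pathways=50,
            genes_per_pathway=(6, 12),
            causal_pathways=[DEFAULT_CAUSAL],
            reserve_causal_genes=True,
            seed=seed + rep,
        )
        ds = simulate_dataset(cfg)
        rc = RunConfig(run_univariate=False)
        res = analyze_dataset(ds.genotypes, ds.annotation, ds.gmt,
                              ds.covariates, rc)
        fam = {r.pathway: r.p for r in res.association
               if r.model == "combined_unadj" and np.isfinite(r.p)}
        if fam and min(fam, key=fam.get) == DEFAULT_CAUSAL.pathway:
            wins += 1
    return {"wins": wins, "n_reps": n_reps, "fraction": wins / n_reps}


def mediation_lrt(seed: int = 3000, n_reps: int = 25) -> dict:
    """Fraction of replicates with score-adjusted population LRT p > 0.05.

    Population offsets are zero, so any prevalence difference between
    populations is mediated entirely by allele-frequency drift at the
    causal variants.  The genetic risk score handed to the LRT is the
    causal pathway's *continuous* combined score: the mediation question
    asks how much genetic risk the samples carry, and the dichotomized
    default deliberately discards within-group variation.
    """
    from pathscore.pathways import map_snps_to_pathways
    from pathscore.population import lrt_population_given_score
    from pathscore.qc import hwe_filter, maf_table
    from pathscore.regression import covariate_design
    from pathscore.scores import score_pathway

    nonsig = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_samples=3000,
            n_genes=80,
            mean_snps_per_gene=5.0,
            n_pathways=10,
            genes_per_pathway=(6, 10),
            causal_pathways=[DEFAULT_CAUSAL],
            reserve_causal_genes=True,
            seed=seed + rep,
        )
        ds = simulate_dataset(cfg)
        cov = ds.covariates
        maf = maf_table(ds.genotypes)
        hwe = hwe_filter(ds.genotypes, cov["population"])
        coll = map_snps_to_pathways(ds.annotation, ds.gmt, hwe.kept, maf)
        lasso_cov = covariate_design(cov, include_traits=True)
        ps = score_pathway(
            ds.genotypes,
            coll[DEFAULT_CAUSAL.pathway],
            cov["affected"].to_numpy(float),
            lasso_cov,
            combine_mode="continuous",
        )
        lrt = lrt_population_given_score(
            cov["affected"], cov["population"], ps.rs_final
        )
        nonsig += bool(lrt.p > 0.05)
    return {"nonsignificant": nonsig, "n_reps": n_reps,
            "fraction": nonsig / n_reps}
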