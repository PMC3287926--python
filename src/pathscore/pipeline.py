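"""End-to-end orchestration: QC -> pathway mapping -> scoring -> tests.

:func:`analyze_dataset` works on in-memory objects; :func:`run_pipeline`
wraps it with file I/O and writes the result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pathscore import association as assoc
from pathscore import io, population, qc
from pathscore.config import RunConfig
from pathscore.io import GenotypeMatrix
from pathscore.pathways import PathwayCollection, map_snps_to_pathways
from pathscore.regression import covariate_design
from pathscore.scores import PathwayScores, score_pathway

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    qc_table: pd.DataFrame
    pathways: PathwayCollection
    scores: dict[str, PathwayScores]
    association: list[assoc.AssociationResult]
    association_table: pd.DataFrame
    significance: pd.DataFrame
    population_report: pd.DataFrame
    empirical_null: assoc.EmpiricalNull | None


def analyze_dataset(
    gm: GenotypeMatrix,
    annotation: pd.DataFrame,
    gmt: list[tuple[str, str, list[str]]],
    covariates: pd.DataFrame,
    cfg: RunConfig,
) -> AnalysisResult:
    """Run the full pathway-association analysis on one dataset."""
    if list(covariates["sample_id"]) != list(gm.sample_ids):
        covariates = (
            covariates.set_index("sample_id").loc[gm.sample_ids].reset_index()
        )
    y = covariates["affected"].to_numpy(dtype=float)
    cov_block = covariate_design(
        covariates, cfg.covariate_list, include_traits=False
    )
    lasso_cov = covariate_design(
        covariates, cfg.covariate_list, include_traits=cfg.include_traits
    )

    log.info("stage qc: %d SNPs, %d samples", gm.n_snps, gm.n_samples)
    try:
        qc_table, hwe = qc.qc_report(
            gm,
            covariates,
            alpha=cfg.hwe_alpha,
            rule=cfg.hwe_rule,
            run_univariate=cfg.run_univariate,
            adjusted=cfg.adjust_covariates,
            covariate_design=cov_block,
        )
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc
    log.info("stage qc: removed %d SNPs by HWE", len(hwe.removed))

    maf = qc_table.set_index("snp")["maf"]
    try:
        collection = map_snps_to_pathways(
            annotation,
            gmt,
            hwe.kept,
            maf,
            min_genes=cfg.min_genes_per_pathway,
            maf_threshold=cfg.maf_threshold,
        )
    except Exception as exc:
        raise RuntimeError(f"stage pathway_model failed: {exc}") from exc
    log.info("stage pathway_model: %d pathways retained", len(collection))
    if cfg.top_k >= len(collection):
        raise ValueError(
            f"top_k exceeds pathway count: k={cfg.top_k}, pathways={len(collection)}"
        )

    scores: dict[str, PathwayScores] = {}
    results: list[assoc.AssociationResult] = []
    for pw in collection:
        try:
            ps = score_pathway(
                gm,
                pw,
                y,
                lasso_cov,
                rare_score_mode=cfg.rare_score_mode,
                combine_mode=cfg.combine_mode,
                lambda_rule=cfg.lasso_lambda_rule,
                n_folds=cfg.lasso_n_folds,
                n_lambda=cfg.lasso_n_lambda,
                seed=cfg.seed,
            )
        except Exception as exc:
            raise RuntimeError(f"stage risk_scores failed at {pw.name}: {exc}") from exc
        scores[pw.name] = ps
        if np.ptp(ps.rs_rare) > 0:
            results.append(
                assoc.pathway_test(ps.rs_rare, y, pathway=pw.name, model="rare_unadj")
            )
        if ps.rs_common is not None and np.ptp(ps.rs_common) > 0:
            results.append(
                assoc.pathway_test(
                    ps.rs_common, y, pathway=pw.name, model="common_unadj"
                )
            )
        if ps.testable:
            results.append(
                assoc.pathway_test(
                    ps.rs_final, y, pathway=pw.name, model="combined_unadj"
                )
            )
            if cfg.adjust_covariates:
                results.append(
                    assoc.pathway_test(
                        ps.rs_final,
                        y,
                        covariates=cov_block,
                        pathway=pw.name,
                        model="combined_adj",
                    )
                )

    null = None
    n_combined = sum(1 for r in results if r.model == "combined_unadj"
                     and np.isfinite(r.z))
    if n_combined > cfg.top_k:
        null = assoc.attach_empirical_pvalues(results, cfg.top_k, "combined_unadj")
    else:
        log.warning("too few testable pathways for the empirical null (k=%d)",
                    cfg.top_k)

    table = assoc.results_table(results)
    signif = assoc.significance_report(results)
    pop_report = population.population_report(
        covariates, {n: s.rs_final for n, s in scores.items() if s.testable}
    )
    return AnalysisResult(
        qc_table, collection, scores, results, table, signif, pop_report, null
    )


def run_pipeline(cfg: RunConfig, paths: dict, outdir) -> AnalysisResult:
    """File-level entry point.

    ``paths`` needs keys genotypes / annotation / gmt / covariates (and
    optionally ``dialect`` for the genotype file).  Writes result tables
    under ``outdir``: qc_report.tsv, pathway_manifest.tsv, scores_*.tsv,
    association.tsv, significance.tsv, population_report.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = io.read_genotypes(paths["genotypes"], paths.get("dialect", "tsv"))
    annotation = io.read_annotation(paths["annotation"])
    gmt = io.read_gmt(paths["gmt"])
    covariates = io.read_covariates(paths["covariates"])

    res = analyze_dataset(gm, annotation, gmt, covariates, cfg)

    ctext = cfg.to_text()
    io.write_table(res.qc_table, outdir / "qc_report.tsv", ctext)
    io.write_table(res.pathways.manifest(), outdir / "pathway_manifest.tsv", ctext)
    for kind in ("rare", "common", "final"):
        mat = pd.DataFrame(
            {
                name: getattr(s, f"rs_{kind}")
                for name, s in res.scores.items()
                if getattr(s, f"rs_{kind}") is not None
            },
            index=gm.sample_ids,
        )
        mat.index.name = "sample_id"
        io.write_table(mat, outdir / f"scores_{kind}.tsv", ctext, index=True)
    meta = pd.DataFrame(
        {
            "pathway": list(res.scores),
            "or_rare": [s.or_rare.odds_ratio for s in res.scores.values()],
            "median_rare": [s.or_rare.median for s in res.scores.values()],
            "or_common": [
                s.or_common.odds_ratio if s.or_common else np.nan
                for s in res.scores.values()
            ],
            "median_common": [
                s.or_common.median if s.or_common else np.nan
                for s in res.scores.values()
            ],
            "n_selected": [len(s.selected_snps) for s in res.scores.values()],
            "selected_snps": [
                ",".join(s.selected_snps) for s in res.scores.values()
            ],
            "directions": [
                ",".join(f"{k}:{v}" for k, v in s.directions.items())
                for s in res.scores.values()
            ],
            "testable": [s.testable for s in res.scores.values()],
        }
    )
    io.write_table(meta, outdir / "score_metadata.tsv", ctext)
    io.write_table(res.association_table, outdir / "association.tsv", ctext)
    io.write_table(res.significance, outdir / "significance.tsv", ctext)
    io.write_table(res.population_report, outdir / "population_report.tsv", ctext)
    return res
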