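"""Pathway-level association tests and the empirical-null correction.

The combined risk score of each pathway is tested by logistic regression
(unadjusted, and adjusted for age, sex, smoking and population).  Because
the score was built with data-driven selection (LASSO, risk-allele
alignment, OR gating), the asymptotic p-values of the top pathways are
optimistic.  The correction ranks pathways by |Z|, treats all Z
statistics *except* the top k as draws from the null, and recomputes
p-values for the top k as two-sided empirical tail probabilities against
that null set (with an add-one correction, so the smallest attainable
empirical p is 1/(n_null + 1)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathscore.regression import add_intercept, fit_logit

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    pathway: str
    model: str  # rare_unadj | common_unadj | combined_unadj | combined_adj
    beta: float
    se: float
    z: float
    p: float
    odds_ratio: float
    ok: bool
    p_empirical: float | None = None


def pathway_test(
    rs: np.ndarray,
    affected: np.ndarray,
    covariates: np.ndarray | None = None,
    pathway: str = "",
    model: str = "combined_unadj",
) -> AssociationResult:
    """Wald test of a per-sample risk score against affection status."""
    rs = np.asarray(rs, dtype=float)
    y = np.asarray(affected, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("affection status has a single class")
    if np.ptp(rs) == 0:
        raise ValueError("risk score is constant; pathway untestable")
    X = add_intercept(rs) if covariates is None else add_intercept(rs, covariates)
    fit = fit_logit(y, X)
    beta, se, z, p, or_ = fit.wald(1)
    return AssociationResult(pathway, model, beta, se, z, p, or_, fit.ok)


@dataclass
class EmpiricalNull:
    null_z: np.ndarray
    top: list[str]  # pathway names ranked most to least extreme
    k: int
    ranking: str = "abs_z"


def build_empirical_null(
    z_by_pathway: dict[str, float], k: int, ranking: str = "abs_z"
) -> EmpiricalNull:
    """Split Z statistics into the top-k set and the empirical null.

    Non-finite Z values are excluded (with a warning) before ranking.
    """
    if ranking != "abs_z":
        raise ValueError(f"unknown ranking {ranking!r}")
    finite = {p: z for p, z in z_by_pathway.items() if np.isfinite(z)}
    dropped = len(z_by_pathway) - len(finite)
    if dropped:
        warnings.warn(f"{dropped} non-finite Z value(s) excluded from the null")
    if len(finite) <= k:
        raise ValueError(
            f"top_k exceeds pathway count: k={k}, tested pathways={len(finite)}"
        )
    order = sorted(finite, key=lambda p: abs(finite[p]), reverse=True)
    top = order[:k]
    null = np.array([finite[p] for p in order[k:]])
    if null.size < 20:
        warnings.warn(f"unstable null: only {null.size} pathway(s) in the null set")
    return EmpiricalNull(null, top, k, ranking)


def empirical_pvalue(z_obs: float, null: EmpiricalNull) -> float:
    """Two-sided empirical tail probability with add-one correction:
    ``p = (#{|z_null| >= |z_obs|} + 1) / (n_null + 1)``."""
    if null.null_z.size == 0:
        raise ValueError("empty empirical null")
    count = int(np.sum(np.abs(null.null_z) >= abs(z_obs)))
    return (count + 1) / (null.null_z.size + 1)


def attach_empirical_pvalues(
    results: list[AssociationResult], k: int, model: str = "combined_unadj"
) -> EmpiricalNull:
    """Compute empirical p-values in place for the top-k pathways of one
    model family; returns the null that was used."""
    fam = [r for r in results if r.model == model]
    z = {r.pathway: r.z for r in fam}
    null = build_empirical_null(z, k)
    by_name = {r.pathway: r for r in fam}
    for name in null.top:
        by_name[name].p_empirical = empirical_pvalue(by_name[name].z, null)
    return null


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Wide per-pathway table: (p, OR) per model family plus empirical p."""
    df = pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "model": [r.model for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ok": [r.ok for r in results],
            "p_empirical": [r.p_empirical for r in results],
        }
    )
    wide = df.pivot(index="pathway", columns="model")
    wide.columns = [f"{stat}_{model}" for stat, model in wide.columns]
    keep = [c for c in wide.columns if not c.startswith(("beta_", "se_", "ok_"))]
    keep = [c for c in keep if not (c.startswith("p_empirical") and wide[c].isna().all())]
    return wide[keep].reset_index()


def significance_report(
    results: list[AssociationResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni flags per model family.

    The threshold divides alpha by the number of pathways actually tested
    in that family (pathways without a usable score never entered the
    family and do not count).  Families with no tested pathway are
    omitted with a log note.  Rows are sorted by the combined adjusted p
    when available.
    """
    if not results:
        raise ValueError("no association results")
    frames = []
    for model in ("rare_unadj", "common_unadj", "combined_unadj", "combined_adj"):
        fam = [r for r in results if r.model == model and np.isfinite(r.p)]
        if not fam:
            log.info("model family %s omitted: no testable pathway", model)
            continue
        thr = alpha / len(fam)
        frames.append(
            pd.DataFrame(
                {
                    "pathway": [r.pathway for r in fam],
                    "model": model,
                    "p": [r.p for r in fam],
                    "odds_ratio": [r.odds_ratio for r in fam],
                    "n_tested": len(fam),
                    "bonferroni_threshold": thr,
                    "significant": [r.p < thr for r in fam],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    adj = out[out["model"] == "combined_adj"].set_index("pathway")["p"]
    out["sort_key"] = out["pathway"].map(adj).fillna(np.inf)
    out = out.sort_values(["sort_key", "pathway", "model"]).drop(columns="sort_key")
    return out.reset_index(drop=True)
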