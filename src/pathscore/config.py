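"""Run configuration shared by the CLI and the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """Analysis constants.

    Defaults follow standard practice for this design: 1% MAF divides rare
    from common variants, per-subpopulation Hardy-Weinberg exact-test
    filtering at ``p < 1e-6``, pathways need at least five mappable genes,
    and empirical p-values are computed for the top ``k = 10`` pathways.
    """

    maf_threshold: float = 0.01
    hwe_alpha: float = 1e-6
    hwe_rule: str = "all_groups"  # remove iff failing in every subpopulation
    min_genes_per_pathway: int = 5
    rare_score_mode: str = "count"  # or "proportion"
    lasso_lambda_rule: str = "cv_1se"  # or "cv" (minimum-deviance)
    lasso_n_folds: int = 10
    lasso_n_lambda: int = 15
    combine_mode: str = "indicator"  # or "continuous"
    top_k: int = 10
    adjust_covariates: bool = True
    covariate_list: tuple[str, ...] = ("age", "sex", "smoke", "population")
    include_traits: bool = True  # q1-q3 enter the LASSO covariate block
    run_univariate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 1:
            raise ValueError("maf_threshold must be in (0,1)")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must be in (0,1)")
        if self.hwe_rule not in ("all_groups", "any_group"):
            raise ValueError(f"unknown hwe_rule {self.hwe_rule!r}")
        if self.rare_score_mode not in ("count", "proportion"):
            raise ValueError(f"unknown rare_score_mode {self.rare_score_mode!r}")
        if self.combine_mode not in ("indicator", "continuous"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if self.lasso_lambda_rule not in ("cv", "cv_1se"):
            raise ValueError(f"unknown lasso_lambda_rule {self.lasso_lambda_rule!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_genes_per_pathway < 1:
            raise ValueError("min_genes_per_pathway must be >= 1")

    def to_text(self) -> str:
        d = asdict(self)
        d["covariate_list"] = list(self.covariate_list)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat key/value file; unknown keys are an error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "covariate_list" in raw:
            raw["covariate_list"] = tuple(raw["covariate_list"])
        return cls(**raw)
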