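"""Synthetic mini-exome generator with known ground truth.

Emulates the structure of an exome-array case-control study of ~700
unrelated individuals drawn from three continental populations (Asian,
African, European): a rare-dominated minor-allele-frequency spectrum,
SNPs annotated to one gene each, genes grouped into overlapping
pathways, allele-frequency divergence between populations under the
Balding-Nichols model, and a logistic disease model in which causal SNPs
are confined to designated causal pathways.

The generator is fully deterministic for a fixed config + seed and
writes the exact file formats the analysis pipeline reads, so every
downstream module can be exercised, calibrated and power-tested without
restricted study data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pathscore import io
from pathscore.io import GenotypeMatrix


@dataclass
class PopulationSpec:
    name: str
    proportion: float
    fst: float = 0.1  # Balding-Nichols divergence from the ancestral pool


@dataclass
class MafSpectrum:
    """Mixture of rare and common ancestral MAFs, log-uniform in each band."""

    rare_fraction: float = 0.75
    rare_range: tuple[float, float] = (5e-4, 0.01)
    common_range: tuple[float, float] = (0.01, 0.5)

    def validate(self) -> None:
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0,1]")
        for lo, hi in (self.rare_range, self.common_range):
            if not (0.0 < lo < hi <= 0.5):
                raise ValueError("MAF bounds must satisfy 0 < lo < hi <= 0.5")


@dataclass
class CausalPathwaySpec:
    """Causal effects placed inside one pathway.

    ``rare_log_or`` / ``common_log_or`` are per-minor-allele log odds
    ratios applied to each causal SNP's dosage.  Causal common SNPs are
    drawn from the pathway's common variants with ancestral MAF at least
    ``common_min_maf`` so the planted effect is detectable at realistic
    sample sizes.
    """

    pathway: str
    rare_log_or: float = 0.4
    common_log_or: float = 0.5
    n_causal_rare: int = 8
    n_causal_common: int = 2
    common_min_maf: float = 0.05


@dataclass
class CovariateEffects:
    """Log-OR contributions of the clinical covariates to the disease logit.

    ``age`` is per 10 years above 55; ``population`` maps population name
    to a direct (non-genetic) logit offset.
    """

    age: float = 0.0
    sex: float = 0.0
    smoke: float = 0.0
    population: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_samples: int = 700
    n_genes: int = 350
    mean_snps_per_gene: float = 4.0
    n_pathways: int = 100
    genes_per_pathway: tuple[int, int] = (5, 40)
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("Asian", 0.35, 0.1),
            PopulationSpec("African", 0.25, 0.1),
            PopulationSpec("European", 0.40, 0.1),
        ]
    )
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    causal_pathways: list[CausalPathwaySpec] = field(default_factory=list)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    baseline_logit: float = -0.85  # prevalence ~0.30 under the null
    trait_loadings: tuple[float, float, float] = (0.0, 0.0, 0.0)
    liability_weight: float = 0.0  # shared latent term linking traits & disease
    smoking_prevalence: float = 0.3
    #: when True, genes drawn into causal pathways are withheld from the
    #: sampling pool of the remaining pathways, so pathway-level ground
    #: truth is unambiguous (used by truth-recovery experiments; real
    #: collections overlap, hence default False)
    reserve_causal_genes: bool = False
    #: emulate variant-panel ascertainment: SNPs monomorphic in the
    #: generated sample get their drifted frequencies and genotypes
    #: redrawn (bounded attempts), as listed sites were by definition
    #: observed segregating.  Without this, Balding-Nichols drift at
    #: tiny ancestral MAFs loses most rare alleles in every population.
    ascertain_segregating: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p.proportion for p in self.populations)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"population proportions sum to {total}, not 1")
        for p in self.populations:
            if not 0.0 <= p.fst < 1.0:
                raise ValueError("fst must lie in [0, 1)")
        self.maf_spectrum.validate()
        lo, hi = self.genes_per_pathway
        if lo < 1 or hi < lo:
            raise ValueError("invalid genes_per_pathway range")
        if hi > self.n_genes:
            raise ValueError("genes_per_pathway max exceeds n_genes")


@dataclass
class SimulationTruth:
    causal_pathways: list[str]
    causal_snps: pd.DataFrame  # snp, gene, pathway, class, log_or
    ancestral_freq: pd.Series
    population_freq: pd.DataFrame  # SNP x population
    prevalence_by_population: dict[str, float]
    population_of_sample: pd.Series


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    annotation: pd.DataFrame
    gmt: list[tuple[str, str, list[str]]]
    covariates: pd.DataFrame
    truth: SimulationTruth
    config: SimulationConfig


def _draw_ancestral_maf(spectrum: MafSpectrum, n: int, rng) -> np.ndarray:
    """Ancestral MAFs: log-uniform within each band, rare band dominant."""
    is_rare = rng.random(n) < spectrum.rare_fraction
    out = np.empty(n)
    for mask, (lo, hi) in ((is_rare, spectrum.rare_range),
                           (~is_rare, spectrum.common_range)):
        k = int(mask.sum())
        out[mask] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))
    return out


def draw_allele_frequencies(
    config: SimulationConfig, n_snps: int, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ancestral and per-population allele frequencies.

    Population frequencies follow the Balding-Nichols model: given an
    ancestral frequency p0 and divergence F, the drifted frequency is
    Beta(p0(1-F)/F, (1-p0)(1-F)/F); F = 0 reproduces p0 exactly.
    """
    p0 = _draw_ancestral_maf(config.maf_spectrum, n_snps, rng)
    cols = _drift_frequencies(p0, config.populations, rng)
    freq = pd.DataFrame(cols, index=[f"SNP{j + 1:06d}" for j in range(n_snps)])
    return p0, freq


def _drift_frequencies(
    p0: np.ndarray, populations: list[PopulationSpec], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    cols = {}
    for pop in populations:
        if pop.fst == 0.0:
            cols[pop.name] = p0.copy()
            continue
        ratio = (1.0 - pop.fst) / pop.fst
        a, b = p0 * ratio, (1.0 - p0) * ratio
        if not (np.all(np.isfinite(a)) and np.all(a > 0) and np.all(b > 0)):
            raise ValueError("ancestral frequency at 0 or 1: Beta undefined")
        cols[pop.name] = rng.beta(a, b)
    return cols


def generate_genotypes(
    freq: pd.DataFrame, pop_of_sample: pd.Series, rng: np.random.Generator
) -> GenotypeMatrix:
    """Binomial(2, p_pop) dosages per sample; Hardy-Weinberg holds within
    each population by construction."""
    n = len(pop_of_sample)
    dosages = np.empty((n, freq.shape[0]))
    for pop in freq.columns:
        rows = np.flatnonzero((pop_of_sample == pop).to_numpy())
        if rows.size == 0:
            continue
        p = freq[pop].to_numpy()
        dosages[rows] = rng.binomial(2, p, size=(rows.size, freq.shape[0]))
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, list(freq.index), dosages)


def generate_pathways(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, str, list[str]]], pd.DataFrame, int]:
    """Gene-set (GMT) records plus a SNP->gene annotation table.

    Every SNP belongs to exactly one gene (SNP counts per gene are
    Poisson, truncated at one); pathways sample genes without
    replacement and may overlap.  Returns the total SNP count too.
    """
    genes = [f"GENE{g + 1:04d}" for g in range(config.n_genes)]
    snps_per_gene = np.maximum(
        1, rng.poisson(config.mean_snps_per_gene, size=config.n_genes)
    )
    ann_rows = []
    snp_no = 0
    for g, gene in enumerate(genes):
        for _ in range(snps_per_gene[g]):
            snp_no += 1
            ann_rows.append(
                {"snp": f"SNP{snp_no:06d}", "chr": str(g % 22 + 1), "gene": gene}
            )
    annotation = pd.DataFrame(ann_rows)

    lo, hi = config.genes_per_pathway
    causal_ids = {c.pathway for c in config.causal_pathways}
    reserved: set[str] = set()
    gmt = []
    for p in range(config.n_pathways):
        name = f"PW{p + 1:04d}"
        pool = genes
        if config.reserve_causal_genes and name not in causal_ids:
            pool = [g for g in genes if g not in reserved]
        size = int(rng.integers(lo, hi + 1))
        if size > len(pool):
            raise ValueError(f"{name}: pathway size {size} exceeds gene pool")
        members = sorted(rng.choice(pool, size=size, replace=False))
        if config.reserve_causal_genes and name in causal_ids:
            reserved.update(members)
        gmt.append((name, f"synthetic pathway {p + 1}", members))
    return gmt, annotation, snp_no


def _assign_causal_snps(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    gmt: list[tuple[str, str, list[str]]],
    p0: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pick causal SNPs inside each designated causal pathway.

    Causal variants are drawn preferentially from genes *private* to the
    designated pathway (genes that belong to no other generated set), so
    that the pathway-level ground truth stays unambiguous under pathway
    overlap.  Each quota is filled greedily across preference tiers —
    private genes at the causal-common MAF floor, private genes at the
    rare/common threshold, then the pathway's shared genes — and only
    errors when the whole pathway cannot supply the quota.
    """
    maf_thr = 0.01
    p0_by_snp = pd.Series(p0, index=annotation["snp"].to_numpy())
    gmt_by_name = {name: genes for name, _, genes in gmt}
    membership: dict[str, int] = {}
    for _, _, genes in gmt:
        for g in genes:
            membership[g] = membership.get(g, 0) + 1
    rows = []
    for spec in config.causal_pathways:
        if spec.pathway not in gmt_by_name:
            raise ValueError(f"causal pathway {spec.pathway!r} not generated")
        all_genes = set(gmt_by_name[spec.pathway])
        private = {g for g in all_genes if membership[g] == 1}

        floor = max(maf_thr, spec.common_min_maf)
        shared = all_genes - private

        def _pool(genes: set, kind: str, lo: float = 0.0) -> list[str]:
            snps = annotation[annotation["gene"].isin(genes)]
            p0_here = p0_by_snp.loc[snps["snp"]].to_numpy()
            keep = p0_here < maf_thr if kind == "rare" else p0_here >= lo
            return snps.loc[keep, "snp"].tolist()

        def _fill(tiers: list[list[str]], want: int, label: str) -> list[str]:
            chosen: list[str] = []
            for pool in tiers:
                pool = [s for s in pool if s not in chosen]
                take = min(want - len(chosen), len(pool))
                if take > 0:
                    chosen.extend(rng.choice(pool, take, replace=False).tolist())
                if len(chosen) == want:
                    return chosen
            raise ValueError(
                f"{spec.pathway}: only {len(chosen)} {label} SNPs available "
                f"for {want} causal"
            )

        chosen_r = _fill(
            [_pool(private, "rare"), _pool(shared, "rare")],
            spec.n_causal_rare, "rare",
        )
        chosen_c = _fill(
            [
                _pool(private, "common", floor),
                _pool(private, "common", maf_thr),
                _pool(shared, "common", floor),
                _pool(shared, "common", maf_thr),
            ],
            spec.n_causal_common, "common",
        )
        gene_of = annotation.set_index("snp")["gene"]
        for s in chosen_r:
            rows.append({"snp": s, "gene": gene_of[s], "pathway": spec.pathway,
                         "class": "rare", "log_or": spec.rare_log_or})
        for s in chosen_c:
            rows.append({"snp": s, "gene": gene_of[s], "pathway": spec.pathway,
                         "class": "common", "log_or": spec.common_log_or})
    return pd.DataFrame(rows, columns=["snp", "gene", "pathway", "class", "log_or"])


def generate_phenotypes(
    gm: GenotypeMatrix,
    causal: pd.DataFrame,
    pop_of_sample: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Covariates and a logistic disease outcome.

    logit P(affected) = baseline + sum_j beta_j * dosage_j
                      + age/sex/smoke effects + population offsets
                      + liability_weight * h,
    where h ~ N(0,1) is a latent liability shared with the quantitative
    traits q1..q3 (q_k = loading_k * h + noise).
    """
    n = gm.n_samples
    eff = config.covariate_effects
    age = np.clip(np.round(rng.normal(55, 12, size=n)), 20, 90).astype(int)
    sex = rng.binomial(1, 0.5, size=n)
    smoke = rng.binomial(1, config.smoking_prevalence, size=n)
    h = rng.normal(size=n)
    traits = {
        f"q{k + 1}": config.trait_loadings[k] * h + rng.normal(size=n)
        for k in range(3)
    }

    logit = np.full(n, config.baseline_logit, dtype=float)
    if len(causal):
        G_causal = gm.columns(causal["snp"].tolist())
        logit += G_causal @ causal["log_or"].to_numpy(dtype=float)
    logit += eff.age * (age - 55) / 10.0
    logit += eff.sex * sex
    logit += eff.smoke * smoke
    offsets = pop_of_sample.map(lambda p: eff.population.get(p, 0.0)).to_numpy(float)
    logit += offsets
    logit += config.liability_weight * h
    affected = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))

    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "affected": affected,
            "age": age,
            "sex": sex,
            "smoke": smoke,
            "population": pop_of_sample.to_numpy(),
            **traits,
        }
    )


def _ascertain_segregating(
    gm: GenotypeMatrix,
    freq: pd.DataFrame,
    p0: np.ndarray,
    pop_of_sample: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_rounds: int = 25,
) -> None:
    """Redraw drifted frequencies + genotypes for sample-monomorphic SNPs.

    Mutates ``gm.dosages`` and ``freq`` in place.  A SNP that stays
    monomorphic after ``max_rounds`` redraws is left as drawn (it will
    be excluded downstream as uninformative).
    """
    pop_rows = {
        pop.name: np.flatnonzero((pop_of_sample == pop.name).to_numpy())
        for pop in config.populations
    }
    for _ in range(max_rounds):
        mono = np.flatnonzero(np.ptp(gm.dosages, axis=0) == 0)
        if mono.size == 0:
            return
        cols = _drift_frequencies(p0[mono], config.populations, rng)
        for pop in freq.columns:
            freq.iloc[mono, freq.columns.get_loc(pop)] = cols[pop]
            rows = pop_rows[pop]
            if rows.size:
                gm.dosages[np.ix_(rows, mono)] = rng.binomial(
                    2, cols[pop], size=(rows.size, mono.size)
                )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator; deterministic for a fixed config + seed."""
    rng = np.random.default_rng(config.seed)
    gmt, annotation, n_snps = generate_pathways(config, rng)
    p0, freq = draw_allele_frequencies(config, n_snps, rng)

    props = np.array([p.proportion for p in config.populations])
    counts = np.floor(props * config.n_samples).astype(int)
    counts[-1] = config.n_samples - counts[:-1].sum()
    pop_of_sample = pd.Series(
        np.repeat([p.name for p in config.populations], counts), name="population"
    )

    gm = generate_genotypes(freq, pop_of_sample, rng)
    if config.ascertain_segregating:
        _ascertain_segregating(gm, freq, p0, pop_of_sample, config, rng)
    causal = _assign_causal_snps(config, annotation, gmt, p0, rng)
    cov = generate_phenotypes(gm, causal, pop_of_sample, config, rng)

    prev = (
        cov.groupby("population", sort=True)["affected"].mean().to_dict()
    )
    truth = SimulationTruth(
        causal_pathways=[c.pathway for c in config.causal_pathways],
        causal_snps=causal,
        ancestral_freq=pd.Series(p0, index=gm.snp_ids, name="p0"),
        population_freq=freq,
        prevalence_by_population={k: float(v) for k, v in prev.items()},
        population_of_sample=pop_of_sample,
    )
    return SimulatedDataset(gm, annotation, gmt, cov, truth, config)


def gaw17_small(seed: int = 0, **overrides) -> SimulationConfig:
    """Default profile: 700 samples, 3 populations, ~1,400 SNPs, 75% rare."""
    return SimulationConfig(seed=seed, **overrides)


def write_fixture(directory, config: SimulationConfig) -> dict:
    """Simulate and write the five input files; returns a summary dict.

    Files: genotypes.tsv, annotation.tsv, pathways.gmt, covariates.tsv,
    truth.yaml — all re-readable losslessly by :mod:`pathscore.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    try:
        io.write_genotypes(ds.genotypes, directory / "genotypes.tsv")
        ds.annotation.to_csv(directory / "annotation.tsv", sep="\t", index=False)
        io.write_gmt(ds.gmt, directory / "pathways.gmt")
        io.write_covariates(ds.covariates, directory / "covariates.tsv")
        truth_doc = {
            "causal_pathways": list(ds.truth.causal_pathways),
            "causal_snps": ds.truth.causal_snps.to_dict("records"),
            "prevalence_by_population": ds.truth.prevalence_by_population,
            "populations": [asdict(p) for p in config.populations],
            "baseline_logit": config.baseline_logit,
            "seed": config.seed,
        }
        io.write_truth(truth_doc, directory / "truth.yaml")
    except OSError as exc:
        raise OSError(f"writing fixture under {directory}: {exc}") from exc

    maf = ds.truth.ancestral_freq
    summary = {
        "n_samples": ds.genotypes.n_samples,
        "n_snps": ds.genotypes.n_snps,
        "n_genes": config.n_genes,
        "n_pathways": config.n_pathways,
        "n_populations": len(config.populations),
        "fraction_rare": float((maf < 0.01).mean()),
        "prevalence": float(ds.covariates["affected"].mean()),
    }
    return summary
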