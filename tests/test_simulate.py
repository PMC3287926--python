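import numpy as np
import pandas as pd
import pytest

from pathscore import io
from pathscore.qc import hwe_exact_test, genotype_counts
from pathscore.simulate import (
    CausalPathwaySpec,
    CovariateEffects,
    MafSpectrum,
    PopulationSpec,
    SimulationConfig,
    draw_allele_frequencies,
    generate_genotypes,
    simulate_dataset,
    write_fixture,
)


def _spectrum_at(p0: float) -> MafSpectrum:
    """Degenerate spectrum concentrating the ancestral MAF near p0."""
    return MafSpectrum(rare_fraction=0.0, common_range=(p0, p0 * 1.0000001))


def _config(**kw) -> SimulationConfig:
    defaults = dict(n_samples=200, n_genes=30, n_pathways=5,
                    genes_per_pathway=(5, 10), seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAlleleFrequencies:
    def test_zero_fst_reproduces_ancestral(self):
        cfg = _config(
            populations=[PopulationSpec("A", 0.5, 0.0), PopulationSpec("B", 0.5, 0.0)],
            maf_spectrum=_spectrum_at(0.3),
        )
        p0, freq = draw_allele_frequencies(cfg, 50, np.random.default_rng(0))
        np.testing.assert_allclose(freq["A"], p0)
        np.testing.assert_allclose(freq["B"], p0)
        np.testing.assert_allclose(p0, 0.3, atol=1e-6)

    def test_balding_nichols_moments(self):
        """Beta(p0(1-F)/F, (1-p0)(1-F)/F): mean p0, variance F*p0*(1-p0)."""
        cfg = _config(
            populations=[PopulationSpec("A", 1.0, 0.1)],
            maf_spectrum=_spectrum_at(0.3),
        )
        _, freq = draw_allele_frequencies(cfg, 10_000, np.random.default_rng(3))
        f = freq["A"].to_numpy()
        assert abs(f.mean() - 0.3) < 0.01
        expected_var = 0.1 * 0.3 * 0.7
        assert abs(f.var() - expected_var) < 0.2 * expected_var

    def test_determinism(self):
        cfg = _config()
        a = draw_allele_frequencies(cfg, 200, np.random.default_rng(7))
        b = draw_allele_frequencies(cfg, 200, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a[1], b[1])


class TestGenotypes:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 2.0)])
    def test_fixed_frequency_limits(self, p, expected):
        freq = pd.DataFrame({"A": [p] * 3}, index=["s1", "s2", "s3"])
        pops = pd.Series(["A"] * 10)
        gm = generate_genotypes(freq, pops, np.random.default_rng(0))
        assert (gm.dosages == expected).all()

    def test_hwe_holds_by_construction(self):
        """At p=0.5 and n=2000, nearly every SNP passes the exact HWE
        test at the 1e-6 filter level."""
        n_snps = 1000
        freq = pd.DataFrame({"A": [0.5] * n_snps},
                            index=[f"rs{j}" for j in range(n_snps)])
        pops = pd.Series(["A"] * 2000)
        gm = generate_genotypes(freq, pops, np.random.default_rng(5))
        fails = 0
        for j in range(n_snps):
            p = hwe_exact_test(*genotype_counts(gm.dosages[:, j]))
            fails += p < 1e-6
        assert fails / n_snps < 0.001


class TestPathways:
    def test_sizes_within_range_and_overlap_possible(self):
        ds = simulate_dataset(_config(n_pathways=50, n_genes=40,
                                      genes_per_pathway=(5, 12)))
        sizes = [len(genes) for _, _, genes in ds.gmt]
        assert all(5 <= s <= 12 for s in sizes)
        union = set.union(*(set(g) for _, _, g in ds.gmt))
        assert len(union) < sum(sizes)  # some genes shared

    def test_each_snp_has_one_gene(self):
        ds = simulate_dataset(_config())
        assert not ds.annotation["snp"].duplicated().any()

    def test_range_exceeding_gene_pool_rejected(self):
        with pytest.raises(ValueError, match="genes_per_pathway"):
            _config(n_genes=8, genes_per_pathway=(5, 20))

    def test_reserved_causal_genes_are_private(self):
        cfg = _config(
            n_samples=100, n_genes=60, n_pathways=8, genes_per_pathway=(5, 8),
            mean_snps_per_gene=5.0,
            causal_pathways=[CausalPathwaySpec("PW0001", n_causal_rare=2,
                                               n_causal_common=1)],
            reserve_causal_genes=True,
        )
        ds = simulate_dataset(cfg)
        causal_genes = set(dict(
            (name, genes) for name, _, genes in ds.gmt)["PW0001"])
        for name, _, genes in ds.gmt:
            if name != "PW0001":
                assert not (set(genes) & causal_genes)


class TestPhenotypes:
    def test_null_model_prevalence_half(self):
        ds = simulate_dataset(_config(n_samples=2000, baseline_logit=0.0))
        prev = ds.covariates["affected"].mean()
        se = np.sqrt(0.25 / 2000)
        assert abs(prev - 0.5) < 3 * se

    def test_population_offsets_order_prevalence(self):
        cfg = _config(
            n_samples=5000,
            covariate_effects=CovariateEffects(
                population={"African": 0.8, "European": 0.4, "Asian": 0.0}
            ),
        )
        ds = simulate_dataset(cfg)
        prev = ds.truth.prevalence_by_population
        assert prev["African"] > prev["European"] > prev["Asian"]

    def test_degenerate_baseline_gives_no_cases(self):
        ds = simulate_dataset(_config(baseline_logit=-50.0))
        assert ds.covariates["affected"].sum() == 0

    def test_covariate_ranges(self):
        ds = simulate_dataset(_config())
        cov = ds.covariates
        assert cov["age"].between(20, 90).all()
        assert set(cov["sex"].unique()) <= {0, 1}
        assert set(cov["smoke"].unique()) <= {0, 1}

    def test_causal_snps_confined_to_causal_pathway_genes(self):
        ds = simulate_dataset(_config(
            n_genes=40, mean_snps_per_gene=6.0, genes_per_pathway=(5, 10),
            causal_pathways=[CausalPathwaySpec("PW0002", n_causal_rare=3,
                                               n_causal_common=1)],
        ))
        pw_genes = set(dict((n, g) for n, _, g in ds.gmt)["PW0002"])
        assert set(ds.truth.causal_snps["gene"]) <= pw_genes


class TestFixtureFiles:
    def test_roundtrip_all_files(self, tmp_path):
        cfg = _config(causal_pathways=[CausalPathwaySpec(
            "PW0001", n_causal_rare=2, n_causal_common=1, common_min_maf=0.01)],
            mean_snps_per_gene=6.0)
        summary = write_fixture(tmp_path, cfg)
        ds = simulate_dataset(cfg)

        gm = io.read_genotypes(tmp_path / "genotypes.tsv")
        np.testing.assert_array_equal(gm.dosages, ds.genotypes.dosages)
        assert gm.snp_ids == ds.genotypes.snp_ids

        ann = io.read_annotation(tmp_path / "annotation.tsv")
        pd.testing.assert_frame_equal(ann, ds.annotation)

        assert io.read_gmt(tmp_path / "pathways.gmt") == ds.gmt

        cov = io.read_covariates(tmp_path / "covariates.tsv")
        assert list(cov["sample_id"]) == list(ds.covariates["sample_id"])
        np.testing.assert_array_equal(cov["affected"], ds.covariates["affected"])

        truth = io.read_truth(tmp_path / "truth.yaml")
        assert truth["causal_pathways"] == ["PW0001"]
        assert summary["n_samples"] == cfg.n_samples

    def test_fixed_seed_identical_bytes(self, tmp_path):
        cfg = _config(seed=9)
        write_fixture(tmp_path / "a", cfg)
        write_fixture(tmp_path / "b", cfg)
        for name in ("genotypes.tsv", "annotation.tsv", "pathways.gmt",
                     "covariates.tsv", "truth.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_default_profile_shape(self, tmp_path):
        summary = write_fixture(tmp_path, SimulationConfig(seed=2))
        assert summary["n_samples"] == 700
        assert summary["n_populations"] == 3
        assert summary["n_snps"] >= 1000
        assert summary["fraction_rare"] >= 0.6


def test_population_proportions_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        SimulationConfig(populations=[PopulationSpec("A", 0.6, 0.1),
                                      PopulationSpec("B", 0.6, 0.1)])


def test_maf_bounds_validated():
    with pytest.raises(ValueError, match="MAF bounds"):
        SimulationConfig(maf_spectrum=MafSpectrum(rare_range=(0.0, 0.01)))
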