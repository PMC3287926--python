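"""SNP -> gene -> pathway resolution and the rare/common MAF split.

A pathway is usable when at least ``min_genes`` of its GMT genes carry at
least one QC-passing SNP.  Each pathway's SNPs are partitioned by minor
allele frequency: rare (0 < MAF < threshold), common (MAF >= threshold);
monomorphic SNPs (MAF = 0) carry no information and enter neither class.
A MAF of exactly the threshold is common, matching the convention that
common variants are those with MAF greater than 1% and rare variants sit
strictly below the cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


def classify_variants(maf: pd.Series, threshold: float = 0.01) -> pd.Series:
    """Label each SNP ``rare`` / ``common`` / ``monomorphic`` by MAF."""
    if ((maf < 0) | (maf > 0.5)).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    out = pd.Series("rare", index=maf.index, dtype=object)
    out[maf >= threshold] = "common"
    out[maf == 0.0] = "monomorphic"
    return out


@dataclass
class Pathway:
    name: str
    description: str
    genes: list[str]  # genes with >=1 kept SNP
    rare_snps: list[str]
    common_snps: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class PathwayCollection:
    pathways: list[Pathway] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> Pathway:
        for pw in self.pathways:
            if pw.name == name:
                return pw
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [pw.name for pw in self.pathways]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway": [pw.name for pw in self.pathways],
                "n_genes": [pw.n_genes for pw in self.pathways],
                "n_rare_snps": [len(pw.rare_snps) for pw in self.pathways],
                "n_common_snps": [len(pw.common_snps) for pw in self.pathways],
            }
        )


def map_snps_to_pathways(
    annotation: pd.DataFrame,
    gmt: list[tuple[str, str, list[str]]],
    kept_snps: list[str],
    maf: pd.Series,
    min_genes: int = 5,
    maf_threshold: float = 0.01,
) -> PathwayCollection:
    """Resolve gene sets to per-pathway rare/common SNP lists.

    Genes named in a GMT set but absent from the annotation (or with no
    kept SNP) do not count toward the ``min_genes`` filter.  A SNP whose
    gene belongs to several sets appears in all of them (sets overlap).
    """
    kept = [s for s in kept_snps if s in set(annotation["snp"])]
    ann = annotation.set_index("snp").loc[kept]
    gene_to_snps: dict[str, list[str]] = {}
    for snp, gene in ann["gene"].items():
        gene_to_snps.setdefault(gene, []).append(snp)

    labels = classify_variants(maf.loc[kept], threshold=maf_threshold)
    collection = PathwayCollection()
    for name, desc, genes in gmt:
        with_snps = [g for g in genes if g in gene_to_snps]
        if len(with_snps) < min_genes:
            continue
        snps = [s for g in with_snps for s in gene_to_snps[g]]
        rare = [s for s in snps if labels[s] == "rare"]
        common = [s for s in snps if labels[s] == "common"]
        collection.pathways.append(Pathway(name, desc, with_snps, rare, common))
    if not collection.pathways:
        raise ValueError("no mappable pathways after the gene filter")
    return collection
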