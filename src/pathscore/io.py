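"""Readers and writers for the pipeline's external formats.

Formats are deliberately plain text: an additive genotype TSV (or the
PLINK ``--recode A`` RAW dialect), a SNP annotation TSV, GMT gene sets,
and a covariate/phenotype TSV.  Dosages count copies of the minor allele
(0/1/2); ``NA``, ``-9`` and empty cells are missing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MISSING_TOKENS = {"NA", "na", "NaN", "nan", "-9", ""}

#: covariate columns required by every downstream model
COVARIATE_REQUIRED = ("sample_id", "affected", "age", "sex", "smoke", "population")
TRAIT_COLUMNS = ("q1", "q2", "q3")


class ParseError(ValueError):
    """Malformed input file; the message carries path and line context."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive minor-allele dosages.

    Parameters
    ----------
    sample_ids, snp_ids
        Unique ordered identifiers for rows and columns.
    dosages
        Float array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}``; missing genotypes are ``NaN``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad!r} outside {{0,1,2,missing}}")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def columns(self, snp_ids) -> np.ndarray:
        """Dosage sub-matrix for the given SNP ids, in the given order."""
        idx = [self._snp_index[s] for s in snp_ids]
        return self.dosages[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


def _parse_dosage_token(tok: str, path, line_no: int, col: str) -> float:
    if tok in MISSING_TOKENS:
        return np.nan
    if tok in ("0", "1", "2"):
        return float(tok)
    raise ParseError(
        f"{path}: line {line_no}, column {col!r}: invalid dosage token {tok!r} "
        "(expected 0, 1, 2 or a missing marker)"
    )


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read an additive genotype matrix.

    ``dialect="tsv"``: header ``sample_id<TAB>snp...``, one sample per row.
    ``dialect="plink_raw"``: PLINK ``--recode A`` output; the six leading
    columns (FID IID PAT MAT SEX PHENOTYPE) are metadata, sample id is IID,
    and the phenotype column is ignored here.
    """
    if dialect == "tsv":
        return _read_genotype_tsv(path)
    if dialect == "plink_raw":
        return _read_plink_raw(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotype_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        fields = header.split("\t")
        snp_ids = fields[1:]
        n_cols = len(fields)
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0] == "":
                continue
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}: line {line_no}: expected {n_cols} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            rows.append(
                [
                    _parse_dosage_token(tok, path, line_no, snp)
                    for tok, snp in zip(parts[1:], snp_ids)
                ]
            )
    return GenotypeMatrix(sample_ids, snp_ids, np.array(rows, dtype=float))


def _read_plink_raw(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ParseError(f"{path}: not a PLINK RAW header")
        snp_cols = header[6:]
        # strip the _A allele suffix PLINK appends to the counted allele
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        sample_ids: list[str] = []
        rows = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: expected {len(header)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            rows.append(
                [
                    _parse_dosage_token(tok, path, line_no, snp)
                    for tok, snp in zip(parts[6:], snp_ids)
                ]
            )
    return GenotypeMatrix(sample_ids, snp_ids, np.array(rows, dtype=float))


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = gm.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT gene-set file: ``name<TAB>description<TAB>gene...``.

    Duplicate genes inside one set are dropped (first occurrence kept);
    duplicate set names are an error.
    """
    records: list[tuple[str, str, list[str]]] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {line_no}: GMT lines need >=3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            name, desc = parts[0], parts[1]
            if name in seen:
                raise ParseError(
                    f"{path}: duplicate gene-set name {name!r} on lines "
                    f"{seen[name]} and {line_no}"
                )
            seen[name] = line_no
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            records.append((name, desc, genes))
    return records


def write_gmt(records, path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in records:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """SNP annotation TSV with columns snp, chr, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"snp", "chr", "gene"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: annotation missing columns {sorted(missing)}")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ParseError(f"{path}: SNP {dup!r} annotated more than once")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    missing = set(COVARIATE_REQUIRED) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: covariate table missing columns {sorted(missing)}")
    if df["affected"].isna().any():
        raise ParseError(f"{path}: affected status has missing values")
    if not set(df["affected"].unique()) <= {0, 1}:
        raise ParseError(f"{path}: affected must be 0/1")
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True, default_flow_style=False)


def table_header_comment(config_text: str) -> str:
    """Commented provenance line for output tables (version + config hash)."""
    from pathscore import __version__

    digest = hashlib.md5(config_text.encode()).hexdigest()[:12]
    return f"# pathscore v{__version__} config_md5={digest}"


def write_table(df: pd.DataFrame, path, config_text: str = "", index=False) -> None:
    with open(path, "w") as fh:
        fh.write(table_header_comment(config_text) + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
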