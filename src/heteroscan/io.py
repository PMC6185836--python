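"""Readers and writers for the pipeline's tab-delimited file formats.

Every format is plain tab-delimited text so that real supplementary-style
data and synthetic fixtures flow through identical code paths.  Readers
validate strictly and reject rather than coerce: duplicate observation keys,
out-of-domain genotype calls, and unknown role labels are errors.  Genotype
coordinates are 1-based inclusive.  Missing phenotypes are allowed and kept
as NaN; genotype missingness is preserved in files and only mean-imputed
inside the association scan.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from heteroscan.core import (
    GenotypeMatrix,
    validate_kinship,
    validate_pedigree,
    validate_trait_table,
)

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_kinship",
    "write_kinship",
    "read_plink_raw",
    "write_scan_results",
    "read_scan_results",
]

_MISSING_TOKENS = ("", "NA", "na", "NaN", "nan", "n.d.", "ND", ".")


def read_trait_table(path, sep: str = "\t", missing_tokens=_MISSING_TOKENS) -> pd.DataFrame:
    """Read a replicate-level trait table.

    Expects columns genotype_id, role, population, trait, replicate, value.
    Missing-value tokens are normalized to NaN; non-numeric values that are
    not recognized missing tokens raise.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    required = ["genotype_id", "role", "population", "trait", "replicate", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    raw = df["value"].fillna("")
    is_missing = raw.str.strip().isin(missing_tokens)
    values = pd.to_numeric(raw.where(~is_missing), errors="coerce")
    bad = (~is_missing) & values.isna()
    if bad.any():
        raise ValueError(f"{path}: unparseable numeric value(s) {raw[bad].unique()[:5].tolist()}")
    df = df.assign(value=values, replicate=pd.to_numeric(df["replicate"]).astype(int))
    return validate_trait_table(df[required])


def write_trait_table(table: pd.DataFrame, path) -> None:
    validate_trait_table(table)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path, map_path) -> GenotypeMatrix:
    """Read an accession x SNP call table plus a 3-column map file.

    The call table has accessions as the first column; calls must be in
    {0, 1, 2} or a missing token.  The map file has columns snp_id,
    chromosome, position (1-based bp).
    """
    calls = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    snp_map = pd.read_csv(map_path, sep="\t", comment="#")
    required = ["snp_id", "chromosome", "position"]
    missing = [c for c in required if c not in snp_map.columns]
    if missing:
        raise ValueError(f"{map_path}: missing column(s) {missing}")
    snp_map = snp_map.set_index("snp_id")
    snp_map["chromosome"] = snp_map["chromosome"].astype(str)
    if calls.shape[1] != snp_map.shape[0] or list(calls.columns) != list(snp_map.index):
        raise ValueError(
            f"genotype/map mismatch: {calls.shape[1]} call columns vs {snp_map.shape[0]} mapped SNPs"
        )
    calls = calls.apply(pd.to_numeric, errors="coerce")
    calls.index.name = None
    snp_map.index.name = None
    return GenotypeMatrix(calls=calls.astype(float), snp_map=snp_map)


def write_genotypes(gm: GenotypeMatrix, path, map_path) -> None:
    out = gm.calls.copy()
    # keep integral calls readable as integers
    out.to_csv(path, sep="\t", index_label="accession", na_rep="NA", float_format="%.10g")
    gm.snp_map.to_csv(map_path, sep="\t", index_label="snp_id")


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    ped["population"] = ped["population"].astype(str)
    return validate_pedigree(ped)


def write_pedigree(ped: pd.DataFrame, path) -> None:
    validate_pedigree(ped)
    ped.to_csv(path, sep="\t", index=False)


def read_kinship(path) -> pd.DataFrame:
    k = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    k.columns = k.columns.astype(str)
    k.index = k.index.astype(str)
    return validate_kinship(k.astype(float))


def write_kinship(k: pd.DataFrame, path) -> None:
    validate_kinship(k)
    k.to_csv(path, sep="\t", index_label="accession", float_format="%.10g")


def read_plink_raw(path) -> GenotypeMatrix:
    """Read a PLINK-style ``.raw`` additive allele-count export.

    Whitespace-delimited with header ``FID IID PAT MAT SEX PHENOTYPE`` then
    one ``<snp>_<allele>`` column per SNP; calls are counted alleles in
    {0, 1, 2} with NA for missing.  Chromosome/position are not carried by
    ``.raw`` files, so the returned map is a single pseudo-chromosome.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a PLINK .raw file (missing {missing})")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    calls = df[snp_cols].apply(pd.to_numeric, errors="coerce").astype(float)
    calls.index = df["IID"].to_numpy()
    calls.columns = [c.rsplit("_", 1)[0] for c in snp_cols]
    return GenotypeMatrix(calls=calls)


_SCAN_COLUMNS = [
    "snp_id", "chromosome", "position", "model", "maf",
    "effect", "neg_log10_p", "q_value",
]


def write_scan_results(result: pd.DataFrame, path) -> None:
    """Write a scan-result table sorted by (chromosome, position).

    Columns: snp_id, chromosome, position, model, maf, effect,
    neg_log10_p, q_value.
    """
    if result.empty:
        raise ValueError("refusing to write an empty scan result")
    missing = [c for c in _SCAN_COLUMNS if c not in result.columns]
    if missing:
        raise ValueError(f"scan result missing column(s): {missing}")
    out = result[_SCAN_COLUMNS].sort_values(["chromosome", "position"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_scan_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chromosome"] = df["chromosome"].astype(str)
    return df
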