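"""Shared domain containers and validation.

Phenotypes travel as long-format :class:`pandas.DataFrame` trait tables, one
row per (genotype, population, trait, replicate) observation.  Genotypes are a
:class:`GenotypeMatrix`: an accession-by-SNP matrix of reference-allele counts
in {0, 1, 2} (NaN = missing) plus a SNP map with chromosome and 1-based
base-pair position.  Pedigrees map each F1 hybrid to its variable parent and
its common-reference parent within a population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical trait codes of the study design, in customary order.
TRAITS = ("LA", "FT", "HT", "MSB", "RB", "SY", "SW", "SZ", "NS")

#: Units per trait (free-form; attached to tables for documentation only).
TRAIT_UNITS = {
    "LA": "cm^2",
    "FT": "days",
    "HT": "cm",
    "MSB": "branches",
    "RB": "branches",
    "SY": "g/plant",
    "SW": "mg/1000 seeds",
    "SZ": "um^2*10^3",
    "NS": "seeds",
}

ROLES = ("parent", "hybrid", "reference")

TRAIT_TABLE_COLUMNS = ["genotype_id", "role", "population", "trait", "replicate", "value"]
PEDIGREE_COLUMNS = ["hybrid_id", "parent_id", "reference_id", "population"]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a set of accessions plus a marker map.

    Parameters
    ----------
    calls
        Accessions (rows) by SNPs (columns); values are allele counts in
        {0, 1, 2} with NaN for missing.  Inbred parents carry only {0, 2}.
    snp_map
        Indexed by SNP id with columns ``chromosome`` and ``position``
        (1-based bp); positions are non-decreasing within a chromosome.
    """

    calls: pd.DataFrame
    snp_map: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.snp_map is None:
            # minimal single-chromosome map when none supplied
            self.snp_map = pd.DataFrame(
                {"chromosome": "1", "position": np.arange(1, self.calls.shape[1] + 1)},
                index=self.calls.columns,
            )
        self.validate()

    def validate(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(finite[~np.isin(finite, (0.0, 1.0, 2.0))]))
            raise ValueError(f"genotype calls outside {{0,1,2,missing}}: {bad[:5]}")
        if not self.calls.columns.equals(self.snp_map.index):
            raise ValueError("calls columns and snp_map index disagree")
        for chrom, grp in self.snp_map.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions decrease within chromosome {chrom}")

    @property
    def accessions(self) -> pd.Index:
        return self.calls.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def is_homozygous(self) -> bool:
        """True when no call is heterozygous (inbred panel)."""
        vals = self.calls.to_numpy(dtype=float)
        return not np.any(vals[np.isfinite(vals)] == 1.0)

    def subset(self, accessions=None, snps=None) -> "GenotypeMatrix":
        calls = self.calls
        if accessions is not None:
            missing = [a for a in accessions if a not in calls.index]
            if missing:
                raise KeyError(f"unknown accession(s): {missing[:5]}")
            calls = calls.loc[list(accessions)]
        snp_map = self.snp_map
        if snps is not None:
            calls = calls[list(snps)]
            snp_map = snp_map.loc[list(snps)]
        return GenotypeMatrix(calls=calls.copy(), snp_map=snp_map.copy())


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format trait table and return it unchanged.

    Enforces the column contract, the role domain and uniqueness of
    (genotype, population, trait, replicate) keys.  Values may be NaN
    (missing observation) but not infinite.
    """
    missing_cols = [c for c in TRAIT_TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"trait table missing column(s): {missing_cols}")
    bad_roles = set(table["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown role label(s): {sorted(bad_roles)}; expected one of {ROLES}")
    vals = pd.to_numeric(table["value"], errors="coerce")
    if np.isinf(vals.to_numpy(dtype=float)).any():
        raise ValueError("trait table contains non-finite values")
    key = ["genotype_id", "population", "trait", "replicate"]
    dup = table.duplicated(subset=key)
    if dup.any():
        first = table.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate trait-table key {tuple(first)}")
    return table


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Check a hybrid pedigree: columns, one reference per population,
    and variable parent distinct from the reference."""
    missing_cols = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
    if missing_cols:
        raise ValueError(f"pedigree missing column(s): {missing_cols}")
    for pop, grp in ped.groupby("population"):
        refs = grp["reference_id"].unique()
        if len(refs) > 1:
            raise ValueError(f"population {pop!r} has multiple reference parents: {list(refs)}")
    selfed = ped["parent_id"] == ped["reference_id"]
    if selfed.any():
        raise ValueError(
            f"hybrid(s) with parent_id == reference_id: {ped.loc[selfed, 'hybrid_id'].tolist()[:5]}"
        )
    if ped["hybrid_id"].duplicated().any():
        raise ValueError("duplicate hybrid_id in pedigree")
    return ped


def validate_kinship(k: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Check a labelled kinship (similarity) matrix: square, symmetric."""
    if k.shape[0] != k.shape[1] or not k.index.equals(k.columns):
        raise ValueError("kinship matrix must be square with matching labels")
    arr = k.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-6):
        raise ValueError("kinship matrix is not symmetric")
    return k
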