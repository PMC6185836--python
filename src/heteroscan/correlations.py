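"""Trait-by-trait, cross-population and genetic-distance correlation analyses.

Spearman rank correlations (average-rank ties, two-tailed p via the t
approximation) describe trait relationships within a group (parents, hybrids,
or per-hybrid MPH values).  Squared Pearson correlations compare the two
populations' experiments for genotypes measured in both.  Kinship between a
hybrid's two parents serves as a proxy for parental genetic distance (higher
kinship = genetically closer), correlated per trait against the hybrids' MPH.
Matrix cells use pairwise-complete observations; p-values are unadjusted by
default, with optional Benjamini-Hochberg adjustment across cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from heteroscan.core import validate_kinship, validate_pedigree, validate_trait_table

__all__ = [
    "trait_means",
    "spearman_matrix",
    "cross_population_r2",
    "gd_heterosis_correlation",
    "matrix_to_long",
]

MIN_PAIRS = 3


def trait_means(table: pd.DataFrame, role: str | None = None, population: str | None = None) -> pd.DataFrame:
    """Genotype x trait matrix of per-genotype means, optionally filtered."""
    validate_trait_table(table)
    sub = table
    if role is not None:
        roles = ["parent", "reference"] if role == "parents" else [role.rstrip("s")]
        sub = sub[sub["role"].isin(roles)]
    if population is not None:
        sub = sub[sub["population"].astype(str) == str(population)]
    means = (
        sub.dropna(subset=["value"])
        .groupby(["genotype_id", "trait"])["value"]
        .mean()
        .unstack("trait")
    )
    return means


def spearman_matrix(values: pd.DataFrame, adjust: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlation matrix over the columns of
    a genotype x trait matrix.

    Returns (r, p) as symmetric DataFrames with unit diagonal; cells with
    fewer than 3 complete pairs are NaN.  ``adjust=True`` applies BH
    adjustment across the off-diagonal cells of the p matrix.
    """
    cols = list(values.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            pair = values[[cols[i], cols[j]]].dropna()
            if len(pair) < MIN_PAIRS or pair.nunique().min() < 2:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    if adjust:
        from heteroscan.gwas import bh_fdr

        iu = np.triu_indices(k, 1)
        flat = p.to_numpy()[iu]
        ok = np.isfinite(flat)
        adj = flat.copy()
        adj[ok] = bh_fdr(flat[ok])
        out = p.to_numpy()
        out[iu] = adj
        out[(iu[1], iu[0])] = adj
        p = pd.DataFrame(out, index=cols, columns=cols)
    return r, p


def matrix_to_long(r: pd.DataFrame, p: pd.DataFrame, group: str) -> pd.DataFrame:
    """Flatten a correlation matrix pair to (trait_i, trait_j, group, r, p)."""
    rows = []
    cols = list(r.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rows.append(
                {"trait_i": cols[i], "trait_j": cols[j], "group": group,
                 "r": r.iloc[i, j], "p": p.iloc[i, j]}
            )
    return pd.DataFrame(rows)


def cross_population_r2(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-trait squared Pearson correlation between two genotype x trait
    mean matrices indexed by a shared id (accession id for parents, shared
    variable-parent id for hybrids or MPH values).

    r^2 is invariant under affine transforms of either table.  Traits with
    fewer than 3 shared complete observations are NaN.
    """
    shared = table_a.index.intersection(table_b.index)
    if len(shared) == 0:
        raise ValueError("no shared ids between the two tables")
    traits = [t for t in table_a.columns if t in table_b.columns]
    rows = []
    for trait in traits:
        pair = pd.concat(
            [table_a.loc[shared, trait], table_b.loc[shared, trait]], axis=1
        ).dropna()
        if len(pair) < MIN_PAIRS or pair.nunique().min() < 2:
            r2, pv, n = np.nan, np.nan, len(pair)
        else:
            r, pv = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r2, n = r * r, len(pair)
        rows.append({"trait": trait, "r2": r2, "p": pv, "n": n})
    return pd.DataFrame(rows)


def gd_heterosis_correlation(
    kinship: pd.DataFrame,
    heterosis: pd.DataFrame,
    pedigree: pd.DataFrame,
    reference_substitution: dict[str, str] | None = None,
    value_col: str = "mph",
) -> pd.DataFrame:
    """Spearman correlation of per-hybrid heterosis against parental kinship.

    For each (population, trait), each hybrid contributes (heterosis value,
    kinship between its variable parent and its reference parent).  Since
    kinship is a similarity, a *negative* correlation means more heterosis
    with greater genetic distance.  ``reference_substitution`` maps an
    engineered reference line's id to the kinship row to use in its place
    (e.g. substituting the wild-type lab accessions for tagged or
    male-sterile derivatives).  Hybrids with no kinship entry are dropped
    with a warning.  Constant heterosis values yield r = NaN with p = 1.
    """
    validate_kinship(kinship)
    validate_pedigree(pedigree)
    subst = reference_substitution or {}
    ped = pedigree.assign(
        kin_ref=[subst.get(r, r) for r in pedigree["reference_id"]],
        kin_parent=[subst.get(p, p) for p in pedigree["parent_id"]],
    )

    kin_vals = {}
    dropped = []
    for rec in ped.itertuples(index=False):
        if rec.kin_parent in kinship.index and rec.kin_ref in kinship.columns:
            kin_vals[rec.hybrid_id] = float(kinship.at[rec.kin_parent, rec.kin_ref])
        else:
            dropped.append(rec.hybrid_id)
    if dropped:
        warnings.warn(f"{len(dropped)} hybrid(s) dropped: no kinship entry (e.g. {dropped[:3]})")

    rows = []
    for (pop, trait), sub in heterosis.groupby(["population", "trait"], sort=True):
        sub = sub.dropna(subset=[value_col])
        kin = np.array([kin_vals.get(h, np.nan) for h in sub["hybrid_id"]])
        ok = np.isfinite(kin)
        vals = sub[value_col].to_numpy()[ok]
        kin = kin[ok]
        if len(vals) < MIN_PAIRS:
            rs, pv = np.nan, np.nan
        elif np.allclose(vals, vals[0]) or np.allclose(kin, kin[0]):
            rs, pv = np.nan, 1.0  # degenerate: no rank variation
        else:
            rs, pv = sps.spearmanr(vals, kin)
        rows.append({"population": str(pop), "trait": trait, "rs": rs, "p": pv, "n": len(vals)})
    return pd.DataFrame(rows)
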