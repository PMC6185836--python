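"""Heterosis statistics and variance decomposition.

Definitions (all on genotype means within one population/experiment):

    MPV      = (mean P1 + mean P2) / 2                    mid-parent value
    MPH      = 100 * (mean F1 - MPV) / MPV                percent
    BPH      = 100 * (mean F1 - mean Pbest) / mean Pbest  percent
    MPH_ABS  = mean F1 - MPV                              trait units
    H^2      = V_G / (V_G + V_E)                          broad-sense heritability
    CV_G     = 100 * sqrt(V_G) / grand mean               percent

MPH_ABS cancels purely additive gene action: if every locus acts additively
the F1 genotypic value equals the mid-parent value exactly.  V_G is the
variance among genotype means and V_E the mean within-genotype variance
(sample variances, divisor n-1); an ANOVA expected-mean-square estimator of
V_G is available behind ``method="anova"`` since the population estimator is
a design choice.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from heteroscan.core import validate_pedigree, validate_trait_table

__all__ = [
    "summarize_genotypes",
    "mid_parent_heterosis",
    "better_parent_heterosis",
    "best_parent_test",
    "heritability",
    "estimate_seed_number",
    "heterosis_table",
    "population_summary",
    "exclude_outlier_lineage",
]


def summarize_genotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(genotype, population, trait) replicate count, mean and SD.

    Missing values are excluded from n; SD is NaN for single observations.
    """
    validate_trait_table(table)
    ok = table.dropna(subset=["value"])
    g = ok.groupby(["genotype_id", "role", "population", "trait"], sort=False)["value"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["variance"] = out["sd"] ** 2
    return out


def mid_parent_heterosis(f1_mean: float, p1_mean: float, p2_mean: float) -> dict:
    """Mid-parent value, absolute and relative mid-parent heterosis.

    Relative MPH is undefined (NaN, flagged) when the mid-parent value is 0.
    """
    mpv = (p1_mean + p2_mean) / 2.0
    mph_abs = f1_mean - mpv
    if mpv == 0:
        return {"mpv": mpv, "mph_abs": mph_abs, "mph": np.nan, "mph_defined": False}
    return {"mpv": mpv, "mph_abs": mph_abs, "mph": 100.0 * mph_abs / mpv, "mph_defined": True}


def better_parent_heterosis(
    f1_mean: float,
    p1_mean: float,
    p2_mean: float,
    p1_id: str = "P1",
    p2_id: str = "P2",
    higher_is_better: bool = True,
) -> dict:
    """Better-parent heterosis and the identity of the best parent."""
    if higher_is_better:
        best_mean, best_id = max((p1_mean, p1_id), (p2_mean, p2_id), key=lambda t: t[0])
    else:
        best_mean, best_id = min((p1_mean, p1_id), (p2_mean, p2_id), key=lambda t: t[0])
    if best_mean == 0:
        return {"bph": np.nan, "best_parent_id": best_id, "bph_defined": False}
    return {
        "bph": 100.0 * (f1_mean - best_mean) / best_mean,
        "best_parent_id": best_id,
        "bph_defined": True,
    }


def best_parent_test(
    hybrid_values, parent_values, mode: str = "welch"
) -> tuple[float, float]:
    """Two-tailed t-test of hybrid vs best-parent replicate values.

    ``mode="welch"`` uses Welch's two-sample t-test (replicates are not
    naturally paired); ``mode="paired"`` pairs replicates by index and
    requires equal counts.  Identical vectors (all paired differences zero)
    return p = 1 by convention.  Returns (t, p); both NaN when either side
    has fewer than two usable replicates.
    """
    h = np.asarray(pd.Series(hybrid_values).dropna(), dtype=float)
    p = np.asarray(pd.Series(parent_values).dropna(), dtype=float)
    if len(h) < 2 or len(p) < 2:
        return np.nan, np.nan
    if mode == "paired":
        if len(h) != len(p):
            raise ValueError("paired mode requires equal replicate counts")
        d = h - p
        if np.allclose(d, 0):
            return 0.0, 1.0
        t, pv = sps.ttest_rel(h, p)
    elif mode == "welch":
        if np.allclose(h, h[0]) and np.allclose(p, p[0]) and h[0] == p[0]:
            return 0.0, 1.0
        t, pv = sps.ttest_ind(h, p, equal_var=False)
    else:
        raise ValueError(f"unknown test mode {mode!r}")
    return float(t), float(pv)


def heritability(
    table: pd.DataFrame, method: str = "means"
) -> dict:
    """Broad-sense heritability and genetic CV for one (population, trait, role) slice.

    V_G is the variance among genotype means ("means", default) or the ANOVA
    expected-mean-square estimator (MS_between - MS_within) / n0 ("anova");
    V_E is the mean of within-genotype sample variances.  H^2 is NaN ("n.d.")
    when no genotype has >= 2 replicates (pooled traits).  CV_G is NaN when
    the grand mean is 0.
    """
    ok = table.dropna(subset=["value"])
    groups = ok.groupby("genotype_id")["value"]
    means = groups.mean()
    counts = groups.count()
    if len(means) < 2:
        return {"vg": np.nan, "ve": np.nan, "h2": np.nan, "cvg": np.nan, "n_genotypes": len(means)}
    within = groups.var(ddof=1).dropna()  # genotypes with >= 2 reps
    ve = within.mean() if len(within) else np.nan

    if method == "means":
        vg = means.var(ddof=1)
    elif method == "anova":
        if not len(within):
            vg, ve = np.nan, np.nan
        else:
            grand = ok["value"].mean()
            n_i = counts.to_numpy(dtype=float)
            k = len(means)
            ss_between = float((n_i * (means.to_numpy() - grand) ** 2).sum())
            ms_between = ss_between / (k - 1)
            df_within = float((n_i - 1).sum())
            ms_within = float(((n_i - 1) * groups.var(ddof=1).fillna(0).to_numpy()).sum()) / df_within
            n0 = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (k - 1)
            vg = max((ms_between - ms_within) / n0, 0.0)
            ve = ms_within
    else:
        raise ValueError(f"unknown heritability method {method!r}")

    grand_mean = means.mean()
    cvg = 100.0 * np.sqrt(vg) / grand_mean if (grand_mean != 0 and np.isfinite(vg)) else np.nan
    h2 = vg / (vg + ve) if (np.isfinite(vg) and np.isfinite(ve) and (vg + ve) > 0) else np.nan
    return {"vg": vg, "ve": ve, "h2": h2, "cvg": cvg, "n_genotypes": len(means)}


def estimate_seed_number(sy: float, sw: float) -> float:
    """Seeds per plant from yield and thousand-seed weight.

    ``sy`` in g/plant, ``sw`` in mg per 1000 seeds, so one seed weighs
    sw * 1e-6 g and NS = 1e6 * sy / sw.
    """
    if sw <= 0:
        raise ValueError("thousand-seed weight must be positive")
    return 1.0e6 * sy / sw


def heterosis_table(
    table: pd.DataFrame,
    pedigree: pd.DataFrame,
    directions: dict[str, bool] | None = None,
    test_mode: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-hybrid, per-trait heterosis records for every population.

    ``directions`` maps trait -> higher_is_better (default True for all).
    Columns: hybrid_id, population, trait, mpv, mph, bph, mph_abs,
    best_parent_id, best_parent_test_p, exceeds_best (mean better than best
    parent AND p < alpha).
    """
    validate_trait_table(table)
    validate_pedigree(pedigree)
    directions = directions or {}
    summ = summarize_genotypes(table)
    mean_lookup = summ.set_index(["genotype_id", "population", "trait"])["mean"]
    reps = {
        k: v["value"].to_numpy()
        for k, v in table.dropna(subset=["value"]).groupby(
            ["genotype_id", "population", "trait"]
        )
    }

    rows = []
    traits = sorted(table["trait"].unique())
    for rec in pedigree.itertuples(index=False):
        pop = str(rec.population)
        for trait in traits:
            try:
                f1 = mean_lookup[(rec.hybrid_id, pop, trait)]
                p1 = mean_lookup[(rec.parent_id, pop, trait)]
                p2 = mean_lookup[(rec.reference_id, pop, trait)]
            except KeyError:
                continue
            higher = directions.get(trait, True)
            mp = mid_parent_heterosis(f1, p1, p2)
            bp = better_parent_heterosis(f1, p1, p2, rec.parent_id, rec.reference_id, higher)
            h_reps = reps.get((rec.hybrid_id, pop, trait), np.array([]))
            b_reps = reps.get((bp["best_parent_id"], pop, trait), np.array([]))
            if test_mode == "paired" and len(h_reps) != len(b_reps):
                t, pv = np.nan, np.nan
            else:
                t, pv = best_parent_test(h_reps, b_reps, mode=test_mode)
            best_mean = p1 if bp["best_parent_id"] == rec.parent_id else p2
            better = f1 > best_mean if higher else f1 < best_mean
            exceeds = bool(better and np.isfinite(pv) and pv < alpha)
            rows.append(
                {
                    "hybrid_id": rec.hybrid_id,
                    "population": pop,
                    "trait": trait,
                    "mpv": mp["mpv"],
                    "mph": mp["mph"],
                    "bph": bp["bph"],
                    "mph_abs": mp["mph_abs"],
                    "best_parent_id": bp["best_parent_id"],
                    "best_parent_test_p": pv,
                    "exceeds_best": exceeds,
                }
            )
    return pd.DataFrame(rows)


def population_summary(
    table: pd.DataFrame,
    pedigree: pd.DataFrame,
    h2_method: str = "means",
) -> pd.DataFrame:
    """Population-level descriptive rows per (population, trait, role).

    AVG/SD are computed across genotype means; H^2 and CV_G via
    :func:`heritability`.  Hybrid rows additionally carry the Spearman rank
    correlation (and two-tailed p) between hybrid means and their mid-parent
    values — the measure of how predictable hybrid performance is from
    parental performance.
    """
    validate_trait_table(table)
    validate_pedigree(pedigree)
    summ = summarize_genotypes(table)
    mean_lookup = summ.set_index(["genotype_id", "population", "trait"])["mean"]

    rows = []
    for (pop, trait), sub in table.groupby(["population", "trait"], sort=True):
        ped = pedigree[pedigree["population"].astype(str) == str(pop)]
        for role_label, mask in (
            ("parents", sub["role"].isin(["parent", "reference"])),
            ("hybrids", sub["role"] == "hybrid"),
        ):
            part = sub[mask]
            if part.empty:
                continue
            gmeans = part.dropna(subset=["value"]).groupby("genotype_id")["value"].mean()
            h = heritability(part, method=h2_method)
            row = {
                "population": str(pop),
                "trait": trait,
                "role": role_label,
                "n_genotypes": len(gmeans),
                "avg": gmeans.mean(),
                "sd": gmeans.std(ddof=1) if len(gmeans) > 1 else np.nan,
                "h2": h["h2"],
                "cvg": h["cvg"],
                "rs_hybrid_vs_mpv": np.nan,
                "rs_p": np.nan,
            }
            if role_label == "hybrids" and len(ped):
                pairs = []
                for rec in ped.itertuples(index=False):
                    try:
                        f1 = mean_lookup[(rec.hybrid_id, str(pop), trait)]
                        p1 = mean_lookup[(rec.parent_id, str(pop), trait)]
                        p2 = mean_lookup[(rec.reference_id, str(pop), trait)]
                    except KeyError:
                        continue
                    pairs.append((f1, (p1 + p2) / 2.0))
                if len(pairs) >= 3:
                    f1s, mpvs = map(np.asarray, zip(*pairs))
                    rs, pv = sps.spearmanr(f1s, mpvs)
                    row["rs_hybrid_vs_mpv"], row["rs_p"] = float(rs), float(pv)
            rows.append(row)
    return pd.DataFrame(rows)


def exclude_outlier_lineage(
    table: pd.DataFrame,
    pedigree: pd.DataFrame,
    genotype_ids,
    traits,
) -> pd.DataFrame:
    """Drop named accessions and their derived hybrids for the named traits only.

    Used to remove a confounding outlier lineage (an accession with extreme
    seed phenotypes and every hybrid it parents) before mapping seed traits.
    Unknown ids warn rather than fail; an empty exclusion list is the identity.
    """
    validate_trait_table(table)
    ids = list(genotype_ids)
    if not ids:
        return table.copy()
    known = set(table["genotype_id"]) | set(pedigree["parent_id"]) | set(pedigree["hybrid_id"])
    for gid in ids:
        if gid not in known:
            warnings.warn(f"exclusion id {gid!r} not found in data or pedigree")
    derived = pedigree[
        pedigree["parent_id"].isin(ids) | pedigree["reference_id"].isin(ids)
    ]["hybrid_id"].tolist()
    drop_ids = set(ids) | set(derived)
    mask = table["trait"].isin(set(traits)) & table["genotype_id"].isin(drop_ids)
    return table[~mask].copy()
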