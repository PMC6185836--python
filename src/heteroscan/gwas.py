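"""Kinship-corrected mixed-model association scan for heterosis mapping.

The scan follows the standard two-stage ("population parameters previously
determined") approximation.  Under the null model

    y = X beta + g + e,   g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

the variance ratio lambda = sigma_g^2 / sigma_e^2 is estimated once by
restricted maximum likelihood on the eigendecomposition of the kinship matrix
K (a log-spaced grid with golden-section refinement).  Every SNP is then
tested by generalized least squares under the fixed covariance
sigma_g^2 K + sigma_e^2 I, which after rotation into the eigenbasis reduces to
weighted ordinary regression and vectorizes over SNPs.  An exact mode that
re-estimates lambda per SNP exists for cross-checking the approximation.

Two binary SNP encodings map distinct genetic effects in a common-reference
hybrid panel:

* dominant (response: per-hybrid MPH_ABS): predictor 1 where the hybrid is
  heterozygous, i.e. its variable parent's allele differs from the reference
  parent's; the regression slope estimates the dominance effect d.
* additive (response: parental means): predictor 1 where the accession is
  homozygous for the reference parent's allele; the slope estimates 2a, the
  full homozygote contrast.  Reversing the orientation flips only the sign.

Hybrids in the dominant scan inherit their variable parent's kinship row,
since all hybrids share the reference genome and their relatedness is driven
by the variable parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from heteroscan.core import GenotypeMatrix, validate_kinship, validate_pedigree

__all__ = [
    "compute_kinship",
    "hybrid_kinship",
    "snp_maf",
    "maf_filter",
    "encode_dominant",
    "encode_additive",
    "NullModelFit",
    "fit_null_model",
    "scan",
    "bh_fdr",
    "threshold_report",
    "allele_class_by_mph_bins",
]


# ---------------------------------------------------------------------------
# kinship

def _impute_mean(calls: pd.DataFrame) -> np.ndarray:
    g = calls.to_numpy(dtype=float)
    mu = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g = g.copy()
    g[idx] = np.take(mu, idx[1])
    return g


def compute_kinship(
    genotypes: GenotypeMatrix, method: str = "standardized", max_missing: float = 0.2
) -> pd.DataFrame:
    """Accession-by-accession similarity matrix from SNP calls.

    ``standardized``: cross-products of per-SNP centered and variance-scaled
    allele counts averaged over SNPs, then normalized to unit mean diagonal
    (the usual GWAS population-structure kinship).  ``ibs``: mean proportion
    of shared alleles, in [0, 1].  SNPs with more than ``max_missing``
    missingness or no variation are dropped; remaining missing calls are
    mean-imputed.
    """
    calls = genotypes.calls
    miss_frac = calls.isna().mean(axis=0)
    calls = calls.loc[:, miss_frac <= max_missing]
    g = _impute_mean(calls)
    sd = g.std(axis=0, ddof=1)
    keep = sd > 0
    if method == "standardized":
        if not keep.any():
            raise ValueError("no polymorphic SNPs; cannot build kinship")
        z = (g[:, keep] - g[:, keep].mean(axis=0)) / sd[keep]
        k = z @ z.T / keep.sum()
        k /= np.mean(np.diag(k))
    elif method == "ibs":
        # shared-allele fraction per pair: 1 - |g_i - g_j| / 2, averaged
        n = g.shape[0]
        k = np.empty((n, n))
        for i in range(n):
            k[i, :] = 1.0 - np.abs(g - g[i]).mean(axis=1) / 2.0
        k = (k + k.T) / 2.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    out = pd.DataFrame(k, index=genotypes.accessions, columns=genotypes.accessions)
    return validate_kinship(out)


def hybrid_kinship(parent_kinship: pd.DataFrame, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Kinship among hybrids: each hybrid inherits its variable parent's row.

    All hybrids of a common-reference population share the reference genome,
    so their relatedness structure is that of their variable parents.
    """
    validate_kinship(parent_kinship)
    validate_pedigree(pedigree)
    parents = pedigree["parent_id"].tolist()
    missing = [p for p in parents if p not in parent_kinship.index]
    if missing:
        raise KeyError(f"parent(s) missing from kinship: {missing[:5]}")
    k = parent_kinship.loc[parents, parents].to_numpy()
    ids = pedigree["hybrid_id"].tolist()
    return pd.DataFrame(k, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# MAF filtering and encodings

def snp_maf(calls: pd.DataFrame) -> pd.Series:
    """Minor-allele frequency per SNP over the given samples (rows)."""
    freq = calls.mean(axis=0, skipna=True) / 2.0
    return pd.concat([freq, 1.0 - freq], axis=1).min(axis=1)


def maf_filter(
    genotypes: GenotypeMatrix, threshold: float = 0.05, samples=None
) -> tuple[GenotypeMatrix, pd.Series]:
    """Drop SNPs with MAF strictly below the threshold.

    MAF is computed over ``samples`` (default: all rows) — pass the samples
    that actually enter the model.  A SNP at exactly the threshold is kept.
    Returns the filtered matrix and the per-SNP MAF of the kept SNPs.
    """
    calls = genotypes.calls if samples is None else genotypes.calls.loc[list(samples)]
    maf = snp_maf(calls)
    keep = maf.index[maf >= threshold] if threshold > 0 else maf.index
    return genotypes.subset(snps=keep), maf.loc[keep]


def encode_dominant(parents: GenotypeMatrix, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Hybrid x SNP heterozygosity indicator: 1 where the variable parent's
    allele differs from the common-reference parent's allele."""
    validate_pedigree(pedigree)
    if not parents.is_homozygous():
        raise ValueError("dominant encoding requires homozygous parental calls")
    p = parents.calls.loc[pedigree["parent_id"]].to_numpy(dtype=float)
    r = parents.calls.loc[pedigree["reference_id"]].to_numpy(dtype=float)
    x = (p != r).astype(float)
    x[np.isnan(p) | np.isnan(r)] = np.nan
    return pd.DataFrame(x, index=pedigree["hybrid_id"].to_numpy(), columns=parents.snp_ids)


def encode_additive(
    parents: GenotypeMatrix,
    accessions,
    reference_id: str,
    orientation: str = "ref",
) -> pd.DataFrame:
    """Accession x SNP indicator for the additive (parental-mean) scan.

    ``orientation="ref"``: 1 where the accession carries two copies of the
    reference parent's allele, 0 for two non-reference copies.
    ``orientation="nonref"`` swaps the coding; only the effect sign changes.
    """
    if orientation not in ("ref", "nonref"):
        raise ValueError("orientation must be 'ref' or 'nonref'")
    if not parents.is_homozygous():
        raise ValueError("additive encoding requires homozygous parental calls")
    acc = parents.calls.loc[list(accessions)].to_numpy(dtype=float)
    ref = parents.calls.loc[reference_id].to_numpy(dtype=float)
    x = (acc == ref).astype(float)
    x[np.isnan(acc) | np.isnan(ref[None, :])] = np.nan
    if orientation == "nonref":
        x = 1.0 - x
    return pd.DataFrame(x, index=list(accessions), columns=parents.snp_ids)


# ---------------------------------------------------------------------------
# mixed model

@dataclass
class NullModelFit:
    """Variance components of the no-SNP mixed model on one response."""

    lam: float                 # sigma_g^2 / sigma_e^2
    sigma_g2: float
    sigma_e2: float
    loglik: float              # restricted log-likelihood at lam (up to a constant)
    eigenvalues: np.ndarray    # of the kinship matrix, aligned to samples
    eigenvectors: np.ndarray
    sample_ids: list
    boundary: bool             # optimizer hit the lambda grid boundary


def _reml_neg_loglik(log10_lam, s, yt, xt):
    lam = 10.0 ** log10_lam
    w = lam * s + 1.0
    n, p = xt.shape
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yt)
    resid = yt - xt @ beta
    rss = float(resid @ (resid / w))
    sigma_e2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    return 0.5 * ((n - p) * np.log(sigma_e2) + np.log(w).sum() + logdet_xtx + (n - p))


def fit_null_model(
    y: pd.Series, kinship: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> NullModelFit:
    """REML fit of the variance ratio lambda on a kinship eigendecomposition.

    Profiles the restricted likelihood over log10(lambda) on a 61-point grid
    spanning 1e-5..1e5, then refines around the best point with bounded
    scalar minimization.  Deterministic.  A fit at the grid boundary (e.g.
    lambda ~ 0 when the response carries no kinship structure) is flagged,
    not an error.
    """
    y = y.dropna()
    ids = [i for i in y.index if i in kinship.index]
    if len(ids) < 5:
        raise ValueError("need at least 5 samples with kinship entries")
    yv = y.loc[ids].to_numpy(dtype=float)
    k = kinship.loc[ids, ids].to_numpy(dtype=float)
    k = (k + k.T) / 2.0
    s, u = np.linalg.eigh(k)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    s = np.clip(s, 0.0, None)

    if covariates is not None:
        x = np.column_stack([np.ones(len(ids)), covariates.loc[ids].to_numpy(dtype=float)])
    else:
        x = np.ones((len(ids), 1))
    yt, xt = u.T @ yv, u.T @ x

    grid = np.linspace(-5.0, 5.0, 61)
    vals = np.array([_reml_neg_loglik(g, s, yt, xt) for g in grid])
    if np.ptp(vals) < 1e-8 * max(1.0, np.abs(vals).max()):
        # flat restricted likelihood (e.g. K proportional to I): lambda is
        # unidentifiable; report the OLS boundary with a flag
        w = np.ones_like(s)
        xw = xt
        beta = np.linalg.solve(xt.T @ xw, xw.T @ yt)
        resid = yt - xt @ beta
        n, p = xt.shape
        sigma_e2 = float(resid @ resid) / (n - p)
        return NullModelFit(
            lam=0.0, sigma_g2=0.0, sigma_e2=sigma_e2, loglik=-float(vals[0]),
            eigenvalues=s, eigenvectors=u, sample_ids=list(ids), boundary=True,
        )
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, yt, xt), method="bounded",
        options={"xatol": 1e-6},
    )
    log10_lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
    lam = 10.0 ** log10_lam
    boundary = i in (0, len(grid) - 1)
    if boundary and i == 0:
        lam = 0.0  # unidentifiable genetic variance: fall back to OLS covariance

    w = lam * s + 1.0
    n, p = xt.shape
    xw = xt / w[:, None]
    beta = np.linalg.solve(xt.T @ xw, xw.T @ yt)
    resid = yt - xt @ beta
    sigma_e2 = float(resid @ (resid / w)) / (n - p)
    return NullModelFit(
        lam=lam,
        sigma_g2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=-_reml_neg_loglik(np.log10(lam) if lam > 0 else -12.0, s, yt, xt),
        eigenvalues=s,
        eigenvectors=u,
        sample_ids=list(ids),
        boundary=boundary,
    )


def _gls_scan_fixed(yv, design, lam, s, u):
    """Vectorized per-SNP GLS with fixed variance ratio.

    Rotating into the kinship eigenbasis and dividing by sqrt(lam*s + 1)
    turns each SNP's GLS fit into ordinary regression of the whitened
    response on (whitened intercept, whitened predictor).
    """
    w = lam * s + 1.0
    a = u.T / np.sqrt(w)[:, None]      # whitening transform
    yt = a @ yv
    ct = a @ np.ones(len(yv))
    xt = a @ design                    # n x m
    n = len(yv)

    s00 = float(ct @ ct)
    s01 = ct @ xt
    s11 = np.einsum("ij,ij->j", xt, xt)
    s0y = float(ct @ yt)
    sxy = xt.T @ yt
    det = s00 * s11 - s01**2
    ok = det > 1e-12 * max(s00, 1.0)

    slope = np.full(design.shape[1], np.nan)
    se = np.full(design.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope[ok] = (s00 * sxy[ok] - s01[ok] * s0y) / det[ok]
        intercept = np.where(ok, (s11 * s0y - s01 * sxy) / np.where(det > 0, det, 1.0), np.nan)
        yty = float(yt @ yt)
        rss = yty - (intercept * s0y + slope * sxy)
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / (n - 2)
        se[ok] = np.sqrt(sigma2[ok] * s00 / det[ok])
    t = slope / se
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return slope, se, t, p, ok


def scan(
    y: pd.Series,
    design: pd.DataFrame,
    null: NullModelFit,
    snp_map: pd.DataFrame | None = None,
    maf: pd.Series | None = None,
    model: str = "dominant",
    exact: bool = False,
    kinship: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP association of a response with binary SNP predictors.

    ``design`` is samples x SNPs with values in {0, 1} (NaN mean-imputed per
    SNP).  Variance components come from ``null`` and are reused for every
    SNP (two-stage approximation); ``exact=True`` instead re-estimates lambda
    per SNP by REML with the SNP as covariate (requires ``kinship``).
    Constant predictors are reported with a skip reason rather than a test.

    Returns one row per SNP: snp_id, chromosome, position, model, maf,
    effect, se, t, p, neg_log10_p, q_value (BH within this scan), skipped.
    """
    ids = [i for i in null.sample_ids if i in design.index]
    if len(ids) != len(null.sample_ids):
        raise ValueError("design does not cover the null-model samples")
    yv = y.loc[ids].to_numpy(dtype=float)
    x = design.loc[ids].to_numpy(dtype=float)
    # mean-impute missing predictor values per SNP (files keep missingness)
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    nan_idx = np.where(np.isnan(x))
    x[nan_idx] = np.take(col_mean, nan_idx[1])

    if exact:
        if kinship is None:
            raise ValueError("exact mode needs the kinship matrix")
        slope = np.full(x.shape[1], np.nan)
        se = np.full(x.shape[1], np.nan)
        tstat = np.full(x.shape[1], np.nan)
        pval = np.full(x.shape[1], np.nan)
        ok = np.ptp(x, axis=0) > 0
        for j in np.flatnonzero(ok):
            cov = pd.DataFrame({"snp": x[:, j]}, index=ids)
            fit_j = fit_null_model(y.loc[ids], kinship, covariates=cov)
            sl, sej, tj, pj, okj = _gls_scan_fixed(
                yv, x[:, j : j + 1], fit_j.lam, fit_j.eigenvalues, fit_j.eigenvectors
            )
            slope[j], se[j], tstat[j], pval[j] = sl[0], sej[0], tj[0], pj[0]
    else:
        slope, se, tstat, pval, ok = _gls_scan_fixed(
            yv, x, null.lam, null.eigenvalues, null.eigenvectors
        )

    out = pd.DataFrame(
        {
            "snp_id": design.columns,
            "model": model,
            "maf": maf.reindex(design.columns).to_numpy() if maf is not None else np.nan,
            "effect": slope,
            "se": se,
            "t": tstat,
            "p": pval,
            "skipped": ~ok,
        }
    )
    if snp_map is not None:
        out["chromosome"] = snp_map["chromosome"].reindex(design.columns).to_numpy()
        out["position"] = snp_map["position"].reindex(design.columns).to_numpy()
    else:
        out["chromosome"] = "1"
        out["position"] = np.arange(1, len(out) + 1)
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    out["q_value"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    cols = [
        "snp_id", "chromosome", "position", "model", "maf",
        "effect", "se", "t", "p", "neg_log10_p", "q_value", "skipped",
    ]
    return out[cols]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in sorted p order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def threshold_report(
    result: pd.DataFrame, raw_threshold: float = 4.0, fdr_alpha: float = 0.05
) -> dict:
    """Flag SNPs by the two reporting criteria used for scan summaries.

    ``raw``: -log10(p) strictly greater than ``raw_threshold`` (a SNP at
    exactly the threshold is not flagged); ``fdr``: BH q-value < alpha.
    Returns the flagged table and the counts under each criterion.
    """
    if result.empty:
        return {"table": result.copy(), "n_raw": 0, "n_fdr": 0}
    flagged = result.copy()
    flagged["sig_raw"] = flagged["neg_log10_p"] > raw_threshold
    flagged["sig_fdr"] = flagged["q_value"] < fdr_alpha
    table = flagged[flagged["sig_raw"] | flagged["sig_fdr"]]
    return {
        "table": table,
        "n_raw": int(flagged["sig_raw"].sum()),
        "n_fdr": int(flagged["sig_fdr"].sum()),
    }


def allele_class_by_mph_bins(
    snp_predictor: pd.Series, mph: pd.Series, bins
) -> pd.DataFrame:
    """Contingency of genotype class (heterozygous/homozygous) by MPH bin
    at one SNP: the allele-class distribution over heterosis classes.

    ``snp_predictor`` is the dominant encoding column (1 = heterozygous) per
    hybrid; ``mph`` per-hybrid relative heterosis in percent; ``bins`` are
    class edges covering the data range.
    """
    shared = snp_predictor.index.intersection(mph.index)
    x = snp_predictor.loc[shared]
    m = mph.loc[shared]
    ok = x.notna() & m.notna()
    x, m = x[ok], m[ok]
    cut = pd.cut(m, bins=bins, include_lowest=True)
    out = pd.crosstab(cut, x.map({1.0: "heterozygous", 0.0: "homozygous"}))
    for col in ("heterozygous", "homozygous"):
        if col not in out.columns:
            out[col] = 0
    out.index.name = "mph_bin"
    return out[["heterozygous", "homozygous"]].astype(int)
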