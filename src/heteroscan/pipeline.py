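"""End-to-end orchestration: simulate/load -> statistics -> correlations ->
growth curves -> association scans -> report bundle.

A single :class:`RunConfig` (constructable from a YAML file) drives the run.
Either real-data paths or a simulation block must be present; stages whose
inputs are absent are skipped with a notice.  Every output is tab-delimited
text in the output directory, and a manifest records the config hash, seed
and library versions so identical configs produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from heteroscan import io as hio
from heteroscan.core import GenotypeMatrix
from heteroscan.correlations import (
    cross_population_r2,
    gd_heterosis_correlation,
    matrix_to_long,
    spearman_matrix,
    trait_means,
)
from heteroscan.growth import establishment_fraction, mph_over_time
from heteroscan.gwas import (
    compute_kinship,
    encode_additive,
    encode_dominant,
    fit_null_model,
    hybrid_kinship,
    maf_filter,
    scan,
    threshold_report,
)
from heteroscan.simulate import (
    CurveParams,
    QtlSpec,
    SimConfig,
    derive_hybrid_genotypes,
    make_two_population_pedigree,
    simulate_growth_curves,
    simulate_parental_genotypes,
    simulate_traits,
)
from heteroscan.stats import exclude_outlier_lineage, heterosis_table, population_summary

log = logging.getLogger("heteroscan")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "load_config"]


@dataclass
class ScanSettings:
    maf_threshold: float = 0.05
    raw_threshold: float = 4.0
    fdr_alpha: float = 0.05
    kinship_method: str = "standardized"
    orientation: str = "ref"  # additive encoding: 1 = reference homozygote
    traits: list[str] | None = None
    reference_substitution: dict[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Run-level configuration.

    Exactly one of ``simulate`` (a :class:`SimConfig`) or ``data`` (paths to
    trait_table, genotypes, genotype_map, pedigree, optional kinship, optional
    growth_curves) must be provided.
    """

    outdir: str = "heteroscan_out"
    seed: int = 0
    simulate: SimConfig | None = None
    data: dict | None = None
    directions: dict[str, bool] = field(default_factory=dict)
    exclude_ids: list[str] = field(default_factory=list)
    exclude_traits: list[str] = field(default_factory=list)
    scan: ScanSettings = field(default_factory=ScanSettings)
    run_growth: bool = True
    run_scan: bool = True
    test_mode: str = "welch"
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        qtls = tuple(QtlSpec(**q) for q in sim.pop("qtls", []))
        curve = CurveParams(**sim.pop("curve_params", {}))
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        if "reference_ids" in sim:
            sim["reference_ids"] = tuple(sim["reference_ids"])
        sim = SimConfig(qtls=qtls, curve_params=curve, **sim)
    scan_settings = ScanSettings(**raw.pop("scan", {}))
    return RunConfig(simulate=sim, scan=scan_settings, **raw)


def validate_config(config: RunConfig) -> list[str]:
    """Collect all config violations at once; empty list means valid."""
    problems = []
    if config.simulate is None and not config.data:
        problems.append("neither a simulation block nor data paths are configured")
    if config.simulate is not None and config.data:
        problems.append("both a simulation block and data paths are configured; pick one")
    if config.data:
        required = ["trait_table", "pedigree"]
        for key in required:
            if key not in config.data:
                problems.append(f"data block missing required path {key!r}")
            elif not Path(config.data[key]).exists():
                problems.append(f"data path does not exist: {config.data[key]}")
        for key in ("genotypes", "genotype_map", "kinship", "growth_curves"):
            if key in config.data and not Path(config.data[key]).exists():
                problems.append(f"data path does not exist: {config.data[key]}")
    if not 0 <= config.scan.maf_threshold < 0.5:
        problems.append(f"MAF threshold {config.scan.maf_threshold} outside [0, 0.5)")
    if not 0 < config.scan.fdr_alpha < 1:
        problems.append(f"FDR alpha {config.scan.fdr_alpha} outside (0, 1)")
    if config.scan.raw_threshold < 0:
        problems.append("raw -log10(p) threshold must be non-negative")
    if config.scan.orientation not in ("ref", "nonref"):
        problems.append(f"unknown encoding orientation {config.scan.orientation!r}")
    if config.test_mode not in ("welch", "paired"):
        problems.append(f"unknown best-parent test mode {config.test_mode!r}")
    return problems


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    """Returns (trait table, parents GenotypeMatrix|None, pedigree, kinship|None, curves|None)."""
    if config.simulate is not None:
        sim = config.simulate.with_(seed=config.seed)
        parents = simulate_parental_genotypes(sim)
        pedigree = make_two_population_pedigree(sim)
        hybrids = derive_hybrid_genotypes(parents, pedigree)
        combined = GenotypeMatrix(
            calls=pd.concat([parents.calls, hybrids.calls]), snp_map=parents.snp_map
        )
        table = simulate_traits(combined, pedigree, sim)
        curves = simulate_growth_curves(sim, pedigree) if config.run_growth else None
        return table, parents, pedigree, None, curves
    d = config.data
    table = hio.read_trait_table(d["trait_table"])
    pedigree = hio.read_pedigree(d["pedigree"])
    parents = None
    if "genotypes" in d and "genotype_map" in d:
        parents = hio.read_genotypes(d["genotypes"], d["genotype_map"])
    kinship = hio.read_kinship(d["kinship"]) if "kinship" in d else None
    curves = pd.read_csv(d["growth_curves"], sep="\t") if "growth_curves" in d else None
    return table, parents, pedigree, kinship, curves


def _run_scans(table, parents, pedigree, kinship, het, config, outdir, notices):
    """Dominant scan on MPH_ABS per (trait, population) and additive scan on
    parental means; BH correction within each scan, never pooled."""
    s = config.scan
    traits = s.traits or sorted(table["trait"].unique())
    if kinship is None:
        kinship = compute_kinship(parents, method=s.kinship_method)
    counts = []
    top_rows = []
    for pop, ped in pedigree.groupby("population", sort=True):
        pop = str(pop)
        var_parents = ped["parent_id"].tolist()
        filtered, maf = maf_filter(parents, s.maf_threshold, samples=var_parents)
        dom_design = encode_dominant(filtered, ped)
        k_hyb = hybrid_kinship(kinship, ped)
        ref_id = ped["reference_id"].iloc[0]
        add_design = encode_additive(filtered, var_parents, ref_id, s.orientation)
        pmeans = trait_means(table, role="parents", population=pop)

        for trait in traits:
            tbl = exclude_outlier_lineage(table, pedigree, config.exclude_ids, config.exclude_traits) \
                if trait in config.exclude_traits else table
            # dominant model: response is per-hybrid MPH_ABS
            sub = het[(het["population"] == pop) & (het["trait"] == trait)]
            y_dom = sub.set_index("hybrid_id")["mph_abs"].dropna()
            y_dom = y_dom[y_dom.index.isin(dom_design.index)]
            if trait in config.exclude_traits:
                keep_h = set(
                    tbl[tbl["role"] == "hybrid"]["genotype_id"].unique()
                )
                y_dom = y_dom[y_dom.index.isin(keep_h)]
            for model, y, design, k in (
                ("dominant", y_dom, dom_design, k_hyb),
                (
                    "additive",
                    pmeans[trait].dropna()[lambda v: v.index.isin(add_design.index)]
                    if trait in pmeans.columns else pd.Series(dtype=float),
                    add_design,
                    kinship,
                ),
            ):
                if trait in config.exclude_traits and model == "additive":
                    y = y[~y.index.isin(set(config.exclude_ids))]
                if len(y) < 5:
                    notices.append(f"scan skipped for {trait}/{model}/pop{pop}: <5 samples")
                    continue
                null = fit_null_model(y, k)
                res = scan(
                    y, design.loc[y.index], null,
                    snp_map=filtered.snp_map, maf=maf, model=model,
                )
                rep = threshold_report(res, s.raw_threshold, s.fdr_alpha)
                counts.append(
                    {"population": pop, "trait": trait, "model": model,
                     "n_snps": int((~res["skipped"]).sum()),
                     "n_raw": rep["n_raw"], "n_fdr": rep["n_fdr"],
                     "lambda": null.lam, "boundary": null.boundary}
                )
                path = outdir / f"scan_{trait}_{model}_pop{pop}.tsv"
                hio.write_scan_results(res.dropna(subset=["p"]), path)
                if model == "dominant" and res["p"].notna().any():
                    top = res.loc[res["p"].idxmin()]
                    top_rows.append(
                        {"population": pop, "trait": trait, "snp_id": top["snp_id"],
                         "neg_log10_p": top["neg_log10_p"], "effect": top["effect"]}
                    )
    return pd.DataFrame(counts), pd.DataFrame(top_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns a dict of in-memory results: trait table, heterosis table,
    population summary, correlation exports, genetic-distance correlations,
    growth outputs, scan count summary, manifest.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []

    log.info("stage: inputs")
    table, parents, pedigree, kinship, curves = _load_inputs(config)
    hio.write_trait_table(table, outdir / "trait_table.tsv")
    hio.write_pedigree(pedigree, outdir / "pedigree.tsv")

    log.info("stage: heterosis statistics")
    het = heterosis_table(table, pedigree, config.directions, config.test_mode)
    het.to_csv(outdir / "heterosis.tsv", sep="\t", index=False, na_rep="NA")
    summary = population_summary(table, pedigree)
    summary.to_csv(outdir / "population_summary.tsv", sep="\t", index=False, na_rep="NA")

    log.info("stage: correlations")
    corr_long = []
    populations = sorted(pedigree["population"].astype(str).unique())
    for pop in populations:
        for group, mat in (
            ("parents", trait_means(table, role="parents", population=pop)),
            ("hybrids", trait_means(table, role="hybrid", population=pop)),
            ("mph", het[het["population"] == pop]
                    .pivot(index="hybrid_id", columns="trait", values="mph")),
        ):
            if mat.shape[0] < 3:
                continue
            r, p = spearman_matrix(mat)
            corr_long.append(matrix_to_long(r, p, f"{group}_pop{pop}"))
    corr = pd.concat(corr_long, ignore_index=True) if corr_long else pd.DataFrame()
    corr.to_csv(outdir / "trait_correlations.tsv", sep="\t", index=False, na_rep="NA")

    xpop = pd.DataFrame()
    if len(populations) == 2:
        a, b = populations
        pieces = []
        pa = trait_means(table, role="parents", population=a)
        pb = trait_means(table, role="parents", population=b)
        pieces.append(cross_population_r2(pa, pb).assign(group="parents"))
        # hybrids and MPH matched by shared variable parent
        par_of = pedigree.set_index("hybrid_id")["parent_id"]
        ha = trait_means(table, role="hybrid", population=a).rename(index=par_of)
        hb = trait_means(table, role="hybrid", population=b).rename(index=par_of)
        pieces.append(cross_population_r2(ha, hb).assign(group="hybrids"))
        ma = het[het["population"] == a].pivot(index="hybrid_id", columns="trait", values="mph").rename(index=par_of)
        mb = het[het["population"] == b].pivot(index="hybrid_id", columns="trait", values="mph").rename(index=par_of)
        pieces.append(cross_population_r2(ma, mb).assign(group="mph"))
        xpop = pd.concat(pieces, ignore_index=True)
        xpop.to_csv(outdir / "cross_population_r2.tsv", sep="\t", index=False, na_rep="NA")

    gd = pd.DataFrame()
    if parents is not None or kinship is not None:
        k = kinship if kinship is not None else compute_kinship(parents, method=config.scan.kinship_method)
        gd = gd_heterosis_correlation(
            k, het, pedigree, reference_substitution=config.scan.reference_substitution
        )
        gd.to_csv(outdir / "gd_heterosis_correlation.tsv", sep="\t", index=False, na_rep="NA")
    else:
        notices.append("genetic-distance stage skipped: no genotypes or kinship")

    growth_out = {}
    if config.run_growth and curves is not None:
        log.info("stage: growth curves")
        frac = establishment_fraction(curves)
        frac.to_csv(outdir / "establishment_fraction.tsv", sep="\t", index=False, na_rep="NA")
        mot = mph_over_time(curves, pedigree, align="t0")
        mot.to_csv(outdir / "mph_over_time.tsv", sep="\t", index=False, na_rep="NA")
        growth_out = {"establishment_fraction": frac, "mph_over_time": mot}
    elif config.run_growth:
        notices.append("growth stage skipped: no curves supplied")

    scan_counts, scan_top = pd.DataFrame(), pd.DataFrame()
    if config.run_scan and parents is not None:
        log.info("stage: association scans")
        scan_counts, scan_top = _run_scans(
            table, parents, pedigree, kinship, het, config, outdir, notices
        )
        scan_counts.to_csv(outdir / "scan_significant_counts.tsv", sep="\t", index=False, na_rep="NA")
        if not scan_top.empty:
            scan_top.to_csv(outdir / "scan_top_snps.tsv", sep="\t", index=False, na_rep="NA")
    elif config.run_scan:
        notices.append("scan stage skipped: no genotypes supplied")

    import scipy

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "heteroscan": __import__("heteroscan").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "notices": notices,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "trait_table": table,
        "pedigree": pedigree,
        "heterosis": het,
        "population_summary": summary,
        "trait_correlations": corr,
        "cross_population_r2": xpop,
        "gd_correlation": gd,
        "growth": growth_out,
        "scan_counts": scan_counts,
        "scan_top": scan_top,
        "manifest": manifest,
    }
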