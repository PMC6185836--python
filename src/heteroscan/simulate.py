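"""Synthetic common-reference hybrid panels with known genetic architecture.

The generator emulates a two-population common-reference design: a panel of
fully inbred accessions is crossed to two shared reference lines, yielding two
overlapping F1 hybrid populations (100 and 99 hybrids, 95 variable parents in
common).  Traits are simulated from an explicit additive/dominance model

    genotypic value = baseline + polygenic additive score
                      + sum over QTLs of (+a, d, -a)

for (two copies, one copy, zero copies) of the counted allele at each QTL,
with i.i.d. Gaussian replicate noise on top.  Because every F1 genotype is the
allele-wise average of its parents, a purely additive architecture (all d = 0)
makes each hybrid's genotypic value exactly the mid-parent value, so absolute
mid-parent heterosis has expectation zero — the null every heterosis statistic
is tested against.

All randomness flows from ``SimConfig.seed`` through per-stage substreams, so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from heteroscan.core import GenotypeMatrix, validate_pedigree, validate_trait_table

__all__ = [
    "QtlSpec",
    "CurveParams",
    "SimConfig",
    "simulate_parental_genotypes",
    "derive_hybrid_genotypes",
    "simulate_traits",
    "simulate_growth_curves",
    "make_pedigree",
    "make_two_population_pedigree",
]

# Table-1-like per-trait baselines and genetic SDs (parental panel scale).
_DEFAULT_BASELINES = {
    "LA": 4.5,      # cm^2 at 17 DAS
    "FT": 29.0,     # days to first flower
    "HT": 50.0,     # cm inflorescence height
    "MSB": 5.5,     # main-stem branches
    "RB": 3.6,      # rosette branches
    "SY": 0.27,     # g seed per plant
    "SW": 25.0,     # mg / 1000 seeds
    "SZ": 82.0,     # um^2 * 10^3
    "NS": 10800.0,  # seeds per plant
}
_DEFAULT_GENETIC_SD = {
    "LA": 1.0,
    "FT": 4.8,
    "HT": 8.5,
    "MSB": 1.6,
    "RB": 1.2,
    "SY": 0.10,
    "SW": 2.2,
    "SZ": 8.0,
    "NS": 3900.0,
}


@dataclass(frozen=True)
class QtlSpec:
    """A single biallelic QTL.

    ``a`` is the additive effect (half the difference between the two
    homozygote means), ``d`` the dominance effect (heterozygote deviation from
    the homozygote midpoint); |d| > |a| represents overdominance.  Effects are
    oriented to the allele whose count the genotype matrix stores.
    """

    snp_index: int
    a: float
    d: float
    trait: str

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.d)):
            raise ValueError("QTL effects must be finite")
        if self.snp_index < 0:
            raise ValueError("QTL snp_index must be non-negative")


@dataclass(frozen=True)
class CurveParams:
    """Logistic growth-curve parameters (areas in mm^2, time in days)."""

    initial_area: float = 0.5
    growth_rate: float = 0.35          # per day
    asymptote: float = 600.0
    onset_day: float = 4.0             # mean establishment onset, days after sowing
    onset_jitter_sd: float = 1.0       # per-plant SD of onset day
    hybrid_onset_advantage: float = 2.5  # hybrids establish this many days earlier
    hybrid_asymptote_boost: float = 1.0  # multiplicative asymptote advantage of hybrids
    rate_cv: float = 0.08              # between-genotype lognormal CV of the rate
    asymptote_cv: float = 0.10         # between-genotype lognormal CV of the asymptote
    n_days: int = 17

    def __post_init__(self):
        if self.asymptote <= 0 or self.growth_rate <= 0:
            raise ValueError("asymptote and growth rate must be positive")
        if self.asymptote <= self.initial_area:
            raise ValueError("asymptote must exceed initial area")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults mirror the two-population common-reference design: 104 inbred
    accessions (95 shared between populations plus 5 + 4 population-specific
    ones), two reference lines, 10 replicates per genotype, and nine traits
    with baselines and genetic SDs on the scale of the real panel.  The SNP
    count defaults to 1000 markers on 5 chromosomes — a desk-scale stand-in
    for a dense genotyping array that preserves the design's structure.
    """

    n_accessions: int = 104
    n_snps: int = 1000
    n_chromosomes: int = 5
    maf_range: tuple[float, float] = (0.1, 0.5)
    qtls: tuple[QtlSpec, ...] = ()
    n_replicates: int = 10
    residual_sd: dict[str, float] | float | None = None
    reference_ids: tuple[str, ...] = ("REF1", "REF2")
    seed: int = 0
    curve_params: CurveParams = field(default_factory=CurveParams)
    trait_baselines: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINES))
    genetic_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GENETIC_SD))

    def __post_init__(self):
        if self.n_accessions < 3:
            raise ValueError("n_accessions must be >= 3")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for q in self.qtls:
            if q.snp_index >= self.n_snps:
                raise ValueError(f"QTL snp_index {q.snp_index} >= n_snps {self.n_snps}")
            if q.trait not in self.trait_baselines:
                raise ValueError(f"QTL trait {q.trait!r} absent from configured trait list")

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.trait_baselines)

    def residual_sd_for(self, trait: str) -> float:
        """Replicate noise SD for a trait.

        Defaults to 0.8 x the trait's genetic SD, which puts broad-sense
        heritability near 0.6 — the middle of the range observed for
        replicated traits in panels of this kind.
        """
        if self.residual_sd is None:
            return 0.8 * self.genetic_sd[trait]
        if isinstance(self.residual_sd, dict):
            return float(self.residual_sd[trait])
        return float(self.residual_sd)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # per-stage substream so each stage is reproducible in isolation
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _accession_ids(config: SimConfig) -> list[str]:
    width = max(3, len(str(config.n_accessions)))
    return [f"P{i + 1:0{width}d}" for i in range(config.n_accessions)]


def simulate_parental_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw fully homozygous biallelic genotypes for the parental panel.

    Per SNP, an allele frequency is drawn uniformly within ``maf_range`` and
    each accession's (single, doubled) allele is Bernoulli at that frequency,
    so calls are in {0, 2}.  Reference accessions are drawn from the same
    distribution and appended after the variable parents.  Map positions are
    assigned in ascending order within chromosomes laid out round-robin.
    """
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    ids = _accession_ids(config) + list(config.reference_ids)
    if not ids:
        raise ValueError("empty accession set")
    rng = _rng(config, 0)
    n, m = len(ids), config.n_snps
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    alleles = rng.random((n, m)) < freqs  # one allele per inbred accession
    calls = (alleles.astype(float)) * 2.0

    snp_ids = [f"m{j + 1:06d}" for j in range(m)]
    chroms = np.array([str(1 + (j % config.n_chromosomes)) for j in range(m)])
    positions = np.empty(m, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos = np.sort(rng.integers(1, 30_000_000, size=idx.size))
        pos = pos + np.arange(idx.size)  # break exact ties, keep ascending
        positions[idx] = pos
    snp_map = pd.DataFrame({"chromosome": chroms, "position": positions}, index=snp_ids)
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=ids, columns=snp_ids), snp_map=snp_map
    )


def make_pedigree(parent_ids, reference_id: str, population: str) -> pd.DataFrame:
    """Pedigree for one common-reference population: every listed variable
    parent crossed once to the shared reference."""
    rows = [
        {
            "hybrid_id": f"H_{p}x{reference_id}",
            "parent_id": p,
            "reference_id": reference_id,
            "population": population,
        }
        for p in parent_ids
    ]
    return validate_pedigree(pd.DataFrame(rows))


def make_two_population_pedigree(
    config: SimConfig,
    n_shared: int | None = None,
    sizes: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Two overlapping populations sharing ``n_shared`` variable parents.

    Population "1" crosses the first ``sizes[0]`` accessions to the first
    reference line, population "2" the shared block plus the remaining
    accessions to the second reference line.  Defaults reproduce the study
    proportions (populations of n-4 and n-5 hybrids sharing n-9 parents,
    i.e. 100/99/95 at the default 104 accessions); small panels fall back to
    fully nested populations of n and n-1.
    """
    if len(config.reference_ids) < 2:
        raise ValueError("two reference ids required for a two-population design")
    ids = _accession_ids(config)
    n_acc = len(ids)
    if sizes is None:
        if n_acc >= 12:
            sizes = (n_acc - 4, n_acc - 5)
            n_shared = n_acc - 9 if n_shared is None else n_shared
        else:
            sizes = (n_acc, n_acc - 1)
            n_shared = n_acc - 1 if n_shared is None else n_shared
    elif n_shared is None:
        n_shared = min(sizes)
    n1, n2 = sizes
    if n_shared > min(n1, n2) or n1 + (n2 - n_shared) > len(ids):
        raise ValueError("population sizes incompatible with n_accessions/n_shared")
    pop1_parents = ids[:n1]
    pop2_parents = ids[:n_shared] + ids[n1 : n1 + (n2 - n_shared)]
    ped1 = make_pedigree(pop1_parents, config.reference_ids[0], "1")
    ped2 = make_pedigree(pop2_parents, config.reference_ids[1], "2")
    return validate_pedigree(pd.concat([ped1, ped2], ignore_index=True))


def derive_hybrid_genotypes(parents: GenotypeMatrix, pedigree: pd.DataFrame) -> GenotypeMatrix:
    """F1 genotypes: the allele-wise average of the two inbred parents.

    A hybrid is heterozygous (call 1) exactly at SNPs where its variable
    parent's allele differs from the common-reference parent's allele, and
    homozygous for the shared allele elsewhere, so its heterozygosity count
    equals the Hamming distance between the two parental genotype vectors.
    """
    validate_pedigree(pedigree)
    if not parents.is_homozygous():
        raise ValueError("parental matrix contains heterozygous calls; expected inbred lines")
    needed = set(pedigree["parent_id"]) | set(pedigree["reference_id"])
    unknown = needed - set(parents.accessions)
    if unknown:
        raise KeyError(f"pedigree parent(s) absent from genotype matrix: {sorted(unknown)[:5]}")
    p = parents.calls.loc[pedigree["parent_id"]].to_numpy(dtype=float)
    r = parents.calls.loc[pedigree["reference_id"]].to_numpy(dtype=float)
    hyb = (p + r) / 2.0
    calls = pd.DataFrame(hyb, index=pedigree["hybrid_id"].to_numpy(), columns=parents.snp_ids)
    return GenotypeMatrix(calls=calls, snp_map=parents.snp_map.copy())


def _roles(genotypes: GenotypeMatrix, pedigree: pd.DataFrame) -> pd.Series:
    hybrids = set(pedigree["hybrid_id"])
    refs = set(pedigree["reference_id"])
    return pd.Series(
        ["hybrid" if g in hybrids else "reference" if g in refs else "parent"
         for g in genotypes.accessions],
        index=genotypes.accessions,
    )


def genotypic_values(genotypes: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Noise-free genotypic value per genotype per trait.

    The polygenic component draws one additive effect per SNP per trait and
    standardizes the resulting scores to mean 0 / SD ``genetic_sd[trait]``
    across the inbred (fully homozygous) genotypes, then applies the same
    affine map to hybrids.  Because hybrid allele counts are parental
    averages and the map is affine, the mid-parent identity of additive
    architectures is exact.
    """
    rng = _rng(config, 1)
    calls = genotypes.calls.to_numpy(dtype=float)
    centered = calls - 1.0  # {-1, 0, +1} allele-count deviation
    is_inbred = ~np.any(calls == 1.0, axis=1)
    if not is_inbred.any():
        is_inbred = np.ones(calls.shape[0], dtype=bool)

    out = {}
    for trait in config.traits:
        beta = rng.normal(size=genotypes.n_snps)
        raw = centered @ beta
        mu = raw[is_inbred].mean()
        sd = raw[is_inbred].std(ddof=1) if is_inbred.sum() > 1 else 0.0
        g_sd = config.genetic_sd.get(trait, 0.0)
        poly = (raw - mu) / sd * g_sd if (sd > 0 and g_sd > 0) else np.zeros_like(raw)
        value = config.trait_baselines[trait] + poly
        for q in config.qtls:
            if q.trait != trait:
                continue
            g = calls[:, q.snp_index]
            value = value + np.where(g == 2, q.a, np.where(g == 1, q.d, -q.a))
        out[trait] = value
    return pd.DataFrame(out, index=genotypes.accessions)


def simulate_traits(
    genotypes: GenotypeMatrix, pedigree: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Replicate-level trait table for the full two-experiment design.

    Each population's experiment phenotypes its reference line, its variable
    parents and its hybrids; accessions shared between populations are grown
    in both experiments with independent replicate noise (no GxE on the
    genotypic values).
    """
    validate_pedigree(pedigree)
    gv = genotypic_values(genotypes, config)
    roles = _roles(genotypes, pedigree)
    rng = _rng(config, 2)

    rows = []
    for pop, ped in pedigree.groupby("population", sort=True):
        members = (
            [ped["reference_id"].iloc[0]]
            + ped["parent_id"].tolist()
            + ped["hybrid_id"].tolist()
        )
        for gid in members:
            for trait in config.traits:
                base = gv.at[gid, trait]
                noise = rng.normal(0.0, config.residual_sd_for(trait), size=config.n_replicates)
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        (gid, roles[gid], str(pop), trait, rep, base + noise[rep - 1])
                    )
    table = pd.DataFrame(
        rows, columns=["genotype_id", "role", "population", "trait", "replicate", "value"]
    )
    return validate_trait_table(table)


def simulate_growth_curves(config: SimConfig, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Per-plant daily logistic projected-leaf-area series.

    Each genotype gets a lognormally perturbed rate and asymptote; each plant
    gets an establishment-onset day jittered around the role-specific mean
    (hybrids ``hybrid_onset_advantage`` days earlier).  Area follows

        A(t) = K / (1 + (K/A0 - 1) * exp(-r (t - onset)))

    which passes through A0 at the onset day and rises monotonically to K.
    Returns long format (plant_id, genotype_id, role, population, time,
    area_mm2) with time in whole days after sowing.
    """
    validate_pedigree(pedigree)
    cp = config.curve_params
    rng = _rng(config, 3)
    days = np.arange(1, cp.n_days + 1, dtype=float)

    rows = []
    for pop, ped in pedigree.groupby("population", sort=True):
        members = (
            [(ped["reference_id"].iloc[0], "reference")]
            + [(p, "parent") for p in ped["parent_id"]]
            + [(h, "hybrid") for h in ped["hybrid_id"]]
        )
        for gid, role in members:
            rate = cp.growth_rate * float(rng.lognormal(0.0, cp.rate_cv)) if cp.rate_cv > 0 else cp.growth_rate
            asym = cp.asymptote * float(rng.lognormal(0.0, cp.asymptote_cv)) if cp.asymptote_cv > 0 else cp.asymptote
            if role == "hybrid" and cp.hybrid_asymptote_boost != 1.0:
                asym *= cp.hybrid_asymptote_boost
            onset_mu = cp.onset_day - (cp.hybrid_onset_advantage if role == "hybrid" else 0.0)
            for plant in range(1, config.n_replicates + 1):
                onset = onset_mu + (rng.normal(0.0, cp.onset_jitter_sd) if cp.onset_jitter_sd > 0 else 0.0)
                shape = asym / cp.initial_area - 1.0
                area = asym / (1.0 + shape * np.exp(-rate * (days - onset)))
                pid = f"{gid}_pop{pop}_r{plant}"
                for t, a in zip(days, area):
                    rows.append((pid, gid, role, str(pop), float(t), float(a)))
    return pd.DataFrame(
        rows, columns=["plant_id", "genotype_id", "role", "population", "time", "area_mm2"]
    )
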