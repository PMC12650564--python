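"""Simulated genotypes and phenotypes for testing every pipeline stage.

Genotypes come from a first-order haplotype copying chain: each marker's
allele is copied from the previous marker on the same haplotype with
probability ``ld_rho``, otherwise drawn fresh at its own frequency, so
adjacent-marker LD decays geometrically.  Optional full-sib families are
built by Mendelian sampling from simulated parents.  Phenotypes are
additive: QTL effects are normal, and the residual variance is scaled so
the realized sample heritability equals the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gpcomp.errors import ConfigurationError
from gpcomp.genotype_io import GenotypeMatrix, Marker, PhenotypeTable


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 200
    m_snps: int = 500
    n_qtl: int = 50
    h2: float = 0.5
    ld_rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_families: int = 0  # 0 = unrelated panel
    effect_distribution: str = "normal"  # or "gamma" (heavy-tailed, signed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.m_snps:
            raise ConfigurationError("n_qtl cannot exceed m_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError("h2 must lie in [0, 1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if self.h2 > 0 and self.n_qtl == 0:
            raise ConfigurationError("h2 > 0 requires at least one QTL")
        if self.effect_distribution not in ("normal", "gamma"):
            raise ConfigurationError("effect_distribution: normal or gamma")


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray  # true breeding values
    realized_h2: float


def _freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, size=cfg.m_snps)


def _haplotypes(
    n_hap: int, freqs: np.ndarray, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """n_hap x m binary haplotypes from the copying chain."""
    m = freqs.size
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        copy = rng.random(n_hap) < ld_rho
        fresh = (rng.random(n_hap) < freqs[j]).astype(np.int8)
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def _to_matrix(dosages: np.ndarray, prefix: str = "ind") -> GenotypeMatrix:
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages.astype(np.int8),
        [f"{prefix}{i}" for i in range(n)],
        [Marker(f"snp{j}", "1", j + 1, "A", "B") for j in range(m)],
    )


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Unrelated diploid panel with geometric adjacent-marker LD."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6E0]))
    freqs = _freqs(cfg, rng)
    hap = _haplotypes(2 * cfg.n_individuals, freqs, cfg.ld_rho, rng)
    dosages = hap[0::2] + hap[1::2]
    return _to_matrix(dosages)


def simulate_families(cfg: SimConfig) -> GenotypeMatrix:
    """Full-sib families: two parents each, offspring by Mendelian sampling.

    Gamete recombination between adjacent markers happens with
    probability ``(1 - ld_rho) / 2``, so tighter simulated LD also means
    tighter within-family co-segregation.
    """
    if cfg.n_families < 1:
        raise ConfigurationError("n_families must be >= 1 for family simulation")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xFA7]))
    freqs = _freqs(cfg, rng)
    m = cfg.m_snps
    base = cfg.n_individuals // cfg.n_families
    sizes = [base] * cfg.n_families
    sizes[-1] += cfg.n_individuals - base * cfg.n_families

    parent_haps = _haplotypes(4 * cfg.n_families, freqs, cfg.ld_rho, rng)
    rec_p = (1.0 - cfg.ld_rho) / 2.0
    dosages = np.empty((cfg.n_individuals, m), dtype=np.int8)
    row = 0
    for fam, size in enumerate(sizes):
        pats = parent_haps[4 * fam : 4 * fam + 2]
        mats = parent_haps[4 * fam + 2 : 4 * fam + 4]
        for _ in range(size):
            child = np.zeros(m, dtype=np.int8)
            for haps in (pats, mats):
                switch = rng.random(m) < rec_p
                which = np.cumsum(switch) % 2
                which = (which + rng.integers(2)) % 2
                child += haps[which, np.arange(m)]
            dosages[row] = child
            row += 1
    return _to_matrix(dosages)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig) -> SimResult:
    """Additive phenotypes with the target heritability hit exactly.

    QTL are sampled without replacement; effects are standard normal (or
    signed gamma for a heavy-tailed architecture); the residual SD is
    chosen from the realized TBV variance so var(TBV)/var(phenotype
    components) equals ``cfg.h2`` on this sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E]))
    n = g.n_individuals
    if cfg.n_qtl > 0:
        qtl = np.sort(rng.choice(g.n_snps, size=cfg.n_qtl, replace=False))
        if cfg.effect_distribution == "gamma":
            effects = rng.gamma(0.4, 1.0, size=cfg.n_qtl) * rng.choice(
                (-1.0, 1.0), size=cfg.n_qtl
            )
        else:
            effects = rng.normal(0.0, 1.0, size=cfg.n_qtl)
        q = g.values[:, qtl].astype(float)
        tbv = (q - q.mean(axis=0)) @ effects
    else:
        qtl = np.array([], dtype=int)
        effects = np.array([])
        tbv = np.zeros(n)

    var_tbv = float(np.var(tbv))
    if cfg.h2 >= 1.0:
        if var_tbv == 0:
            raise ConfigurationError("h2 = 1 needs non-zero genetic variance")
        resid = np.zeros(n)
    elif cfg.h2 <= 0.0 or var_tbv == 0:
        if cfg.h2 > 0 and var_tbv == 0:
            raise ConfigurationError("target h2 > 0 but genetic variance is zero")
        # h2 = 0: pure noise; zero out the genetic signal so the realized
        # heritability matches the target exactly
        effects = np.zeros_like(effects)
        tbv = np.zeros(n)
        var_tbv = 0.0
        resid = rng.normal(0.0, 1.0, size=n)
    else:
        raw = rng.normal(0.0, 1.0, size=n)
        raw = (raw - raw.mean()) / raw.std()
        sigma_e = np.sqrt(var_tbv * (1.0 - cfg.h2) / cfg.h2)
        resid = raw * sigma_e

    phenotype = tbv + resid
    var_e = float(np.var(resid))
    realized = var_tbv / (var_tbv + var_e) if (var_tbv + var_e) > 0 else 0.0

    import pandas as pd

    table = PhenotypeTable(
        pd.DataFrame({"trait": phenotype}, index=pd.Index(g.individual_ids, name="id"))
    )
    return SimResult(g, table, qtl, effects, tbv, realized)


def simulate(cfg: SimConfig) -> SimResult:
    """Genotypes (family-structured if requested) plus phenotypes."""
    g = simulate_families(cfg) if cfg.n_families > 0 else simulate_genotypes(cfg)
    return simulate_phenotypes(g, cfg)
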