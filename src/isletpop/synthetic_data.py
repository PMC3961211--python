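"""Synthetic genotype and haplotype generators with known truth.

Background genotypes are site-independent (no LD); linkage enters only through
planted autozygous tracts and shared sweep-founder haplotypes, which are the
signals the downstream callers detect. All generators are pure functions of
their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    SampleInfo,
    VariantTable,
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_pops: int = 1
    samples_per_pop: int = 50
    n_snps: int = 1000
    fst: float = 0.0  # Balding-Nichols differentiation parameter F
    inbreeding_f: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_spacing_bp: float = 3000.0  # mean inter-marker spacing (array-like density)
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if not 0 <= self.inbreeding_f < 1:
            raise ValueError("inbreeding_f must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.snp_spacing_bp <= 0 or self.n_snps < 1:
            raise ValueError("need positive snp spacing and at least one SNP")


@dataclass(frozen=True)
class TractSpec:
    """A planted autozygous tract for one sample."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    het_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("tract end_bp must exceed start_bp")
        if not 0 <= self.het_error_rate < 1:
            raise ValueError("het_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep around one core SNP."""

    core_index: int
    derived_freq: float
    shared_len_mean_bp: float
    background_shared_len_mean_bp: float

    def __post_init__(self) -> None:
        if not 0 < self.derived_freq < 1:
            raise ValueError("derived_freq must be in (0, 1)")
        if self.shared_len_mean_bp <= self.background_shared_len_mean_bp:
            raise ValueError("sweep shared length must exceed the background length")


def _positions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    gaps = rng.exponential(cfg.snp_spacing_bp, size=cfg.n_snps)
    pos = np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
    # enforce strict increase after rounding
    pos += np.arange(cfg.n_snps)
    return pos


def _variant_table(rng: np.random.Generator, cfg: SimConfig) -> VariantTable:
    pos = _positions(rng, cfg)
    n = cfg.n_snps
    ids = [f"snp{j + 1}" for j in range(n)]
    pairs = np.array([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")], dtype=object)
    pick = rng.integers(0, len(pairs), size=n)
    a = pairs[pick, 0]
    b = pairs[pick, 1]
    return VariantTable([cfg.chrom] * n, pos, ids, a, b)


def gen_balding_nichols(cfg: SimConfig):
    """Simulate unlinked genotypes under the Balding-Nichols model.

    Per SNP an ancestral frequency p ~ Uniform(maf_range); each population
    draws p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (p_k = p exactly when F = 0);
    each sample draws its genotype with inbreeding-adjusted probabilities
    {(1-p_k)^2 + f p_k(1-p_k), 2 p_k(1-p_k)(1-f), p_k^2 + f p_k(1-p_k)}
    for {0, 1, 2} copies of allele_b.

    Returns (GenotypeMatrix, SampleInfo, truth dict with F, f, p, p_k).
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _variant_table(rng, cfg)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)

    if cfg.fst > 0:
        a = p * (1 - cfg.fst) / cfg.fst
        b = (1 - p) * (1 - cfg.fst) / cfg.fst
        pk = rng.beta(a[None, :], b[None, :], size=(cfg.n_pops, cfg.n_snps))
    else:
        pk = np.broadcast_to(p, (cfg.n_pops, cfg.n_snps)).copy()

    f = cfg.inbreeding_f
    n_per = cfg.samples_per_pop
    calls = np.empty((cfg.n_pops * n_per, cfg.n_snps), dtype=np.int8)
    for k in range(cfg.n_pops):
        q = pk[k]
        p_hom_b = q * q + f * q * (1 - q)
        p_het = 2 * q * (1 - q) * (1 - f)
        u = rng.random(size=(n_per, cfg.n_snps))
        g = np.where(u < p_hom_b, 2, np.where(u < p_hom_b + p_het, 1, 0))
        calls[k * n_per:(k + 1) * n_per] = g

    samples = [f"pop{k + 1}_s{i + 1}" for k in range(cfg.n_pops) for i in range(n_per)]
    groups = [f"pop{k + 1}" for k in range(cfg.n_pops) for _ in range(n_per)]
    info = SampleInfo(samples, groups)
    truth = {"F": cfg.fst, "f": f, "p": p, "p_k": pk, "seed": cfg.seed}
    return GenotypeMatrix(samples, variants, calls), info, truth


def plant_roh(geno: GenotypeMatrix, tracts: list[TractSpec], seed: int) -> GenotypeMatrix:
    """Return a copy of ``geno`` with autozygous tracts planted.

    Within each tract every call becomes homozygous (heterozygotes resolved to
    one allele at random), then re-flipped to heterozygous independently at
    the tract's het_error_rate. Genotypes outside tracts are untouched.
    """
    by_sample: dict[str, list[TractSpec]] = {}
    for t in tracts:
        mine = by_sample.setdefault(t.sample_id, [])
        for o in mine:
            if o.chrom == t.chrom and t.start_bp < o.end_bp and o.start_bp < t.end_bp:
                raise ValueError(f"overlapping tracts for sample {t.sample_id}")
        mine.append(t)
    if not tracts:
        return geno

    rng = np.random.default_rng(seed)
    calls = geno.calls.copy()
    sample_index = {s: i for i, s in enumerate(geno.samples)}
    for t in tracts:
        if t.sample_id not in sample_index:
            raise KeyError(f"unknown sample {t.sample_id}")
        i = sample_index[t.sample_id]
        mask = (
            (geno.variants.chrom == t.chrom)
            & (geno.variants.pos >= t.start_bp)
            & (geno.variants.pos <= t.end_bp)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        g = calls[i, idx].astype(np.int8)
        het = g == 1
        g[het] = np.where(rng.random(het.sum()) < 0.5, 0, 2)
        g[g == MISSING] = np.where(rng.random((g == MISSING).sum()) < 0.5, 0, 2)
        flip = rng.random(idx.size) < t.het_error_rate
        g[flip] = 1
        calls[i, idx] = g
    return GenotypeMatrix(list(geno.samples), geno.variants, calls)


def gen_sweep_haplotypes(cfg: SimConfig, sweep: SweepSpec):
    """Simulate phased haplotypes with a planted sweep.

    Background alleles are independent per site at a per-site derived
    frequency drawn from maf_range. Haplotypes carrying the derived core
    allele copy a single shared founder haplotype over an interval around the
    core whose one-sided lengths are Exponential(shared_len_mean_bp);
    non-carriers do the same with a distinct founder and
    background_shared_len_mean_bp.

    Returns (HaplotypeMatrix, truth dict with carriers and founder intervals).
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _variant_table(rng, cfg)
    n_hap = 2 * cfg.n_pops * cfg.samples_per_pop
    if not 0 <= sweep.core_index < cfg.n_snps:
        raise IndexError("core_index out of range")

    freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    haps = (rng.random((n_hap, cfg.n_snps)) < freq[None, :]).astype(np.uint8)

    n_carriers = int(round(sweep.derived_freq * n_hap))
    if n_carriers < 2 or n_carriers > n_hap - 2:
        raise ValueError("derived_freq leaves fewer than 2 carriers or 2 non-carriers")
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    carrier_mask = np.zeros(n_hap, dtype=bool)
    carrier_mask[carriers] = True

    founder_d = (rng.random(cfg.n_snps) < freq).astype(np.uint8)
    founder_a = (rng.random(cfg.n_snps) < freq).astype(np.uint8)
    founder_d[sweep.core_index] = 1
    founder_a[sweep.core_index] = 0

    pos = variants.pos
    core_pos = pos[sweep.core_index]
    intervals = np.empty((n_hap, 2), dtype=np.int64)
    for h in range(n_hap):
        mean = sweep.shared_len_mean_bp if carrier_mask[h] else sweep.background_shared_len_mean_bp
        founder = founder_d if carrier_mask[h] else founder_a
        left = core_pos - rng.exponential(mean)
        right = core_pos + rng.exponential(mean)
        sel = (pos >= left) & (pos <= right)
        haps[h, sel] = founder[sel]
        intervals[h] = (int(np.ceil(left)), int(np.floor(right)))
    haps[carrier_mask, sweep.core_index] = 1
    haps[~carrier_mask, sweep.core_index] = 0

    samples = [f"s{i + 1}" for i in range(n_hap // 2)]
    # code ancestral = allele_a so derived bit == stored bit
    variants = VariantTable(
        variants.chrom, variants.pos, variants.ids,
        variants.allele_a, variants.allele_b, variants.allele_a,
    )
    truth = {
        "carriers": carriers,
        "intervals": intervals,
        "core_index": sweep.core_index,
        "core_pos": int(core_pos),
        "seed": cfg.seed,
    }
    return HaplotypeMatrix(samples, variants, haps), truth


def null_split(geno: GenotypeMatrix, seed: int) -> SampleInfo:
    """Random permutation split into two equal halves labelled g1/g2.

    With an odd sample count the larger group is g1.
    """
    n = geno.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n1 = (n + 1) // 2
    groups = np.empty(n, dtype=object)
    groups[perm[:n1]] = "g1"
    groups[perm[n1:]] = "g2"
    return SampleInfo(list(geno.samples), list(groups))
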