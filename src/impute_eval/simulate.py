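"""Synthetic diploid populations for imputation-accuracy studies.

The generator emulates, at desk scale, the statistical features that a
sequence-level imputation evaluation in a livestock population depends on:

* a site-frequency spectrum skewed toward rare variants (allele frequencies
  drawn from a symmetric Beta law, folded to MAF; the default shape is
  calibrated so roughly 13.5% of realized sites have MAF <= 0.03);
* linkage disequilibrium decaying with distance, induced by an
  ancestral-mosaic copying process (every founder haplotype is a mosaic of a
  small pool of ancestral haplotypes, switching ancestor with a fixed
  per-site probability);
* a related target generation bred from the founders by Poisson-recombining
  gametes, with a small number of heavily used sires;
* a sparse "HD array" subset of sites ascertained toward common variants
  (array membership sampled with probability proportional to MAF);
* functional-impact labels (high / moderate / low / modifier) whose
  high+moderate classes are enriched for rare variants;
* sequencing-style artifacts: per-genotype errors, phred-scaled genotype
  qualities, and site-level filter statistics with a configurable fraction
  of sites violating each QC threshold.

All randomness flows from ``SimConfig.seed`` through named
:class:`numpy.random.Generator` streams; no global state is touched, and a
fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    IMPACT_CLASSES,
    SITE_STAT_COLUMNS,
    GenotypeMatrix,
    HaplotypePanel,
    new_variant_table,
)

#: value ranges used to draw site filter statistics; (pass_lo, pass_hi,
#: fail_lo, fail_hi) per statistic, chosen to straddle the standard GATK
#: hard-filter thresholds without ever landing exactly on one.
_SITE_STAT_RANGES = {
    "qd": (5.0, 35.0, 0.0, 1.9),
    "fs": (0.0, 30.0, 60.5, 200.0),
    "mq": (45.0, 60.0, 10.0, 39.5),
    "read_pos_rank_sum": (-4.0, 4.0, -20.0, -8.5),
    "mq_rank_sum": (-4.0, 4.0, -20.0, -13.0),
    "sor": (0.2, 2.5, 3.1, 9.0),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults describe the standard evaluation scenario used throughout the
    tests and docs: 200 animals over 2 chromosomes of 100 Mb with 10,000
    polymorphic sequence sites each, an array covering ~1.9% of sites
    (mirroring the ~777k-array-to-~30M-sequence density ratio of bovine
    data), and a recombination rate of 1 cM/Mb.
    """

    n_founders: int = 60
    n_samples: int = 200
    n_chromosomes: int = 2
    chrom_length_bp: int = 100_000_000
    n_sites_per_chrom: int = 10_000
    array_fraction: float = 0.019
    #: Beta(shape, shape) law for ancestral allele frequencies; calibrated by
    #: simulation so ~13.5% of realized sites are rare (MAF <= 0.03).
    sfs_shape: float = 0.25
    n_ancestors: int = 40
    recomb_rate: float = 1e-8  # Morgans per bp (1 cM/Mb)
    mosaic_switch_rate: float = 5e-4  # per-site ancestor-switch probability
    #: founder MAF at or below which a site is realized as a recent mutation:
    #: carrier haplotypes are redrawn at random, so the minor allele sits in
    #: weak LD with the mosaic background the array sites tag (young alleles
    #: are harder to impute than old ones, as in real sequence data)
    recent_mutation_maf: float = 0.05
    #: per-genotype call error; the default reproduces the ~99.6%
    #: array-vs-sequence genotype concordance typical of ~15x bovine calls
    genotype_error_rate: float = 0.004
    gq_distribution_params: tuple[float, float] = (45.0, 15.0)  # mean, sd of GQ
    annotation_proportions: dict = field(
        default_factory=lambda: {"high": 0.01, "moderate": 0.04, "low": 0.05, "modifier": 0.90}
    )
    rare_enrichment_high_moderate: float = 0.15
    rare_maf_threshold: float = 0.03
    site_stat_fail_fractions: dict = field(
        default_factory=lambda: {s: 0.01 for s in SITE_STAT_COLUMNS}
    )
    n_sires: int = 12
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_founders", "n_samples", "n_chromosomes", "chrom_length_bp", "n_ancestors", "n_sires"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_sites_per_chrom < 2:
            raise ValueError("n_sites_per_chrom must be >= 2")
        if not 0.0 < self.array_fraction < 1.0:
            raise ValueError("array_fraction must lie in (0, 1)")
        if self.sfs_shape <= 0:
            raise ValueError("sfs_shape must be positive")
        for name in ("mosaic_switch_rate", "genotype_error_rate", "rare_enrichment_high_moderate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        total = sum(self.annotation_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"annotation_proportions must sum to 1, got {total}")
        if set(self.annotation_proportions) - set(IMPACT_CLASSES):
            raise ValueError("annotation_proportions keys must be impact classes")
        for stat, frac in self.site_stat_fail_fractions.items():
            if stat not in _SITE_STAT_RANGES:
                raise ValueError(f"unknown site statistic {stat!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"site_stat_fail_fractions[{stat!r}] must lie in [0, 1]")


def _named_rng(seed: int, stream: str) -> np.random.Generator:
    """Named child generator so each stage has an independent, reproducible
    stream (stream names are hashed with crc32, which is process-stable)."""
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return _named_rng(config.seed, stream)


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct 1-based positions, sorted; oversample-and-dedupe."""
    draw = n
    while True:
        cand = np.unique(rng.integers(1, length + 1, size=draw + max(16, draw // 8)))
        if len(cand) >= n:
            return np.sort(rng.choice(cand, size=n, replace=False))
        draw *= 2


def _mosaic_haplotypes(
    rng: np.random.Generator,
    ancestors: np.ndarray,
    n_haplotypes: int,
    switch_rate: float,
) -> np.ndarray:
    """Each output haplotype copies segments of the ancestral haplotypes,
    switching ancestor with probability ``switch_rate`` at each site."""
    n_anc, m = ancestors.shape
    switches = rng.random((n_haplotypes, m)) < switch_rate
    switches[:, 0] = True
    choices = rng.integers(0, n_anc, size=(n_haplotypes, m))
    # forward-fill the ancestor chosen at the most recent switch
    idx = np.where(switches, np.arange(m)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    paths = np.take_along_axis(choices, idx, axis=1)
    return np.take_along_axis(ancestors, paths, axis=0)


def simulate_founders(config: SimConfig) -> HaplotypePanel:
    """Generate the founder generation.

    Allele frequencies are drawn per site from Beta(sfs_shape, sfs_shape),
    realized in a pool of ``n_ancestors`` ancestral haplotypes, and founder
    haplotypes are mosaics of that pool.  Sites monomorphic across the
    realized founders are dropped, so the returned panel can hold slightly
    fewer than ``n_sites_per_chrom`` sites per chromosome.
    """
    config.validate()
    rng = _rng(config, "founders")
    n_hap = 2 * config.n_founders

    chroms, positions, hap_blocks = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        m = config.n_sites_per_chrom
        pos = _draw_positions(rng, m, config.chrom_length_bp)
        freqs = rng.beta(config.sfs_shape, config.sfs_shape, size=m)
        ancestors = (rng.random((config.n_ancestors, m)) < freqs).astype(np.int8)
        haps = _mosaic_haplotypes(rng, ancestors, n_hap, config.mosaic_switch_rate)
        _rejuvenate_rare_sites(rng, haps, config.recent_mutation_maf)
        poly = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < n_hap)
        chroms.append(np.repeat(str(c), poly.sum()))
        positions.append(pos[poly])
        hap_blocks.append(haps[:, poly])

    haplotypes = np.concatenate(hap_blocks, axis=1)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    ref, alt = _draw_alleles(rng, len(pos))
    sites = new_variant_table(chrom=chrom, pos=pos, ref=ref, alt=alt)
    p = haplotypes.mean(axis=0)
    sites["maf"] = np.minimum(p, 1 - p)
    sample_ids = [f"F{i:04d}" for i in range(config.n_founders)]
    return HaplotypePanel(sample_ids=sample_ids, haplotypes=haplotypes, sites=sites, phased=True)


def _rejuvenate_rare_sites(rng: np.random.Generator, haps: np.ndarray, maf_threshold: float) -> None:
    """Re-realize rare sites as recent mutations, in place.

    At sites whose realized founder MAF is at or below ``maf_threshold`` the
    carrier haplotypes are re-drawn uniformly (the column is permuted),
    detaching the minor allele from the ancestral mosaic.  Frequencies are
    untouched; only the linkage of rare alleles to the old haplotype
    background is broken, mirroring the youth of rare variants.
    """
    if maf_threshold <= 0:
        return
    n_hap = haps.shape[0]
    count = haps.sum(axis=0)
    freq = count / n_hap
    cols = np.flatnonzero((np.minimum(freq, 1 - freq) <= maf_threshold) & (count > 0) & (count < n_hap))
    if cols.size == 0:
        return
    order = np.argsort(rng.random((n_hap, cols.size)), axis=0)
    haps[:, cols] = np.take_along_axis(haps[:, cols], order, axis=0)


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return bases[ref_idx], bases[alt_idx]


def breed_population(founders: HaplotypePanel, config: SimConfig) -> HaplotypePanel:
    """Breed ``n_samples`` offspring from the founders.

    A small pool of sires (``n_sires``) is mated to randomly drawn dams, so
    progeny are enriched for half-sib relationships like a cattle cohort.
    Each gamete recombines the parent's two haplotypes with a
    Poisson(recomb_rate * chrom_length_bp) crossover count.  The pedigree
    (with simulated progeny counts for downstream reference selection) is
    attached to the returned panel.
    """
    config.validate()
    if founders.n_samples < 2:
        raise ValueError("need at least 2 founders to breed")
    if not founders.phased:
        raise ValueError("founders must be phased")
    rng = _rng(config, "breed")

    chrom_arr = founders.sites["chrom"].to_numpy()
    pos_arr = founders.sites["pos"].to_numpy()
    chrom_ids = list(dict.fromkeys(chrom_arr))
    chrom_slices = {c: np.flatnonzero(chrom_arr == c) for c in chrom_ids}

    n_sires = min(config.n_sires, founders.n_samples - 1)
    sire_pool = rng.choice(founders.n_samples, size=n_sires, replace=False)

    n = config.n_samples
    sires = sire_pool[rng.integers(0, n_sires, size=n)]
    dams = rng.integers(0, founders.n_samples, size=n)
    clash = dams == sires
    while clash.any():
        dams[clash] = rng.integers(0, founders.n_samples, size=clash.sum())
        clash = dams == sires

    haplotypes = np.empty((2 * n, founders.n_sites), dtype=np.int8)
    for i in range(n):
        for which, parent in ((0, sires[i]), (1, dams[i])):
            haplotypes[2 * i + which] = _make_gamete(rng, founders, parent, chrom_slices, pos_arr, config)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    pedigree = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sire_id": [founders.sample_ids[s] for s in sires],
            "dam_id": [founders.sample_ids[d] for d in dams],
            "progeny_count": rng.poisson(5.0, size=n),
        }
    )
    sites = founders.sites.copy()
    p = haplotypes.mean(axis=0)
    sites["maf"] = np.minimum(p, 1 - p)
    return HaplotypePanel(
        sample_ids=sample_ids, haplotypes=haplotypes, sites=sites, phased=True, pedigree=pedigree
    )


def _make_gamete(
    rng: np.random.Generator,
    parents: HaplotypePanel,
    parent: int,
    chrom_slices: dict,
    pos_arr: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    h0 = parents.haplotypes[2 * parent]
    h1 = parents.haplotypes[2 * parent + 1]
    gamete = np.empty_like(h0)
    for c, idx in chrom_slices.items():
        n_cross = rng.poisson(config.recomb_rate * config.chrom_length_bp)
        start = rng.integers(0, 2)
        if n_cross == 0:
            phase = np.full(len(idx), start, dtype=np.int8)
        else:
            cross_pos = np.sort(rng.integers(1, config.chrom_length_bp + 1, size=n_cross))
            segment = np.searchsorted(cross_pos, pos_arr[idx], side="left")
            phase = ((start + segment) % 2).astype(np.int8)
        gamete[idx] = np.where(phase == 0, h0[idx], h1[idx])
    return gamete


def assign_annotations(sites: pd.DataFrame, config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw functional-impact labels with rare-variant enrichment.

    Marginal class proportions follow ``annotation_proportions`` while the
    share of rare sites (MAF <= rare_maf_threshold) within the combined
    high+moderate classes is tilted toward ``rare_enrichment_high_moderate``.
    MAF must already be computed for every site.
    """
    config.validate()
    if sites["maf"].isna().any():
        raise ValueError("assign_annotations requires maf for every site")
    rng = _named_rng(config.seed if seed is None else seed, "annotations")

    pi = {c: config.annotation_proportions.get(c, 0.0) for c in IMPACT_CLASSES}
    rare = (sites["maf"].to_numpy() <= config.rare_maf_threshold)
    f = rare.mean()
    hm = pi["high"] + pi["moderate"]
    e = config.rare_enrichment_high_moderate

    # Class law conditional on rarity, chosen so that marginals match pi and
    # P(rare | class in {high, moderate}) = e.  Feasibility is clamped.
    q_rare = dict(pi)
    q_common = dict(pi)
    if 0.0 < f < 1.0 and hm > 0.0:
        target_rare_hm = min(e * hm, f * 0.999, hm)  # total mass rare & high+moderate
        scale_rare = target_rare_hm / (f * hm)
        for c in ("high", "moderate"):
            q_rare[c] = pi[c] * scale_rare
            q_common[c] = (pi[c] - f * q_rare[c]) / (1.0 - f)
        # redistribute leftover mass over low/modifier proportionally
        rest = pi["low"] + pi["modifier"]
        if rest > 0:
            rare_rest = 1.0 - q_rare["high"] - q_rare["moderate"]
            common_rest = 1.0 - q_common["high"] - q_common["moderate"]
            for c in ("low", "modifier"):
                q_rare[c] = pi[c] / rest * rare_rest
                q_common[c] = pi[c] / rest * common_rest

    labels = np.empty(len(sites), dtype=object)
    for mask, law in ((rare, q_rare), (~rare, q_common)):
        if mask.any():
            probs = np.array([max(law[c], 0.0) for c in IMPACT_CLASSES])
            probs = probs / probs.sum()
            labels[mask] = rng.choice(IMPACT_CLASSES, size=mask.sum(), p=probs)

    out = sites.copy()
    out["impact"] = labels
    return out


def degrade_to_sequenced_genotypes(panel: HaplotypePanel, config: SimConfig) -> GenotypeMatrix:
    """Turn truth haplotypes into sequencing-style called genotypes.

    Injects per-genotype errors at ``genotype_error_rate`` (an erroneous call
    is replaced by one of the two other genotype codes, uniformly), draws
    phred-scaled genotype qualities from a rounded normal law, and fills the
    site filter statistics so that the configured fraction of sites violates
    each hard-filter threshold.
    """
    config.validate()
    if not panel.phased:
        raise ValueError("panel must be phased")
    rng = _rng(config, "degrade")

    codes = panel.genotypes().astype(np.int8)
    err = rng.random(codes.shape) < config.genotype_error_rate
    if err.any():
        # replace with one of the other two codes, uniformly
        shift = rng.integers(1, 3, size=err.sum())
        codes[err] = ((codes[err] + shift) % 3).astype(np.int8)

    mean, sd = config.gq_distribution_params
    gq = np.clip(np.rint(rng.normal(mean, sd, size=codes.shape)), 0, 99).astype(np.int16)

    sites = panel.sites.copy()
    m = len(sites)
    for stat, (plo, phi, flo, fhi) in _SITE_STAT_RANGES.items():
        frac = config.site_stat_fail_fractions.get(stat, 0.0)
        vals = rng.uniform(plo, phi, size=m)
        failing = rng.random(m) < frac
        vals[failing] = rng.uniform(flo, fhi, size=failing.sum())
        sites[stat] = vals

    return GenotypeMatrix(sample_ids=list(panel.sample_ids), codes=codes, sites=sites, gq=gq)


def select_array_sites(
    sites: pd.DataFrame, array_fraction: float, seed: int
) -> pd.DataFrame:
    """Flag an "HD array" subset of sites.

    Sites are drawn without replacement with probability proportional to
    MAF, mimicking the common-variant ascertainment of commercial chips.
    Raises if any chromosome would end up with fewer than 2 array sites.
    """
    if not 0.0 < array_fraction < 1.0:
        raise ValueError("array_fraction must lie in (0, 1)")
    maf = sites["maf"].to_numpy(dtype=float)
    if np.isnan(maf).any():
        raise ValueError("select_array_sites requires maf for every site")
    n_array = int(round(array_fraction * len(sites)))
    weights = np.clip(maf, 0.0, None)
    if weights.sum() <= 0:
        raise ValueError("no polymorphic sites to place on the array")
    rng = _named_rng(seed, "array")
    chosen = rng.choice(len(sites), size=n_array, replace=False, p=weights / weights.sum())
    flag = np.zeros(len(sites), dtype=bool)
    flag[chosen] = True
    out = sites.copy()
    out["on_array"] = flag
    per_chrom = out.groupby("chrom", sort=False)["on_array"].sum()
    if (per_chrom < 2).any():
        bad = per_chrom[per_chrom < 2].index.tolist()
        raise ValueError(f"array_fraction {array_fraction} leaves <2 array sites on chromosome(s) {bad}")
    return out


def simulate_population(config: SimConfig) -> tuple[HaplotypePanel, GenotypeMatrix]:
    """Convenience end-to-end generator: founders -> offspring -> annotations
    -> array flags -> degraded sequencing genotypes.

    Returns the truth panel (phased, with annotated sites and array flags)
    and the matching sequencing-style genotype matrix.
    """
    founders = simulate_founders(config)
    cohort = breed_population(founders, config)
    sites = assign_annotations(cohort.sites, config)
    sites = select_array_sites(sites, config.array_fraction, config.seed)
    cohort = replace(cohort, sites=sites)
    observed = degrade_to_sequenced_genotypes(cohort, config)
    return cohort, observed
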