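"""Core in-memory containers shared by every pipeline stage.

Variant metadata lives in a plain :class:`pandas.DataFrame` (one row per
site, ordered by chromosome then position) so that filtering, joining and
stratification can use ordinary pandas operations.  Haplotypes and genotypes
are dense ``numpy`` arrays: sites are few enough at evaluation scale
(tens of thousands) that sparse storage would only obscure the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: genotype code for a missing call
MISSING = -1

#: functional-impact classes, most to least severe
IMPACT_CLASSES = ("high", "moderate", "low", "modifier")

#: site-level filter statistics carried in the variant table / VCF INFO
SITE_STAT_COLUMNS = ("qd", "fs", "mq", "read_pos_rank_sum", "mq_rank_sum", "sor")

VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "maf",
    "impact",
    "on_array",
) + SITE_STAT_COLUMNS


def new_variant_table(
    chrom: Sequence[str],
    pos: Sequence[int],
    ref: Sequence[str] | str = "A",
    alt: Sequence[str] | str = "C",
    maf: Sequence[float] | float = np.nan,
    impact: Sequence[str] | str = "modifier",
    on_array: Sequence[bool] | bool = False,
    **site_stats: Sequence[float] | float,
) -> pd.DataFrame:
    """Build a variant table with the canonical column set.

    Unspecified site statistics are NaN, meaning "statistic not reported";
    QC rules skip a site where the statistic they test is absent.
    """
    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str) if not np.isscalar(chrom) else np.repeat(str(chrom), n),
            "pos": np.asarray(pos, dtype=np.int64),
        }
    )
    for col, val in [("ref", ref), ("alt", alt), ("maf", maf), ("impact", impact), ("on_array", on_array)]:
        df[col] = val
    for col in SITE_STAT_COLUMNS:
        df[col] = site_stats.get(col, np.nan)
    validate_variant_table(df)
    return df


def validate_variant_table(sites: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"variant table lacks columns: {missing}")
    if sites["pos"].le(0).any():
        raise ValueError("positions must be 1-based and positive")
    dup = sites.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ValueError("duplicate (chrom, pos) in variant table")
    # strictly increasing position within each chromosome block
    for _, grp in sites.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("positions must be sorted within chromosome")
    bad = sites["maf"].dropna()
    if ((bad < 0) | (bad > 0.5)).any():
        raise ValueError("maf outside [0, 0.5]")


def site_key(sites: pd.DataFrame) -> pd.Index:
    """(chrom, pos) multi-key used to align tables across stages."""
    return pd.MultiIndex.from_arrays([sites["chrom"], sites["pos"]], names=["chrom", "pos"])


@dataclass
class HaplotypePanel:
    """Phased haplotypes for diploid samples over an ordered site set.

    ``haplotypes`` has shape ``(2 * n_samples, n_sites)``; rows ``2i`` and
    ``2i + 1`` are the two haplotypes of sample ``i``.  Alleles are 0/1.
    """

    sample_ids: list[str]
    haplotypes: np.ndarray
    sites: pd.DataFrame
    phased: bool = True
    pedigree: pd.DataFrame | None = None  # columns sample_id, sire_id, dam_id, progeny_count

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotypes must be (2 * n_samples, n_sites)")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("haplotype and site counts disagree")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        validate_variant_table(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """Per-sample genotype codes (alt-allele counts), shape (n, m)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset_samples(self, ids: Sequence[str]) -> "HaplotypePanel":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.concatenate([(2 * index[s], 2 * index[s] + 1) for s in ids]) if ids else np.empty(0, int)
        return replace(self, sample_ids=list(ids), haplotypes=self.haplotypes[rows], pedigree=None)

    def subset_sites(self, mask: np.ndarray) -> "HaplotypePanel":
        mask = np.asarray(mask)
        return replace(self, haplotypes=self.haplotypes[:, mask], sites=self.sites.loc[mask].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Unphased genotype codes {0, 1, 2, MISSING} with optional dosages/GQ."""

    sample_ids: list[str]
    codes: np.ndarray
    sites: pd.DataFrame
    dosages: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.sites)
        if self.codes.shape != (n, m):
            raise ValueError(f"codes must be shape {(n, m)}, got {self.codes.shape}")
        if self.codes.size and not np.isin(self.codes, (0, 1, 2, MISSING)).all():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        for name in ("dosages", "gq"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != (n, m):
                raise ValueError(f"{name} must match codes shape")
        validate_variant_table(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def observed_maf(self) -> np.ndarray:
        """Alt-frequency folded to MAF, from non-missing calls; NaN if no calls."""
        obs = self.codes != MISSING
        counts = np.where(obs, self.codes, 0).sum(axis=0).astype(float)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, counts / denom, np.nan)
        return np.minimum(p, 1.0 - p)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([index[s] for s in ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(ids),
            codes=self.codes[rows],
            sites=self.sites,
            dosages=None if self.dosages is None else self.dosages[rows],
            gq=None if self.gq is None else self.gq[rows],
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            codes=self.codes[:, mask],
            sites=self.sites.loc[mask].reset_index(drop=True),
            dosages=None if self.dosages is None else self.dosages[:, mask],
            gq=None if self.gq is None else self.gq[:, mask],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            codes=self.codes.copy(),
            sites=self.sites.copy(),
            dosages=None if self.dosages is None else self.dosages.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )


@dataclass
class ImputationResult:
    """Output of one imputation run on one target set.

    ``dosages`` are expected alt-allele counts in [0, 2]; ``best_guess`` the
    hard-called genotypes; ``rsq`` the model-based imputation quality
    (variance of half-dosages over binomial variance) per site.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray
    best_guess: np.ndarray
    rsq: np.ndarray
    engine: str

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), len(self.sites)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.best_guess = np.asarray(self.best_guess, dtype=np.int8)
        self.rsq = np.asarray(self.rsq, dtype=float)
        if self.dosages.shape != (n, m) or self.best_guess.shape != (n, m):
            raise ValueError("dosages/best_guess must be (n_samples, n_sites)")
        if self.rsq.shape != (m,):
            raise ValueError("rsq must be one value per site")
        if self.dosages.size and (np.nanmin(self.dosages) < -1e-9 or np.nanmax(self.dosages) > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")


def round_half_toward(dosages: np.ndarray, major_genotype: np.ndarray | int) -> np.ndarray:
    """Round dosages to genotype codes; exact halves go toward the major genotype.

    ``major_genotype`` is the most common reference-panel genotype per site
    (scalar or per-site vector).  Deterministic replacement for banker's
    rounding so .5 dosages have a reproducible call.
    """
    d = np.asarray(dosages, dtype=float)
    lo = np.floor(d)
    frac = d - lo
    up = frac > 0.5
    major = np.broadcast_to(np.asarray(major_genotype, dtype=float), d.shape)
    tie_up = (frac == 0.5) & (major > d)
    out = lo + (up | tie_up)
    return np.clip(out, 0, 2).astype(np.int8)


def model_rsq_haploid(hap_dosages: np.ndarray) -> np.ndarray:
    """Imputation-quality estimate from haplotype dosages (Minimac-style Rsq).

    Per site: population variance (divide by n) of the per-haplotype alt
    dosages divided by the binomial variance ``p(1-p)``, ``p`` being the
    mean haplotype dosage; 0 when the estimated frequency is 0 or 1,
    clamped into [0, 1].  Perfectly imputed alleles give exactly 1.
    """
    d = np.asarray(hap_dosages, dtype=float)
    p = d.mean(axis=0)
    var = d.var(axis=0)
    denom = p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        rsq = np.where(denom > 0, var / denom, 0.0)
    return np.clip(rsq, 0.0, 1.0)


def model_rsq(dosages: np.ndarray) -> np.ndarray:
    """Rsq from diploid (per-sample) dosages when haplotype dosages are
    unavailable: variance of dosages over the Hardy-Weinberg genotype
    variance ``2 p(1-p)``.  Coincides with the haploid formula in
    expectation under random mating."""
    d = np.asarray(dosages, dtype=float)
    p = d.mean(axis=0) / 2.0
    var = d.var(axis=0)
    denom = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        rsq = np.where(denom > 0, var / denom, 0.0)
    return np.clip(rsq, 0.0, 1.0)
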