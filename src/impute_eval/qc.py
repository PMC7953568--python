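"""Genotype and site quality control for sequencing-derived VCF panels.

Implements the standard GATK-style hard filters on site statistics
(QD, FS, MQ, ReadPosRankSum, MQRankSum, SOR), the biallelic restriction, a
phred-scaled genotype-quality filter that sets low-confidence genotypes to
missing, a per-site missingness cap, and a minor-allele-frequency floor.
Removal is applied in a fixed, logged order — site-statistic rules, then
biallelic, then genotype missingness, then MAF (recomputed after genotypes
are set missing) — so that the per-rule counts in the report reconcile
exactly with the input and output dimensions.

All thresholds use strict inequalities: a site sitting exactly on a
threshold (QD = 2.0, FS = 60.0, ...) survives.  A site whose statistic is
absent (NaN) is not tested by that rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, site_key

logger = logging.getLogger(__name__)

#: canonical order in which exclusion rules are attributed; a site violating
#: several rules is counted under the first one.
SITE_RULE_ORDER = ("qd", "fs", "mq", "read_pos_rank_sum", "mq_rank_sum", "sor")


@dataclass
class QCThresholds:
    """Hard-filter thresholds; defaults are the standard exclusion criteria
    for bovine short-read SNP calls."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    read_pos_rank_sum_min: float = -8.0
    mq_rank_sum_min: float = -12.5
    sor_max: float = 3.0
    maf_min: float = 0.01
    gq_min: int = 15
    max_missing_individuals: int = 40
    #: fallback missingness cap as a fraction of the cohort, used when the
    #: cohort differs from the 151-animal design the absolute count assumes
    max_missing_fraction: float = 0.265
    apply_gq_filter: bool = True

    def validate(self) -> None:
        for name in ("qd_min", "fs_max", "mq_min", "read_pos_rank_sum_min", "mq_rank_sum_min", "sor_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")

    def missing_cap(self, n_samples: int, reference_cohort: int = 151) -> int:
        """Absolute missingness cap, rescaled by fraction for other cohorts."""
        if n_samples == reference_cohort:
            return self.max_missing_individuals
        return int(np.floor(self.max_missing_fraction * n_samples))


@dataclass
class QCReport:
    n_sites_in: int = 0
    n_removed_by_rule: dict = field(default_factory=dict)
    n_genotypes_set_missing: int = 0
    n_sites_out: int = 0

    def reconciles(self) -> bool:
        return self.n_sites_out == self.n_sites_in - sum(self.n_removed_by_rule.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_sites_in": self.n_sites_in,
                "n_removed_by_rule": self.n_removed_by_rule,
                "n_genotypes_set_missing": self.n_genotypes_set_missing,
                "n_sites_out": self.n_sites_out,
            },
            indent=2,
        )


def _site_stat_violations(sites: pd.DataFrame, thr: QCThresholds) -> dict[str, np.ndarray]:
    """Per-rule boolean violation masks; NaN statistics never violate."""
    col = {r: sites[r].to_numpy(dtype=float) for r in SITE_RULE_ORDER if r in sites.columns}
    out = {}
    with np.errstate(invalid="ignore"):
        out["qd"] = col["qd"] < thr.qd_min
        out["fs"] = col["fs"] > thr.fs_max
        out["mq"] = col["mq"] < thr.mq_min
        out["read_pos_rank_sum"] = col["read_pos_rank_sum"] < thr.read_pos_rank_sum_min
        out["mq_rank_sum"] = col["mq_rank_sum"] < thr.mq_rank_sum_min
        out["sor"] = col["sor"] > thr.sor_max
    return out


def apply_genotype_filters(
    genotypes: GenotypeMatrix, thresholds: QCThresholds
) -> tuple[GenotypeMatrix, QCReport]:
    """Set low-GQ genotypes missing, then drop over-missing sites.

    With ``apply_gq_filter`` false the GQ step is skipped (the less strict
    genotype-filtering scenario); the missingness cap still applies.
    """
    thresholds.validate()
    report = QCReport(n_sites_in=genotypes.n_sites)
    out = genotypes.copy()

    n_set = 0
    if thresholds.apply_gq_filter:
        if out.gq is None:
            raise ValueError("apply_gq_filter=True but genotype matrix has no GQ")
        low = (out.gq < thresholds.gq_min) & (out.codes != MISSING)
        n_set = int(low.sum())
        out.codes[low] = MISSING
    report.n_genotypes_set_missing = n_set

    cap = thresholds.missing_cap(out.n_samples)
    if cap >= out.n_samples:
        logger.warning("missingness cap %d >= cohort size %d; rule is vacuous", cap, out.n_samples)
    n_missing = (out.codes == MISSING).sum(axis=0)
    keep = n_missing <= cap
    report.n_removed_by_rule["missing_individuals"] = int((~keep).sum())
    out = out.subset_sites(keep)
    report.n_sites_out = out.n_sites
    return out, report


def apply_site_filters(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds,
) -> tuple[pd.DataFrame, GenotypeMatrix, QCReport]:
    """Full site-level QC pass.

    Order: site-statistic hard filters -> biallelic restriction ->
    genotype-level filtering (GQ missingness + missingness cap) -> MAF floor
    computed on the surviving genotype calls.  Returns the filtered variant
    table, the filtered genotype matrix, and a reconciling report.
    """
    thresholds.validate()
    if len(variants) != genotypes.n_sites:
        raise ValueError("variant table and genotype matrix disagree on site count")
    report = QCReport(n_sites_in=len(variants))

    # 1. site-statistic rules, attributed in canonical order
    violations = _site_stat_violations(variants, thresholds)
    removed = np.zeros(len(variants), dtype=bool)
    for rule in SITE_RULE_ORDER:
        hit = violations[rule] & ~removed
        report.n_removed_by_rule[rule] = int(hit.sum())
        removed |= hit
    keep = ~removed
    variants = variants.loc[keep].reset_index(drop=True)
    genotypes = genotypes.subset_sites(keep)

    # 2. biallelic restriction (multi-allelic ALT encoded with a comma)
    multi = variants["alt"].astype(str).str.contains(",").to_numpy()
    report.n_removed_by_rule["non_biallelic"] = int(multi.sum())
    variants = variants.loc[~multi].reset_index(drop=True)
    genotypes = genotypes.subset_sites(~multi)

    # 3. genotype-level filtering
    genotypes, g_report = apply_genotype_filters(genotypes, thresholds)
    report.n_genotypes_set_missing = g_report.n_genotypes_set_missing
    report.n_removed_by_rule["missing_individuals"] = g_report.n_removed_by_rule["missing_individuals"]
    kept_key = site_key(genotypes.sites)
    variants = variants.loc[site_key(variants).isin(kept_key)].reset_index(drop=True)

    # 4. MAF floor on the post-missingness calls
    maf = genotypes.observed_maf()
    with np.errstate(invalid="ignore"):
        low_maf = ~(maf >= thresholds.maf_min)  # NaN (no calls) counts as low
    report.n_removed_by_rule["maf"] = int(low_maf.sum())
    variants = variants.loc[~low_maf].reset_index(drop=True)
    genotypes = genotypes.subset_sites(~low_maf)
    variants["maf"] = genotypes.observed_maf()
    genotypes.sites["maf"] = variants["maf"].to_numpy()

    report.n_sites_out = len(variants)
    if report.n_sites_out == 0:
        last = [r for r, n in report.n_removed_by_rule.items() if n > 0]
        raise ValueError(f"quality control removed every site (last removing rule: {last[-1] if last else 'none'})")
    logger.info("site QC: %d -> %d sites; removals %s", report.n_sites_in, report.n_sites_out, report.n_removed_by_rule)
    return variants, genotypes, report


def genotype_concordance(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> tuple[pd.Series, dict]:
    """Per-sample genotype concordance between two panels.

    Samples are matched by id and sites by (chrom, pos); entries missing in
    either matrix are excluded pairwise.  Returns the per-sample fraction of
    identical genotype codes plus a mean/min/max summary, the check used to
    validate sequencing calls against array genotypes.
    """
    shared_samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    key_a, key_b = site_key(a.sites), site_key(b.sites)
    shared_key = key_a.intersection(key_b)
    if len(shared_samples) == 0 or len(shared_key) == 0:
        raise ValueError("no shared samples or sites to compare")
    ia = np.flatnonzero(key_a.isin(shared_key))
    ib = np.flatnonzero(key_b.isin(shared_key))
    sub_a = a.subset_samples(shared_samples).subset_sites(ia)
    sub_b = b.subset_samples(shared_samples).subset_sites(ib)

    both = (sub_a.codes != MISSING) & (sub_b.codes != MISSING)
    if not both.any():
        raise ValueError("no comparable genotype pairs (all missing)")
    agree = (sub_a.codes == sub_b.codes) & both
    n_pairs = both.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_pairs > 0, agree.sum(axis=1) / n_pairs, np.nan)
    per_sample = pd.Series(frac, index=shared_samples, name="concordance")
    valid = per_sample.dropna()
    summary = {
        "mean": float(valid.mean()),
        "min": float(valid.min()),
        "max": float(valid.max()),
        "n_samples": int(valid.size),
        "n_shared_sites": int(len(shared_key)),
    }
    return per_sample, summary
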