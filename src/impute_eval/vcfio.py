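"""Reading and writing VCF 4.2 panels via pysam.

Truth/reference panels are written with phased GT ("|"); sequencing-style
genotype matrices with unphased GT plus per-genotype GQ; imputation results
with GT, DS and the per-site INFO key R2.  Site filter statistics travel as
the standard INFO keys (QD, FS, MQ, ReadPosRankSum, MQRankSum, SOR) and the
functional class as INFO/IMPACT, so external tools can round-trip every
field the pipeline consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .containers import (
    MISSING,
    SITE_STAT_COLUMNS,
    GenotypeMatrix,
    HaplotypePanel,
    ImputationResult,
    new_variant_table,
)

_INFO_KEYS = {
    "qd": ("QD", "Float", "Quality by depth"),
    "fs": ("FS", "Float", "Fisher strand bias"),
    "mq": ("MQ", "Float", "RMS mapping quality"),
    "read_pos_rank_sum": ("ReadPosRankSum", "Float", "Read position rank-sum"),
    "mq_rank_sum": ("MQRankSum", "Float", "Mapping quality rank-sum"),
    "sor": ("SOR", "Float", "Symmetric odds ratio"),
}


def _build_header(sites: pd.DataFrame, sample_ids: list[str], with_gq: bool, with_ds: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##source=impute-eval')
    for chrom in dict.fromkeys(sites["chrom"].astype(str)):
        length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1
        header.contigs.add(chrom, length=length)
    for _, (key, typ, desc) in _INFO_KEYS.items():
        header.info.add(key, 1, typ, desc)
    header.info.add("IMPACT", 1, "String", "Predicted functional impact class")
    header.info.add("ARRAY", 0, "Flag", "Site is on the HD array panel")
    header.info.add("R2", 1, "Float", "Model-based imputation quality")
    header.formats.add("GT", 1, "String", "Genotype")
    if with_gq:
        header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    if with_ds:
        header.formats.add("DS", 1, "Float", "Estimated alternate allele dosage")
    for s in sample_ids:
        header.add_sample(s)
    return header


def _fill_site(rec, row: pd.Series) -> None:
    for col, (key, _, _) in _INFO_KEYS.items():
        val = row.get(col)
        if val is not None and np.isfinite(val):
            rec.info[key] = float(val)
    impact = row.get("impact")
    if isinstance(impact, str) and impact:
        rec.info["IMPACT"] = impact
    if bool(row.get("on_array", False)):
        rec.info["ARRAY"] = True


def write_haplotype_panel(panel: HaplotypePanel, path: str) -> None:
    """Phased truth/reference panel VCF (GT with '|')."""
    header = _build_header(panel.sites, panel.sample_ids, with_gq=False, with_ds=False)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, (_, row) in enumerate(panel.sites.iterrows()):
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1, alleles=(row["ref"], row["alt"])
            )
            _fill_site(rec, row)
            for i in range(panel.n_samples):
                rec.samples[i]["GT"] = (int(panel.haplotypes[2 * i, j]), int(panel.haplotypes[2 * i + 1, j]))
                rec.samples[i].phased = True
            vf.write(rec)


def write_genotype_matrix(gm: GenotypeMatrix, path: str) -> None:
    """Unphased called-genotype VCF with GQ and site filter statistics."""
    header = _build_header(gm.sites, gm.sample_ids, with_gq=gm.gq is not None, with_ds=False)
    code_to_gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, (_, row) in enumerate(gm.sites.iterrows()):
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1, alleles=(row["ref"], row["alt"])
            )
            _fill_site(rec, row)
            for i in range(gm.n_samples):
                rec.samples[i]["GT"] = code_to_gt[int(gm.codes[i, j])]
                if gm.gq is not None:
                    rec.samples[i]["GQ"] = int(gm.gq[i, j])
            vf.write(rec)


def write_imputation_result(result: ImputationResult, path: str) -> None:
    """Imputed VCF with GT, DS and INFO/R2."""
    header = _build_header(result.sites, result.sample_ids, with_gq=False, with_ds=True)
    code_to_gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, (_, row) in enumerate(result.sites.iterrows()):
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1, alleles=(row["ref"], row["alt"])
            )
            _fill_site(rec, row)
            rec.info["R2"] = float(result.rsq[j])
            for i in range(len(result.sample_ids)):
                rec.samples[i]["GT"] = code_to_gt[int(result.best_guess[i, j])]
                rec.samples[i]["DS"] = float(result.dosages[i, j])
            vf.write(rec)


def read_genotype_matrix(path: str) -> GenotypeMatrix:
    """Load a biallelic-SNP VCF into a genotype matrix.

    Multi-allelic records keep their first ALT and are marked by a
    comma-joined alt string so the QC biallelic rule can drop them.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        has_gq = "GQ" in vf.header.formats
        chroms, poss, refs, alts, impacts, on_array = [], [], [], [], [], []
        stats: dict[str, list] = {c: [] for c in SITE_STAT_COLUMNS}
        codes_rows, gq_rows = [], []
        for rec in vf:
            chroms.append(str(rec.chrom))
            poss.append(rec.pos)
            refs.append(rec.ref or "N")
            alts.append(",".join(rec.alts) if rec.alts else "N")
            impacts.append(rec.info.get("IMPACT", "modifier"))
            on_array.append("ARRAY" in rec.info)
            for col, (key, _, _) in _INFO_KEYS.items():
                val = rec.info.get(key)
                stats[col].append(np.nan if val is None else float(val))
            crow = np.empty(len(samples), dtype=np.int8)
            qrow = np.zeros(len(samples), dtype=np.int16)
            for i, s in enumerate(samples):
                sm = rec.samples[s]
                gt = sm.get("GT")
                crow[i] = MISSING if gt is None or None in gt else sum(1 for a in gt if a and a > 0)
                if has_gq:
                    q = sm.get("GQ")
                    qrow[i] = 0 if q is None else int(q)
            codes_rows.append(crow)
            gq_rows.append(qrow)
    sites = new_variant_table(
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=int),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        impact=np.array(impacts, dtype=object),
        on_array=np.array(on_array, dtype=bool),
        **{c: np.array(v, dtype=float) for c, v in stats.items()},
    )
    codes = np.vstack(codes_rows).T if codes_rows else np.empty((len(samples), 0), dtype=np.int8)
    gm = GenotypeMatrix(
        sample_ids=samples, codes=codes, sites=sites, gq=np.vstack(gq_rows).T if has_gq else None
    )
    gm.sites["maf"] = gm.observed_maf()
    return gm


def read_haplotype_panel(path: str) -> HaplotypePanel:
    """Load a phased VCF as a haplotype panel; unphased or missing genotypes
    are rejected since the truth substrate must be complete."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chroms, poss, refs, alts, impacts, on_array = [], [], [], [], [], []
        hap_rows = []
        for rec in vf:
            chroms.append(str(rec.chrom))
            poss.append(rec.pos)
            refs.append(rec.ref or "N")
            alts.append(rec.alts[0] if rec.alts else "N")
            impacts.append(rec.info.get("IMPACT", "modifier"))
            on_array.append("ARRAY" in rec.info)
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or None in gt or len(gt) != 2:
                    raise ValueError(f"missing or haploid genotype at {rec.chrom}:{rec.pos}")
                col[2 * i], col[2 * i + 1] = gt
            hap_rows.append(col)
    sites = new_variant_table(
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=int),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        impact=np.array(impacts, dtype=object),
        on_array=np.array(on_array, dtype=bool),
    )
    haps = np.vstack(hap_rows).T if hap_rows else np.empty((2 * len(samples), 0), dtype=np.int8)
    panel = HaplotypePanel(sample_ids=samples, haplotypes=haps, sites=sites, phased=True)
    panel.sites["maf"] = panel.maf()
    return panel
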