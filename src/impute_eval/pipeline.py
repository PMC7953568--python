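"""End-to-end orchestration: simulate -> QC -> reference selection ->
fold/mask -> impute -> evaluate -> report.

Also hosts the deterministic fixture catalogue used by the test-suite and
the docs, and :func:`run_accuracy_study`, the study driver that the
reproduction script and the directional acceptance checks share.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import vcfio
from .containers import MISSING, GenotypeMatrix, HaplotypePanel, new_variant_table, site_key
from .evaluate import (
    CvPlan,
    animal_summary,
    imputation_fraction_table,
    make_folds,
    mask_to_panel,
    per_animal_accuracy,
    per_snp_accuracy,
    rsq_calibration,
    stratify,
)
from .impute import HmmParams, OswParams, impute_ls_hmm, impute_osw, prephase_target
from .qc import QCThresholds, apply_site_filters
from .refselect import compute_grm, kmeans_reference_clusters, pick_representatives
from .simulate import SimConfig, simulate_population

logger = logging.getLogger(__name__)

ENGINES = ("lshmm", "osw")


@dataclass
class RunConfig:
    """Single serialisable configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    hmm: HmmParams = field(default_factory=HmmParams)
    osw: OswParams = field(default_factory=OswParams)
    engines: tuple[str, ...] = ENGINES
    n_folds: int = 5
    folds_to_run: tuple[int, ...] | None = None  # None = all folds
    n_clusters: int = 20
    seed: int = 0
    write_vcfs: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hmm"].pop("genetic_map", None)
        d["engines"] = list(self.engines)
        d["folds_to_run"] = None if self.folds_to_run is None else list(self.folds_to_run)
        d["sim"]["gq_distribution_params"] = list(self.sim.gq_distribution_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_kwargs = dict(d.get("sim", {}))
        if "gq_distribution_params" in sim_kwargs:
            sim_kwargs["gq_distribution_params"] = tuple(sim_kwargs["gq_distribution_params"])
        return cls(
            sim=SimConfig(**sim_kwargs),
            qc=QCThresholds(**d.get("qc", {})),
            hmm=HmmParams(**d.get("hmm", {})),
            osw=OswParams(**d.get("osw", {})),
            engines=tuple(d.get("engines", ENGINES)),
            n_folds=d.get("n_folds", 5),
            folds_to_run=None if d.get("folds_to_run") is None else tuple(d["folds_to_run"]),
            n_clusters=d.get("n_clusters", 20),
            seed=d.get("seed", 0),
            write_vcfs=d.get("write_vcfs", True),
        )

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _impute_one(engine, reference, target_array, hmm_params, osw_params):
    if engine == "lshmm":
        phased = prephase_target(target_array, reference)
        return impute_ls_hmm(reference, phased, hmm_params)
    if engine == "osw":
        return impute_osw(reference, target_array, osw_params)
    raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")


def run_accuracy_study(
    seed: int,
    sim_config: SimConfig | None = None,
    qc_thresholds: QCThresholds | None = None,
    hmm_params: HmmParams | None = None,
    osw_params: OswParams | None = None,
    engines: tuple[str, ...] = ENGINES,
    n_folds: int = 5,
    folds_to_run: tuple[int, ...] | None = None,
) -> dict:
    """One full masking cross-validation study on a synthetic population.

    Simulates the cohort, applies quality control, then for each requested
    fold masks the held-out animals down to their array genotypes, imputes
    them back with every engine, and scores per-SNP and per-animal accuracy
    against the hidden (post-QC) truth.  Stratification MAF is the
    pre-masking cohort MAF, not the reference-only MAF.
    """
    config = replace(sim_config or SimConfig(), seed=seed)
    truth, observed = simulate_population(config)
    thresholds = qc_thresholds or QCThresholds()

    variants_qc, observed_qc, qc_report = apply_site_filters(observed.sites, observed, thresholds)
    qc_keys = site_key(variants_qc)
    keep = site_key(truth.sites).isin(qc_keys)
    truth_qc = truth.subset_sites(keep)
    # observed carries the post-QC site set but truth-panel (pre-masking) MAF
    observed_qc.sites = truth_qc.sites
    sites_qc = truth_qc.sites

    plan = make_folds(list(truth.sample_ids), n_folds=n_folds, seed=seed)
    folds = tuple(range(n_folds)) if folds_to_run is None else tuple(folds_to_run)
    on_array = sites_qc["on_array"].to_numpy(dtype=bool)

    per_snp_frames, per_animal_frames = [], []
    for fold in folds:
        fold_samples = plan.samples_in_fold(fold)
        ref_samples = plan.samples_out_of_fold(fold)
        reference = truth_qc.subset_samples(ref_samples)
        masked = mask_to_panel(observed_qc, sites_qc, fold, plan)
        target_array = masked.subset_samples(fold_samples).subset_sites(on_array)
        for engine in engines:
            result = _impute_one(engine, reference, target_array, hmm_params, osw_params)
            per_snp_frames.append(per_snp_accuracy(observed_qc, result, fold_samples, fold=fold))
            per_animal_frames.append(per_animal_accuracy(observed_qc, result, fold_samples, fold=fold))

    return {
        "config": config,
        "plan": plan,
        "qc_report": qc_report,
        "sites": sites_qc,
        "truth": truth_qc,
        "observed": observed_qc,
        "per_snp": pd.concat(per_snp_frames, ignore_index=True),
        "per_animal": pd.concat(per_animal_frames, ignore_index=True),
        "fraction_table": imputation_fraction_table(sites_qc),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Run every stage and write a self-describing manifest.

    The manifest records the full configuration, every artifact path with
    its sha256 checksum, and per-stage dimensions, so identical
    configuration and seed reproduce identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        study = run_accuracy_study(
            seed=config.seed,
            sim_config=config.sim,
            qc_thresholds=config.qc,
            hmm_params=config.hmm,
            osw_params=config.osw,
            engines=config.engines,
            n_folds=config.n_folds,
            folds_to_run=config.folds_to_run,
        )
        stage = "select-ref"
        grm = compute_grm(study["observed"])
        k = min(config.n_clusters, len(grm.sample_ids))
        assignment = kmeans_reference_clusters(grm, k=k, seed=config.seed)
        pedigree = study["truth"].pedigree
        progeny = (
            dict(zip(pedigree["sample_id"], pedigree["progeny_count"]))
            if pedigree is not None
            else {s: 0 for s in grm.sample_ids}
        )
        assignment = pick_representatives(assignment, progeny)
        stage = "report"
        artifacts = _write_reports(config, study, assignment, out)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_sites_after_qc": int(len(study["sites"])),
        "qc_report": json.loads(study["qc_report"].to_json()),
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _write_reports(config: RunConfig, study: dict, assignment, out: Path) -> dict[str, Path]:
    artifacts: dict[str, Path] = {}

    def save_tsv(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        artifacts[name] = p

    save_tsv("per_snp_accuracy", study["per_snp"])
    save_tsv("per_animal_accuracy", study["per_animal"])
    for engine, grp in study["per_snp"].groupby("engine"):
        save_tsv(f"strata_maf_{engine}", stratify(grp, "maf_bins"))
        save_tsv(f"strata_impact_{engine}", stratify(grp, "impact_class"))
        save_tsv(f"strata_window_{engine}", stratify(grp, "window"))
        defined = grp["r2"].notna() & grp["rsq"].notna()
        if defined.any():
            curve, summary = rsq_calibration(grp)
            save_tsv(f"rsq_calibration_{engine}", curve)
            (out / f"rsq_calibration_{engine}.json").write_text(json.dumps(summary, indent=2))
            artifacts[f"rsq_calibration_{engine}_summary"] = out / f"rsq_calibration_{engine}.json"
    for engine, grp in study["per_animal"].groupby("engine"):
        save_tsv(f"per_animal_summary_{engine}", animal_summary(grp))
    save_tsv("imputation_fractions", study["fraction_table"])

    clusters = pd.DataFrame(
        {
            "sample_id": list(assignment.labels),
            "cluster": [assignment.labels[s] for s in assignment.labels],
            "representative": [
                assignment.representatives.get(assignment.labels[s]) == s for s in assignment.labels
            ],
        }
    )
    save_tsv("reference_clusters", clusters)

    (out / "qc_report.json").write_text(study["qc_report"].to_json())
    artifacts["qc_report"] = out / "qc_report.json"

    pedigree = study["truth"].pedigree
    meta = pd.DataFrame(
        {
            "sample_id": study["truth"].sample_ids,
            "progeny_count": (
                pedigree.set_index("sample_id").loc[study["truth"].sample_ids, "progeny_count"].to_numpy()
                if pedigree is not None
                else 0
            ),
            "fold": [study["plan"].fold_of[s] for s in study["truth"].sample_ids],
        }
    )
    save_tsv("samples", meta)

    if config.write_vcfs:
        vcfio.write_haplotype_panel(study["truth"], out / "truth_panel.vcf")
        artifacts["truth_panel"] = out / "truth_panel.vcf"
        vcfio.write_genotype_matrix(study["observed"], out / "observed.vcf")
        artifacts["observed"] = out / "observed.vcf"
    return artifacts


def directional_study(seeds, sim_config: SimConfig | None = None) -> pd.DataFrame:
    """Per-seed summary statistics of the rare/common and Rsq-calibration
    structure, one masking-CV fold per seed (the fold index rotates with the
    seed so all folds are exercised across the study).

    Returns one row per seed with mean per-SNP R2 for rare (MAF <= 0.03)
    and common variants per engine, the mean signed difference
    Rsq - empirical R2 for the copying-HMM engine, the fraction of MAF bins
    where the binned mean Rsq sits below the binned mean R2, and per-animal
    summaries.
    """
    from .evaluate import RARE_MAF, rsq_calibration

    rows = []
    for seed in seeds:
        study = run_accuracy_study(
            seed=seed, sim_config=sim_config, folds_to_run=(seed % 5,)
        )
        snp = study["per_snp"]
        row = {"seed": seed}
        for engine, grp in snp.groupby("engine"):
            rare = grp["maf"] <= RARE_MAF
            row[f"{engine}_rare_r2"] = grp.loc[rare, "r2"].mean()
            row[f"{engine}_common_r2"] = grp.loc[~rare, "r2"].mean()
            row[f"{engine}_undefined_fraction"] = grp["r2"].isna().mean()
        hmm = snp[snp["engine"] == "lshmm"]
        curve, summary = rsq_calibration(hmm)
        row["rsq_minus_r2"] = summary["mean_signed_difference"]
        row["rsq_r2_correlation"] = summary["correlation"]
        row["bins_rsq_below_r2"] = float((curve["mean_rsq"] <= curve["mean_r2"]).mean())
        animal = study["per_animal"]
        for engine, grp in animal.groupby("engine"):
            row[f"{engine}_animal_r2"] = grp["r2"].mean()
            row[f"{engine}_animal_perc"] = grp["perc"].mean()
        row["per_snp_mean_r2_lshmm"] = hmm["r2"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture catalogue


def _fixture_tiny_panel() -> dict:
    """4 reference haplotypes x 5 sites (3 array + 2 hidden): small enough
    for exhaustive path enumeration against the copying HMM."""
    sites = new_variant_table(
        chrom=["1"] * 5,
        pos=[1_000, 200_000, 400_000, 600_000, 800_000],
        on_array=[True, False, True, False, True],
    )
    haps = np.array(
        [
            [0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1],
            [0, 1, 1, 0, 1],
            [1, 0, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    reference = HaplotypePanel(sample_ids=["R0", "R1"], haplotypes=haps, sites=sites)
    reference.sites["maf"] = reference.maf()
    arr = sites["on_array"].to_numpy(dtype=bool)
    target = HaplotypePanel(
        sample_ids=["T0"],
        haplotypes=np.array([[0, 1, 1], [1, 0, 0]], dtype=np.int8),
        sites=sites.loc[arr].reset_index(drop=True),
    )
    return {"reference": reference, "target_haps": target}


def _fixture_exact_copy(n_reference: int = 8, n_sites: int = 400, seed: int = 2024) -> dict:
    """Targets duplicated from reference samples on error-free data: both
    engines must recover the sequence genotypes perfectly."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 4_000_000), size=n_sites, replace=False))
    freq = rng.uniform(0.15, 0.85, size=n_sites)
    haps = (rng.random((2 * n_reference, n_sites)) < freq).astype(np.int8)
    poly = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < 2 * n_reference)
    haps, pos = haps[:, poly], pos[poly]
    m = haps.shape[1]
    on_array = np.zeros(m, dtype=bool)
    on_array[::4] = True
    sites = new_variant_table(chrom=["1"] * m, pos=pos, on_array=on_array)
    reference = HaplotypePanel(
        sample_ids=[f"R{i}" for i in range(n_reference)], haplotypes=haps, sites=sites
    )
    reference.sites["maf"] = reference.maf()
    sites = reference.sites

    copied = ["R0", "R1", "R2"]
    truth_targets = reference.subset_samples(copied)
    truth_targets = HaplotypePanel(
        sample_ids=[f"T{i}" for i in range(len(copied))],
        haplotypes=truth_targets.haplotypes,
        sites=sites,
    )
    observed = GenotypeMatrix(
        sample_ids=list(truth_targets.sample_ids), codes=truth_targets.genotypes(), sites=sites
    )
    target_array = observed.subset_sites(on_array)
    return {
        "reference": reference,
        "observed": observed,
        "target_array": target_array,
        "hmm_params": HmmParams(mutation_rate=1e-6, recomb_scale=1e-3),
        "osw_params": OswParams(),
    }


def _fixture_rare_variant_stress(seed: int = 7) -> dict:
    """Panel dominated by rare variants, for MAF-stratification edge cases."""
    rng = np.random.default_rng(seed)
    n_samples, m = 30, 500
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=m, replace=False))
    freq = rng.beta(0.2, 2.0, size=m)
    haps = (rng.random((2 * n_samples, m)) < freq).astype(np.int8)
    poly = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < 2 * n_samples)
    haps, pos = haps[:, poly], pos[poly]
    sites = new_variant_table(chrom=["1"] * haps.shape[1], pos=pos)
    panel = HaplotypePanel(
        sample_ids=[f"S{i}" for i in range(n_samples)], haplotypes=haps, sites=sites
    )
    panel.sites["maf"] = panel.maf()
    return {"panel": panel}


def _fixture_qc_violations() -> dict:
    """Hand-built panel where specific sites violate exactly one QC rule.

    Sites 0-5 each fail one site-statistic hard filter, site 6 is
    multi-allelic, site 7 has 41 of 151 genotypes missing after the GQ
    step, site 8 has MAF below 1%, sites 9-11 pass everything.
    """
    n_samples, m = 151, 12
    rng = np.random.default_rng(11)
    pos = np.arange(1, m + 1) * 1_000
    stats = {c: np.full(m, np.nan) for c in ("qd", "fs", "mq", "read_pos_rank_sum", "mq_rank_sum", "sor")}
    for c in stats:
        stats[c][:] = {"qd": 20.0, "fs": 5.0, "mq": 55.0, "read_pos_rank_sum": 0.0, "mq_rank_sum": 0.0, "sor": 1.0}[c]
    stats["qd"][0] = 1.5
    stats["fs"][1] = 75.0
    stats["mq"][2] = 30.0
    stats["read_pos_rank_sum"][3] = -9.0
    stats["mq_rank_sum"][4] = -13.0
    stats["sor"][5] = 4.0
    alt = np.array(["C"] * m, dtype=object)
    alt[6] = "C,G"
    sites = new_variant_table(chrom=["1"] * m, pos=pos, alt=alt, **stats)

    codes = rng.integers(0, 3, size=(n_samples, m)).astype(np.int8)
    gq = np.full((n_samples, m), 60, dtype=np.int16)
    gq[:41, 7] = 10  # 41 genotypes lost to the GQ rule -> site dropped
    codes[:, 8] = 0
    codes[0, 8] = 1  # MAF = 1/302 < 0.01
    gm = GenotypeMatrix(sample_ids=[f"A{i:03d}" for i in range(n_samples)], codes=codes, sites=sites, gq=gq)
    return {"variants": sites, "genotypes": gm, "violating_sites": list(range(9)), "passing_sites": [9, 10, 11]}


FIXTURES = {
    "tiny-panel": _fixture_tiny_panel,
    "exact-copy": _fixture_exact_copy,
    "rare-variant-stress": _fixture_rare_variant_stress,
    "qc-violations": _fixture_qc_violations,
}


def make_fixture(name: str, out_dir: str | None = None) -> dict:
    """Build a catalogued deterministic fixture; optionally write its panels
    to VCF/TSV under ``out_dir``."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; catalogue: {sorted(FIXTURES)}")
    objs = FIXTURES[name]()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, obj in list(objs.items()):
            path = out / f"{name}-{key}"
            if isinstance(obj, HaplotypePanel):
                vcfio.write_haplotype_panel(obj, f"{path}.vcf")
                objs[f"{key}_path"] = f"{path}.vcf"
            elif isinstance(obj, GenotypeMatrix):
                vcfio.write_genotype_matrix(obj, f"{path}.vcf")
                objs[f"{key}_path"] = f"{path}.vcf"
            elif isinstance(obj, pd.DataFrame):
                obj.to_csv(f"{path}.tsv", sep="\t", index=False)
                objs[f"{key}_path"] = f"{path}.tsv"
    return objs
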