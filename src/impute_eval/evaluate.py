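"""Imputation-accuracy assessment by masking cross-validation.

The evaluation design: the sequenced cohort is split into balanced random
folds; for each fold the held-out animals keep only their HD-array
genotypes, everything else is masked and imputed back from the remaining
animals; the imputed values are then scored against the hidden truth with
two statistics, per SNP and per animal:

* R² — squared Pearson correlation between observed genotype codes and
  imputed dosages (or hard calls); undefined when either vector is
  constant, which is tracked with a reason code rather than silently
  dropped;
* PERC — percentage of best-guess genotypes identical to the observed ones.

On top of the raw records the module provides MAF / functional-impact /
1-Mb-window stratification in the six-number summary layout
(min, Q1, median, mean, Q3, max), a binned-mean calibration of the model
Rsq statistic against empirical R², and the bookkeeping arithmetic for the
fraction of sites that have to be imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, ImputationResult, site_key

logger = logging.getLogger(__name__)

#: MAF at or below which a variant counts as rare
RARE_MAF = 0.03

#: stratification window length in bp (1 Mb, half-open windows)
WINDOW_BP = 1_000_000

#: variance below which a vector is treated as constant
_CONST_TOL = 1e-12

#: published per-autosome site counts for a bovine HD-array-to-sequence
#: imputation panel (151 sequenced sires, ~777k-SNP HD chip): chromosome ->
#: (sequence sites in the reference panel, array sites in the target panel).
#: Used to exercise the imputation-fraction arithmetic at real scale.
BOVINE_PANEL_COUNTS: dict[str, tuple[int, int]] = {
    "1": (1_965_500, 36_424),
    "2": (1_594_559, 30_832),
    "3": (1_396_284, 28_583),
    "4": (1_514_666, 26_434),
    "5": (1_350_367, 25_150),
    "6": (1_461_356, 28_480),
    "7": (1_297_470, 25_926),
    "8": (1_309_174, 26_848),
    "9": (1_281_310, 25_088),
    "10": (1_219_761, 22_454),
    "11": (1_246_742, 24_204),
    "12": (1_121_539, 19_004),
    "13": (947_897, 17_794),
    "14": (991_359, 20_322),
    "15": (1_120_179, 18_849),
    "16": (974_221, 18_626),
    "17": (928_571, 17_803),
    "18": (753_566, 14_541),
    "19": (713_820, 13_370),
    "20": (910_476, 16_074),
    "21": (857_266, 16_234),
    "22": (729_871, 13_479),
    "23": (774_175, 12_292),
    "24": (790_397, 14_192),
    "25": (521_876, 9_425),
    "26": (655_622, 11_869),
    "27": (642_015, 10_030),
    "28": (636_577, 9_991),
    "29": (687_868, 10_717),
    "Overall": (30_394_484, 565_035),
}


@dataclass
class CvPlan:
    """Balanced random partition of samples into folds."""

    n_folds: int
    fold_of: dict[str, int]
    seed: int

    def samples_in_fold(self, fold: int) -> list[str]:
        if fold not in set(self.fold_of.values()):
            raise KeyError(f"fold {fold} not in plan")
        return [s for s, f in self.fold_of.items() if f == fold]

    def samples_out_of_fold(self, fold: int) -> list[str]:
        if fold not in set(self.fold_of.values()):
            raise KeyError(f"fold {fold} not in plan")
        return [s for s, f in self.fold_of.items() if f != fold]


def make_folds(sample_ids: list[str], n_folds: int = 5, seed: int = 0) -> CvPlan:
    """Random balanced folds; sizes differ by at most one (earlier folds get
    the remainder, e.g. 151 samples in 5 folds -> 31, 30, 30, 30, 30)."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(sample_ids):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    fold_of: dict[str, int] = {}
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        for i in chunk:
            fold_of[sample_ids[i]] = f
    return CvPlan(n_folds=n_folds, fold_of=fold_of, seed=seed)


def mask_to_panel(
    genotypes: GenotypeMatrix, sites: pd.DataFrame, fold: int, plan: CvPlan
) -> GenotypeMatrix:
    """Mask every non-array genotype of the fold's samples; samples outside
    the fold (the imputation reference) are untouched."""
    if fold not in set(plan.fold_of.values()):
        raise KeyError(f"fold {fold} not in plan")
    if len(sites) != genotypes.n_sites:
        raise ValueError("site table and genotype matrix disagree")
    on_array = sites["on_array"].to_numpy(dtype=bool)
    out = genotypes.copy()
    in_fold = np.array([plan.fold_of.get(s) == fold for s in genotypes.sample_ids])
    out.codes[np.ix_(in_fold, ~on_array)] = MISSING
    return out


def impute_fraction(n_reference_sites: int, n_array_sites: int) -> float:
    """Percentage of reference-panel sites that must be imputed, to two
    decimals: 100 * (n_ref - n_array) / n_ref."""
    if n_reference_sites <= 0:
        raise ValueError("n_reference_sites must be positive")
    if not 0 <= n_array_sites <= n_reference_sites:
        raise ValueError("n_array_sites must lie in [0, n_reference_sites]")
    return round(100.0 * (n_reference_sites - n_array_sites) / n_reference_sites, 2)


def imputation_fraction_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome and overall site counts with the percentage of sites
    to impute, from a variant table with on_array flags."""
    rows = []
    for c, grp in sites.groupby("chrom", sort=False):
        n_ref = len(grp)
        n_arr = int(grp["on_array"].sum())
        rows.append({"chrom": c, "n_reference": n_ref, "n_array": n_arr, "pct_to_impute": impute_fraction(n_ref, n_arr)})
    total_ref = len(sites)
    total_arr = int(sites["on_array"].sum())
    rows.append(
        {"chrom": "Overall", "n_reference": total_ref, "n_array": total_arr, "pct_to_impute": impute_fraction(total_ref, total_arr)}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# accuracy statistics


def _align(observed: GenotypeMatrix, result: ImputationResult, fold_samples: list[str]):
    """Truth and imputed blocks restricted to fold samples and the scored
    (non-array) sites; returns (truth, imputed_values, best_guess, scored_sites)."""
    sidx = site_key(result.sites).get_indexer(site_key(observed.sites))
    if (sidx < 0).any():
        raise ValueError("observed sites must all exist in the imputation result")
    scored = ~result.sites["on_array"].to_numpy(dtype=bool)
    obs_rows = {s: i for i, s in enumerate(observed.sample_ids)}
    res_rows = {s: i for i, s in enumerate(result.sample_ids)}
    fold_samples = [s for s in fold_samples if s in obs_rows and s in res_rows]
    if not fold_samples:
        raise ValueError("no fold samples present in both observed and imputed data")

    # reorder result columns into observed site order, then keep scored sites
    obs_scored_cols = np.flatnonzero(scored[sidx])
    res_cols = sidx[obs_scored_cols]
    oi = np.array([obs_rows[s] for s in fold_samples])
    ri = np.array([res_rows[s] for s in fold_samples])
    truth = observed.codes[np.ix_(oi, obs_scored_cols)].astype(float)
    truth[truth == MISSING] = np.nan
    dos = result.dosages[np.ix_(ri, res_cols)]
    best = result.best_guess[np.ix_(ri, res_cols)].astype(float)
    meta = result.sites.iloc[res_cols].reset_index(drop=True)
    meta = meta.assign(rsq=result.rsq[res_cols])
    return fold_samples, truth, dos, best, meta


def _masked_pearson_r2(x: np.ndarray, y: np.ndarray, axis: int):
    """Vectorised squared Pearson correlation with NaN pairwise deletion.

    Returns (r2, n, var_x, var_y); r2 is NaN where undefined.
    """
    ok = ~np.isnan(x)
    n = ok.sum(axis=axis).astype(float)
    xs = np.where(ok, x, 0.0)
    ys = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xs.sum(axis=axis) / n
        my = ys.sum(axis=axis) / n
        sxx = (xs**2).sum(axis=axis) / n - mx**2
        syy = (ys**2).sum(axis=axis) / n - my**2
        sxy = (xs * ys).sum(axis=axis) / n - mx * my
        r2 = sxy**2 / (sxx * syy)
    bad = (n < 2) | (sxx <= _CONST_TOL) | (syy <= _CONST_TOL)
    r2 = np.where(bad, np.nan, np.clip(r2, 0.0, 1.0))
    return r2, n, sxx, syy


def per_snp_accuracy(
    observed: GenotypeMatrix,
    result: ImputationResult,
    fold_samples: list[str],
    fold: int = 0,
    use_dosage: bool = True,
) -> pd.DataFrame:
    """Per-SNP R² and PERC over the fold samples at imputed sites.

    R² correlates observed genotype codes with imputed dosages (or hard
    calls when ``use_dosage`` is false) across the fold samples, pairwise
    complete over missing truth.  Sites where either vector is constant
    (or fewer than two truth genotypes exist) carry an undefined-R² reason
    code and R² = NaN; PERC is reported for them regardless.
    """
    fold_samples, truth, dos, best, meta = _align(observed, result, fold_samples)
    imputed = dos if use_dosage else best
    r2, n, var_o, var_i = _masked_pearson_r2(truth, imputed, axis=0)
    reason = np.full(truth.shape[1], "", dtype=object)
    reason[var_i <= _CONST_TOL] = "constant_imputed"
    reason[var_o <= _CONST_TOL] = "constant_observed"
    reason[n < 2] = "too_few_observations"
    reason[~np.isnan(r2)] = ""

    ok = ~np.isnan(truth)
    with np.errstate(invalid="ignore"):
        perc = 100.0 * np.where(ok, best == truth, False).sum(axis=0) / ok.sum(axis=0)

    return pd.DataFrame(
        {
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "fold": fold,
            "engine": result.engine,
            "r2": r2,
            "undefined_reason": reason,
            "perc": perc,
            "rsq": meta["rsq"].to_numpy(),
            "maf": meta["maf"].to_numpy(),
            "impact": meta["impact"].to_numpy(),
            "window_id": (meta["pos"].to_numpy() - 1) // WINDOW_BP,
            "n_scored": n.astype(int),
        }
    )


def per_animal_accuracy(
    observed: GenotypeMatrix,
    result: ImputationResult,
    fold_samples: list[str],
    fold: int = 0,
    use_dosage: bool = True,
) -> pd.DataFrame:
    """Per-animal R² and PERC across all imputed sites of each fold sample.

    Animals with no observed truth at any scored site are excluded with a
    warning.
    """
    fold_samples, truth, dos, best, _ = _align(observed, result, fold_samples)
    imputed = dos if use_dosage else best
    r2, n, _, _ = _masked_pearson_r2(truth, imputed, axis=1)
    ok = ~np.isnan(truth)
    with np.errstate(invalid="ignore"):
        perc = 100.0 * np.where(ok, best == truth, False).sum(axis=1) / ok.sum(axis=1)
    rows = []
    for i, s in enumerate(fold_samples):
        if n[i] == 0:
            logger.warning("animal %s has no observed truth at imputed sites; excluded", s)
            continue
        rows.append(
            {"sample_id": s, "fold": fold, "engine": result.engine, "r2": r2[i], "perc": perc[i], "n_scored": int(n[i])}
        )
    return pd.DataFrame(rows)


def animal_summary(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level per-animal summary (mean, SD, min, max per statistic)."""
    out = []
    for stat in ("r2", "perc"):
        v = per_animal[stat].dropna()
        out.append({"statistic": stat, "mean": v.mean(), "sd": v.std(), "min": v.min(), "max": v.max(), "n": v.size})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# stratification


def _six_number(values: np.ndarray) -> dict:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return {"count": 0, "min": np.nan, "q1": np.nan, "median": np.nan, "mean": np.nan, "q3": np.nan, "max": np.nan}
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear-interpolation convention
    return {"count": int(v.size), "min": v.min(), "q1": q1, "median": med, "mean": v.mean(), "q3": q3, "max": v.max()}


def stratify(
    frame: pd.DataFrame,
    scheme: str,
    statistics: tuple[str, ...] = ("r2", "perc", "rsq"),
    maf_threshold: float = RARE_MAF,
) -> pd.DataFrame:
    """Six-number summaries of accuracy statistics per stratum.

    ``scheme`` is one of ``maf_bins`` (rare MAF <= threshold vs common),
    ``impact_class`` (high / moderate / low / modifier), or ``window``
    (half-open 1-Mb windows per chromosome).  Undefined R² records are
    excluded from the R² summaries only; empty strata yield a row with
    count 0.
    """
    if scheme == "maf_bins":
        labels = np.where(frame["maf"].to_numpy() <= maf_threshold, f"maf<={maf_threshold}", f"maf>{maf_threshold}")
        strata = [f"maf<={maf_threshold}", f"maf>{maf_threshold}"]
    elif scheme == "impact_class":
        labels = frame["impact"].astype(str).to_numpy()
        strata = ["high", "moderate", "low", "modifier"]
    elif scheme == "window":
        labels = (frame["chrom"].astype(str) + ":" + frame["window_id"].astype(str)).to_numpy()
        strata = list(dict.fromkeys(labels))
    else:
        raise ValueError(f"unknown stratification scheme {scheme!r}")

    rows = []
    for stratum in strata:
        mask = labels == stratum
        for stat in statistics:
            if stat not in frame.columns:
                continue
            vals = frame.loc[mask, stat].to_numpy(dtype=float)
            rows.append({"stratum": stratum, "statistic": stat, **_six_number(vals)})
    return pd.DataFrame(rows)


def rsq_calibration(frame: pd.DataFrame, maf_bin_width: float = 0.01) -> tuple[pd.DataFrame, dict]:
    """Binned-mean calibration of the model Rsq against empirical R².

    Restricted to records where both statistics are defined; a fixed-width
    binned mean stands in for a smoothed conditional-mean curve.  Returns
    the per-MAF-bin curve plus an overall summary: Pearson correlation of
    the two statistics and the mean signed difference (Rsq - R²), negative
    when the model statistic underestimates the empirical accuracy.
    """
    ok = frame["r2"].notna() & frame["rsq"].notna()
    sub = frame.loc[ok]
    if sub.empty:
        raise ValueError("no sites with both empirical R2 and model Rsq defined")
    bins = np.floor(sub["maf"].to_numpy() / maf_bin_width).astype(int)
    curve = (
        sub.assign(maf_bin=bins * maf_bin_width)
        .groupby("maf_bin")
        .agg(mean_r2=("r2", "mean"), mean_rsq=("rsq", "mean"), n=("r2", "size"))
        .reset_index()
    )
    r2 = sub["r2"].to_numpy()
    rsq = sub["rsq"].to_numpy()
    if np.std(r2) > 0 and np.std(rsq) > 0:
        corr = float(np.corrcoef(r2, rsq)[0, 1])
    else:
        corr = np.nan
    summary = {
        "correlation": corr,
        "mean_signed_difference": float(np.mean(rsq - r2)),
        "n_sites": int(sub.shape[0]),
    }
    return curve, summary
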