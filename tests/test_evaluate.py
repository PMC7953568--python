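"""Accuracy statistics: folds, masking, R2/PERC, stratification, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from impute_eval import (
    MISSING,
    GenotypeMatrix,
    ImputationResult,
    impute_fraction,
    imputation_fraction_table,
    make_folds,
    mask_to_panel,
    new_variant_table,
    per_animal_accuracy,
    per_snp_accuracy,
    rsq_calibration,
    stratify,
)
from impute_eval.evaluate import BOVINE_PANEL_COUNTS

# "%SNPs to be imputed" printed for the bovine panel, chromosome -> percent
PRINTED_PCT = {
    "1": 98.15, "2": 98.07, "3": 97.95, "4": 98.25, "5": 98.14, "6": 98.05,
    "7": 98.00, "8": 97.95, "9": 98.04, "10": 98.16, "11": 98.06, "12": 98.31,
    "13": 98.12, "14": 97.95, "15": 98.32, "16": 98.09, "17": 98.08,
    "18": 98.07, "19": 98.13, "20": 98.23, "21": 98.11, "22": 98.15,
    "23": 98.41, "24": 98.20, "25": 98.19, "26": 98.19, "27": 98.44,
    "28": 98.43, "29": 98.44, "Overall": 98.14,
}


# ---------------------------------------------------------------------------
# folds and masking


def test_folds_151_in_5_gives_31_30_30_30_30():
    plan = make_folds([f"A{i}" for i in range(151)], n_folds=5, seed=0)
    sizes = sorted(
        (np.array(list(plan.fold_of.values())) == f).sum() for f in range(5)
    )
    assert sizes == [30, 30, 30, 30, 31]


def test_folds_leave_one_out_and_determinism():
    ids = [f"A{i}" for i in range(10)]
    plan = make_folds(ids, n_folds=10, seed=3)
    assert sorted(plan.fold_of.values()) == list(range(10))
    assert make_folds(ids, n_folds=10, seed=3).fold_of == plan.fold_of
    with pytest.raises(ValueError):
        make_folds(ids, n_folds=1, seed=0)


def _panel(codes, on_array):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    sites = new_variant_table(chrom=["1"] * m, pos=list(range(1000, 1000 + m)), on_array=list(on_array))
    return GenotypeMatrix(sample_ids=[f"A{i}" for i in range(n)], codes=codes, sites=sites), sites


def test_mask_hides_only_fold_samples_non_array_sites():
    gm, sites = _panel(np.ones((4, 6), dtype=np.int8), [True, False, True, False, False, True])
    plan = make_folds(gm.sample_ids, n_folds=2, seed=0)
    fold0 = [s for s, f in plan.fold_of.items() if f == 0]
    masked = mask_to_panel(gm, sites, 0, plan)
    for i, s in enumerate(gm.sample_ids):
        if s in fold0:
            assert (masked.codes[i, ~sites["on_array"].to_numpy()] == MISSING).all()
            assert (masked.codes[i, sites["on_array"].to_numpy()] == 1).all()
        else:
            assert (masked.codes[i] == 1).all()
    with pytest.raises(KeyError):
        mask_to_panel(gm, sites, 9, plan)


def test_mask_counts_match_panel_arithmetic():
    """Chromosome-1-scale bookkeeping: of 1,965,500 sites with 36,424 on the
    array, each fold sample has 1,929,076 genotypes masked (98.15%)."""
    n_ref, n_arr = BOVINE_PANEL_COUNTS["1"]
    assert n_ref - n_arr == 1_929_076
    assert impute_fraction(n_ref, n_arr) == 98.15


# ---------------------------------------------------------------------------
# imputation-fraction arithmetic


@pytest.mark.parametrize("chrom", sorted(BOVINE_PANEL_COUNTS))
def test_impute_fraction_reproduces_printed_percentages(chrom):
    n_ref, n_arr = BOVINE_PANEL_COUNTS[chrom]
    assert impute_fraction(n_ref, n_arr) == PRINTED_PCT[chrom]


def test_impute_fraction_edge_cases():
    assert impute_fraction(100, 100) == 0.0
    assert impute_fraction(100, 0) == 100.0
    with pytest.raises(ValueError):
        impute_fraction(0, 0)
    with pytest.raises(ValueError):
        impute_fraction(10, 11)


def test_imputation_fraction_table_totals():
    total_ref = sum(v[0] for c, v in BOVINE_PANEL_COUNTS.items() if c != "Overall")
    total_arr = sum(v[1] for c, v in BOVINE_PANEL_COUNTS.items() if c != "Overall")
    assert (total_ref, total_arr) == BOVINE_PANEL_COUNTS["Overall"]
    assert total_ref - total_arr == 29_829_449  # sites actually imputed


def test_imputation_fraction_table_from_sites(small_population):
    truth, _ = small_population
    table = imputation_fraction_table(truth.sites)
    overall = table[table["chrom"] == "Overall"].iloc[0]
    assert overall["n_reference"] == truth.n_sites
    assert overall["pct_to_impute"] == impute_fraction(
        truth.n_sites, int(truth.sites["on_array"].sum())
    )


# ---------------------------------------------------------------------------
# per-SNP / per-animal statistics


def _result_from(dosages, sites, sample_ids, rsq=None):
    dosages = np.asarray(dosages, dtype=float)
    return ImputationResult(
        sample_ids=sample_ids,
        sites=sites,
        dosages=dosages,
        best_guess=np.clip(np.floor(dosages + 0.5), 0, 2).astype(np.int8),
        rsq=np.zeros(len(sites)) if rsq is None else np.asarray(rsq, dtype=float),
        engine="test",
    )


def _snp_case(observed_col, dosage_col):
    codes = np.array(observed_col, dtype=np.int8)[:, None]
    codes = np.hstack([np.ones((len(codes), 1), dtype=np.int8), codes])  # col 0 = array site
    gm, sites = _panel(codes, [True, False])
    result = _result_from(np.hstack([np.ones((len(observed_col), 1)), np.array(dosage_col, dtype=float)[:, None]]), sites, gm.sample_ids)
    return per_snp_accuracy(gm, result, gm.sample_ids).iloc[0]


def test_per_snp_perfect_agreement():
    row = _snp_case([0, 1, 2, 1], [0, 1, 2, 1])
    assert row["r2"] == pytest.approx(1.0)
    assert row["perc"] == 100.0


def test_per_snp_half_correlated_case():
    row = _snp_case([0, 0, 2, 2], [0, 1, 1, 2])
    assert row["r2"] == pytest.approx(0.5)
    assert row["perc"] == 50.0


def test_per_snp_constant_imputed_undefined_but_perc_kept():
    row = _snp_case([0, 1, 2, 1], [1, 1, 1, 1])
    assert np.isnan(row["r2"])
    assert row["undefined_reason"] == "constant_imputed"
    assert row["perc"] == 50.0


def test_per_snp_constant_observed_undefined():
    row = _snp_case([1, 1, 1, 1], [0, 1, 2, 1])
    assert np.isnan(row["r2"])
    assert row["undefined_reason"] == "constant_observed"


def test_per_snp_too_few_observations_flagged():
    row = _snp_case([0, MISSING, MISSING, MISSING], [0, 1, 2, 1])
    assert np.isnan(row["r2"])
    assert row["undefined_reason"] == "too_few_observations"


def test_per_snp_matches_scipy_pearson_on_random_vectors(rng):
    """Vectorised per-SNP statistics agree with a direct per-site
    scipy.stats.pearsonr / counting oracle on 1,000 random small vectors,
    including constant and missing-value cases."""
    n, m = 8, 1000
    truth = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    truth[rng.random((n, m)) < 0.1] = MISSING
    dosages = np.clip(rng.normal(truth.clip(0), 0.7), 0, 2)
    const = rng.random(m) < 0.05
    dosages[:, const] = 1.0  # constant-imputed cases
    gm, sites = _panel(truth, [False] * m)
    result = _result_from(dosages, sites, gm.sample_ids)
    frame = per_snp_accuracy(gm, result, gm.sample_ids)
    best = result.best_guess
    for j in range(m):
        ok = truth[:, j] != MISSING
        row = frame.iloc[j]
        if ok.sum() >= 1:
            expect_perc = 100.0 * (best[ok, j] == truth[ok, j]).mean()
            assert row["perc"] == pytest.approx(expect_perc)
        x, y = truth[ok, j].astype(float), dosages[ok, j]
        if ok.sum() < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            assert np.isnan(row["r2"])
        else:
            expect = sps.pearsonr(x, y).statistic ** 2
            assert row["r2"] == pytest.approx(expect, abs=1e-9)


def test_per_animal_perfect_and_excluded(rng):
    truth = rng.integers(0, 3, size=(3, 50)).astype(np.int8)
    truth[2, :] = MISSING  # animal with no observed truth
    gm, sites = _panel(truth, [False] * 50)
    result = _result_from(truth.clip(0).astype(float), sites, gm.sample_ids)
    frame = per_animal_accuracy(gm, result, gm.sample_ids)
    assert list(frame["sample_id"]) == ["A0", "A1"]
    assert np.allclose(frame["r2"], 1.0)
    assert np.allclose(frame["perc"], 100.0)


def test_scored_sites_are_exactly_the_non_array_sites(rng):
    truth = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
    on_array = rng.random(30) < 0.3
    gm, sites = _panel(truth, on_array)
    result = _result_from(truth.astype(float), sites, gm.sample_ids)
    frame = per_snp_accuracy(gm, result, gm.sample_ids)
    assert len(frame) == (~on_array).sum()
    assert impute_fraction(30, int(on_array.sum())) == round(100 * len(frame) / 30, 2)


# ---------------------------------------------------------------------------
# stratification and calibration


def _make_frame(**cols):
    base = {
        "chrom": "1",
        "pos": np.arange(1, len(next(iter(cols.values()))) + 1),
        "fold": 0,
        "engine": "test",
        "undefined_reason": "",
    }
    base.update(cols)
    df = pd.DataFrame(base)
    if "window_id" not in df:
        df["window_id"] = (df["pos"] - 1) // 1_000_000
    if "impact" not in df:
        df["impact"] = "modifier"
    return df


def test_stratify_quartiles_match_order_statistics():
    vals = np.array([0.1, 0.9, 0.4, 0.6, 0.8])
    frame = _make_frame(r2=vals, perc=100 * vals, rsq=vals, maf=np.full(5, 0.2))
    out = stratify(frame, "maf_bins")
    row = out[(out["stratum"] == "maf>0.03") & (out["statistic"] == "r2")].iloc[0]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    assert (row["min"], row["q1"], row["median"], row["q3"], row["max"]) == (0.1, q1, med, q3, 0.9)
    assert row["mean"] == pytest.approx(vals.mean())
    rare = out[(out["stratum"] == "maf<=0.03") & (out["statistic"] == "r2")].iloc[0]
    assert rare["count"] == 0 and np.isnan(rare["median"])


def test_stratify_excludes_undefined_r2_only():
    frame = _make_frame(
        r2=[0.5, np.nan, 0.7], perc=[50.0, 60.0, 70.0], rsq=[0.4, 0.5, 0.6], maf=[0.2, 0.2, 0.2]
    )
    out = stratify(frame, "maf_bins")
    r2_row = out[(out["stratum"] == "maf>0.03") & (out["statistic"] == "r2")].iloc[0]
    perc_row = out[(out["stratum"] == "maf>0.03") & (out["statistic"] == "perc")].iloc[0]
    assert r2_row["count"] == 2
    assert perc_row["count"] == 3


def test_stratify_impact_classes_all_rows_present():
    frame = _make_frame(r2=[0.5, 0.6], perc=[90.0, 95.0], rsq=[0.4, 0.5], maf=[0.1, 0.2], impact=["high", "modifier"])
    out = stratify(frame, "impact_class")
    assert set(out["stratum"]) == {"high", "moderate", "low", "modifier"}
    assert out[(out["stratum"] == "moderate") & (out["statistic"] == "r2")].iloc[0]["count"] == 0


def test_window_id_half_open_boundary():
    frame = _make_frame(
        r2=[0.5, 0.6], perc=[1.0, 1.0], rsq=[0.1, 0.1], maf=[0.1, 0.1], pos=[1_000_000, 1_000_001]
    )
    assert list(frame["window_id"]) == [0, 1]


def test_rsq_calibration_identical_statistics():
    frame = _make_frame(r2=[0.2, 0.5, 0.9], perc=[1, 1, 1], rsq=[0.2, 0.5, 0.9], maf=[0.01, 0.2, 0.4])
    curve, summary = rsq_calibration(frame)
    assert summary["mean_signed_difference"] == 0.0
    assert summary["correlation"] == pytest.approx(1.0)
    assert np.allclose(curve["mean_r2"], curve["mean_rsq"])


def test_rsq_calibration_single_bin_reduces_to_scalars():
    frame = _make_frame(r2=[0.2, 0.6], perc=[1, 1], rsq=[0.1, 0.5], maf=[0.201, 0.209])
    curve, summary = rsq_calibration(frame, maf_bin_width=0.01)
    assert len(curve) == 1
    assert curve.iloc[0]["mean_r2"] == pytest.approx(0.4)
    assert curve.iloc[0]["mean_rsq"] == pytest.approx(0.3)


def test_rsq_calibration_requires_joint_sites():
    frame = _make_frame(r2=[np.nan], perc=[1.0], rsq=[0.5], maf=[0.2])
    with pytest.raises(ValueError):
        rsq_calibration(frame)


def test_fold_average_equals_pooled_mean_for_balanced_folds(rng):
    """With balanced folds over identical site sets, averaging per-SNP means
    fold-by-fold equals the pooled mean."""
    m = 40
    frames = []
    for fold in range(2):
        frames.append(
            _make_frame(r2=rng.uniform(0, 1, m), perc=rng.uniform(0, 100, m), rsq=rng.uniform(0, 1, m), maf=np.full(m, 0.2), fold=fold)
        )
    allf = pd.concat(frames, ignore_index=True)
    foldwise = allf.groupby("fold")["r2"].mean().mean()
    pooled = allf["r2"].mean()
    assert foldwise == pytest.approx(pooled)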