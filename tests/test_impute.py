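"""Imputation engines: HMM oracle equivalence, exact recovery, invariants."""

import itertools

import numpy as np
import pytest

from impute_eval import (
    GenotypeMatrix,
    HaplotypePanel,
    HmmParams,
    OswParams,
    copying_posteriors,
    import_external,
    impute_ls_hmm,
    impute_osw,
    model_rsq,
    new_variant_table,
    per_animal_accuracy,
    per_snp_accuracy,
    prephase_target,
)
from impute_eval.containers import model_rsq_haploid
from impute_eval.impute import _batched_posteriors
from impute_eval import vcfio


def enumerate_posteriors(haps, obs, gmap, mu, rho_scale):
    """Exhaustive path-sum oracle for the copying model.

    Sums the joint probability of every reference-haplotype state sequence
    (uniform start, uniform-jump transitions with switch probability
    1 - exp(-rho_scale * dmap), miscopy emission mu) and accumulates the
    marginal state posterior per observed site.
    """
    K, T = haps.shape
    rho = 1.0 - np.exp(-rho_scale * np.diff(gmap))
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        w = 1.0 / K
        for t, k in enumerate(path):
            if obs[t] >= 0:
                w *= (1.0 - mu) if haps[k, t] == obs[t] else mu
            if t > 0:
                stay = path[t - 1] == k
                w *= (1.0 - rho[t - 1]) + rho[t - 1] / K if stay else rho[t - 1] / K
        total += w
        for t, k in enumerate(path):
            post[t, k] += w
    return post / total


@pytest.mark.parametrize("K,T,seed", [(2, 2, 0), (3, 3, 1), (4, 3, 2), (5, 4, 3), (4, 4, 4), (5, 3, 5)])
def test_forward_backward_matches_path_enumeration(K, T, seed):
    """Posterior copying probabilities from the scaled forward-backward
    equal brute-force enumeration over all K^T paths to 1e-10."""
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(K, T)).astype(np.int8)
    obs = rng.integers(0, 2, size=T)
    obs[rng.random(T) < 0.2] = -1  # some unobserved entries
    gmap = np.sort(rng.uniform(0, 0.05, size=T))
    mu, rho_scale = 0.02, 8.0
    expected = enumerate_posteriors(haps, obs, gmap, mu, rho_scale)
    got = copying_posteriors(haps, obs, gmap, mu, rho_scale)
    np.testing.assert_allclose(got, expected, atol=1e-10)
    assert np.allclose(got.sum(axis=1), 1.0, atol=1e-9)


def test_tiny_panel_dosages_match_enumeration_interpolation(tiny_panel):
    """Full engine output on the 4-haplotype fixture equals dosages derived
    independently from enumerated posteriors plus genetic-map interpolation."""
    ref = tiny_panel["reference"]
    target = tiny_panel["target_haps"]
    params = HmmParams(mutation_rate=0.01, recomb_scale=5.0)
    result = impute_ls_hmm(ref, target, params)

    arr = ref.sites["on_array"].to_numpy(bool)
    gmap = ref.sites["pos"].to_numpy(float) * 1e-8
    haps_obs = ref.haplotypes[:, arr]
    arr_idx = np.flatnonzero(arr)
    expected_sample_dosage = np.zeros(ref.n_sites)
    for h in range(2):
        obs = target.haplotypes[h].astype(int)
        post = enumerate_posteriors(haps_obs, obs, gmap[arr], 0.01, 5.0)
        got = _batched_posteriors(haps_obs, obs[None, :].astype(np.int16), gmap[arr], 0.01, 5.0)[0]
        np.testing.assert_allclose(got, post, atol=1e-10)
        expected_sample_dosage[arr] += obs  # observed alleles pass through
        for s in np.flatnonzero(~arr):
            t_right = int(np.searchsorted(arr_idx, s))
            left, right = arr_idx[t_right - 1], arr_idx[t_right]
            w = (gmap[s] - gmap[left]) / (gmap[right] - gmap[left])
            expected_sample_dosage[s] += (
                (1 - w) * post[t_right - 1] @ ref.haplotypes[:, s]
                + w * post[t_right] @ ref.haplotypes[:, s]
            )
    np.testing.assert_allclose(result.dosages[0], expected_sample_dosage, atol=1e-10)


def test_identical_reference_haplotypes_degenerate_panel():
    """All-identical reference panel: every dosage is twice that haplotype's
    allele and the model Rsq is 0 at the (monomorphic) sites."""
    m = 6
    sites = new_variant_table(chrom=["1"] * m, pos=[10, 20, 30, 40, 50, 60],
                              on_array=[True, False, True, False, True, False])
    hap = np.array([1, 0, 1, 1, 0, 0], dtype=np.int8)
    ref = HaplotypePanel(sample_ids=["R0", "R1"], haplotypes=np.tile(hap, (4, 1)), sites=sites)
    ref.sites["maf"] = ref.maf()
    arr = sites["on_array"].to_numpy(bool)
    target = HaplotypePanel(sample_ids=["T0"], haplotypes=np.tile(hap[arr], (2, 1)),
                            sites=sites.loc[arr].reset_index(drop=True))
    result = impute_ls_hmm(ref, target, HmmParams())
    np.testing.assert_allclose(result.dosages[0], 2.0 * hap, atol=1e-12)
    assert np.all(result.rsq == 0.0)


def test_rsq_formula_is_one_for_perfect_allele_dosages():
    """Haplotype dosages equal to the true alleles give Rsq exactly 1
    (population-variance convention), whatever the frequency."""
    rng = np.random.default_rng(0)
    alleles = (rng.random((40, 30)) < rng.uniform(0.1, 0.9, size=30)).astype(float)
    poly = (alleles.sum(axis=0) > 0) & (alleles.sum(axis=0) < 40)
    rsq = model_rsq_haploid(alleles[:, poly])
    np.testing.assert_allclose(rsq, 1.0, atol=1e-12)


def test_prephase_exact_copy_recovers_true_pair(exact_copy):
    ref = exact_copy["reference"]
    target = exact_copy["target_array"]
    phased = prephase_target(target, ref)
    arr = ref.sites["on_array"].to_numpy(bool)
    for i in range(3):  # targets copy reference samples 0..2
        t1, t2 = phased.haplotypes[2 * i], phased.haplotypes[2 * i + 1]
        r1, r2 = ref.haplotypes[2 * i, arr], ref.haplotypes[2 * i + 1, arr]
        same = np.array_equal(t1, r1) and np.array_equal(t2, r2)
        swap = np.array_equal(t1, r2) and np.array_equal(t2, r1)
        assert same or swap


def test_prephase_all_homozygous_unique():
    m = 5
    sites = new_variant_table(chrom=["1"] * m, pos=list(range(100, 100 + m)))
    ref = HaplotypePanel(
        sample_ids=["R0"], haplotypes=np.array([[0, 1, 0, 1, 1], [1, 0, 1, 0, 0]], dtype=np.int8), sites=sites
    )
    ref.sites["maf"] = ref.maf()
    target = GenotypeMatrix(sample_ids=["T0"], codes=np.array([[0, 2, 0, 2, 0]], dtype=np.int8), sites=sites)
    phased = prephase_target(target, ref)
    np.testing.assert_array_equal(phased.haplotypes[0], [0, 1, 0, 1, 0])
    np.testing.assert_array_equal(phased.haplotypes[1], [0, 1, 0, 1, 0])


def test_prephase_rejects_all_missing_sample():
    m = 3
    sites = new_variant_table(chrom=["1"] * m, pos=[1, 2, 3])
    ref = HaplotypePanel(sample_ids=["R0"], haplotypes=np.array([[0, 1, 0], [1, 0, 1]], dtype=np.int8), sites=sites)
    target = GenotypeMatrix(sample_ids=["T0"], codes=np.full((1, 3), -1, dtype=np.int8), sites=sites)
    with pytest.raises(ValueError, match="T0"):
        prephase_target(target, ref)


def test_prephase_switch_error_low_for_offspring_of_reference():
    """Offspring of reference animals phase with <5% switch error at array
    density."""
    from impute_eval import SimConfig, breed_population, simulate_founders, select_array_sites
    import dataclasses

    cfg = SimConfig(n_founders=40, n_samples=40, n_chromosomes=1, n_sites_per_chrom=6000, seed=9)
    founders = simulate_founders(cfg)
    kids = breed_population(founders, cfg)
    sites = select_array_sites(kids.sites, 0.019, seed=9)
    founders = dataclasses.replace(founders, sites=sites)
    kids = dataclasses.replace(kids, sites=sites, pedigree=kids.pedigree)
    arr = sites["on_array"].to_numpy(bool)
    target = GenotypeMatrix(
        sample_ids=list(kids.sample_ids),
        codes=kids.genotypes()[:, arr],
        sites=sites.loc[arr].reset_index(drop=True),
    )
    phased = prephase_target(target, founders)
    truth = kids.subset_sites(arr)
    switches, hets = 0, 0
    for i in range(truth.n_samples):
        t1, t2 = phased.haplotypes[2 * i], phased.haplotypes[2 * i + 1]
        r1, r2 = truth.haplotypes[2 * i], truth.haplotypes[2 * i + 1]
        het = (r1 != r2) & (t1 != t2)
        if het.sum() < 2:
            continue
        orient = (t1[het] == r1[het]).astype(int)
        switches += (np.diff(orient) != 0).sum()
        hets += het.sum() - 1
    assert switches / hets < 0.05


@pytest.mark.parametrize("engine", ["lshmm", "osw"])
def test_exact_copy_recovery_both_engines(exact_copy, engine):
    """Targets duplicated from the reference are recovered perfectly."""
    ref = exact_copy["reference"]
    observed = exact_copy["observed"]
    target = exact_copy["target_array"]
    if engine == "lshmm":
        result = impute_ls_hmm(ref, prephase_target(target, ref), exact_copy["hmm_params"])
    else:
        result = impute_osw(ref, target, exact_copy["osw_params"])
    animals = per_animal_accuracy(observed, result, list(observed.sample_ids))
    np.testing.assert_allclose(animals["r2"], 1.0, atol=1e-9)
    np.testing.assert_allclose(animals["perc"], 100.0, atol=0)
    snps = per_snp_accuracy(observed, result, list(observed.sample_ids))
    assert (snps["perc"] == 100.0).all()


@pytest.mark.parametrize("engine", ["lshmm", "osw"])
def test_observed_array_genotypes_never_overwritten(exact_copy, engine):
    ref = exact_copy["reference"]
    target = exact_copy["target_array"]
    if engine == "lshmm":
        result = impute_ls_hmm(ref, prephase_target(target, ref), exact_copy["hmm_params"])
    else:
        result = impute_osw(ref, target, exact_copy["osw_params"])
    arr = ref.sites["on_array"].to_numpy(bool)
    np.testing.assert_allclose(result.dosages[:, arr], target.codes.astype(float), atol=1e-12)
    assert result.dosages.min() >= 0.0 and result.dosages.max() <= 2.0


def test_osw_falls_back_to_expected_dosage():
    """With no compatible reference pair anywhere, unobserved sites take the
    reference expected dosage 2p."""
    m = 8
    sites = new_variant_table(
        chrom=["1"] * m, pos=[i * 100 for i in range(1, m + 1)],
        on_array=[True, False] * 4,
    )
    rng = np.random.default_rng(3)
    haps = rng.integers(0, 2, size=(6, m)).astype(np.int8)
    arr = sites["on_array"].to_numpy(bool)
    haps[:, arr] = 0  # panel is hom-ref at every array site
    ref = HaplotypePanel(sample_ids=["R0", "R1", "R2"], haplotypes=haps, sites=sites)
    ref.sites["maf"] = ref.maf()
    # target hom-alt at every array site: no pair is compatible anywhere
    codes = np.full((1, int(arr.sum())), 2, dtype=np.int8)
    target = GenotypeMatrix(sample_ids=["T0"], codes=codes, sites=sites.loc[arr].reset_index(drop=True))
    result = impute_osw(ref, target, OswParams(initial_window_sites=4, min_window_sites=2, min_match_fraction=1.0))
    p = ref.allele_frequencies()
    hidden = ~arr
    np.testing.assert_allclose(result.dosages[0, hidden], 2.0 * p[hidden], atol=1e-12)


def test_osw_window_schedule():
    assert OswParams(initial_window_sites=64, shrink_factor=0.5, min_window_sites=4).schedule() == [64, 32, 16, 8, 4]
    with pytest.raises(ValueError, match="shrink_factor"):
        OswParams(shrink_factor=1.0).validate()
    with pytest.raises(ValueError, match="initial_window_sites"):
        OswParams(initial_window_sites=2, min_window_sites=4).validate()


def test_hmm_rejects_empty_reference():
    with pytest.raises(ValueError):
        _batched_posteriors(np.empty((0, 3), dtype=np.int8), np.zeros((1, 3), dtype=np.int16),
                            np.array([0.0, 0.01, 0.02]), 0.01, 5.0)


def test_import_external_roundtrip(tmp_path, exact_copy):
    """An imputed VCF written by the package re-imports with identical
    dosages, hard calls and per-site R2."""
    ref = exact_copy["reference"]
    target = exact_copy["target_array"]
    result = impute_osw(ref, target, exact_copy["osw_params"])
    path = str(tmp_path / "imputed.vcf")
    vcfio.write_imputation_result(result, path)
    back = import_external(path)
    np.testing.assert_allclose(back.dosages, result.dosages, atol=1e-5)
    np.testing.assert_array_equal(back.best_guess, result.best_guess)
    np.testing.assert_allclose(back.rsq, result.rsq, atol=1e-5)
    assert back.engine == "import"


def test_import_external_gt_only(tmp_path, exact_copy):
    """A VCF with GT but no DS yields dosages equal to the genotype codes."""
    observed = exact_copy["observed"]
    path = str(tmp_path / "gt_only.vcf")
    vcfio.write_genotype_matrix(observed, path)
    back = import_external(path)
    np.testing.assert_allclose(back.dosages, observed.codes.astype(float), atol=1e-12)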