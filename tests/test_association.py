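from itertools import combinations

import numpy as np
import pytest

from rarebin.association import (
    bin_and_test,
    burden_statistic,
    madsen_browning_weights,
    skat_statistic,
    skato_pvalue,
    unweighted,
    _permute_within_strata,
)
from rarebin.containers import GenotypeMatrix
from rarebin.simulate import CohortSimSpec, simulate_cohort


def exhaustive_burden_p(G, y):
    """Exact permutation p of the squared burden statistic by enumerating
    every distinct case-label placement."""
    G = np.asarray(G, float)
    n, n_case = y.size, int(y.sum())
    obs = burden_statistic(G, None, y)
    hits = total = 0
    for cases in combinations(range(n), n_case):
        yy = np.zeros(n)
        yy[list(cases)] = 1.0
        total += 1
        hits += burden_statistic(G, None, yy) >= obs - 1e-12
    return hits / total


# -- weights -----------------------------------------------------------------


def test_mb_weight_at_half_frequency():
    # m = n_controls makes q = 1/2; with n_i = 1, w = 1/sqrt(0.25) = 2
    spec = madsen_browning_weights([10], [1], 10)
    assert spec.q[0] == pytest.approx(0.5)
    assert spec.w[0] == pytest.approx(2.0)


def test_mb_weight_study_scale_singleton():
    spec = madsen_browning_weights([1], [760], 380)
    assert spec.q[0] == pytest.approx(2 / 762)
    assert spec.w[0] == pytest.approx(0.709, abs=1e-3)


def test_mb_weights_decrease_with_frequency():
    spec = madsen_browning_weights([1, 10], [760, 760], 380)
    assert spec.w[0] > spec.w[1]


def test_mb_weight_count_bounds():
    with pytest.raises(ValueError):
        madsen_browning_weights([21], [20], 10)
    with pytest.raises(ValueError):
        madsen_browning_weights([-1], [20], 10)


# -- statistics --------------------------------------------------------------


def test_burden_trivial_cases():
    y = np.array([1, 1, 0, 0], float)
    assert burden_statistic(np.zeros((4, 3)), None, y) == 0.0
    # one case and one control carrier cancel in the collapsed score
    G = np.array([[1], [0], [1], [0]], float)
    assert burden_statistic(G, None, y) == pytest.approx(0.0)


def test_burden_hand_computation():
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
    G = np.zeros((8, 1))
    G[:2, 0] = 1.0  # two case het carriers
    assert burden_statistic(G, None, y) == pytest.approx(1.0)


def test_skat_equals_burden_for_single_variant():
    y = np.array([1, 1, 1, 0, 0, 0], float)
    G = np.array([[1], [0], [1], [0], [0], [0]], float)
    assert skat_statistic(G, None, y) == pytest.approx(burden_statistic(G, None, y))


def test_skat_resists_cancellation():
    """Opposite-direction carrier imbalance cancels in the burden sum but
    not in the per-variant squared scores."""
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
    G = np.zeros((8, 2))
    G[[0, 1], 0] = 1.0  # variant 1: two case carriers
    G[[4, 5], 1] = 1.0  # variant 2: two control carriers
    q_skat = skat_statistic(G, None, y)
    q_burden = burden_statistic(G, None, y)
    assert q_burden == pytest.approx(0.0)
    assert q_skat == pytest.approx(2.0)
    assert q_skat > q_burden


def test_zero_phenotype_variance_rejected():
    with pytest.raises(ValueError):
        burden_statistic(np.ones((3, 1)), None, np.ones(3))


# -- permutation SKAT-O ------------------------------------------------------


def test_skato_all_zero_genotypes_gives_p_one():
    y = np.array([1, 1, 0, 0] * 5, float)
    res = skato_pvalue(np.zeros((20, 2)), np.ones(2), y, B=199, seed=0)
    assert res.p_value == 1.0


def test_skato_toy_matches_exhaustive_enumeration(toy_single_variant):
    G, y = toy_single_variant
    exact = exhaustive_burden_p(G, y)
    assert exact == pytest.approx(30 / 70)
    res = skato_pvalue(G, np.ones(1), y, B=9999, seed=5)
    assert res.p_value == pytest.approx(exact, abs=0.02)


def test_skato_pvalue_bounds_and_grid():
    y = np.array([1] * 5 + [0] * 5, float)
    G = np.zeros((10, 3))
    G[0, 0] = 1
    res = skato_pvalue(G, np.ones(3), y, B=499, seed=1)
    assert 1 / 500 <= res.p_value <= 1.0
    assert set(res.rho_grid) >= {0.0, 1.0}
    # min-p over the grid never exceeds any single rho's p
    assert min(res.p_per_rho.values()) >= res.p_per_rho[res.best_rho] - 1e-12


def test_skato_requires_valid_grid_and_B(toy_single_variant):
    G, y = toy_single_variant
    with pytest.raises(ValueError):
        skato_pvalue(G, np.ones(1), y, rho_grid=(0.0, 0.5), B=500)
    with pytest.raises(ValueError):
        skato_pvalue(G, np.ones(1), y, B=50)


def test_weight_scale_invariance(rng):
    G = rng.binomial(1, 0.05, size=(60, 6)).astype(float)
    y = np.array([1] * 30 + [0] * 30, float)
    w = rng.uniform(0.5, 2.0, 6)
    p1 = skato_pvalue(G, w, y, B=499, seed=7).p_value
    p2 = skato_pvalue(G, 13.7 * w, y, B=499, seed=7).p_value
    assert p1 == p2


def test_stratified_permutation_preserves_cohort_case_counts(rng):
    y = np.array([1] * 6 + [0] * 4 + [1] * 3 + [0] * 7, float)
    strata = np.array(["a"] * 10 + ["b"] * 10)
    Y = _permute_within_strata(y, strata, 200, rng)
    assert np.all(Y[:10].sum(axis=0) == 6)
    assert np.all(Y[10:].sum(axis=0) == 3)


# -- binning -----------------------------------------------------------------


def _labelled_cohort(seed=0):
    spec = CohortSimSpec(
        n_cases=50,
        n_controls=50,
        n_variants_per_class={"benign": 4, "hypomorph": 3, "lof": 3, "common": 0},
        seed=seed,
    )
    gm, samples, variants = simulate_cohort(spec)
    y = (samples["status"] == "case").to_numpy().astype(float)
    labels = dict(zip(variants["variant_id"], variants["true_class"]))
    return gm, y, labels


def test_bins_partition_variants():
    gm, y, labels = _labelled_cohort()
    res = {
        s: bin_and_test(gm, labels, s, y, weights=None, B=199, seed=0)
        for s in ("all", "benign", "hypomorph", "lof", "pathogenic")
    }
    assert res["all"].n_variants == sum(
        res[s].n_variants for s in ("benign", "hypomorph", "lof")
    )
    assert res["pathogenic"].n_variants == (
        res["hypomorph"].n_variants + res["lof"].n_variants
    )


def test_unlabelled_variants_default_benign():
    gm, y, labels = _labelled_cohort()
    only_pathogenic = {v: c for v, c in labels.items() if c != "benign"}
    res = bin_and_test(gm, only_pathogenic, "benign", y, weights=None, B=199, seed=0)
    assert res.n_variants == 4


def test_empty_bin_flagged():
    gm, y, labels = _labelled_cohort()
    no_lof = {v: "benign" for v in labels}
    res = bin_and_test(gm, no_lof, "lof", y, B=199, seed=0)
    assert res.n_variants == 0 and res.p_value is None
    assert any("empty" in w for w in res.warnings)


def test_planted_enrichment_separates_bins():
    """With all pathogenic carriers planted in cases, the pathogenic bin's
    median p over replicates is smaller than the benign bin's."""
    p_path, p_ben = [], []
    for i in range(100):
        spec = CohortSimSpec(
            n_cases=100,
            n_controls=100,
            n_variants_per_class={"benign": 6, "hypomorph": 5, "lof": 6, "common": 0},
            seed=500 + i,
        )
        gm, samples, variants = simulate_cohort(spec)
        y = (samples["status"] == "case").to_numpy().astype(float)
        labels = dict(zip(variants["variant_id"], variants["true_class"]))
        p_path.append(
            bin_and_test(gm, labels, "pathogenic", y, B=299, seed=i).p_value
        )
        p_ben.append(bin_and_test(gm, labels, "benign", y, B=299, seed=i).p_value)
    assert np.median(p_path) < np.median(p_ben)
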