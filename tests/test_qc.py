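import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarebin.containers import GenotypeMatrix
from rarebin.qc import (
    apply_sample_qc,
    compute_call_rate,
    compute_maf,
    pairwise_ibs,
    pca_outliers,
    stratify_variants,
    variant_qc_table,
)
from rarebin.simulate import CohortSimSpec, simulate_cohort

nan = np.nan


@pytest.mark.parametrize(
    "column, expected",
    [
        ([0, 1, nan, 2], 0.75),
        ([nan, nan, nan], 0.0),
        ([0] * 293 + [nan] * 467, 293 / 760),
    ],
)
def test_call_rate(column, expected):
    assert compute_call_rate(np.array(column, float)) == pytest.approx(expected)


def test_call_rate_empty_column_rejected():
    with pytest.raises(ValueError):
        compute_call_rate(np.array([]))


@pytest.mark.parametrize(
    "column, expected",
    [
        ([1] + [0] * 8 + [nan], 1 / 18),  # one het among 9 genotyped
        ([2, 2, 2], 0.0),  # all hom-alt folds to zero
        ([2, 1, 1, 0, 0, 0], 1 / 3),
    ],
)
def test_maf(column, expected):
    assert compute_maf(np.array(column, float)) == pytest.approx(expected)


def test_maf_all_missing_rejected():
    with pytest.raises(ValueError):
        compute_maf(np.array([nan, nan]))


@given(
    st.lists(st.sampled_from([0.0, 1.0, 2.0, nan]), min_size=1, max_size=40).filter(
        lambda xs: any(not np.isnan(x) for x in xs)
    )
)
def test_maf_folded_and_allele_swap_invariant(column):
    col = np.array(column, float)
    maf = compute_maf(col)
    assert 0.0 <= maf <= 0.5
    assert compute_maf(2.0 - col) == pytest.approx(maf)


def _records(mafs, call_rates=None, annotation="non-synonymous"):
    call_rates = call_rates or [1.0] * len(mafs)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(mafs))],
            "maf": mafs,
            "call_rate": call_rates,
            "annotation": annotation,
        }
    )


def test_stratify_direct_comparison():
    rec = _records([0.04, 0.008, 0.0005])
    assert len(stratify_variants(rec, 0.15, 0.01)) == 2
    # maf_max = 1.0 with no annotation restriction is the identity on
    # call-rate passers
    assert stratify_variants(rec, 0.15, 1.0) == ["v0", "v1", "v2"]


def test_stratify_unknown_annotation_rejected():
    with pytest.raises(ValueError):
        stratify_variants(_records([0.1]), 0.15, 0.5, ["weird"])


def test_strata_nested_and_filter_order_invariant(rng):
    mafs = rng.uniform(0, 0.5, 1000)
    crs = rng.uniform(0, 1, 1000)
    rec = _records(list(mafs), list(crs))
    sizes = [len(stratify_variants(rec, 0.15, m)) for m in (0.001, 0.01, 0.05)]
    assert sizes[0] <= sizes[1] <= sizes[2]
    # call-rate-then-MAF equals MAF-then-call-rate
    step1 = rec[rec["call_rate"] > 0.15]
    step2 = step1[step1["maf"] < 0.01]["variant_id"].tolist()
    assert step2 == stratify_variants(rec, 0.15, 0.01)


# -- IBS ---------------------------------------------------------------------


def _brute_ibs(D, i, j):
    num, den = 0.0, 0
    for a, b in zip(D[i], D[j]):
        if np.isnan(a) or np.isnan(b):
            continue
        num += 1 - abs(a - b) / 2
        den += 1
    return num / den if den else np.nan


def test_ibs_trivial_pairs():
    D = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, nan, 0, nan]], float)
    gm = GenotypeMatrix(D, ["s1", "s2", "s3"], list("abcd"))
    ibs, flags = pairwise_ibs(gm)
    assert ibs.loc["s1", "s2"] == 1.0
    dup = flags[flags["relation"] == "duplicate"]
    assert set(dup[["sample_i", "sample_j"]].iloc[0]) == {"s1", "s2"}
    # fully opposite homozygotes share nothing
    assert _brute_ibs(np.array([[0.0, 0.0], [2.0, 2.0]]), 0, 1) == 0.0
    gm2 = GenotypeMatrix(np.array([[0, 0], [2, 2]], float), ["x", "y"], ["a", "b"])
    assert pairwise_ibs(gm2)[0].loc["x", "y"] == 0.0


def test_ibs_matches_bruteforce_and_symmetry(rng):
    D = rng.choice([0.0, 1.0, 2.0, nan], size=(3, 4), p=[0.4, 0.3, 0.2, 0.1])
    D[0, 0] = 1.0  # guarantee a shared variant
    D[1, 0] = 1.0
    D[2, 0] = 0.0
    gm = GenotypeMatrix(D, ["s1", "s2", "s3"], list("abcd"))
    ibs, _ = pairwise_ibs(gm)
    for i in range(3):
        for j in range(3):
            expect = _brute_ibs(D, i, j)
            got = ibs.iloc[i, j]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect)
            assert ibs.iloc[i, j] == pytest.approx(ibs.iloc[j, i], nan_ok=True)
    # self-IBS is 1 wherever a sample has any non-missing call
    assert all(ibs.iloc[i, i] == pytest.approx(1.0) for i in range(3))


def test_planted_duplicates_flagged_exactly():
    spec = CohortSimSpec(
        n_cases=40,
        n_controls=40,
        n_variants_per_class={"benign": 5, "common": 40},
        n_duplicate_samples=3,
        seed=99,
    )
    gm, samples, _ = simulate_cohort(spec)
    _, flags = pairwise_ibs(gm, dup_threshold=0.99, rel_threshold=0.99)
    dup = flags[flags["relation"] == "duplicate"]
    found = {frozenset(p) for p in dup[["sample_i", "sample_j"]].itertuples(index=False)}
    planted = {
        frozenset((s.removesuffix("_dup"), s))
        for s in samples["sample_id"]
        if s.endswith("_dup")
    }
    assert found == planted


# -- PCA ---------------------------------------------------------------------


def test_pca_no_outliers_when_identical():
    D = np.tile(np.array([0.0, 1.0, 2.0, 1.0, 0.0]), (12, 1))
    gm = GenotypeMatrix(D, [f"s{i}" for i in range(12)], list("abcde"))
    out, _ = pca_outliers(gm, n_components=2, maf_min=0.0)
    assert out == []


def test_pca_flags_inverted_sample_and_sign_symmetry(rng):
    base = rng.binomial(2, 0.3, size=(49, 30)).astype(float)
    odd = 2.0 - base[0]  # systematically inverted dosages
    D = np.vstack([base, odd])
    ids = [f"s{i}" for i in range(50)]
    gm = GenotypeMatrix(D, ids, [f"v{j}" for j in range(30)])
    out, _ = pca_outliers(gm, n_components=2, sd_threshold=6.0)
    assert "s49" in out
    # allele-swapping every variant flips component signs at most; flags hold
    gm_swap = GenotypeMatrix(2.0 - D, ids, [f"v{j}" for j in range(30)])
    out_swap, _ = pca_outliers(gm_swap, n_components=2, sd_threshold=6.0)
    assert set(out) == set(out_swap)


def test_pca_more_components_than_samples_rejected():
    gm = GenotypeMatrix(np.zeros((3, 5)), ["a", "b", "c"], list("vwxyz"))
    with pytest.raises(ValueError):
        pca_outliers(gm, n_components=10)


def test_apply_sample_qc_removes_one_member_per_duplicate_pair():
    spec = CohortSimSpec(
        n_cases=30,
        n_controls=30,
        n_variants_per_class={"benign": 5, "common": 30},
        n_duplicate_samples=2,
        seed=4,
    )
    gm, samples, _ = simulate_cohort(spec)
    gm2, flagged, excl = apply_sample_qc(gm, samples, run_pca=False)
    assert len(excl["ibs_duplicate"]) == 2
    assert gm2.n_samples == gm.n_samples - 2


def test_variant_qc_table_counts_carriers_per_status():
    D = np.array([[1, 0], [nan, 2], [0, 1], [0, 0]], float)
    gm = GenotypeMatrix(D, ["c1", "c2", "k1", "k2"], ["v1", "v2"])
    samples = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "k1", "k2"],
            "cohort": "x",
            "status": ["case", "case", "control", "control"],
        }
    )
    vqc = variant_qc_table(gm, samples).set_index("variant_id")
    assert vqc.loc["v1", "carriers_case"] == 1
    assert vqc.loc["v1", "carriers_control"] == 0
    assert vqc.loc["v2", "carriers_case"] == 1
    assert vqc.loc["v2", "carriers_control"] == 1
    assert vqc.loc["v1", "call_rate"] == pytest.approx(0.75)
    assert vqc.loc["v1", "maf"] == pytest.approx(1 / 6)
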