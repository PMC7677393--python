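"""Sample- and variant-level quality control.

Implements the QC ladder applied to the sequenced cohorts before
association: per-variant call rate and folded minor-allele frequency
(computed within the analyzed cohort, cases and controls jointly), MAF /
annotation stratification, identity-by-state screening for duplicates and
first-degree relatives, and PCA-based ancestry-outlier flagging on common
variants.

Missing-dosage policy: missing calls are excluded from call-rate and MAF
denominators, mean-imputed per variant for PCA, and treated as non-carrier
(dosage 0) when counting carriers.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from rarebin.containers import ANNOTATIONS, GenotypeMatrix


def compute_call_rate(column: np.ndarray) -> float:
    """Fraction of samples with a non-missing genotype call."""
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValueError("empty dosage column")
    return float(np.count_nonzero(~np.isnan(column)) / column.size)


def compute_maf(column: np.ndarray) -> float:
    """Folded minor-allele frequency over non-missing diploid calls."""
    column = np.asarray(column, dtype=float)
    obs = column[~np.isnan(column)]
    if obs.size == 0:
        raise ValueError("MAF undefined: no non-missing genotypes")
    f = obs.sum() / (2 * obs.size)
    return float(min(f, 1.0 - f))


def variant_qc_table(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-variant call rate, folded MAF and per-cohort carrier counts.

    ``annotations`` (variant_id, annotation) is merged when given; variants
    without an entry get annotation ``other``. Carrier counts treat a
    missing call as non-carrier.
    """
    D = gm.dosages
    miss = np.isnan(D)
    n = D.shape[0]
    call_rate = 1.0 - miss.sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        alt = np.nansum(D, axis=0)
        denom = 2.0 * (n - miss.sum(axis=0))
        f = np.divide(alt, denom, out=np.full(D.shape[1], np.nan), where=denom > 0)
    maf = np.fmin(f, 1.0 - f)

    carrier = np.nan_to_num(D, nan=0.0) > 0
    status = samples.set_index("sample_id").loc[gm.sample_ids, "status"].to_numpy()
    is_case = status == "case"
    out = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "call_rate": call_rate,
            "maf": maf,
            "carriers_case": carrier[is_case, :].sum(axis=0),
            "carriers_control": carrier[~is_case, :].sum(axis=0),
        }
    )
    if annotations is not None and "annotation" in annotations.columns:
        bad = set(annotations["annotation"]) - set(ANNOTATIONS)
        if bad:
            raise ValueError(f"unknown annotation labels: {sorted(bad)}")
        out = out.merge(
            annotations[["variant_id", "annotation"]], on="variant_id", how="left"
        )
        out["annotation"] = out["annotation"].fillna("other")
    else:
        out["annotation"] = "other"
    return out


def stratify_variants(
    records: pd.DataFrame,
    call_rate_min: float = 0.15,
    maf_max: float = 1.0,
    annotation_subset: Optional[Iterable[str]] = None,
) -> List[str]:
    """Variant ids passing call_rate > ``call_rate_min`` and
    maf < ``maf_max``, optionally restricted to an annotation subset.

    Strata are nested: tightening ``maf_max`` can only shrink the list.
    """
    if not (0.0 < maf_max <= 1.0) or not (0.0 <= call_rate_min <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    keep = (records["call_rate"] > call_rate_min) & (records["maf"] < maf_max)
    if annotation_subset is not None:
        subset = set(annotation_subset)
        bad = subset - set(ANNOTATIONS)
        if bad:
            raise ValueError(f"unknown annotation labels: {sorted(bad)}")
        keep &= records["annotation"].isin(subset)
    return records.loc[keep, "variant_id"].tolist()


def pairwise_ibs(
    gm: GenotypeMatrix,
    dup_threshold: float = 0.99,
    rel_threshold: float = 0.85,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mean identity-by-state for every sample pair, plus exclusion flags.

    IBS(i, j) averages ``1 - |d_i - d_j| / 2`` over variants non-missing in
    both samples. Pairs at or above ``dup_threshold`` are duplicates, at or
    above ``rel_threshold`` first-degree relatives; the member of each
    flagged pair with the lower sample call rate is marked for exclusion.

    Returns (ibs matrix as DataFrame, flagged-pair table with columns
    sample_i, sample_j, ibs, relation, excluded_sample). Pairs with no
    shared non-missing variant get IBS NaN and relation ``uncomputable``.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    D = gm.dosages
    mask = ~np.isnan(D)
    # decompose |d_i - d_j| via dosage-indicator cross-counts (BLAS-friendly)
    X = [((D == v) & mask).astype(float) for v in (0.0, 1.0, 2.0)]
    shared = mask.astype(float) @ mask.astype(float).T
    absdiff = np.zeros_like(shared)
    for a in range(3):
        for b in range(3):
            if a != b:
                absdiff += abs(a - b) * (X[a] @ X[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - absdiff / (2.0 * shared)
    ibs[shared == 0] = np.nan
    ibs_df = pd.DataFrame(ibs, index=gm.sample_ids, columns=gm.sample_ids)

    call_rates = mask.mean(axis=1)
    rows = []
    upper = np.triu(np.ones_like(shared, dtype=bool), k=1)
    with np.errstate(invalid="ignore"):
        hits = np.argwhere(upper & ((shared == 0) | (ibs >= rel_threshold)))
    for i, j in hits:
        if shared[i, j] == 0:
            rows.append((gm.sample_ids[i], gm.sample_ids[j], np.nan, "uncomputable", None))
            continue
        v = ibs[i, j]
        relation = "duplicate" if v >= dup_threshold else "relative"
        worse = i if call_rates[i] <= call_rates[j] else j
        rows.append(
            (gm.sample_ids[i], gm.sample_ids[j], v, relation, gm.sample_ids[worse])
        )
    flags = pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "ibs", "relation", "excluded_sample"]
    )
    return ibs_df, flags


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> List[str]:
    """Greedy window/step LD pruning on dosage correlation (r^2)."""
    D = gm.imputed("mean")
    m = D.shape[1]
    keep = np.ones(m, dtype=bool)
    sd = D.std(axis=0)
    for start in range(0, max(m - 1, 1), step):
        idx = [j for j in range(start, min(start + window, m)) if keep[j] and sd[j] > 0]
        for ai in range(len(idx)):
            for bi in range(ai + 1, len(idx)):
                a, b = idx[ai], idx[bi]
                if not (keep[a] and keep[b]):
                    continue
                r = np.corrcoef(D[:, a], D[:, b])[0, 1]
                if r * r > r2_max:
                    keep[b] = False
    return [v for v, k in zip(gm.variant_ids, keep) if k]


def pca_outliers(
    gm: GenotypeMatrix,
    n_components: int = 10,
    sd_threshold: float = 6.0,
    maf_min: float = 0.05,
) -> Tuple[List[str], pd.DataFrame]:
    """Flag ancestry outliers on the top principal components.

    Common variants (folded MAF > ``maf_min``) are mean-imputed, centered
    and unit-scaled; a sample is an outlier when its score on any retained
    component lies more than ``sd_threshold`` robust standard deviations
    (1.4826 x MAD) from the component median. Deterministic up to component
    sign, which cannot change the flags.
    """
    maf = np.array([compute_maf(gm.dosages[:, j]) for j in range(gm.n_variants)])
    common = maf > maf_min
    if common.sum() < 2:
        raise ValueError("need at least two common variants for PCA")
    D = gm.imputed("mean")[:, common]
    D = D - D.mean(axis=0)
    sd = D.std(axis=0)
    sd[sd == 0] = 1.0
    D = D / sd
    k = min(n_components, min(D.shape) - 0)
    if gm.n_samples < n_components:
        raise ValueError("fewer samples than requested components")
    U, S, _ = np.linalg.svd(D, full_matrices=False)
    scores = U[:, :k] * S[:k]
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0)
    robust_sd = 1.4826 * mad
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(scores - med) / robust_sd
    z[:, robust_sd == 0] = 0.0  # zero-variance component: nothing to flag
    outliers = [gm.sample_ids[i] for i in range(gm.n_samples) if np.any(z[i] > sd_threshold)]
    score_df = pd.DataFrame(
        scores, index=gm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return outliers, score_df


def apply_sample_qc(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    dup_threshold: float = 0.99,
    rel_threshold: float = 0.85,
    pca_components: int = 10,
    pca_sd_threshold: float = 6.0,
    run_pca: bool = True,
    maf_min_ibs: float = 0.05,
    min_markers_rel: int = 200,
) -> Tuple[GenotypeMatrix, pd.DataFrame, Dict[str, List[str]]]:
    """IBS then PCA screening; returns the filtered matrix, the sample
    sheet with a ``qc_flags`` column, and the per-step exclusion lists.

    IBS is computed on common markers only (folded MAF > ``maf_min_ibs``):
    ultra-rare sites are homozygous reference in nearly every pair and
    would push mean IBS toward 1 regardless of relatedness. Duplicate
    calling is robust on a handful of markers; relative calling is not,
    so it is attempted only when at least ``min_markers_rel`` common
    markers are available (otherwise only duplicates are flagged).
    """
    maf = np.array([compute_maf(gm.dosages[:, j]) for j in range(gm.n_variants)])
    common_ids = [v for v, m in zip(gm.variant_ids, maf) if m > maf_min_ibs]
    gm_ibs = gm.subset_variants(common_ids) if common_ids else gm
    if len(common_ids) < min_markers_rel:
        rel_threshold = 2.0  # too few markers: relative inference underpowered
    _, ibs_flags = pairwise_ibs(gm_ibs, dup_threshold, min(rel_threshold, dup_threshold))
    excl: Dict[str, List[str]] = {"ibs_duplicate": [], "ibs_relative": [], "pca_outlier": []}
    for _, row in ibs_flags.iterrows():
        if row["relation"] == "duplicate":
            excl["ibs_duplicate"].append(row["excluded_sample"])
        elif row["relation"] == "relative":
            excl["ibs_relative"].append(row["excluded_sample"])
    removed = set(excl["ibs_duplicate"]) | set(excl["ibs_relative"])
    kept = [s for s in gm.sample_ids if s not in removed]
    gm2 = gm.subset_samples(kept)
    if run_pca:
        try:
            outliers, _ = pca_outliers(gm2, pca_components, pca_sd_threshold)
        except ValueError:
            outliers = []  # too few common variants / samples: skip the step
        excl["pca_outlier"] = outliers
        gm2 = gm2.subset_samples([s for s in gm2.sample_ids if s not in set(outliers)])
    flags = {}
    for step, ids in excl.items():
        for s in ids:
            flags.setdefault(s, []).append(step)
    samples = samples.copy()
    samples["qc_flags"] = [
        ";".join(flags.get(s, [])) for s in samples["sample_id"]
    ]
    return gm2, samples, excl
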