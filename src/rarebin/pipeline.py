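"""End-to-end orchestration: QC -> classification -> binned association ->
effect sizes -> meta pooling.

A run consumes a VCF plus sample / annotation sheets and an assay table
(or precomputed labels), applies the QC ladder, classifies each assayed
allele, tests every functional bin per cohort and pooled (with
cohort-stratified permutation), fits Firth odds ratios from the carrier
tables, and writes per-cohort and pooled summary tables in a fixed,
bit-stable TSV layout. Every filter logs its input and output counts so
the variant/sample accounting can be audited from the run log.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from rarebin import io as rio
from rarebin.association import DEFAULT_RHO_GRID, SUBSETS, bin_and_test, derive_seed
from rarebin.containers import ContingencyTable2x2, GenotypeMatrix
from rarebin.firth import cap_ci, firth_2x2
from rarebin.qc import apply_sample_qc, stratify_variants, variant_qc_table
from rarebin.rescue import classify_assay_table

logger = logging.getLogger("rarebin")

SUMMARY_COLUMNS = [
    "cohort",
    "subset",
    "n_variants",
    "n_variants_cases",
    "n_variants_controls",
    "p_unweighted",
    "p_weighted",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "ci_capped",
]


@dataclass
class RunConfig:
    """Flat, serializable configuration of one pipeline run."""

    vcf: Optional[str] = None
    samples: Optional[str] = None
    annotations: Optional[str] = None
    assay: Optional[str] = None
    labels: Optional[str] = None
    out_dir: str = "rarebin_out"

    call_rate_min: float = 0.15
    maf_strata: List[float] = field(default_factory=lambda: [0.05, 0.01, 0.001])
    ultra_rare_maf: float = 0.001
    alpha: float = 0.05
    dup_threshold: float = 0.99
    rel_threshold: float = 0.85
    pca_components: int = 10
    pca_sd_threshold: float = 6.0

    rho_grid: List[float] = field(default_factory=lambda: list(DEFAULT_RHO_GRID))
    B: int = 9999
    seed: int = 0
    or_cap: float = 999.0
    #: optional {cohort: [n_cases, n_controls]} overriding the analyzed
    #: (post-QC) denominators in the effect-size tables
    denominators: Optional[Dict[str, List[int]]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min outside [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha outside (0, 1)")
        if any(not 0.0 < m <= 1.0 for m in self.maf_strata):
            raise ValueError("maf strata must lie in (0, 1]")
        if self.B < 100:
            raise ValueError("B must be >= 100")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def pool_counts(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Column-wise sum of per-cohort count columns, subset by subset.

    All tables must carry the same subset rows. Count columns are summed;
    statistic columns are dropped (they must be recomputed on the pooled
    genotypes, not averaged).
    """
    if not tables:
        raise ValueError("nothing to pool")
    ref = list(tables[0]["subset"])
    for t in tables[1:]:
        if list(t["subset"]) != ref:
            raise ValueError("cohort tables have mismatched subset rows")
    out = tables[0][["subset"]].copy()
    for col in ("n_variants", "n_variants_cases", "n_variants_controls"):
        out[col] = sum(t[col].to_numpy() for t in tables)
    return out


def _carrier_counts(
    gm: GenotypeMatrix, is_case: np.ndarray
) -> Tuple[int, int, int, int]:
    """(summed case/control variant observations, distinct case/control
    carrier individuals) for the variants currently in ``gm``."""
    carrier = gm.imputed("zero") > 0
    per_variant_cases = int(carrier[is_case, :].sum())
    per_variant_controls = int(carrier[~is_case, :].sum())
    ind_cases = int(carrier[is_case, :].any(axis=1).sum())
    ind_controls = int(carrier[~is_case, :].any(axis=1).sum())
    return per_variant_cases, per_variant_controls, ind_cases, ind_controls


def _summary_rows(
    name: str,
    gm: GenotypeMatrix,
    y: np.ndarray,
    labels: Dict[str, str],
    strata: Optional[np.ndarray],
    denominators: Tuple[int, int],
    cfg: RunConfig,
) -> pd.DataFrame:
    n_cases_den, n_controls_den = denominators
    is_case = y == 1
    rows = []
    for subset in SUBSETS:
        res_u = bin_and_test(
            gm, labels, subset, y, weights="unweighted",
            rho_grid=cfg.rho_grid, B=cfg.B,
            seed=derive_seed(cfg.seed, name), strata=strata,
        )
        res_w = bin_and_test(
            gm, labels, subset, y, weights="madsen_browning",
            rho_grid=cfg.rho_grid, B=cfg.B,
            seed=derive_seed(cfg.seed, name), strata=strata,
        )
        if res_u.n_variants:
            if subset == "all":
                keep = list(gm.variant_ids)
            elif subset == "pathogenic":
                keep = [v for v in gm.variant_ids
                        if labels.get(v, "benign") in ("hypomorph", "lof")]
            else:
                keep = [v for v in gm.variant_ids
                        if labels.get(v, "benign") == subset]
            vc, vn, ica, ico = _carrier_counts(gm.subset_variants(keep), is_case)
        else:
            vc = vn = ica = ico = 0
        if ica > n_cases_den or ico > n_controls_den:
            raise ValueError(
                f"{name}/{subset}: carrier counts exceed configured denominators"
            )
        or_, lo, hi, capped = np.nan, np.nan, np.nan, False
        if n_cases_den > 0 and n_controls_den > 0:
            fit = cap_ci(
                firth_2x2(
                    ContingencyTable2x2(
                        ica, n_cases_den - ica, ico, n_controls_den - ico
                    ),
                    cap=None,
                ),
                cfg.or_cap,
            )
            or_, lo, hi, capped = fit.or_, fit.ci_low, fit.ci_high, fit.ci_capped
        rows.append(
            {
                "cohort": name,
                "subset": subset,
                "n_variants": res_u.n_variants,
                "n_variants_cases": vc,
                "n_variants_controls": vn,
                "p_unweighted": res_u.p_value,
                "p_weighted": res_w.p_value,
                "odds_ratio": or_,
                "ci_low": lo,
                "ci_high": hi,
                "ci_capped": capped,
            }
        )
        logger.info(
            "[assoc] %s/%s: n=%d cases=%d controls=%d p_unw=%s p_mb=%s OR=%.4g",
            name, subset, res_u.n_variants, vc, vn,
            res_u.p_value, res_w.p_value, or_,
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def analyze(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    annotations: Optional[pd.DataFrame],
    cfg: RunConfig,
    assay: Optional[pd.DataFrame] = None,
    labels: Optional[Dict[str, str]] = None,
) -> Dict[str, object]:
    """In-memory pipeline; returns all artifacts keyed by name."""
    n0 = gm.n_samples
    logger.info("[load] %d samples x %d variants", n0, gm.n_variants)

    # -- sample QC ----------------------------------------------------------
    gm, samples_flagged, excl = apply_sample_qc(
        gm, samples,
        dup_threshold=cfg.dup_threshold, rel_threshold=cfg.rel_threshold,
        pca_components=cfg.pca_components, pca_sd_threshold=cfg.pca_sd_threshold,
    )
    n_excl = sum(len(v) for v in excl.values())
    logger.info(
        "[sample-qc] %d -> %d samples (excluded %d: %s)",
        n0, gm.n_samples, n_excl,
        ", ".join(f"{k}={len(v)}" for k, v in excl.items()),
    )
    kept = set(gm.sample_ids)
    samples_kept = samples[samples["sample_id"].isin(kept)]
    sinfo = samples_kept.set_index("sample_id").loc[gm.sample_ids]
    y = (sinfo["status"] == "case").to_numpy().astype(float)
    cohorts = sinfo["cohort"].to_numpy()

    # -- variant QC ---------------------------------------------------------
    vqc = variant_qc_table(gm, samples_kept, annotations)
    passing = stratify_variants(vqc, call_rate_min=cfg.call_rate_min)
    logger.info(
        "[variant-qc] call rate > %g: %d -> %d variants",
        cfg.call_rate_min, gm.n_variants, len(passing),
    )
    for maf_max in cfg.maf_strata:
        stratum = stratify_variants(vqc, cfg.call_rate_min, maf_max)
        logger.info("[variant-qc] MAF < %g: %d variants", maf_max, len(stratum))
    ultra = stratify_variants(
        vqc,
        cfg.call_rate_min,
        cfg.ultra_rare_maf,
        ["non-synonymous"] if annotations is not None else None,
    )
    logger.info(
        "[variant-qc] ultra-rare (MAF < %g) non-synonymous: %d variants",
        cfg.ultra_rare_maf, len(ultra),
    )
    if not ultra:
        raise ValueError("no ultra-rare non-synonymous variants pass QC")
    gm_ultra = gm.subset_variants(ultra)

    # -- allele classification ---------------------------------------------
    if labels is None:
        labels = {}
        if assay is not None:
            classified = classify_assay_table(assay, alpha=cfg.alpha)
            labels = {a: c.label for a, c in classified.items()}
            logger.info(
                "[classify] %d alleles: %s", len(labels),
                ", ".join(
                    f"{cls}={sum(1 for v in labels.values() if v == cls)}"
                    for cls in ("benign", "hypomorph", "lof")
                ),
            )
    label_table = pd.DataFrame(
        sorted(labels.items()), columns=["allele_id", "label"]
    )

    # -- association + effect sizes, per cohort then pooled -----------------
    cohort_names = list(dict.fromkeys(cohorts))
    per_cohort = []
    for cname in cohort_names:
        in_c = cohorts == cname
        gm_c = gm_ultra.subset_samples([s for s, m in zip(gm.sample_ids, in_c) if m])
        # keep only variants observed in this cohort, so that pooled counts
        # are exactly the column-wise sums of the per-cohort tables
        seen = gm_c.imputed("zero").sum(axis=0) > 0
        if seen.any():
            gm_c = gm_c.subset_variants(
                [v for v, s in zip(gm_c.variant_ids, seen) if s]
            )
        den = (
            tuple(cfg.denominators[cname])
            if cfg.denominators and cname in cfg.denominators
            else (int(y[in_c].sum()), int((1 - y[in_c]).sum()))
        )
        per_cohort.append(
            _summary_rows(cname, gm_c, y[in_c], labels, None, den, cfg)
        )
    if cfg.denominators and "pooled" in cfg.denominators:
        den = tuple(cfg.denominators["pooled"])
    else:
        den = (int(y.sum()), int((1 - y).sum()))
    pooled = _summary_rows(
        "pooled", gm_ultra, y, labels,
        cohorts if len(cohort_names) > 1 else None, den, cfg,
    )
    pooled_counts = pool_counts(per_cohort)
    # consistency: pooled counts must equal the sum of the cohort tables
    for col in ("n_variants_cases", "n_variants_controls"):
        if not np.array_equal(pooled_counts[col].to_numpy(), pooled[col].to_numpy()):
            raise AssertionError(f"pooled {col} disagree with per-cohort sums")

    summary = pd.concat(per_cohort + [pooled], ignore_index=True)
    return {
        "summary": summary,
        "per_cohort": per_cohort,
        "pooled": pooled,
        "variant_qc": vqc,
        "samples": samples_flagged,
        "labels": label_table,
        "excluded": excl,
    }


def run_pipeline(cfg: RunConfig) -> Dict[str, object]:
    """File-based entry point: read inputs, analyze, write the out_dir."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"))
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if cfg.vcf is None or cfg.samples is None:
            raise ValueError("config must provide vcf and samples paths")
        gm, _ = rio.read_vcf(cfg.vcf)
        samples = rio.read_sample_sheet(cfg.samples)
        annotations = (
            rio.read_variant_sheet(cfg.annotations) if cfg.annotations else None
        )
        assay = rio.read_assay_table(cfg.assay) if cfg.assay else None
        labels = None
        if cfg.labels:
            lt = pd.read_csv(cfg.labels, sep="\t", dtype=str)
            labels = dict(zip(lt["allele_id"], lt["label"]))
        result = analyze(gm, samples, annotations, cfg, assay=assay, labels=labels)
        rio.write_tsv(result["summary"], os.path.join(cfg.out_dir, "summary.tsv"))
        rio.write_tsv(result["variant_qc"], os.path.join(cfg.out_dir, "variant_qc.tsv"))
        rio.write_tsv(result["samples"], os.path.join(cfg.out_dir, "sample_qc.tsv"))
        rio.write_tsv(result["labels"], os.path.join(cfg.out_dir, "labels.tsv"))
        cfg.to_yaml(os.path.join(cfg.out_dir, "config.yaml"))
        logger.info("[done] outputs written to %s", cfg.out_dir)
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
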