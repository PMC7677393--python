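"""Synthetic cohorts and rescue-assay measurements.

The generator emulates the structure the downstream analysis assumes: two
severe-schizophrenia case-control cohorts (~380/380 and ~477/479) carrying
an ultra-rare, mostly-singleton variant spectrum in a single gene, a
planted mixture of benign / hypomorph / loss-of-function case alleles, and
per-embryo ventricular-area measurements for the zebrafish morpholino
rescue assay (arms: uninjected control, MO alone, MO + wild-type mRNA,
MO + variant mRNA).

Ultra-rare variants are simulated as exact-carrier-count events (default a
single het carrier) rather than binomial draws: at a few hundred subjects,
a minor allele frequency below 0.1% implies singletons. Carriers land in
cases with a per-class probability, which is how case enrichment is
planted. Missingness, when requested, is applied uniformly at random per
variant; genotypes are otherwise independent across variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from rarebin.containers import CLASSES, GenotypeMatrix

RARE_CLASSES = ("benign", "hypomorph", "lof")
CONDITIONS = ("control", "MO", "MO+WT", "MO+variant")

CountPerCohort = Union[int, Sequence[int]]


def _per_cohort(value: CountPerCohort, n_cohorts: int, name: str) -> Tuple[int, ...]:
    if np.isscalar(value):
        out = (int(value),) * n_cohorts
    else:
        out = tuple(int(v) for v in value)
        if len(out) != n_cohorts:
            raise ValueError(f"{name} must have one entry per cohort")
    if any(v < 0 for v in out):
        raise ValueError(f"{name} entries must be non-negative")
    return out


@dataclass
class CohortSimSpec:
    """Design of a multi-cohort case-control simulation.

    ``n_cases`` / ``n_controls`` and the per-class variant counts may be a
    single integer (same in every cohort) or one value per cohort. Rare
    variants (benign / hypomorph / lof) are private to their cohort; common
    variants are shared by all samples so that PCA and IBS have
    cross-cohort support.
    """

    n_cases: CountPerCohort = 380
    n_controls: CountPerCohort = 380
    n_cohorts: int = 1
    n_variants_per_class: Dict[str, CountPerCohort] = field(
        default_factory=lambda: {"benign": 10, "hypomorph": 5, "lof": 6, "common": 30}
    )
    #: expected (exact) carriers per ultra-rare variant
    carrier_count: int = 1
    class_case_fraction: Dict[str, float] = field(
        default_factory=lambda: {"benign": 0.5, "hypomorph": 1.0, "lof": 1.0}
    )
    #: per-variant missingness fraction in [0, 1)
    missingness: float = 0.0
    #: samples to duplicate verbatim (for IBS testing)
    n_duplicate_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("need at least one cohort")
        self.n_cases = _per_cohort(self.n_cases, self.n_cohorts, "n_cases")
        self.n_controls = _per_cohort(self.n_controls, self.n_cohorts, "n_controls")
        for cls in self.n_variants_per_class:
            if cls not in RARE_CLASSES + ("common",):
                raise ValueError(f"unknown variant class {cls!r}")
        for cls, frac in self.class_case_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"class_case_fraction[{cls!r}] outside [0, 1]")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if self.carrier_count < 1:
            raise ValueError("carrier_count must be >= 1")

    def class_counts(self, cohort: int) -> Dict[str, int]:
        out = {}
        for cls, value in self.n_variants_per_class.items():
            out[cls] = _per_cohort(value, self.n_cohorts, cls)[cohort]
        return out


def simulate_cohort(
    spec: CohortSimSpec,
) -> Tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw genotypes, a sample sheet, and a variant sheet with true labels.

    Returns
    -------
    (GenotypeMatrix, samples, variants)
        ``samples``: sample_id, cohort, status. ``variants``: variant_id,
        chrom, pos, ref, alt, annotation, true_class, cohort.
    """
    rng = np.random.default_rng(spec.seed)

    sample_rows = []
    cohort_slices = {}  # cohort index -> (case indices, control indices)
    offset = 0
    for c in range(spec.n_cohorts):
        cid = f"cohort{c + 1}"
        nca, nco = spec.n_cases[c], spec.n_controls[c]
        for i in range(nca):
            sample_rows.append((f"{cid}_case{i:04d}", cid, "case"))
        for i in range(nco):
            sample_rows.append((f"{cid}_ctrl{i:04d}", cid, "control"))
        cohort_slices[c] = (
            np.arange(offset, offset + nca),
            np.arange(offset + nca, offset + nca + nco),
        )
        offset += nca + nco
    n_total = offset

    variant_rows = []
    columns = []
    pos = 17_780_000  # arbitrary anchor on the gene's chromosome
    for c in range(spec.n_cohorts):
        counts = spec.class_counts(c)
        case_idx, ctrl_idx = cohort_slices[c]
        for cls in RARE_CLASSES:
            frac = spec.class_case_fraction.get(cls, 0.5)
            for k in range(counts.get(cls, 0)):
                m = spec.carrier_count
                if m > case_idx.size + ctrl_idx.size:
                    raise ValueError(
                        f"carrier count {m} exceeds cohort{c + 1} size "
                        f"{case_idx.size + ctrl_idx.size}"
                    )
                n_case_carriers = rng.binomial(m, frac)
                if n_case_carriers > case_idx.size or m - n_case_carriers > ctrl_idx.size:
                    raise ValueError(
                        f"carrier count {m} cannot be placed in cohort{c + 1} "
                        f"({case_idx.size} cases / {ctrl_idx.size} controls)"
                    )
                col = np.zeros(n_total)
                carriers = np.concatenate(
                    [
                        rng.choice(case_idx, n_case_carriers, replace=False),
                        rng.choice(ctrl_idx, m - n_case_carriers, replace=False),
                    ]
                ).astype(int)
                col[carriers] = 1.0
                pos += 100
                variant_rows.append(
                    {
                        "variant_id": f"c{c + 1}_{cls}_{k:03d}",
                        "chrom": "8",
                        "pos": pos,
                        "ref": "A",
                        "alt": "G",
                        "annotation": "non-synonymous",
                        "true_class": cls,
                        "cohort": f"cohort{c + 1}",
                    }
                )
                columns.append(col)
    # common variants: shared across every cohort
    n_common = _per_cohort(
        spec.n_variants_per_class.get("common", 0), spec.n_cohorts, "common"
    )[0]
    for k in range(n_common):
        f = rng.uniform(0.05, 0.45)
        col = rng.binomial(2, f, n_total).astype(float)
        pos += 100
        variant_rows.append(
            {
                "variant_id": f"common_{k:03d}",
                "chrom": "8",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "annotation": "synonymous",
                "true_class": "common",
                "cohort": "shared",
            }
        )
        columns.append(col)

    if not columns:
        raise ValueError("spec produces zero variants")
    dosages = np.column_stack(columns)

    if spec.missingness > 0:
        mask = rng.random(dosages.shape) < spec.missingness
        dosages[mask] = np.nan

    if spec.n_duplicate_samples:
        dup_src = rng.choice(n_total, spec.n_duplicate_samples, replace=False)
        dup_rows = dosages[dup_src, :].copy()
        for i, src in enumerate(dup_src):
            sid, cid, status = sample_rows[src]
            sample_rows.append((f"{sid}_dup", cid, status))
        dosages = np.vstack([dosages, dup_rows])

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "cohort", "status"])
    variants = pd.DataFrame(variant_rows)
    gm = GenotypeMatrix(
        dosages, samples["sample_id"].tolist(), variants["variant_id"].tolist()
    )
    return gm, samples, variants


@dataclass
class AssaySimSpec:
    """Per-condition means and noise for the ventricular-area assay.

    Areas are on the control-normalized scale (control mean 1). Morphants
    show enlarged ventricles (``mu_mo`` > rescue means); the hypomorph mean
    sits strictly between full rescue and no rescue.
    """

    mu_control: float = 1.0
    mu_mo: float = 1.6
    mu_wt_rescue: float = 1.05
    mu_hypomorph: float = 1.30
    sigma: float = 0.15
    n_embryos_per_arm: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_mo > self.mu_wt_rescue >= self.mu_control > 0):
            raise ValueError(
                "require mu_mo > mu_wt_rescue >= mu_control > 0 (morphant enlargement)"
            )
        if not (self.mu_wt_rescue < self.mu_hypomorph < self.mu_mo):
            raise ValueError("hypomorph mean must lie strictly between rescue and MO")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_embryos_per_arm < 2:
            raise ValueError("need at least 2 embryos per arm")

    @property
    def class_means(self) -> Dict[str, float]:
        return {
            "benign": self.mu_wt_rescue,
            "hypomorph": self.mu_hypomorph,
            "lof": self.mu_mo,
        }


def _draw_arm(rng: np.random.Generator, mu: float, spec: AssaySimSpec) -> np.ndarray:
    areas = rng.normal(mu, spec.sigma, spec.n_embryos_per_arm)
    return np.clip(areas, 1e-9, None)  # areas are physical, strictly positive


def simulate_assay_batch(
    spec: AssaySimSpec,
    labels: Dict[str, str],
    batch: str = "batch1",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """One injection-round batch: shared control / MO / MO+WT arms plus one
    MO+variant arm per allele in ``labels`` (allele id -> planted class)."""
    for allele, cls in labels.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown class label {cls!r} for allele {allele!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = []
    shared = {
        "control": spec.mu_control,
        "MO": spec.mu_mo,
        "MO+WT": spec.mu_wt_rescue,
    }
    for cond, mu in shared.items():
        for area in _draw_arm(rng, mu, spec):
            rows.append(("_shared", cond, area, batch))
    for allele, cls in labels.items():
        for area in _draw_arm(rng, spec.class_means[cls], spec):
            rows.append((allele, "MO+variant", area, batch))
    return pd.DataFrame(rows, columns=["allele_id", "condition", "area", "batch"])


def simulate_assay(
    spec: AssaySimSpec,
    allele_class: str,
    allele_id: str = "allele1",
    batch: str = "batch1",
) -> pd.DataFrame:
    """Single-allele experiment: the four assay arms for one variant."""
    return simulate_assay_batch(spec, {allele_id: allele_class}, batch=batch)


# Factory specs for the two study cohorts -----------------------------------


def discovery_spec(seed: int = 0, **kw) -> CohortSimSpec:
    """380 cases / 380 controls; 6 LOF + 5 hypomorph singletons in cases,
    10 benign singletons split evenly between cases and controls."""
    return CohortSimSpec(
        n_cases=380,
        n_controls=380,
        n_cohorts=1,
        n_variants_per_class={"benign": 10, "hypomorph": 5, "lof": 6, "common": 30},
        seed=seed,
        **kw,
    )


def replication_spec(seed: int = 0, **kw) -> CohortSimSpec:
    """477 cases / 479 controls; 6 LOF + 5 hypomorph case singletons,
    6 benign singletons split evenly."""
    return CohortSimSpec(
        n_cases=477,
        n_controls=479,
        n_cohorts=1,
        n_variants_per_class={"benign": 6, "hypomorph": 5, "lof": 6, "common": 30},
        seed=seed,
        **kw,
    )


def two_cohort_spec(seed: int = 0, **kw) -> CohortSimSpec:
    """Both cohorts in one pooled design (discovery + replication sizes)."""
    return CohortSimSpec(
        n_cases=(380, 477),
        n_controls=(380, 479),
        n_cohorts=2,
        n_variants_per_class={
            "benign": (10, 6),
            "hypomorph": (5, 5),
            "lof": (6, 6),
            "common": 30,
        },
        seed=seed,
        **kw,
    )
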