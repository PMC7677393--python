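"""Core in-memory containers shared across the pipeline stages.

Dosages are stored as a dense ``float64`` samples x variants matrix with
``numpy.nan`` marking missing genotype calls; observed values are 0, 1 or 2
copies of the alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Functional classes assigned by the rescue assay.
CLASSES = ("benign", "hypomorph", "lof")

#: Annotation vocabulary consumed from the variant sheet.
ANNOTATIONS = ("non-synonymous", "synonymous", "other")


class GenotypeMatrix:
    """Samples x variants dosage matrix with missingness.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` array; entries in {0, 1, 2} or NaN.
    sample_ids, variant_ids
        Unique identifiers for the rows / columns.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        sample_ids: Sequence[str],
        variant_ids: Sequence[str],
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        sample_ids = list(map(str, sample_ids))
        variant_ids = list(map(str, variant_ids))
        if dosages.shape != (len(sample_ids), len(variant_ids)):
            raise ValueError(
                f"dosage shape {dosages.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(variant_ids)} variants"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("duplicate variant ids")
        obs = dosages[~np.isnan(dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("observed dosages must be 0, 1 or 2")
        self.dosages = dosages
        self.sample_ids = sample_ids
        self.variant_ids = variant_ids
        self._sidx = {s: i for i, s in enumerate(sample_ids)}
        self._vidx = {v: i for i, v in enumerate(variant_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._vidx[variant_id]]

    # -- subsetting ----------------------------------------------------------
    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._vidx[v] for v in variant_ids]
        return GenotypeMatrix(self.dosages[:, idx], self.sample_ids, list(variant_ids))

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._sidx[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[idx, :], list(sample_ids), self.variant_ids)

    def imputed(self, policy: str = "zero") -> np.ndarray:
        """Return a dense matrix with missing dosages imputed.

        ``zero``: a missing call is treated as non-carrier (rare-variant
        carrier counting and association). ``mean``: per-variant mean
        imputation (PCA on common variants).
        """
        out = self.dosages.copy()
        miss = np.isnan(out)
        if policy == "zero":
            out[miss] = 0.0
        elif policy == "mean":
            col_mean = np.nanmean(np.where(miss, np.nan, out), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
        else:
            raise ValueError(f"unknown imputation policy {policy!r}")
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


@dataclass
class AlleleClassification:
    """Three-class functional label for one allele with its evidence.

    ``p_vs_mo`` / ``p_vs_wt`` are the two-sided Welch p-values of the
    variant-rescue arm against the morpholino-alone and wild-type-rescue
    arms; the label is a pure function of these p-values, the arm means and
    the significance level used by the classifier.
    """

    allele_id: str
    label: str
    p_vs_mo: float
    p_vs_wt: float
    means: dict = field(default_factory=dict)  # condition -> normalized mean
    n: dict = field(default_factory=dict)  # condition -> embryos

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass
class ContingencyTable2x2:
    """Carrier counts: a/b case carriers/non-carriers, c/d for controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass
class FirthFit:
    """Penalized-likelihood logistic fit for the carrier effect."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    ci_capped: bool = False
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("Firth estimate must be finite")
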