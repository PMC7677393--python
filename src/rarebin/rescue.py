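"""Three-class functional labels from zebrafish rescue measurements.

Each allele is scored by co-injecting a pcm1 morpholino with the human
variant mRNA and measuring 3-dpf ventricular area against three reference
arms: uninjected controls, morpholino alone (no rescue) and morpholino +
wild-type mRNA (full rescue). The decision rule, applied to two-sided
Welch t-tests at level alpha on control-normalized areas:

* benign      — indistinguishable from the wild-type rescue
                (p_vs_wt >= alpha);
* lof         — indistinguishable from (or worse than) the morpholino
                alone (p_vs_mo >= alpha, or variant mean >= MO mean);
* hypomorph   — significantly different from both, with the variant mean
                strictly between full rescue and no rescue.

The rule is exhaustive: every allele receives exactly one label.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from rarebin.containers import AlleleClassification

PATHOGENIC = ("hypomorph", "lof")


def normalize_areas(assay: pd.DataFrame) -> pd.DataFrame:
    """Divide each area by the mean control-arm area of its batch.

    After normalization the control-arm mean is exactly 1 within every
    batch; ordering of arm means within a batch is preserved.
    """
    if "batch" not in assay.columns:
        assay = assay.assign(batch="batch1")
    out = []
    for batch, grp in assay.groupby("batch", sort=False):
        ctrl = grp.loc[grp["condition"] == "control", "area"]
        if ctrl.empty:
            raise ValueError(f"batch {batch!r} has no control arm")
        mean = ctrl.mean()
        if not np.isfinite(mean) or mean <= 0:
            raise ValueError(f"batch {batch!r} control mean is not positive")
        g = grp.copy()
        g["area"] = g["area"] / mean
        out.append(g)
    return pd.concat(out, ignore_index=True)


def welch_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value with a degenerate fast path:
    two zero-variance arms compare by exact equality of their means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 embryos per arm")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def classify_allele(
    variant_areas: Sequence[float],
    mo_areas: Sequence[float],
    wt_rescue_areas: Sequence[float],
    alpha: float = 0.05,
    allele_id: str = "allele",
) -> AlleleClassification:
    """Label one allele from its normalized rescue-arm measurements."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    v = np.asarray(variant_areas, dtype=float)
    mo = np.asarray(mo_areas, dtype=float)
    wt = np.asarray(wt_rescue_areas, dtype=float)
    p_vs_mo = welch_p(v, mo)
    p_vs_wt = welch_p(v, wt)
    if p_vs_wt >= alpha:
        label = "benign"
    elif p_vs_mo >= alpha or v.mean() >= mo.mean():
        label = "lof"
    else:
        label = "hypomorph"
    return AlleleClassification(
        allele_id=allele_id,
        label=label,
        p_vs_mo=p_vs_mo,
        p_vs_wt=p_vs_wt,
        means={"MO+variant": v.mean(), "MO": mo.mean(), "MO+WT": wt.mean()},
        n={"MO+variant": v.size, "MO": mo.size, "MO+WT": wt.size},
    )


def classify_assay_table(
    assay: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> Dict[str, AlleleClassification]:
    """Classify every allele in a (possibly multi-batch) assay table.

    Reference arms (control / MO / MO+WT) are taken from each allele's own
    batch; shared reference arms may carry any allele_id. With
    ``bonferroni`` the per-allele alpha is divided by the allele count.
    """
    norm = normalize_areas(assay)
    allele_rows = norm[norm["condition"] == "MO+variant"]
    alleles = [a for a in allele_rows["allele_id"].unique()]
    if not alleles:
        raise ValueError("assay table contains no MO+variant arm")
    eff_alpha = alpha / len(alleles) if bonferroni else alpha
    out = {}
    for allele in alleles:
        batch = allele_rows.loc[allele_rows["allele_id"] == allele, "batch"].iloc[0]
        in_batch = norm[norm["batch"] == batch]
        v = in_batch.loc[
            (in_batch["condition"] == "MO+variant") & (in_batch["allele_id"] == allele),
            "area",
        ]
        mo = in_batch.loc[in_batch["condition"] == "MO", "area"]
        wt = in_batch.loc[in_batch["condition"] == "MO+WT", "area"]
        if mo.empty or wt.empty:
            raise ValueError(f"batch {batch!r} lacks an MO or MO+WT reference arm")
        out[allele] = classify_allele(v, mo, wt, alpha=eff_alpha, allele_id=allele)
    return out


def binarize_pathogenicity(classification) -> str:
    """Collapse the three classes to pathogenic (hypomorph, lof) / benign."""
    label = (
        classification.label
        if isinstance(classification, AlleleClassification)
        else str(classification)
    )
    if label in PATHOGENIC:
        return "pathogenic"
    if label == "benign":
        return "benign"
    raise ValueError(f"unknown class label {label!r}")


def assay_concordance(
    labels_assay1: Dict[str, str],
    labels_assay2: Dict[str, str],
) -> Tuple[int, int, float, pd.DataFrame]:
    """Concordance of two assays' qualitative (pathogenic/benign) scores.

    Both label maps must cover the same non-empty allele set; within-class
    hypomorph/lof disagreements are reported separately in the per-allele
    table but do not count as discordant after binarization.
    """
    ids1, ids2 = set(labels_assay1), set(labels_assay2)
    if not ids1 or ids1 != ids2:
        raise ValueError("assays must cover the same non-empty allele set")
    rows = []
    n_conc = 0
    for allele in sorted(ids1):
        b1 = binarize_pathogenicity(labels_assay1[allele])
        b2 = binarize_pathogenicity(labels_assay2[allele])
        agree = b1 == b2
        n_conc += agree
        rows.append(
            {
                "allele_id": allele,
                "label_assay1": labels_assay1[allele]
                if isinstance(labels_assay1[allele], str)
                else labels_assay1[allele].label,
                "label_assay2": labels_assay2[allele]
                if isinstance(labels_assay2[allele], str)
                else labels_assay2[allele].label,
                "binarized_concordant": agree,
            }
        )
    total = len(ids1)
    return n_conc, total, n_conc / total, pd.DataFrame(rows)
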