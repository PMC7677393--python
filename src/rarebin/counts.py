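"""Published carrier counts for the two severe-schizophrenia cohorts.

Worked-example inputs: per-cohort counts of ultra-rare (MAF < 0.1%)
non-synonymous PCM1 variants observed in cases and controls, binned by
the zebrafish-rescue functional class. Each ultra-rare variant has a
single carrier, so variant counts equal carrier counts. Denominators are
the pre-QC cohort totals; the handful of subjects removed by QC makes
odds ratios computed from these totals approximate to within a few
percent, which is why downstream comparisons carry a documented
tolerance.

Per-embryo assay measurements are not transcribed here (they are not
redistributable); the classifier is exercised on synthetic data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from rarebin.containers import ContingencyTable2x2


@dataclass(frozen=True)
class CohortCounts:
    """Case/control totals plus per-bin (case carriers, control carriers)."""

    name: str
    n_cases: int
    n_controls: int
    bins: Dict[str, Tuple[int, int]]

    def table(self, subset: str) -> ContingencyTable2x2:
        if subset == "pathogenic":
            ca = self.bins["hypomorph"][0] + self.bins["lof"][0]
            co = self.bins["hypomorph"][1] + self.bins["lof"][1]
        else:
            ca, co = self.bins[subset]
        return ContingencyTable2x2(
            a=ca, b=self.n_cases - ca, c=co, d=self.n_controls - co
        )


DISCOVERY = CohortCounts(
    name="discovery",
    n_cases=380,
    n_controls=380,
    bins={"all": (16, 5), "benign": (5, 5), "hypomorph": (5, 0), "lof": (6, 0)},
)

REPLICATION = CohortCounts(
    name="replication",
    n_cases=477,
    n_controls=479,
    bins={"all": (14, 3), "benign": (3, 3), "hypomorph": (5, 0), "lof": (6, 0)},
)

POOLED = CohortCounts(
    name="pooled",
    n_cases=DISCOVERY.n_cases + REPLICATION.n_cases,
    n_controls=DISCOVERY.n_controls + REPLICATION.n_controls,
    bins={
        k: (
            DISCOVERY.bins[k][0] + REPLICATION.bins[k][0],
            DISCOVERY.bins[k][1] + REPLICATION.bins[k][1],
        )
        for k in DISCOVERY.bins
    },
)

#: Reported odds ratios for the worked example (same binning), used as
#: cross-checks in the test suite.
REPORTED_OR = {
    ("discovery", "all"): 3.007,
    ("discovery", "benign"): 1.000,
    ("discovery", "hypomorph"): 10.987,
    ("discovery", "lof"): 13.084,
    ("replication", "all"): 4.179,
    ("replication", "benign"): 1.000,
    ("replication", "hypomorph"): 11.003,
    ("replication", "lof"): 13.181,
    ("pooled", "all"): 3.598,
    ("pooled", "benign"): 1.000,
    ("pooled", "hypomorph"): 20.912,
    ("pooled", "lof"): 25.192,
    ("pooled", "pathogenic"): 44.6,
}

COHORTS = {"discovery": DISCOVERY, "replication": REPLICATION, "pooled": POOLED}
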