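"""Study statistics: split-plot ANOVA (loading within; genotype, age
between), the separate ANOVA on interlimb differences, and the formatted
group table with significance letters and paired-test asterisks.

Simulates a cohort (n = 7/genotype/age, both limbs) with a Ct.Th-like
outcome whose group means follow the published day-15 table, runs the full
statistical layer, and writes results/effects.csv and
results/group_table.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from bone4d import reference_data as ref
from bone4d.stats import group_table, interlimb_anova, rm_anova

SEED = 20260925
OUT = Path(__file__).resolve().parents[1] / "results"


def simulate_cohort(seed: int, outcome: str = "Ct.Th", day: int = 15,
                    n: int = 7) -> pd.DataFrame:
    """Cohort with group means/SDs equal to the published day-15 cells;
    within-animal limb correlation enters through a shared animal effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for gt, age in ref.GROUPS:
        for i in range(n):
            shared = rng.normal(0, 0.5)   # animal effect, fraction of group SD
            for limb in ("control", "loaded"):
                mean, sd = ref.microct_cell(outcome, gt, age, limb, day)
                value = mean + sd * (shared + rng.normal(0, np.sqrt(0.75)))
                rows.append({"animal": f"{gt}{age}-{i}", "genotype": gt,
                             "age": age, "limb": limb, "outcome": outcome,
                             "value": value})
    return pd.DataFrame(rows)


def main(seed: int = SEED) -> pd.DataFrame:
    table = simulate_cohort(seed)
    report = rm_anova(table, "Ct.Th")
    relative = interlimb_anova(table, "Ct.Th")

    effects = report.as_frame().assign(analysis="absolute")
    effects = pd.concat(
        [effects, relative.as_frame().assign(analysis="interlimb_difference")],
        ignore_index=True)
    OUT.mkdir(exist_ok=True)
    effects.to_csv(OUT / "effects.csv", index=False)

    groups = group_table(table, "Ct.Th", report)
    groups.to_csv(OUT / "group_table.csv", index=False)

    print(effects.round(4).to_string(index=False))
    print()
    print(groups.round(1).to_string(index=False))
    print(f"\nANOVA letters: {report.letters()!r} — at the published effect "
          "sizes the genotype, age, loading and genotype×loading terms "
          "dominate, mirroring the published day-15 annotations.")
    return effects


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
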