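"""Reliable change index: which memory declines are clinically significant?

Generates a synthetic cohort, regresses the pre-to-post change in verbal
encoding z-scores on age at surgery, resection volume and the preoperative
score with an MM-robust regression, and classifies each residual against
the lower limit of the 80% confidence interval: -1 = unexpected decline,
0 = predicted change.
"""

from disconnectome import SimulationConfig, gen_cohort, rci_table

cohort = gen_cohort(SimulationConfig(n_subjects=80, seed=42), include_maps=False)
rci = rci_table(cohort.manifest, confidence=0.80)

for (task, tp), grp in rci.groupby(["task", "timepoint"]):
    classified = grp["rci"].dropna()
    n_decline = int((classified == -1).sum())
    print(
        f"{task:>9} at {tp:>3}: {n_decline:2d}/{len(classified)} "
        f"({100 * n_decline / len(classified):.1f}%) unexpected decline"
    )
print()
print(
    "About 10% of subjects fall below the 80% two-sided lower limit by\n"
    "construction when residuals are Gaussian; excess decline beyond that\n"
    "rate tracks the tract-transection effect built into the simulation."
)
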