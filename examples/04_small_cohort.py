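"""Run the full pipeline on a scaled-down synthetic cohort.

Simulates a small two-group cohort (3 + 3 mice, weeks 0-3, positions
P2/P4/P6 + contralateral P7, two separations, 10 repeats), fits every
curve, and prints the group-mean rBF table, the elevation durations and
any significant weekly group differences. Runs in a few seconds.
"""

import pandas as pd

from dcsflow import CohortDesign, analyze_records, fit_cohort, simulate_cohort, summary_report

design = CohortDesign(
    n_autograft=3, n_allograft=3,
    weeks=(0, 1, 2, 3),
    graft_positions=("P2", "P4", "P6"),
    separations_mm=(2.9, 5.0),
    repeats=10,
    master_seed=42,
)
sim = simulate_cohort(design)
print(f"simulating + fitting {len(sim.ground_truth) * design.repeats} curves ...")
analysis = analyze_records(fit_cohort(sim))

table = analysis.rbf_summary
deep = table[(table.separation_mm == 5.0) & (table.week >= 1)]
print("\ngroup-mean rBF at 5.0 mm (weeks 1-3):")
print(deep.pivot_table(index=["group", "position"], columns="week", values="mean").round(2))

report = summary_report(analysis)
print("\nelevation durations (consecutive weeks with mean rBF > 1.25 from week 1):")
print(report["elevation_durations"].to_string(index=False))

sig = report["significant_tests"]
print(f"\n{len(sig)} significant weekly comparisons (p < 0.05)")
print()
print("The allograft group surges later and longer than the autograft group;")
print("with only 3 mice per group and 4 weeks, durations are noisier than in")
print("the full design (7 + 10 mice, 10 weeks, 30 repeats).")
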