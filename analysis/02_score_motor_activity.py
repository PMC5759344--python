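#!/usr/bin/env python
"""Motor activity scoring, end to end, for control and iron-deficient cohorts.

Generates synthetic 24-h recordings (bilateral leg EMG at 250 Hz), runs the
full jerk-detection -> PLM-classification chain, and tabulates PLMSI/PLMWI/
ILMSI per animal and per group, alongside the programmed ground truth and
detection performance. The headline contrast: ID animals show roughly a
six-fold PLMSI elevation over controls and periodic movements in quiet
wake, while isolated movements in sleep do not differ.

Writes results/table1_motor_per_animal.csv and
results/table1_motor_summary.csv.  Takes a few minutes (24 h x 13 animals
of 250-Hz EMG).
"""

import pandas as pd

from ratplm import get_preset, summarize_groups
from ratplm.pipeline import cohort_motor_indices

SEED = 22


def main():
    rows = []
    for name, n in (("C", 6), ("ID", 7)):
        print(f"scoring {name} cohort (n={n}) ...")
        for r in cohort_motor_indices(get_preset(name), n, seed=SEED):
            rows.append({"group": name, **r})
    per_animal = pd.DataFrame(rows)
    per_animal.to_csv("results/table1_motor_per_animal.csv", index=False,
                      float_format="%.5g")

    summary = summarize_groups(
        per_animal, metrics=["plmsi", "plmwi", "ilmsi", "hematocrit",
                             "sensitivity", "precision"])
    summary.to_csv("results/table1_motor_summary.csv", index=False,
                   float_format="%.4g")
    pivot = summary.pivot(index="metric", columns="group", values="mean")
    print(pivot.round(2).to_string())
    print("\nDetection vs programmed truth: mean |error| "
          f"{(per_animal.plmsi - per_animal.true_plmsi).abs().mean():.2f} "
          "events/h (PLMSI)")


if __name__ == "__main__":
    main()
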