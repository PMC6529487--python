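"""End-to-end study report: eight subjects, four scans, full read-out.

Runs the whole chain — per-subject plasma simulation with between-
subject variability and measurement noise, cohort outlier screening,
NCA, voxel phantoms, SUV quantification, tissue-to-plasma
classification, urine recovery and dosimetry arithmetic — and prints
the summary blocks a study report would contain.
"""

import warnings

from albupet.report import run_pipeline
from albupet.simulate import SimulationConfig

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # extrapolation warnings on noisy curves
    report = run_pipeline(SimulationConfig(seed=17))

act = report["administered_activity_MBq"]
print(f"administered activity: {act['mean']:.1f} +/- {act['stdev']:.1f} MBq "
      f"(range {act['min']:.2f}-{act['max']:.2f}), n={act['n']}")
print(f"mean effective dose:   {report['effective_dose_mSv']['mean']:.1f} mSv "
      "(PET coefficient route + 4 low-dose CTs)")

print("\nNCA cohort summary (mean +/- SD):")
for p in ("clearance", "half_life", "vss"):
    row = report["nca"]["cohort_summary"][p]
    print(f"  {p:<10} {row['mean']:9.1f} +/- {row['stdev']:.1f}")

print("\ntissue-to-plasma classification (consensus over subjects):")
for organ, entry in report["tissue_to_plasma"]["per_organ"].items():
    print(f"  {organ:<14} {entry['consensus']}")

urine = report["urine"]
print(f"\nurine: {urine['mean_pct_dose_24h']:.1f}% of dose in first 24 h; "
      "day-6/day-1 concentration ratio "
      f"{urine['per_subject'][0]['day6_day1_concentration_ratio']:.2f}")

# With the default seed-17 conditions the cohort reproduces the study-
# scale numbers: ~14 MBq administered, ~8.3 mSv exposure, clearance near
# 10 mL/h, terminal half-life in the 400-450 h range, Vss ~5.5 L, ~4%
# urinary recovery, and the four organ trajectory groups.
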