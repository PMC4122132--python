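"""Compute the five insertion-quality metrics for every simulated recording.

Reads results/manifest.csv (written by 01_simulate_cohort.py), computes
peak force, momentum, over-threshold occurrences, sudden-rise count and
jerk RMS per insertion, and writes results/metrics.csv.
"""

from pathlib import Path

import pandas as pd

from insertmetrics import MetricConfig, build_cohort_table, read_recording

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = pd.read_csv(ROOT / "results" / "manifest.csv")
    recordings = [
        read_recording(
            ROOT / row["path"],
            specimen_id=row["specimen_id"],
            technique=row["technique"],
            insertion_order=int(row["insertion_order"]),
        )
        for _, row in manifest.iterrows()
    ]
    table = build_cohort_table(recordings, MetricConfig())
    table.to_csv(ROOT / "results" / "metrics.csv", index=False)
    print(f"computed metrics for {len(table)} insertions -> results/metrics.csv")
    print(table.groupby("technique")[["peak_n", "over_threshold_n", "sudden_rise_n"]]
          .mean().round(2).to_string())


if __name__ == "__main__":
    main()
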