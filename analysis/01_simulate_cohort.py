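"""Simulate the study cohort: 10 forceps, 8 commercial-tool and 8 motorized
insertions with technique-specific force-profile archetypes.

Recordings (one CSV per insertion, ~2k-4k samples each) go to
scratch/cohort/; the manifest (specimen, technique, order, seed, file) goes
to results/manifest.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from insertmetrics import CohortConfig, simulate_cohort, write_recording

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    out = ROOT / "scratch" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(CohortConfig(master_seed=SEED))
    rows = []
    for rec in cohort:
        fname = f"{rec.specimen_id}_o{rec.insertion_order}.csv"
        write_recording(rec, out / fname)
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "technique": rec.technique,
                "insertion_order": rec.insertion_order,
                "seed": rec.seed,
                "path": str((out / fname).relative_to(ROOT)),
            }
        )
    manifest = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    manifest.to_csv(ROOT / "results" / "manifest.csv", index=False)
    counts = manifest.groupby("technique").size().to_dict()
    print(f"simulated {len(manifest)} insertions (master seed {SEED}): {counts}")
    print(f"recordings in {out}, manifest in results/manifest.csv")


if __name__ == "__main__":
    main()
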