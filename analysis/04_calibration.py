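"""Monte-Carlo calibration of the statistical stages.

(1) Type-I error of the two-group ANOVA: both groups drawn from the
    motorized archetype (n = 10 vs 8), rejection rate at alpha = 0.05.
(2) Null exclusion rate of the insertion-order screen on cohorts with no
    injected order effect.

Writes results/calibration.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from insertmetrics import (
    CohortConfig,
    default_params,
    force_norm,
    order_effect_screen,
    peak_force,
    simulate,
    simulate_cohort,
)
from insertmetrics.comparison import _anova_p

ROOT = Path(__file__).resolve().parents[1]
N_ANOVA, N_SCREEN, ALPHA = 600, 300, 0.05


def main() -> None:
    rng = np.random.default_rng(2014)
    rejections = 0
    for _ in range(N_ANOVA):
        peaks = []
        for _ in range(18):
            seed = int(rng.integers(2**31 - 1))
            f = float(np.clip(1.0 + 0.15 * rng.standard_normal(), 0.5, 1.5))
            peaks.append(peak_force(force_norm(
                simulate(default_params("motorized", seed=seed, base_peak=0.26 * f)))))
        rejections += _anova_p([np.asarray(peaks[:10]), np.asarray(peaks[10:])]) < ALPHA

    exclusions = 0
    for rep in range(N_SCREEN):
        cohort = simulate_cohort(CohortConfig(master_seed=50_000 + rep))
        table = pd.DataFrame(
            [
                {
                    "specimen_id": r.specimen_id,
                    "technique": r.technique,
                    "insertion_order": r.insertion_order,
                    "peak_n": peak_force(force_norm(r)),
                }
                for r in cohort
            ]
        )
        exclusions += bool(order_effect_screen(table, alpha=ALPHA).excluded_orders)

    out = pd.DataFrame(
        [
            {"check": "anova_type1_rate", "alpha": ALPHA,
             "rate": rejections / N_ANOVA, "n_replicates": N_ANOVA},
            {"check": "order_screen_null_exclusion_rate", "alpha": ALPHA,
             "rate": exclusions / N_SCREEN, "n_replicates": N_SCREEN},
        ]
    )
    out.to_csv(ROOT / "results" / "calibration.csv", index=False)
    print(out.to_string(index=False))
    print("both rates should sit near the nominal alpha")


if __name__ == "__main__":
    main()
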