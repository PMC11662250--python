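#!/usr/bin/env python
"""Fit the pooled propensity model and compute stabilized weights.

Writes results/03_balance.csv (unweighted and weighted standardized mean
differences per covariate) and prints the weight diagnostics.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, get_db, run_config  # noqa: E402

from ttemu import prepare_cohort  # noqa: E402
from ttemu.ipw import balance_report  # noqa: E402


def main():
    db = get_db()
    prep = prepare_cohort(db, run_config())
    point = prep.estimate(crude=False)
    rep = balance_report(
        prep.covariates.reset_index(drop=True), prep.arm_entry, point["sw"]
    )
    RESULTS.mkdir(exist_ok=True)
    rep.table.to_csv(RESULTS / "03_balance.csv", index=False)
    t = rep.table
    worst = t.sort_values("smd_unweighted", ascending=False).head(6)
    print(worst.to_string(index=False))
    nonfy = t[~t["covariate"].str.startswith("trial_fy")]
    print(
        f"\nstabilized weights: mean {np.mean(point['sw']):.4f}, "
        f"max {np.max(point['sw']):.1f}"
    )
    print(
        f"max weighted |SMD| outside the fiscal-year design margins: "
        f"{nonfy['smd_weighted'].max():.3f} (all confounders < 0.1: "
        f"{bool((nonfy['smd_weighted'] < 0.1).all())})"
    )


if __name__ == "__main__":
    main()
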