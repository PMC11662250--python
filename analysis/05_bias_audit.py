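#!/usr/bin/env python
"""Negative-control outcome run, bias-calibrated hazard ratio and E-values.

Re-runs the full pipeline with the depression-coded negative-control outcome
(prevalent cases excluded at baseline, no drug conjunction), calibrates the
primary HR by the negative-control HR, converts to a risk ratio with the
common-outcome transformation, and reports E-values.  Writes
results/05_bias_audit.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ANALYSIS_SEED, RESULTS, get_db, run_config  # noqa: E402

from ttemu import (  # noqa: E402
    BootstrapSpec,
    bias_audit,
    bootstrap_cis,
    prepare_cohort,
)


def main():
    db = get_db()
    rc = run_config()
    prep = prepare_cohort(db, rc)
    primary = prep.estimate()
    boot_p = bootstrap_cis(
        prep.bootstrap_pipeline(), prep.person_ids,
        BootstrapSpec(n_reps=100, seed=ANALYSIS_SEED),
    )
    prep_nc = prepare_cohort(db, rc, outcome_name="negative_control")
    nc = prep_nc.estimate()
    boot_nc = bootstrap_cis(
        prep_nc.bootstrap_pipeline(), prep_nc.person_ids,
        BootstrapSpec(n_reps=100, seed=ANALYSIS_SEED + 1),
    )
    audit = bias_audit(
        primary["hr"], nc["hr"], boot_p.hr_ci, boot_nc.hr_ci, outcome_rare=False
    )
    out = {
        "primary_hr": round(primary["hr"], 4),
        "primary_ci": [round(x, 4) for x in boot_p.hr_ci],
        "negative_control_hr": round(nc["hr"], 4),
        "negative_control_ci": [round(x, 4) for x in boot_nc.hr_ci],
        **{k: (round(v, 4) if isinstance(v, float) else v)
           for k, v in audit.to_dict().items()},
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "05_bias_audit.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))
    covers = out["negative_control_ci"][0] <= 1 <= out["negative_control_ci"][1]
    print(
        f"\nNegative-control HR {out['negative_control_hr']} "
        f"({'consistent with' if covers else 'inconsistent with'} no residual "
        f"bias); calibrated HR {out['hr_calibrated']:.3f}; E-value "
        f"{out['e_value_point']:.3f}."
    )


if __name__ == "__main__":
    main()
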