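#!/usr/bin/env python
"""Designed-failure experiment: the normoxic combination arm misbehaves.

Arm VI is regenerated with its immunotherapy kill increment gamma_i
inflated 18-fold — the structure the staged framework is meant to
diagnose.  Stage 3 should fail (CCC near zero), the sensitivity ranking
should put gamma_i first, and a single-parameter re-calibration should
recover the inflation factor.
"""

import json
from pathlib import Path

from evoimmune import (
    MCMCSettings,
    NoiseSpec,
    StagedSettings,
    default_protocol,
    generate_cohort,
    posterior_mean_parameters,
    staged_calibration,
)

BASE = Path(__file__).resolve().parents[1] / "results"
INFLATION = 18.0


def main():
    params = posterior_mean_parameters()
    specs = default_protocol()
    data = generate_cohort(params, specs, NoiseSpec(seed=0),
                           param_overrides={"VI": {"gamma_i": INFLATION * params.gamma_i}})
    res = staged_calibration(data, specs,
                             settings=StagedSettings(mcmc=MCMCSettings(seed=0)))
    print(f"stage-3 predictive CCC: {res.stage3_ccc:.3f} -> status {res.status}")
    s4 = res.stage4
    print(f"sensitivity rank order: {s4['rank_order']}")
    print(f"re-calibrated: {s4['selected']} = {s4['value']:.4g} "
          f"(fold change {s4['fold_change']:.1f}, generating inflation {INFLATION})")
    print(f"post-recalibration CCC: {s4['ccc']:.3f}")
    out = BASE / "designed_failure"
    out.mkdir(parents=True, exist_ok=True)
    (out / "stage4.json").write_text(json.dumps(
        {k: v for k, v in s4.items() if k != "tested"}, indent=2, sort_keys=True))
    print(f"wrote {out}/stage4.json")


if __name__ == "__main__":
    main()
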