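#!/usr/bin/env python
"""Point-estimate decision-tree run over trial and lifetime horizons.

Evaluates the tree with the bundled published point values (treatment-mix
probabilities, MACE baseline and odds ratios, adjusted branch costs, arm
QALYs) and the lifetime extension (life expectancy conditioned on index-year
MACE, £423/year tariff, age-declining utility with a -0.05 MACE decrement,
3.5% discounting). Writes results/point_estimates.json.
"""

import dataclasses
import json
from pathlib import Path

from ffrcea.config import load_model_params
from ffrcea.decision_model import run_model
from ffrcea.psa import icer

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = load_model_params()
    results = run_model(params)
    inc = results["incremental"]
    payload = {arm: dataclasses.asdict(results[arm]) for arm in ("standard", "ffr")}
    payload["incremental"] = inc
    payload["icer_trial"] = icer(inc["trial_cost"], inc["trial_qaly"])
    payload["icer_lifetime"] = icer(inc["lifetime_cost"], inc["lifetime_qaly"])
    (OUT / "point_estimates.json").write_text(json.dumps(payload, indent=2))

    for arm in ("standard", "ffr"):
        r = results[arm]
        print(f"{arm:8s} trial £{r.trial_cost:.0f} / {r.trial_qaly:.3f} QALYs | "
              f"lifetime £{r.lifetime_cost:.0f} / {r.lifetime_qaly:.2f} QALYs "
              f"(P(MACE) {r.p_mace:.3f})")
    print(f"increments: trial £{inc['trial_cost']:.0f} / {inc['trial_qaly']:.3f}; "
          f"lifetime £{inc['lifetime_cost']:.0f} / {inc['lifetime_qaly']:.3f}")
    print(f"ICER: trial {payload['icer_trial']}, lifetime {payload['icer_lifetime']}")
    print(f"wrote {OUT / 'point_estimates.json'}")


if __name__ == "__main__":
    main()
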