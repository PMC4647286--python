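#!/usr/bin/env python
"""Probabilistic sensitivity analysis and decision uncertainty.

Propagates 10,000 draws of every calibrated parameter distribution
(Dirichlet treatment mixes, beta MACE baseline, lognormal odds ratios,
gamma costs, normal life expectancies, beta utility decrement) through the
decision tree for both horizons. Reports mean increments with percentile
CIs, ICERs, and the cost-effectiveness acceptability curves over a
£0-50,000/QALY willingness-to-pay grid. Writes results/psa_draws.csv,
results/ceac.csv and results/psa_summary.json; pass --plot to render the
CE plane and CEAC under scratch/.
"""

import argparse
import json
from pathlib import Path

from ffrcea.config import load_model_params
from ffrcea.psa import run_psa, summarise_psa

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
N_DRAWS = 10_000


def plot(draws, result) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    axes[0].scatter(draws.de_trial, draws.dc_trial, s=2, alpha=0.2, label="trial")
    axes[0].scatter(draws.de_life, draws.dc_life, s=2, alpha=0.2, label="lifetime")
    axes[0].axhline(0, lw=0.5, c="k"); axes[0].axvline(0, lw=0.5, c="k")
    axes[0].set_xlabel("incremental QALYs"); axes[0].set_ylabel("incremental cost (£)")
    axes[0].set_title("Cost-effectiveness plane"); axes[0].legend()
    ct = result.ceac_table
    axes[1].plot(ct["wtp"], ct["prob_trial"], label="trial")
    axes[1].plot(ct["wtp"], ct["prob_life"], label="lifetime")
    axes[1].set_xlabel("willingness to pay (£/QALY)")
    axes[1].set_ylabel("probability cost-effective")
    axes[1].set_ylim(0, 1); axes[1].set_title("CEAC"); axes[1].legend()
    fig.tight_layout()
    fig.savefig(scratch / "ce_plane_ceac.png", dpi=150)
    print(f"wrote {scratch / 'ce_plane_ceac.png'}")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--plot", action="store_true")
    parser.add_argument("--seed", type=int, default=20140105)
    args = parser.parse_args()

    params = load_model_params()
    draws = run_psa(params, n_draws=N_DRAWS, seed=args.seed)
    result = summarise_psa(draws)

    draws.to_frame().to_csv(OUT / "psa_draws.csv", index=False)
    result.ceac_table.to_csv(OUT / "ceac.csv", index=False)
    payload = {
        "summary": result.summary.to_dict(orient="index"),
        "icer_trial": result.icer_trial,
        "icer_lifetime": result.icer_life,
        "n_draws": draws.n_draws,
        "seed": draws.seed,
    }
    (OUT / "psa_summary.json").write_text(json.dumps(payload, indent=2))

    s = result.summary
    for h in ("trial", "life"):
        print(f"{h:5s}: dC £{s.loc[f'dc_{h}', 'mean']:.0f} "
              f"({s.loc[f'dc_{h}', 'ci_low']:.0f} to {s.loc[f'dc_{h}', 'ci_high']:.0f}), "
              f"dE {s.loc[f'de_{h}', 'mean']:.3f} "
              f"({s.loc[f'de_{h}', 'ci_low']:.3f} to {s.loc[f'de_{h}', 'ci_high']:.3f})")
    ct = result.ceac_table
    band = ct[(ct.wtp >= 20_000) & (ct.wtp <= 30_000)]
    print(f"ICER: trial {result.icer_trial}, lifetime {result.icer_life}")
    print(f"P(cost-effective) at £20-30k/QALY: trial "
          f"{band.prob_trial.min():.2f}-{band.prob_trial.max():.2f}, "
          f"lifetime {band.prob_life.min():.2f}-{band.prob_life.max():.2f}")
    for f in ("psa_draws.csv", "ceac.csv", "psa_summary.json"):
        print(f"wrote {OUT / f}")
    if args.plot:
        plot(draws, result)


if __name__ == "__main__":
    main()
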