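"""Per-cell fumarate uptake rates by Bayesian depletion fitting.

Simulates depletion + cell-count traces for the four transporter-induction
levels (steady-state uptake 1.8, 2.1, 2.6, 3.7 e-6 nmol/cell/h at 2 g/l),
fits each by MCMC, and reports posterior uptake medians with 95% intervals.
Writes results/uptake_posteriors.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from bistflux.kinetics import fit_depletion_mcmc, steady_state_uptake
from bistflux.synthetic import simulate_depletion

UPTAKE_LEVELS = [1.8e-6, 2.1e-6, 2.6e-6, 3.7e-6]  # nmol/cell/h at 2 g/l
K_U = 0.5
S0 = 2.0


def main(seed: int = 1) -> None:
    rows = []
    for i, uptake in enumerate(UPTAKE_LEVELS):
        q_max = uptake * (K_U + S0) / S0
        # 16 timepoints at 3% noise: enough resolution to separate adjacent
        # induction levels (~15% apart) in a single trace each
        trace = simulate_depletion(q_max, K_U, 0.25, 0.5, 2e7, S0,
                                   np.linspace(0, 24, 16), noise_cv=0.03,
                                   seed=seed * 100 + i)
        post = fit_depletion_mcmc(
            trace, chain_config={"n_walkers": 16, "n_steps": 1250,
                                 "seed": seed * 100 + i})
        est = steady_state_uptake(post, S0)
        rows.append({
            "uptake_true": uptake, "uptake_median": est.median,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "acceptance": post.acceptance_rate,
            "max_rhat": max(post.rhat.values()),
        })
        print(f"level {i}: true {uptake:.2e} -> median {est.median:.2e} "
              f"[{est.ci_low:.2e}, {est.ci_high:.2e}] nmol/cell/h")
    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/uptake_posteriors.csv", index=False)
    mono = np.all(np.diff(df["uptake_median"]) > 0)
    print(f"\nposterior medians monotone in the induction level: {mono}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
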