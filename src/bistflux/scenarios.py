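"""Registry of named substrate-shift scenarios used as synthetic fixtures.

Each scenario fixes the ground-truth growing fraction ``alpha_true`` and
growth rate ``mu_g_true`` for one experimental shift condition
(substrate, concentration, strain/induction), together with a sampling plan
for the dye-dilution generator.  The alpha values are reported experimental
subpopulation fractions for these conditions and the growth rates follow the acetate Monod fit
(mu_max = 0.34 h^-1, K_S = 0.5 g/l); they are generator settings here, not
claims about new data.

Sampling times are expressed in divisions of the growing pool and converted
to hours with each scenario's own growth rate, so every series spans the
same dynamic range of dye dilution.  Small-alpha scenarios sample further
divisions (the growing peak must clear the reductive-division shoulder of
the non-growing peak before its tiny weight is measurable).
"""

from __future__ import annotations

import numpy as np

from .synthetic import ScenarioConfig

#: Monod parameters of the acetate growth-rate fit, used as generator defaults.
MU_MAX_DEFAULT = 0.34  # h^-1
K_S_DEFAULT = 0.5  # g/l

#: division grid for ordinary scenarios (first timepoint is the stained t=0)
_DIVISIONS = np.array([0.0, 1.6, 2.4, 3.2, 4.0, 4.8])
#: deeper grid for scenarios with alpha below ~1%
_DIVISIONS_SMALL_ALPHA = np.array([0.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])


def default_mu_g(substrate_g_per_l: float) -> float:
    """Growing-subpopulation growth rate implied by the default Monod fit."""
    s = substrate_g_per_l
    return MU_MAX_DEFAULT * s / (K_S_DEFAULT + s)


def _times_for(mu_g: float, divisions: np.ndarray) -> np.ndarray:
    return divisions * np.log(2.0) / mu_g


_SPECS: dict[str, dict] = {
    # condition: wild type shifted to 2 g/l acetate
    "acetate-2gL": dict(alpha=0.5, substrate=2.0),
    # wild type, 0.75 g/l acetate
    "acetate-0.75gL-wt": dict(alpha=0.25, substrate=0.75),
    # fructose-1,6-bisphosphatase overexpression, 0.75 g/l acetate
    "acetate-0.75gL-fbpOE": dict(alpha=0.70, substrate=0.75),
    # wild type, 2 g/l malate (small subpopulation)
    "malate-2gL": dict(alpha=0.049, substrate=2.0, n_events=50000,
                       divisions=_DIVISIONS_SMALL_ALPHA),
    # wild type, 2 g/l fumarate, transporter uninduced (alpha ~ 0.1%)
    "fumarate-2gL": dict(alpha=0.001, substrate=2.0, n_events=50000,
                         divisions=_DIVISIONS_SMALL_ALPHA),
    # DctA transporter fully induced (100 uM IPTG) on 2 g/l fumarate
    "fumarate-100uM-IPTG": dict(alpha=0.53, substrate=2.0),
}


def scenario_names() -> list[str]:
    return list(_SPECS)


def get_scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build the named scenario's :class:`ScenarioConfig`.

    ``overrides`` may replace any config field (e.g. ``n_events``); the
    sampling times are regenerated if ``mu_g_true`` is overridden.
    """
    try:
        entry = _SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {sorted(_SPECS)}"
        ) from None
    mu_g = overrides.pop("mu_g_true", default_mu_g(entry["substrate"]))
    divisions = entry.get("divisions", _DIVISIONS)
    cfg = ScenarioConfig(
        name=name,
        alpha_true=overrides.pop("alpha_true", entry["alpha"]),
        mu_g_true=mu_g,
        times=overrides.pop("times", _times_for(mu_g, divisions)),
        n_events=overrides.pop("n_events", entry.get("n_events", 20000)),
        substrate=entry["substrate"],
        seed=seed,
        **overrides,
    )
    return cfg
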