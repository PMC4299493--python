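"""Seeded generators for the synthetic measurements the analysis consumes.

Each generator emulates one class of measurement from the substrate-shift
experiments: dye-dilution flow cytometry of a population splitting into a
growing and a non-growing subpopulation, total cell-count growth curves,
substrate-depletion time courses under Monod growth, promoter-GFP reporter
series, and lognormal cell-to-cell enzyme-abundance variation.

Conventions
-----------
* Fluorescence is handled on the log10 scale throughout (cytometers
  log-amplify; the membrane dye halves per division, i.e. the growing
  component's mean decreases by log10(2) per division).
* All randomness flows through :func:`numpy.random.default_rng` with an
  explicit integer seed, so every generator is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

LOG10_2 = np.log10(2.0)
#: slope of the growing-component mean per unit (mu * t): log10(2)/ln(2) = log10(e)
LOG10_E = np.log10(np.e)


class DyeExhaustedError(ValueError):
    """The growing component's mean would fall below the detection floor."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """One dye-dilution shift experiment's ground truth and sampling plan.

    Parameters
    ----------
    alpha_true : fraction of the population that resumes growth after the
        shift (the central statistic of the analysis, alpha).
    mu_g_true : steady-state exponential growth rate of the growing
        subpopulation (h^-1).
    times : sampling times after the shift (h), strictly increasing.
    n_events : flow-cytometry events recorded per timepoint.
    m0 : mean log10 fluorescence of the freshly stained population (a.u.).
    s_ng, s_g0 : component standard deviations on the log10 scale.
    reductive_fraction : fraction of non-growing cells undergoing one
        reductive division (a single extra halving) after the shift.
    k_div : per-division variance added to the growing component,
        (log10 units)^2; 0 keeps the width constant.
    floor : instrument detection floor (log10 a.u.); values are clipped here.
    substrate : substrate concentration after the shift (g/l), carried as
        metadata for downstream kinetic fits.
    """

    name: str
    alpha_true: float
    mu_g_true: float
    times: np.ndarray
    n_events: int = 20000
    m0: float = 4.0
    s_ng: float = 0.12
    s_g0: float = 0.12
    reductive_fraction: float = 0.3
    k_div: float = 0.0
    floor: float = 1.0
    substrate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not 0.0 <= self.alpha_true <= 1.0:
            raise ValueError(f"alpha_true must lie in [0,1], got {self.alpha_true}")
        if self.mu_g_true < 0:
            raise ValueError("mu_g_true must be nonnegative")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0) or self.times[0] < 0:
            raise ValueError("times must be 1-D, nonnegative and strictly increasing")
        if self.n_events < 100:
            raise ValueError("n_events must be >= 100")
        if self.s_ng <= 0 or self.s_g0 <= 0:
            raise ValueError("component SDs must be positive")
        if not 0.0 <= self.reductive_fraction <= 1.0:
            raise ValueError("reductive_fraction must lie in [0,1]")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))


@dataclass
class CytometryEventSet:
    """Single-cell log10-fluorescence values recorded at one timepoint."""

    time: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class GrowthCurve:
    """Total-population cell counts over time."""

    times: np.ndarray
    counts: np.ndarray
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")


@dataclass
class DepletionTrace:
    """Paired substrate-concentration and cell-count time series."""

    times: np.ndarray
    substrate: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not (len(self.times) == len(self.substrate) == len(self.counts)):
            raise ValueError("all channels must have equal length")
        if np.any(self.substrate < 0):
            raise ValueError("substrate must be nonnegative")
        # counts >= 0 (not > 0): the n0 = 0 degenerate experiment is legal
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class PromoterActivitySeries:
    """GFP-reporter time series with its biomass readout.

    ``mode='batch'`` carries an OD time course; ``mode='chemostat'`` carries a
    constant dilution rate instead.
    """

    times: np.ndarray
    gfp: np.ndarray
    mode: Literal["batch", "chemostat"]
    channel: Literal["regulated", "deregulated", "background"]
    od: np.ndarray | None = None
    dilution_rate: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.mode == "batch":
            if self.od is None:
                raise ValueError("batch mode requires an OD series")
            self.od = np.asarray(self.od, dtype=float)
            if np.any(self.od <= 0):
                raise ValueError("OD must be positive")
        elif self.mode == "chemostat":
            if self.dilution_rate is None or self.dilution_rate <= 0:
                raise ValueError("chemostat mode requires dilution_rate > 0")
            if self.od is None:
                raise ValueError("chemostat mode still requires a (steady) OD series")
            self.od = np.asarray(self.od, dtype=float)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def growing_weight(alpha: float, mu_g: float, t: np.ndarray | float) -> np.ndarray | float:
    """Fraction of events belonging to the growing subpopulation at time t.

    The growing pool multiplies as exp(mu_g t) while the non-growing pool is
    constant, so the event-level mixture weight is
    ``alpha e^{mu t} / (alpha e^{mu t} + 1 - alpha)``.
    """
    g = alpha * np.exp(mu_g * np.asarray(t, dtype=float))
    return g / (g + (1.0 - alpha))


def growing_mean(m0: float, mu_g: float, t: np.ndarray | float) -> np.ndarray | float:
    """Mean log10 fluorescence of the growing component at time t.

    One halving per division and mu_g/ln2 divisions per hour give a linear
    decay ``m0 - log10(e) * mu_g * t`` on the log10 axis.
    """
    return m0 - LOG10_E * mu_g * np.asarray(t, dtype=float)


def simulate_dye_dilution(config: ScenarioConfig) -> list[CytometryEventSet]:
    """Draw per-timepoint single-cell fluorescence values for a shift experiment.

    At each sampling time events come from a two-component mixture on the
    log10 scale: the non-growing component stays at ``m0`` (a
    ``reductive_fraction`` subset is shifted down by one halving at t > 0),
    while the growing component's mean falls by log10(2) per division and its
    mixture weight grows with exp(mu_g t).  Values below the detection floor
    are clipped to the floor.

    Raises
    ------
    DyeExhaustedError
        If any requested time would place the growing mean below the floor.
    """
    rng = np.random.default_rng(config.seed)
    a, mu = config.alpha_true, config.mu_g_true

    means_g = growing_mean(config.m0, mu, config.times)
    if a > 0 and np.any(means_g < config.floor):
        bad = config.times[means_g < config.floor]
        raise DyeExhaustedError(
            f"dye exhausted: growing mean below floor at t={bad.tolist()} h"
        )

    out: list[CytometryEventSet] = []
    for t, mg in zip(config.times, means_g):
        w = float(growing_weight(a, mu, t)) if a > 0 else 0.0
        is_growing = rng.random(config.n_events) < w
        n_g = int(is_growing.sum())
        n_ng = config.n_events - n_g

        divisions = mu * t / np.log(2.0)
        sd_g = float(np.sqrt(config.s_g0**2 + config.k_div * divisions))
        vals = np.empty(config.n_events)
        vals[is_growing] = rng.normal(mg, sd_g, size=n_g)

        ng = rng.normal(config.m0, config.s_ng, size=n_ng)
        if t > 0 and config.reductive_fraction > 0:
            reductive = rng.random(n_ng) < config.reductive_fraction
            ng[reductive] -= LOG10_2
        vals[~is_growing] = ng

        np.clip(vals, config.floor, None, out=vals)
        out.append(
            CytometryEventSet(
                time=float(t),
                values=vals,
                meta={"scenario": config.name, "seed": config.seed},
            )
        )
    return out


def simulate_growth_curve(
    alpha: float,
    mu_g: float,
    n0: float,
    times: Sequence[float],
    noise_cv: float = 0.05,
    seed: int = 0,
) -> GrowthCurve:
    """Total-population growth curve: a constant plus an exponential branch.

    Expected counts are ``N(t) = n0 [(1 - alpha) + alpha e^{mu_g t}]``,
    multiplied by lognormal noise with coefficient of variation ``noise_cv``
    (unit mean).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0,1]")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    times = np.asarray(times, dtype=float)
    expected = n0 * ((1.0 - alpha) + alpha * np.exp(mu_g * times))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=times.shape)
        counts = expected * noise
    else:
        counts = expected
    return GrowthCurve(times=times, counts=counts, noise_cv=noise_cv)


#: molar mass of fumaric acid, g/mol, for nmol/cell/h -> g/l/h conversion
FUMARATE_MW = 116.07


def depletion_rhs(
    t: float,
    y: np.ndarray,
    q_max: float,
    K_u: float,
    mu_max: float,
    K_S: float,
    mw_g_per_mol: float = FUMARATE_MW,
) -> list[float]:
    """Coupled substrate depletion / Monod growth vector field.

    State is ``(N, S)`` with N in cells/ml and S in g/l; per-cell uptake
    ``q(S) = q_max S/(K_u + S)`` is in nmol cell^-1 h^-1, converted to
    g l^-1 h^-1 via ``mw * 1e-6`` (nmol/ml -> mol/l is 1e-6).
    """
    N, S = y
    S = max(S, 0.0)
    dN = mu_max * S / (K_S + S) * N
    dS = -q_max * S / (K_u + S) * N * mw_g_per_mol * 1e-6
    return [dN, dS]


def integrate_depletion(
    q_max: float,
    K_u: float,
    mu_max: float,
    K_S: float,
    n0: float,
    S0: float,
    times: np.ndarray,
    mw_g_per_mol: float = FUMARATE_MW,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (counts, substrate) trajectories at the requested times."""
    times = np.asarray(times, dtype=float)
    if n0 == 0:
        return np.zeros_like(times), np.full_like(times, S0)
    sol = solve_ivp(
        depletion_rhs,
        (times[0], times[-1]),
        [n0, S0],
        t_eval=times,
        args=(q_max, K_u, mu_max, K_S, mw_g_per_mol),
        method="LSODA",
        rtol=rtol,
        atol=[n0 * 1e-10, 1e-12],
    )
    if not sol.success:
        raise RuntimeError(
            "depletion integration failed "
            f"(q_max={q_max}, K_u={K_u}, mu_max={mu_max}, K_S={K_S}, "
            f"n0={n0}, S0={S0}): {sol.message}"
        )
    counts = sol.y[0]
    substrate = np.clip(sol.y[1], 0.0, None)
    return counts, substrate


def simulate_depletion(
    q_max: float,
    K_u: float,
    mu_max: float,
    K_S: float,
    n0: float,
    S0: float,
    times: Sequence[float],
    noise_cv: float = 0.05,
    seed: int = 0,
    mw_g_per_mol: float = FUMARATE_MW,
) -> DepletionTrace:
    """Substrate-depletion + cell-count trace with multiplicative noise.

    Integrates dN/dt = mu_max S/(K_S+S) N and dS/dt = -q_max S/(K_u+S) N
    (after unit conversion) and applies independent lognormal noise with CV
    ``noise_cv`` to both channels; substrate is clipped at zero.
    """
    for name, v in [("q_max", q_max), ("K_u", K_u), ("mu_max", mu_max), ("K_S", K_S)]:
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    times = np.asarray(times, dtype=float)
    counts, substrate = integrate_depletion(
        q_max, K_u, mu_max, K_S, n0, S0, times, mw_g_per_mol
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        counts = counts * rng.lognormal(-0.5 * sigma**2, sigma, size=times.shape)
        substrate = substrate * rng.lognormal(-0.5 * sigma**2, sigma, size=times.shape)
    return DepletionTrace(times=times, substrate=substrate, counts=counts)


def simulate_promoter_activity(
    mode: Literal["batch", "chemostat"],
    true_activity: float,
    deregulated_pa: float = 1000.0,
    mu: float = 0.3,
    od0: float = 0.05,
    background_gfp: float = 50.0,
    dilution_rate: float = 0.3,
    od_chemostat: float = 0.5,
    times: Sequence[float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[PromoterActivitySeries, PromoterActivitySeries, PromoterActivitySeries]:
    """Regulated / deregulated / promoterless-background reporter channels.

    The regulated promoter's activity is ``(1 - true_activity)`` times the
    deregulated one, so the downstream repressor-occupancy estimator
    (1 - regulated/deregulated) returns ``true_activity`` exactly on
    noise-free output.

    In batch mode GFP accumulates as the integral of activity x OD on an
    exponential OD curve; in chemostat mode GFP sits at its dilution balance
    ``activity * OD / D`` on a flat OD.
    """
    if not 0.0 <= true_activity <= 1.0:
        raise ValueError("true_activity must lie in [0,1]")
    if times is None:
        times = np.linspace(0.0, 6.0, 25)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)

    pa = {
        "deregulated": deregulated_pa,
        "regulated": (1.0 - true_activity) * deregulated_pa,
        "background": 0.0,
    }
    out = []
    for channel in ("regulated", "deregulated", "background"):
        a = pa[channel]
        if mode == "batch":
            od = od0 * np.exp(mu * times)
            gfp = background_gfp + a * od0 * (np.exp(mu * times) - 1.0) / mu
            series = PromoterActivitySeries(
                times=times, gfp=gfp, od=od, mode="batch", channel=channel
            )
        else:
            od = np.full_like(times, od_chemostat)
            gfp = np.full_like(
                times, background_gfp + a * od_chemostat / dilution_rate
            )
            series = PromoterActivitySeries(
                times=times, gfp=gfp, od=od, mode="chemostat",
                channel=channel, dilution_rate=dilution_rate,
            )
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            series.gfp = series.gfp * rng.lognormal(
                -0.5 * sigma**2, sigma, size=times.shape
            )
        out.append(series)
    return tuple(out)  # type: ignore[return-value]


def sample_initial_enzyme(
    n_cells: int, mean_E: float, cv: float, seed: int = 0
) -> np.ndarray:
    """Lognormal single-cell enzyme abundances.

    Parameterized by the arithmetic mean and coefficient of variation, the
    moments in which cell-to-cell expression noise is usually reported.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if mean_E <= 0 or cv <= 0:
        raise ValueError("mean_E and cv must be positive")
    sigma2 = np.log1p(cv**2)
    mu_log = np.log(mean_E) - 0.5 * sigma2
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu_log, np.sqrt(sigma2), size=n_cells)
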