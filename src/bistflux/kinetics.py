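"""Growth and uptake kinetics: Monod fits, depletion MCMC, Cra activity.

Three estimation problems around the subpopulation measurements:

* Monod kinetics ``mu(S) = mu_max S/(K_S + S)`` fit to growth rates of the
  growing subpopulation at several substrate concentrations.
* A Bayesian fit of the coupled substrate-depletion / Monod-growth model to
  paired cell-count and substrate time series, yielding the steady-state
  per-cell uptake rate ``q(S) = q_max S/(K_u + S)`` with credible intervals.
  Sampling uses emcee on log-parameters with a Gaussian likelihood on log
  counts and log substrate; the walkers double as chains for split-Rhat.
* The transcription-factor occupancy statistic ("Cra activity")
  ``1 - PA_regulated/PA_deregulated`` computed from promoter-activity pairs,
  where promoter activity is dGFP/dt/OD in batch or D*GFP/OD in chemostat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import DepletionTrace, PromoterActivitySeries, integrate_depletion


@dataclass
class MonodParams:
    """Hyperbolic growth kinetics mu(S) = mu_max S / (K_S + S)."""

    mu_max: float  # h^-1
    K_S: float  # g/l
    residual_sd: float = 0.0  # h^-1

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.K_S <= 0:
            raise ValueError("mu_max and K_S must be positive")


def monod_mu(S: float | np.ndarray, params: MonodParams) -> float | np.ndarray:
    """Growth rate at substrate concentration S (g/l)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be nonnegative")
    out = params.mu_max * S / (params.K_S + S)
    return float(out) if out.ndim == 0 else out


def fit_monod(points: list[tuple[float, float]] | np.ndarray) -> MonodParams:
    """Nonlinear least-squares Monod fit to (S, mu) pairs.

    Multistarts around (max mu, median S) guard against the flat-likelihood
    valley at large K_S; needs >= 3 distinct concentrations spanning both
    sides of K_S for identifiability.
    """
    pts = np.asarray(points, dtype=float)
    S, mu = pts[:, 0], pts[:, 1]
    if len(np.unique(S)) < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    if np.ptp(mu) < 1e-12:
        raise ValueError("non-identifiable: all growth rates equal")

    mu0 = float(mu.max())
    K0 = float(np.median(S))
    best = None
    for mu_start, K_start in [(mu0, K0), (mu0, K0 / 10), (mu0, K0 * 10),
                              (1.5 * mu0, K0)]:
        try:
            popt, _ = optimize.curve_fit(
                lambda s, m, k: m * s / (k + s), S, mu,
                p0=[mu_start, K_start],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        pred = popt[0] * S / (popt[1] + S)
        sse = float(np.sum((mu - pred) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("Monod fit failed from all starts")
    sse, (mu_max, K_S) = best
    dof = max(len(S) - 2, 1)
    return MonodParams(mu_max=float(mu_max), K_S=float(K_S),
                       residual_sd=float(np.sqrt(sse / dof)))


# ---------------------------------------------------------------------------
# depletion MCMC
# ---------------------------------------------------------------------------

_PARAM_NAMES = ["q_max", "K_u", "mu_max", "K_S", "n0", "sigma_N", "sigma_S"]


@dataclass
class UptakePosterior:
    """Posterior draws of the depletion-growth model parameters."""

    samples: pd.DataFrame  # columns: q_max, K_u, mu_max, K_S, n0 (+ noise scales)
    acceptance_rate: float
    rhat: dict[str, float]
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.acceptance_rate < 1.0:
            raise ValueError("acceptance_rate must lie in (0,1)")


def _default_priors(trace: DepletionTrace) -> dict[str, tuple[float, float]]:
    """Log-uniform prior bounds spanning 4 decades around moment estimates."""
    t, N, S = trace.times, trace.counts, trace.substrate
    n0_est = float(N[0])
    # early log-slope of counts ~ mu at high S
    k = max(len(t) // 2, 2)
    mu_est = max(float(np.polyfit(t[:k], np.log(N[:k]), 1)[0]), 1e-3)
    # whole-trace mass balance: consumed substrate over integrated cell-hours
    # (robust to noise on individual early samples)
    consumed = max(float(S.max() - S.min()), 0.05 * float(S.max()))
    cell_hours = float(np.trapezoid(N, t))
    q_est = max(consumed / (cell_hours * 116.07e-6), 1e-12)
    K_est = max(float(S[0]) / 4.0, 1e-6)
    around = lambda c: (c / 100.0, c * 100.0)
    return {
        "q_max": around(q_est),
        "K_u": around(K_est),
        "mu_max": around(mu_est),
        "K_S": around(K_est),
        "n0": (n0_est / 10.0, n0_est * 10.0),
        "sigma_N": (1e-3, 1.0),
        "sigma_S": (1e-3, 1.0),
    }


def fit_depletion_mcmc(
    trace: DepletionTrace,
    priors: dict[str, tuple[float, float]] | None = None,
    chain_config: dict | None = None,
) -> UptakePosterior:
    """Bayesian fit of the fumarate-depletion + Monod-growth model.

    Parameters are sampled on the log scale with log-uniform priors; the
    likelihood is Gaussian on log cell counts and log substrate with the
    noise scales co-estimated.  Returns thinned post-burn-in draws, the mean
    acceptance fraction and per-parameter split-Rhat (walkers as chains).
    A warning note is attached when Rhat exceeds 1.1; if acceptance falls
    outside (0.1, 0.6) the sampler is re-run once with a retuned stretch
    move.
    """
    if len(trace.times) < 6:
        raise ValueError("need >= 6 timepoints")
    cfg = {"n_walkers": 16, "n_steps": 2000, "burn_frac": 0.5, "thin": 10,
           "seed": 0, "stretch_a": 2.0}
    cfg.update(chain_config or {})
    priors = priors or _default_priors(trace)
    lo = np.log([priors[p][0] for p in _PARAM_NAMES])
    hi = np.log([priors[p][1] for p in _PARAM_NAMES])

    t = trace.times
    S0 = float(trace.substrate[0])
    logN_obs = np.log(trace.counts)
    s_floor = max(trace.substrate.max() * 1e-4, 1e-6)
    logS_obs = np.log(np.maximum(trace.substrate, s_floor))

    def log_prob(theta: np.ndarray) -> float:
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        q_max, K_u, mu_max, K_S, n0, sig_N, sig_S = np.exp(theta)
        try:
            N, S = integrate_depletion(q_max, K_u, mu_max, K_S, n0, S0, t,
                                       rtol=1e-6)
        except RuntimeError:
            return -np.inf
        if np.any(~np.isfinite(N)) or np.any(N <= 0):
            return -np.inf
        rN = (np.log(N) - logN_obs) / sig_N
        rS = (np.log(np.maximum(S, s_floor)) - logS_obs) / sig_S
        ll = -0.5 * float(np.sum(rN**2) + np.sum(rS**2))
        ll -= len(t) * (np.log(sig_N) + np.log(sig_S))
        return ll

    ndim = len(_PARAM_NAMES)
    rng = np.random.default_rng(cfg["seed"])
    center = 0.5 * (lo + hi)
    # crude posterior-mode search to seed the walkers (keeps burn-in short)
    res = optimize.minimize(
        lambda th: -log_prob(np.clip(th, lo + 1e-9, hi - 1e-9)),
        center, method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-4},
    )
    start = np.clip(res.x, lo + 1e-6, hi - 1e-6)
    p0 = start + 0.02 * (hi - lo) * rng.standard_normal((cfg["n_walkers"], ndim))
    p0 = np.clip(p0, lo + 1e-6, hi - 1e-6)

    def run(a: float) -> emcee.EnsembleSampler:
        sampler = emcee.EnsembleSampler(
            cfg["n_walkers"], ndim, log_prob,
            moves=emcee.moves.StretchMove(a=a),
        )
        sampler.random_state = np.random.RandomState(cfg["seed"]).get_state()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler.run_mcmc(p0, cfg["n_steps"], progress=False)
        return sampler

    notes: list[str] = []
    sampler = run(cfg["stretch_a"])
    acc = float(np.mean(sampler.acceptance_fraction))
    if not 0.1 < acc < 0.6:
        new_a = 1.3 if acc <= 0.1 else 4.0
        notes.append(f"acceptance {acc:.3f} outside (0.1,0.6); retuned stretch a={new_a}")
        sampler = run(new_a)
        acc = float(np.mean(sampler.acceptance_fraction))

    burn = int(cfg["burn_frac"] * cfg["n_steps"])
    chain = sampler.get_chain(discard=burn, thin=cfg["thin"])  # (draws, walkers, dim)
    rhat: dict[str, float] = {}
    for j, name in enumerate(_PARAM_NAMES):
        ds = az.convert_to_dataset(chain[:, :, j].T)  # (chain=walker, draw)
        rhat[name] = float(az.rhat(ds)["x"].values)
        if rhat[name] > 1.1:
            notes.append(f"rhat({name})={rhat[name]:.3f} > 1.1: chains may not have mixed")

    flat = np.exp(chain.reshape(-1, ndim))
    samples = pd.DataFrame(flat, columns=_PARAM_NAMES)
    acc = float(np.clip(acc, 1e-6, 1 - 1e-6))
    return UptakePosterior(samples=samples, acceptance_rate=acc, rhat=rhat,
                           notes=notes)


@dataclass
class UptakeEstimate:
    median: float
    ci_low: float
    ci_high: float


def steady_state_uptake(posterior: UptakePosterior, S: float) -> UptakeEstimate:
    """Per-cell uptake rate q(S) = q_max S/(K_u+S), median and 95% interval."""
    if len(posterior.samples) == 0:
        raise ValueError("empty posterior")
    q = posterior.samples["q_max"].to_numpy()
    K = posterior.samples["K_u"].to_numpy()
    draws = q * S / (K + S)
    lo, med, hi = np.percentile(draws, [2.5, 50, 97.5])
    return UptakeEstimate(median=float(med), ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# promoter activity and the Cra statistic
# ---------------------------------------------------------------------------

def _exponential_window(times: np.ndarray, od: np.ndarray, r2_min: float = 0.99
                        ) -> slice:
    """Largest contiguous window where log OD is linear (R^2 > r2_min)."""
    logod = np.log(od)
    n = len(times)
    best = slice(0, n)
    for length in range(n, 2, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            t, y = times[sl], logod[sl]
            coef = np.polyfit(t, y, 1)
            pred = np.polyval(coef, t)
            ss_res = np.sum((y - pred) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            if ss_tot <= 0 or 1 - ss_res / ss_tot > r2_min:
                return sl
    return best


def promoter_activity(
    series: PromoterActivitySeries,
    background: PromoterActivitySeries,
    window: int = 5,
) -> float:
    """Promoter activity from a GFP reporter time series.

    Batch mode: background-corrected GFP is differentiated by a sliding
    local linear regression and divided by OD, then averaged over the
    detected exponential-growth window.  Chemostat mode: D*(GFP-bg)/OD at
    steady state (mean over the last half of the series).
    """
    if series.mode != background.mode:
        raise ValueError("series and background must share a mode")
    if window < 3:
        raise ValueError("regression window must span >= 3 points")
    t = series.times
    gfp = series.gfp - np.interp(t, background.times, background.gfp)

    if series.mode == "chemostat":
        half = len(t) // 2
        act = series.dilution_rate * gfp[half:] / series.od[half:]
        return float(np.mean(act))

    if len(t) < window:
        raise ValueError("series shorter than the regression window")
    half_w = window // 2
    centers, rates = [], []
    for i in range(half_w, len(t) - half_w):
        sl = slice(i - half_w, i + half_w + 1)
        slope = np.polyfit(t[sl], gfp[sl], 1)[0]
        centers.append(i)
        rates.append(slope / series.od[i])
    centers = np.array(centers)
    rates = np.array(rates)
    expo = _exponential_window(t, series.od)
    mask = (centers >= expo.start) & (centers < expo.stop)
    if not np.any(mask):
        mask = np.ones_like(centers, dtype=bool)
    return float(np.mean(rates[mask]))


@dataclass
class CraActivityEstimate:
    """Fraction of time the repressor-bound promoter is occupied by Cra."""

    activity: float
    pa_regulated: float
    pa_deregulated: float
    se: float = 0.0
    out_of_range: bool = False


def cra_activity(
    regulated_pa: float,
    deregulated_pa: float,
    regulated_se: float = 0.0,
    deregulated_se: float = 0.0,
) -> CraActivityEstimate:
    """Cra activity = 1 - PA_regulated / PA_deregulated.

    The regulated promoter is repressed while Cra occupies it, so its
    activity relative to the Cra-blind (deregulated) promoter measures the
    fraction of unoccupied time; one minus that ratio is the occupancy.
    Values outside [0,1] are flagged, never clipped.
    """
    if deregulated_pa <= 0:
        raise ValueError("deregulated promoter activity must be positive")
    ratio = regulated_pa / deregulated_pa
    activity = 1.0 - ratio
    se = float(np.sqrt(
        (regulated_se / deregulated_pa) ** 2
        + (regulated_pa * deregulated_se / deregulated_pa**2) ** 2
    ))
    return CraActivityEstimate(
        activity=float(activity),
        pa_regulated=float(regulated_pa),
        pa_deregulated=float(deregulated_pa),
        se=se,
        out_of_range=not (0.0 <= activity <= 1.0),
    )
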