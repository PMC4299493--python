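"""Recovering the growing fraction and its growth rate from dye-dilution data.

The measurement idea: a membrane dye halves per division, so on the log10
fluorescence axis the growing subpopulation's peak moves down linearly in
time while the non-growing peak stays put, and the growing peak's mixture
weight rises as the growing pool multiplies.  The estimator is two-stage:

1. each timepoint's distribution is fit with a two-component Gaussian
   mixture ("bi-Gaussian") by expectation-maximization;
2. the per-timepoint component weights and growing-component means are fit
   jointly with the exponential-growth model

       weight_g(t) = alpha e^{mu t} / (alpha e^{mu t} + 1 - alpha)
       mean_g(t)   = m0 - log10(e) * mu * t

   sharing a single (alpha, mu_g), by weighted least squares on a logit/log
   parameter scale.

Timepoints where the two components are not resolvable (including t = 0,
where the peaks coincide) and early timepoints where the non-growing peak
has shifted by more than half a halving (reductive division) are excluded
from stage 2.

A total-population growth curve offers an independent, lower-resolution
route to alpha: N(t) = n0 [(1-alpha) + alpha e^{mu t}], fit on log counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .synthetic import LOG10_2, LOG10_E, CytometryEventSet, GrowthCurve, growing_mean, growing_weight


class EMConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget."""


@dataclass
class BiGaussianComponents:
    """One timepoint's fitted two-component mixture.

    The component with the larger mean is labelled non-growing (it retains
    the dye); ``weight_g`` is the growing component's mixture weight.
    """

    time: float
    mean_g: float
    sd_g: float
    mean_ng: float
    sd_ng: float
    weight_g: float
    loglik: float
    n: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def separation(self) -> float:
        """Mean separation in pooled-SD units (resolvability measure)."""
        pooled = np.sqrt(0.5 * (self.sd_g**2 + self.sd_ng**2))
        return abs(self.mean_ng - self.mean_g) / pooled


@dataclass
class SubpopulationFit:
    """Joint estimate of the growing fraction and its growth rate."""

    alpha: float
    mu_g: float
    alpha_se: float
    mu_g_se: float
    m0: float
    per_timepoint: list[BiGaussianComponents]
    excluded_times: list[float]
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stage 1: per-timepoint mixture EM
# ---------------------------------------------------------------------------

def _em_once(
    x: np.ndarray,
    m1: float,
    m2: float,
    s1: float,
    s2: float,
    w1: float,
    tol: float,
    max_iter: int,
    sd_min: float,
) -> tuple[float, float, float, float, float, float, int, list[str]]:
    """Run EM from one start; returns params, loglik, iterations, flags."""
    n = x.size
    flags: list[str] = []
    ll_old = -np.inf
    for it in range(max_iter):
        p1 = w1 * norm.pdf(x, m1, s1)
        p2 = (1.0 - w1) * norm.pdf(x, m2, s2)
        tot = p1 + p2
        tot = np.where(tot <= 0, np.finfo(float).tiny, tot)
        r1 = p1 / tot
        ll = float(np.sum(np.log(tot)))

        n1 = r1.sum()
        n2 = n - n1
        if n1 < 1e-8 or n2 < 1e-8:
            flags.append("component_vanished")
            break
        m1 = float(np.dot(r1, x) / n1)
        m2 = float(np.dot(1.0 - r1, x) / n2)
        s1 = float(np.sqrt(np.dot(r1, (x - m1) ** 2) / n1))
        s2 = float(np.sqrt(np.dot(1.0 - r1, (x - m2) ** 2) / n2))
        if s1 < sd_min or s2 < sd_min:
            # degenerate shrink-to-a-point fit; refit with bounded SD
            s1, s2 = max(s1, sd_min), max(s2, sd_min)
            if "sd_clamped" not in flags:
                flags.append("sd_clamped")
        w1 = float(n1 / n)

        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            return m1, m2, s1, s2, w1, ll, it + 1, flags
        ll_old = ll
    else:
        raise EMConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last loglik={ll_old:.6g}, params m=({m1:.3g},{m2:.3g}) "
            f"s=({s1:.3g},{s2:.3g}) w={w1:.3g})"
        )
    return m1, m2, s1, s2, w1, ll, max_iter, flags


def fit_bigaussian(
    events: CytometryEventSet | np.ndarray,
    init: BiGaussianComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    sd_min: float = 0.01,
) -> BiGaussianComponents:
    """Maximum-likelihood two-component Gaussian mixture on log10 values.

    Initialization is from the 25th/75th percentiles unless ``init`` is
    given.  The component with the larger fitted mean is labelled
    non-growing.  Degenerate fits (an SD collapsing below ``sd_min``) are
    refit with the SD bound and flagged ``sd_clamped``.
    """
    if isinstance(events, CytometryEventSet):
        x = np.asarray(events.values, dtype=float)
        t = events.time
    else:
        x = np.asarray(events, dtype=float)
        t = np.nan
    if x.size < 100:
        raise ValueError(f"need >= 100 events, got {x.size}")

    if init is not None:
        starts = [(init.mean_g, init.mean_ng, init.sd_g, init.sd_ng, init.weight_g)]
    else:
        q25, q75 = np.percentile(x, [25, 75])
        s0 = max(float(np.std(x)) * 0.7, sd_min)
        starts = [(q25, q75, s0, s0, 0.5)]

    m1, m2, s1, s2, w1, ll, _, flags = _em_once(
        x, *starts[0], tol=tol, max_iter=max_iter, sd_min=sd_min
    )

    # label: larger mean = non-growing (dye retained)
    if m1 <= m2:
        mean_g, sd_g, w_g = m1, s1, w1
        mean_ng, sd_ng = m2, s2
    else:
        mean_g, sd_g, w_g = m2, s2, 1.0 - w1
        mean_ng, sd_ng = m1, s1
    return BiGaussianComponents(
        time=t, mean_g=mean_g, sd_g=sd_g, mean_ng=mean_ng, sd_ng=sd_ng,
        weight_g=w_g, loglik=ll, n=x.size, flags=flags,
    )


def mixture_loglik(
    x: np.ndarray, mean_g: float, sd_g: float, mean_ng: float, sd_ng: float,
    weight_g: float,
) -> float:
    """Log-likelihood of a two-component Gaussian mixture (oracle helper)."""
    p = weight_g * norm.pdf(x, mean_g, sd_g) + (1 - weight_g) * norm.pdf(
        x, mean_ng, sd_ng
    )
    return float(np.sum(np.log(np.maximum(p, np.finfo(float).tiny))))


# ---------------------------------------------------------------------------
# stage 2: joint exponential-growth fit
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


#: minimum component separation (pooled SDs) for a timepoint to enter stage 2
SEPARATION_MIN = 1.0
#: non-growing mean shift beyond which a timepoint is excluded (reductive rule)
NG_SHIFT_MAX = 0.5 * LOG10_2


def fit_subpopulations(
    series: Sequence[CytometryEventSet],
    exclude_auto: bool = True,
    global_likelihood: bool = False,
    separation_min: float = SEPARATION_MIN,
) -> SubpopulationFit:
    """Two-stage estimate of (alpha, mu_g) from a dye-dilution time series.

    Parameters
    ----------
    series : event sets at >= 3 timepoints spanning at least one expected
        division of the growing pool.
    exclude_auto : apply the reductive-division exclusion rule (non-growing
        mean shifted by more than half a halving from its t=0 reference).
    global_likelihood : refine the two-stage estimate by maximizing the
        joint raw-event likelihood across all timepoints (optional mode;
        the two-stage fit is the default estimator).
    """
    if len(series) < 3:
        raise ValueError("need >= 3 timepoints")
    series = sorted(series, key=lambda e: e.time)
    times = np.array([e.time for e in series])

    # reference for the undivided (non-growing) mean
    if times[0] == 0:
        m0_ref = float(np.mean(series[0].values))
    else:
        first = fit_bigaussian(series[0])
        m0_ref = first.mean_ng

    comps: list[BiGaussianComponents] = []
    prev_ng = m0_ref
    for ev in series:
        try:
            c = fit_bigaussian(ev)
        except EMConvergenceError:
            # EM crawls when the components coincide (e.g. t = 0); treat the
            # timepoint as a single unresolvable Gaussian and exclude it
            x = np.asarray(ev.values, dtype=float)
            m, sd = float(np.mean(x)), float(np.std(x))
            c = BiGaussianComponents(
                time=ev.time, mean_g=m, sd_g=sd, mean_ng=m, sd_ng=sd,
                weight_g=0.5, loglik=float(np.sum(norm.logpdf(x, m, sd))),
                n=x.size, flags=["em_nonconverged"],
            )
        # label guard: if the higher-mean component has wandered far from the
        # tracked non-growing mean while the lower one is close, swap labels
        if (abs(c.mean_ng - prev_ng) > 2 * NG_SHIFT_MAX
                and abs(c.mean_g - prev_ng) < NG_SHIFT_MAX):
            c = BiGaussianComponents(
                time=c.time, mean_g=c.mean_ng, sd_g=c.sd_ng,
                mean_ng=c.mean_g, sd_ng=c.sd_g, weight_g=1.0 - c.weight_g,
                loglik=c.loglik, n=c.n, flags=c.flags + ["labels_swapped"],
            )
        comps.append(c)
        if abs(c.mean_ng - m0_ref) <= NG_SHIFT_MAX:
            prev_ng = c.mean_ng

    excluded: list[float] = []
    included_idx: list[int] = []
    shoulder = m0_ref - LOG10_2  # reductively divided non-growing cells sit here
    for i, c in enumerate(comps):
        reductive_shift = exclude_auto and abs(c.mean_ng - m0_ref) > NG_SHIFT_MAX
        unresolved = c.separation < separation_min
        pooled = np.sqrt(0.5 * (c.sd_g**2 + c.sd_ng**2))
        # while the growing peak overlaps the reductive-division shoulder the
        # fitted growing component absorbs part of it, biasing its weight up
        shoulder_overlap = (
            exclude_auto and c.time > 0
            and abs(c.mean_g - shoulder) < 2.0 * pooled
        )
        if reductive_shift or unresolved or shoulder_overlap:
            excluded.append(float(c.time))
        else:
            included_idx.append(i)

    # boundary situations -------------------------------------------------
    pop_means = np.array([float(np.mean(e.values)) for e in series])
    if len(included_idx) < 2:
        if pop_means[-1] < m0_ref - 0.75 * LOG10_2:
            # whole population diluted its dye: everyone grew
            slope = np.polyfit(times, pop_means, 1)[0]
            mu_hat = max(-slope / LOG10_E, 0.0)
            return SubpopulationFit(
                alpha=1.0, mu_g=mu_hat, alpha_se=np.nan, mu_g_se=np.nan,
                m0=m0_ref, per_timepoint=comps, excluded_times=excluded,
                flags=["alpha_at_upper_boundary"],
            )
        # no resolvable growing component anywhere: alpha below detection
        return SubpopulationFit(
            alpha=0.0, mu_g=np.nan, alpha_se=np.nan, mu_g_se=np.nan,
            m0=m0_ref, per_timepoint=comps, excluded_times=excluded,
            flags=["upper_bound"],
        )

    t_in = times[included_idx]
    w_in = np.array([comps[i].weight_g for i in included_idx])
    mg_in = np.array([comps[i].mean_g for i in included_idx])
    sdg_in = np.array([comps[i].sd_g for i in included_idx])
    n_in = np.array([comps[i].n for i in included_idx], dtype=float)

    sig_w = np.sqrt(np.maximum(w_in * (1 - w_in), 1e-6) / n_in) + 1e-4
    sig_m = sdg_in / np.sqrt(np.maximum(n_in * w_in, 1.0)) + 1e-4

    # initialization: mu from the mean-dilution slope, alpha by inverting the
    # weight law at each timepoint
    slope = np.polyfit(t_in, mg_in, 1)[0]
    mu0 = float(np.clip(-slope / LOG10_E, 1e-4, 10.0))
    r = w_in / np.maximum(1 - w_in, 1e-12)
    alpha_candidates = r / (np.exp(mu0 * t_in) + r)
    alpha0 = float(np.clip(np.median(alpha_candidates), 1e-6, 1 - 1e-6))

    def residuals(theta: np.ndarray) -> np.ndarray:
        a = _expit(theta[0])
        mu = np.exp(theta[1])
        m0 = theta[2]
        w_model = growing_weight(a, mu, t_in)
        m_model = growing_mean(m0, mu, t_in)
        return np.concatenate(
            [(w_in - w_model) / sig_w, (mg_in - m_model) / sig_m]
        )

    theta0 = np.array([_logit(alpha0), np.log(mu0), m0_ref])
    sol = optimize.least_squares(residuals, theta0, method="lm")

    alpha_hat = float(_expit(sol.x[0]))
    mu_hat = float(np.exp(sol.x[1]))
    m0_hat = float(sol.x[2])

    flags: list[str] = []
    if alpha_hat > 1 - 1e-4:
        flags.append("alpha_at_upper_boundary")
    if alpha_hat < 1e-6:
        flags.append("alpha_at_lower_boundary")

    # standard errors from the stage-2 Gauss-Newton Hessian (delta method)
    dof = max(sol.fun.size - 3, 1)
    s2 = float(2 * sol.cost / dof)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se_logit = np.sqrt(max(cov[0, 0], 0.0))
        se_logmu = np.sqrt(max(cov[1, 1], 0.0))
        alpha_se = alpha_hat * (1 - alpha_hat) * se_logit
        mu_se = mu_hat * se_logmu
    except np.linalg.LinAlgError:
        alpha_se = mu_se = np.nan
        flags.append("singular_hessian")

    fit = SubpopulationFit(
        alpha=alpha_hat, mu_g=mu_hat, alpha_se=alpha_se, mu_g_se=mu_se,
        m0=m0_hat, per_timepoint=comps, excluded_times=excluded, flags=flags,
    )
    if global_likelihood:
        fit = _refine_global(series, fit)
    return fit


def _refine_global(
    series: Sequence[CytometryEventSet], start: SubpopulationFit
) -> SubpopulationFit:
    """Joint raw-event maximum likelihood across all timepoints.

    The non-growing component is modelled as its reductive-division doublet
    (a free fraction rho sits one halving below m0 at t > 0), so no
    timepoint needs to be excluded in this mode.
    """
    times = np.array([e.time for e in series])
    sd0 = np.median([c.sd_ng for c in start.per_timepoint])
    sdg0 = np.median([c.sd_g for c in start.per_timepoint])
    theta0 = np.array([
        _logit(float(np.clip(start.alpha, 1e-5, 1 - 1e-5))),
        np.log(max(start.mu_g, 1e-3)),
        start.m0,
        np.log(max(sd0, 1e-3)),
        np.log(max(sdg0, 1e-3)),
        _logit(0.3),
    ])

    def nll(theta: np.ndarray) -> float:
        a = float(_expit(theta[0]))
        mu = float(np.exp(theta[1]))
        m0 = theta[2]
        s_ng = float(np.exp(theta[3]))
        s_g = float(np.exp(theta[4]))
        rho = float(_expit(theta[5]))
        total = 0.0
        for t, ev in zip(times, series):
            x = ev.values
            w = float(growing_weight(a, mu, t))
            mg = float(growing_mean(m0, mu, t))
            rho_t = rho if t > 0 else 0.0
            p = (
                w * norm.pdf(x, mg, s_g)
                + (1 - w) * (1 - rho_t) * norm.pdf(x, m0, s_ng)
                + (1 - w) * rho_t * norm.pdf(x, m0 - LOG10_2, s_ng)
            )
            total += float(np.sum(np.log(np.maximum(p, np.finfo(float).tiny))))
        return -total

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-7})
    alpha_hat = float(_expit(res.x[0]))
    mu_hat = float(np.exp(res.x[1]))
    return SubpopulationFit(
        alpha=alpha_hat, mu_g=mu_hat, alpha_se=start.alpha_se,
        mu_g_se=start.mu_g_se, m0=float(res.x[2]),
        per_timepoint=start.per_timepoint, excluded_times=[],
        flags=start.flags + ["global_likelihood"],
    )


# ---------------------------------------------------------------------------
# growth-curve decomposition and lag time
# ---------------------------------------------------------------------------

class GrowthDecomposition(NamedTuple):
    alpha: float
    mu_g: float
    n0: float


def decompose_growth_curve(curve: GrowthCurve) -> GrowthDecomposition:
    """Split a total-count curve into constant and exponential branches.

    Fits ``N(t) = n0 [(1 - alpha) + alpha e^{mu t}]`` to log counts by
    nonlinear least squares (logit-alpha / log-mu parameterization).
    """
    t = curve.times
    y = np.log(curve.counts)
    if len(t) < 5:
        raise ValueError("need >= 5 points including late exponential phase")
    if curve.counts.max() / curve.counts[0] < 1.5:
        raise ValueError("no growth detected: curve never departs from flat")

    # initialization: late-phase slope gives mu, back-extrapolation gives alpha
    k = max(len(t) // 3, 2)
    mu0, b = np.polyfit(t[-k:], y[-k:], 1)
    mu0 = max(float(mu0), 1e-3)
    n0_0 = float(curve.counts[0])
    alpha0 = float(np.clip(np.exp(b) / n0_0, 1e-8, 1 - 1e-8))

    def model(theta: np.ndarray) -> np.ndarray:
        a = _expit(theta[0])
        mu = np.exp(theta[1])
        n0 = np.exp(theta[2])
        return np.log(n0 * ((1 - a) + a * np.exp(mu * t)))

    def resid(theta: np.ndarray) -> np.ndarray:
        return model(theta) - y

    theta0 = np.array([_logit(alpha0), np.log(mu0), np.log(n0_0)])
    sol = optimize.least_squares(resid, theta0, method="lm")
    alpha = float(_expit(sol.x[0]))
    return GrowthDecomposition(
        alpha=min(alpha, 1.0),
        mu_g=float(np.exp(sol.x[1])),
        n0=float(np.exp(sol.x[2])),
    )


def apparent_lag_time(alpha: float, mu_g: float) -> float:
    """Lag time implied by exclusive growth of an initial fraction alpha.

    The extrapolated exponential branch ``n0 alpha e^{mu t}`` crosses the
    inoculum level n0 at ``t = -ln(alpha)/mu``: the population-level 'lag'
    is not an adaptation delay but the time the small growing subpopulation
    needs to dominate the counts.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]; alpha=0 implies infinite lag")
    if mu_g <= 0:
        raise ValueError("mu_g must be positive")
    return -np.log(alpha) / mu_g
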