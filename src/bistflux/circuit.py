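"""The flux-sensing bistable circuit: ODEs, steady states, bifurcations.

The model collapses all reactions from gluconeogenic substrate uptake to
FBP formation into a single "super-enzyme" E.  The wiring is a positive
feedback loop built from two negative links:

* gluconeogenic flux J = k_E u E s/(K_s + s) produces FBP;
* fructose-1,6-bisphosphatase consumes FBP, with a cooperative
  flux-dependent activation (the PEP feed-forward collapsed into a Hill
  term in J), so high flux *lowers* FBP;
* FBP inhibits the transcriptional activator Cra, so low FBP *raises*
  production of E, which raises J.

Growth dilutes both E and FBP at rate mu = Y J.  State is (E, F); J is a
derived quantity.  The two-variable system supports two stable steady
fluxes (growing/non-growing phenotypes) separated by a saddle whose E value
acts as a watershed between the basins of attraction.

Steady states are found by reducing to a scalar problem: for fixed E the
FBP nullcline has a unique root F*(E) (the left side is monotone in F), and
the remaining scalar residual g(E) = dE/dt at (E, F*(E)) is scanned on a
dense log grid for sign changes, which are then polished and classified by
the eigenvalues of the analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace as _replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.integrate import solve_ivp


@dataclass
class CircuitParams:
    """Parameters of the flux-sensor circuit (arbitrary flux/abundance units).

    ``k_E`` catalytic scale (flux per E); ``K_s`` uptake half-saturation
    (g/l); ``u`` transporter capacity multiplier; ``V_f``/``K_F`` Fbp
    maximal rate and substrate constant; ``K_J``/``n`` flux-activation
    half-point and Hill coefficient; ``K_I``/``h`` Cra inhibition constant
    and Hill coefficient; ``beta0``/``beta1`` basal and Cra-activated E
    production; ``delta`` E degradation (h^-1); ``Y`` growth yield on flux
    (h^-1 per flux unit); ``f_fbp`` Fbp activity multiplier
    (overexpression > 1, inhibition < 1).
    """

    k_E: float = 1.0
    K_s: float = 5.2
    u: float = 1.0
    V_f: float = 5.94
    K_F: float = 0.3
    K_J: float = 0.367
    n: float = 4.0
    K_I: float = 0.0443
    h: float = 6.0
    beta0: float = 0.105
    beta1: float = 2.0
    delta: float = 0.0813
    Y: float = 0.35475
    f_fbp: float = 1.0
    dilute_F: bool = True  # growth dilution acting on FBP (switchable)

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name == "dilute_F":
                continue
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n < 1 or self.h < 1:
            raise ValueError("Hill coefficients n and h must be >= 1")

    def replace(self, **kw) -> "CircuitParams":
        return _replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "CircuitParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def reference(cls) -> "CircuitParams":
        """The calibrated reference parameter set shipped with the package."""
        with resources.files("bistflux.data").joinpath("params_ref.yaml").open() as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class CircuitState:
    E: float
    F: float

    def __post_init__(self) -> None:
        if self.E < 0 or self.F < 0:
            raise ValueError("E and F must be nonnegative")


@dataclass
class SteadyState:
    state: CircuitState
    J: float
    stable: bool
    eigenvalues: tuple[complex, complex]


@dataclass
class BifurcationDiagram:
    parameter_name: str
    grid: np.ndarray
    branches: list[list[SteadyState]]  # states per grid point, sorted by E
    fold_points: list[float]
    ambiguous_links: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p, states in zip(self.grid, self.branches):
            for b, st in enumerate(states):
                rows.append({
                    "parameter": p, "branch_id": b, "E": st.state.E,
                    "F": st.state.F, "J": st.J, "stable": st.stable,
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary rates
# ---------------------------------------------------------------------------

def flux(E: float, s: float, p: CircuitParams) -> float:
    """Gluconeogenic flux through the super-enzyme: J = k_E u E s/(K_s+s)."""
    return p.k_E * p.u * E * s / (p.K_s + s)


def fbp_rate(F: float, J: float, p: CircuitParams) -> float:
    """Fbp-catalyzed FBP consumption with cooperative flux activation."""
    act = J**p.n / (J**p.n + p.K_J**p.n) if J > 0 else 0.0
    return p.f_fbp * p.V_f * (F / (p.K_F + F)) * act


def cra_response(F: float, p: CircuitParams) -> float:
    """Cra activity as a decreasing Hill function of FBP."""
    return 1.0 / (1.0 + (F / p.K_I) ** p.h)


def growth_rate(J: float, p: CircuitParams) -> float:
    return p.Y * J


def rhs(state: Sequence[float], s: float, p: CircuitParams) -> np.ndarray:
    """Time derivatives (dE/dt, dF/dt) at state (E, F)."""
    E, F = state
    J = flux(E, s, p)
    mu = growth_rate(J, p)
    dF = J - fbp_rate(F, J, p) - (mu * F if p.dilute_F else 0.0)
    dE = p.beta0 + p.beta1 * cra_response(F, p) - (p.delta + mu) * E
    return np.array([dE, dF])


def jacobian(state: Sequence[float], s: float, p: CircuitParams) -> np.ndarray:
    """Analytic Jacobian of the (E, F) vector field."""
    E, F = state
    sig = p.k_E * p.u * s / (p.K_s + s)  # dJ/dE
    J = sig * E
    c = p.f_fbp * p.V_f
    g = F / (p.K_F + F)
    gp = p.K_F / (p.K_F + F) ** 2
    if J > 0:
        Jn, Kn = J**p.n, p.K_J**p.n
        hJ = Jn / (Jn + Kn)
        hp = p.n * Kn * J ** (p.n - 1) / (Jn + Kn) ** 2
    else:
        hJ = 0.0
        hp = 0.0  # n > 1: activation slope vanishes at J = 0
    dil = 1.0 if p.dilute_F else 0.0
    # dF/dt = J - c g(F) h(J) - Y J F
    dF_dE = sig * (1.0 - c * g * hp - dil * p.Y * F)
    dF_dF = -c * gp * hJ - dil * p.Y * J
    # dE/dt = beta0 + beta1 C(F) - (delta + Y J) E
    x = (F / p.K_I) ** p.h if F > 0 else 0.0
    Cp = 0.0
    if F > 0:
        Cp = -(p.h / F) * x / (1.0 + x) ** 2
    dE_dE = -(p.delta + p.Y * J) - p.Y * sig * E
    dE_dF = p.beta1 * Cp
    return np.array([[dE_dE, dE_dF], [dF_dE, dF_dF]])


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def fbp_nullcline(E: float, s: float, p: CircuitParams) -> float:
    """Unique F with dF/dt = 0 at fixed E (quasi-steady FBP level)."""
    J = flux(E, s, p)
    if J <= 0:
        return 0.0
    act = J**p.n / (J**p.n + p.K_J**p.n)
    A = p.f_fbp * p.V_f * act

    def h(F: float) -> float:
        dil = p.Y * J * F if p.dilute_F else 0.0
        return A * F / (p.K_F + F) + dil - J

    if not p.dilute_F:
        # without dilution a balance requires A > J; otherwise FBP diverges
        if A <= J:
            return np.inf
        return p.K_F * J / (A - J)
    F_hi = 1.0 / p.Y + p.K_F
    if h(F_hi) < 0:  # numerical safety margin
        F_hi *= 10.0
    return float(optimize.brentq(h, 0.0, F_hi, xtol=1e-14, rtol=1e-14))


def _scalar_residual(E: float, s: float, p: CircuitParams) -> float:
    """dE/dt evaluated on the FBP nullcline; zeros are the fixed points."""
    F = fbp_nullcline(E, s, p)
    J = flux(E, s, p)
    if not np.isfinite(F):
        return -np.inf
    return p.beta0 + p.beta1 * cra_response(F, p) - (p.delta + p.Y * J) * E


STABILITY_MARGIN = -1e-10


def _classify(E: float, s: float, p: CircuitParams) -> SteadyState:
    F = fbp_nullcline(E, s, p)
    J = flux(E, s, p)
    eig = np.linalg.eigvals(jacobian((E, F), s, p))
    stable = bool(np.all(eig.real < STABILITY_MARGIN))
    return SteadyState(
        state=CircuitState(E=max(E, 0.0), F=max(F, 0.0)), J=J, stable=stable,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
    )


def find_steady_states(
    s: float,
    p: CircuitParams,
    e_min: float = 1e-4,
    e_max: float = 1e3,
    n_grid: int = 2000,
) -> list[SteadyState]:
    """All fixed points at substrate s, sorted by E, with stability flags.

    Sign changes of the scalar residual on a log-spaced E grid are bracketed
    and polished with Brent's method; roots closer than 1e-6 relative are
    merged.  At s = 0 there is no flux and the unique balance point of E
    production/degradation (at F = 0) is returned.
    """
    if s < 0:
        raise ValueError("s must be nonnegative")
    if s == 0:
        E0 = (p.beta0 + p.beta1) / p.delta
        return [_classify(E0, s, p)]

    grid = np.geomspace(e_min, e_max, n_grid)
    vals = np.array([_scalar_residual(E, s, p) for E in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(optimize.brentq(
                _scalar_residual, grid[i], grid[i + 1], args=(s, p),
                xtol=1e-14, rtol=1e-14,
            )))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    # deduplicate
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-6 * max(abs(r), 1e-12):
            uniq.append(r)
    return [_classify(E, s, p) for E in uniq]


def watershed(s: float, p: CircuitParams) -> float | None:
    """E value of the saddle separating the two basins, or None if monostable."""
    states = find_steady_states(s, p)
    unstable = [st for st in states if not st.stable]
    stable = [st for st in states if st.stable]
    if len(stable) == 2 and len(unstable) == 1:
        return unstable[0].state.E
    return None


# ---------------------------------------------------------------------------
# bifurcation scan
# ---------------------------------------------------------------------------

_SWEEPABLE = {"substrate", "beta1", "f_fbp", "u"}


def _states_at(value: float, parameter_name: str, s: float, p: CircuitParams
               ) -> list[SteadyState]:
    if parameter_name == "substrate":
        return find_steady_states(value, p)
    return find_steady_states(s, p.replace(**{parameter_name: value}))


def bifurcation_scan(
    parameter_name: Literal["substrate", "beta1", "f_fbp", "u"],
    grid: Sequence[float],
    params: CircuitParams,
    s: float | None = None,
    fold_tol: float = 1e-6,
) -> BifurcationDiagram:
    """Steady-state branches along a parameter sweep, with fold points.

    Runs :func:`find_steady_states` at every grid value, links branches by
    nearest continuation in log E, and locates fold points (where the
    steady-state count changes) by bisection between grid points.
    """
    if parameter_name not in _SWEEPABLE:
        raise ValueError(f"cannot sweep {parameter_name!r}; one of {_SWEEPABLE}")
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 20 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted with >= 20 points")
    if parameter_name != "substrate" and s is None:
        raise ValueError("parameter sweeps other than substrate need s")

    branches = [_states_at(v, parameter_name, s, params) for v in grid]

    ambiguous: list[float] = []
    for v, prev, cur in zip(grid[1:], branches[:-1], branches[1:]):
        if len(prev) == len(cur) and len(cur) > 1:
            # nearest-continuation check: flag if two branches nearly collide
            Es = sorted(st.state.E for st in cur)
            gaps = np.diff(np.log(np.maximum(Es, 1e-300)))
            if np.any(gaps < 1e-3):
                ambiguous.append(float(v))

    fold_points: list[float] = []
    for i in range(len(grid) - 1):
        if len(branches[i]) != len(branches[i + 1]):
            a, b = grid[i], grid[i + 1]
            na = len(branches[i])
            while b - a > fold_tol * max(abs(a), abs(b), 1.0):
                mid = 0.5 * (a + b)
                if len(_states_at(mid, parameter_name, s, params)) == na:
                    a = mid
                else:
                    b = mid
            fold_points.append(0.5 * (a + b))

    return BifurcationDiagram(
        parameter_name=parameter_name, grid=grid, branches=branches,
        fold_points=fold_points, ambiguous_links=ambiguous,
    )


def fold_points_exact(
    parameter_name: str,
    approx: float,
    params: CircuitParams,
    s: float | None = None,
    E_guess: float | None = None,
) -> tuple[float, float]:
    """Fold location by solving g = 0, dg/dE = 0 simultaneously.

    Independent refinement used to cross-check the bisection-based fold
    locations: a fold is a parameter value where a pair of fixed points of
    the scalar reduced system merges, i.e. the residual and its E-derivative
    vanish together.  Returns (parameter value, E at the fold).
    """

    def g_and_dg(x: np.ndarray) -> np.ndarray:
        E, v = x
        if parameter_name == "substrate":
            p, sv = params, v
        else:
            p, sv = params.replace(**{parameter_name: v}), s
        dE = max(1e-7 * max(E, 1e-3), 1e-10)
        g0 = _scalar_residual(E, sv, p)
        g1 = _scalar_residual(E + dE, sv, p)
        return np.array([g0, (g1 - g0) / dE])

    if E_guess is None:
        E_guess = 1.0
    sol = optimize.fsolve(g_and_dg, np.array([E_guess, approx]), full_output=True)
    x, _, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"fold refinement failed: {msg}")
    return float(x[1]), float(x[0])


# ---------------------------------------------------------------------------
# perturbations and integration
# ---------------------------------------------------------------------------

def apply_perturbation(
    params: CircuitParams,
    kind: Literal["transporter", "cra_level", "fbp_oe", "dg6p"],
    magnitude: float,
) -> CircuitParams:
    """Experimental perturbations mapped onto circuit parameters.

    transporter: scales uptake capacity u (e.g. DctA induction);
    cra_level: scales Cra-activated E production beta1;
    fbp_oe: multiplies Fbp activity (overexpression, magnitude > 1);
    dg6p: multiplies Fbp activity (allosteric inhibition, magnitude < 1).
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if kind == "transporter":
        return params.replace(u=params.u * magnitude)
    if kind == "cra_level":
        return params.replace(beta1=params.beta1 * magnitude)
    if kind in ("fbp_oe", "dg6p"):
        return params.replace(f_fbp=params.f_fbp * magnitude)
    raise ValueError(f"unknown perturbation kind {kind!r}")


def integrate(
    state0: Sequence[float],
    s: float,
    p: CircuitParams,
    t_end: float = 200.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    dense: bool = False,
):
    """Integrate the circuit ODEs from a given initial state."""
    sol = solve_ivp(
        lambda t, y: rhs(y, s, p), (0.0, t_end), np.asarray(state0, float),
        method="LSODA", rtol=rtol, atol=atol, dense_output=dense,
    )
    if not sol.success:
        raise RuntimeError(f"circuit integration failed: {sol.message}")
    return sol
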