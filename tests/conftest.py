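import numpy as np
import pytest

from bistflux.synthetic import ScenarioConfig


def vec_rhs(E, F, s, p):
    """Vectorized, independently written circuit vector field (test oracle)."""
    J = p.k_E * p.u * E * s / (p.K_s + s)
    act = np.where(J > 0, J**p.n / (J**p.n + p.K_J**p.n), 0.0)
    consume = p.f_fbp * p.V_f * (F / (p.K_F + F)) * act
    mu = p.Y * J
    dF = J - consume - (mu * F if p.dilute_F else 0.0)
    C = 1.0 / (1.0 + (F / p.K_I) ** p.h)
    dE = p.beta0 + p.beta1 * C - (p.delta + mu) * E
    return dE, dF


def rk4_endpoints(E0, F0, s, p, t_end=300.0, dt=0.02, track_min=False):
    """Fixed-step RK4 integration of many trajectories at once (test oracle)."""
    E = np.array(E0, dtype=float, copy=True)
    F = np.array(F0, dtype=float, copy=True)
    n_steps = int(round(t_end / dt))
    min_E = E.copy()
    min_F = F.copy()
    for _ in range(n_steps):
        k1E, k1F = vec_rhs(E, F, s, p)
        k2E, k2F = vec_rhs(E + 0.5 * dt * k1E, F + 0.5 * dt * k1F, s, p)
        k3E, k3F = vec_rhs(E + 0.5 * dt * k2E, F + 0.5 * dt * k2F, s, p)
        k4E, k4F = vec_rhs(E + dt * k3E, F + dt * k3F, s, p)
        E = E + dt / 6.0 * (k1E + 2 * k2E + 2 * k3E + k4E)
        F = F + dt / 6.0 * (k1F + 2 * k2F + 2 * k3F + k4F)
        if track_min:
            np.minimum(min_E, E, out=min_E)
            np.minimum(min_F, F, out=min_F)
    if track_min:
        return E, F, min_E, min_F
    return E, F


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_config(alpha, mu=0.272, divisions=(0.0, 1.6, 2.4, 3.2, 4.0, 4.8),
                **kw) -> ScenarioConfig:
    """Small helper building a scenario over a division grid."""
    divisions = np.asarray(divisions, dtype=float)
    times = divisions * np.log(2.0) / mu if mu > 0 else divisions
    defaults = dict(name="test", alpha_true=alpha, mu_g_true=mu, times=times,
                    n_events=20000, seed=0)
    defaults.update(kw)
    return ScenarioConfig(**defaults)
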