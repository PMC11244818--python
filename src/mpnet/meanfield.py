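"""Mean-field theory of the simplified clustered network.

The simplified model has N_E excitatory neurons uniformly partitioned
into Q *non-overlapping* clusters.  Intra-cluster efficacies w+ are
i.i.d. with mean mu_plus and sd sigma_plus, supported on [0, w_max];
inter-cluster efficacies are a small constant w_minus.  Under the
diffusion approximation the input to each population is white noise
with infinitesimal mean mu_alpha and variance s_alpha built from the
first two moments of the weights, and the stationary rates solve

    nu_alpha = F_alpha(mu_alpha(nu), s_alpha(nu)),

where F is the EIF transfer function, evaluated by backward threshold
integration of the stationary Fokker-Planck equation (from V_peak down
to a reflecting lower bound, with reinjection of the exit flux at V_r).

Scanning (mu_plus, sigma_plus) with a one-active-cluster ansatz yields
the landscape whose lowest active/inactive contour is the instability
line that the plasticity rule self-tunes the trained network towards.
Moments above sigma_max(mu) = sqrt(w_max*mu - mu^2) are impossible for
any distribution on [0, w_max] and are masked as forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import NeuronParams

__all__ = [
    "MeanFieldConfig",
    "SolverSettings",
    "RateSolution",
    "sigma_max",
    "eif_transfer_rate",
    "eif_mc_rate",
    "population_inputs",
    "solve_self_consistent",
    "landscape",
]


def sigma_max(mu: float | np.ndarray, w_max: float = 4.0):
    """Largest sd of a distribution on [0, w_max] with mean mu.

    The bound sqrt(w_max*mu - mu^2) is saturated by the two-point
    distribution P(w_max) = mu/w_max, P(0) = 1 - mu/w_max.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or np.any(mu > w_max):
        raise ValueError("mu must lie in [0, w_max]")
    out = np.sqrt(np.maximum(w_max * mu - mu**2, 0.0))
    return out if out.ndim else float(out)


@dataclass
class MeanFieldConfig:
    """Simplified non-overlapping clustered network for mean-field."""

    N_E: int = 4000
    N_I: int = 1000
    Q: int = 50
    p_EE: float = 0.2
    p_EI: float = 0.5
    p_IE: float = 0.5
    p_II: float = 0.5
    mu_plus: float = 0.5      # mean intra-cluster E->E efficacy (mV)
    sigma_plus: float = 0.5   # sd of intra-cluster efficacies (mV)
    w_minus: float = 0.005    # inter-cluster E->E efficacy (mV)
    w_EI: float = -0.34
    w_IE: float = 0.54
    w_II: float = -0.46
    w_max: float = 4.0        # weight support bound (mV)
    h_ext_E: float = 1.50     # mV/ms
    h_ext_I: float = 2.19
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu_plus <= self.w_max:
            raise ValueError("mu_plus must lie in [0, w_max]")
        if self.sigma_plus < 0:
            raise ValueError("sigma_plus must be >= 0")
        if self.sigma_plus > sigma_max(self.mu_plus, self.w_max) + 1e-12:
            raise ValueError(
                "sigma_plus exceeds sigma_max(mu_plus): no distribution on "
                "[0, w_max] has these moments"
            )
        if self.Q < 1 or self.N_E % self.Q:
            raise ValueError("N_E must split uniformly into Q clusters")


@dataclass
class SolverSettings:
    """Numerics of the transfer function and the fixed-point iteration."""

    V_lb: float = -30.0    # lower integration bound (mV)
    dV: float = 0.01       # voltage grid step (mV)
    damping: float = 0.1   # fixed-point relaxation factor
    tol: float = 1e-6      # rate convergence tolerance (spikes/s)
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.dV <= 0 or not (0 < self.damping <= 1) or self.tol <= 0:
            raise ValueError("invalid solver settings")


@dataclass
class RateSolution:
    """Self-consistent rates [nu_E^(1..Q), nu_I] with input moments."""

    nu: np.ndarray          # spikes/s, length Q+1
    mu: np.ndarray          # mV/ms, length Q+1
    s: np.ndarray           # mV^2/ms, length Q+1
    converged: bool
    residual: float         # max |nu - F(mu, s)| in spikes/s
    n_iter: int
    ansatz: str


@njit(cache=False, fastmath=True)
def _fp_rate(mu, s, V_L, V_T, Delta_T, V_peak, V_r, tau_m, V_lb, dV):
    """Stationary EIF rate (spikes/ms) by backward threshold integration.

    Integrates the scaled density p = P/r downward from the absorbing
    boundary at V_peak with unit flux above the reinjection point V_r,
    using a per-cell exponential (integrating-factor) step; the rate is
    the inverse of the total probability mass.
    """
    n = int(round((V_peak - V_lb) / dV))
    h = (V_peak - V_lb) / n
    k_r = int(round((V_r - V_lb) / h))
    p = 0.0
    mass = 0.0
    for k in range(n, 0, -1):
        Vk = V_lb + k * h
        F = (-(Vk - V_L) + Delta_T * np.exp((Vk - V_T) / Delta_T)) / tau_m + mu
        G = 2.0 * F / s
        H = 2.0 / s if k > k_r else 0.0
        x = G * h
        if x > 500.0:
            # strong upward drift: density relaxes to the drift solution
            p_new = H / G
        elif x < -500.0:
            # strong downward drift at vanishing noise: the mass below
            # diverges and the escape rate is numerically zero
            return 0.0
        elif -1e-12 < x < 1e-12:
            p_new = p + H * h
        else:
            em = np.exp(-x)
            p_new = p * em + (H / G) * (1.0 - em)
        mass += 0.5 * (p + p_new) * h
        if mass > 1e250 or p_new > 1e250:
            return 0.0
        p = p_new
    if mass <= 0.0:
        return 0.0
    return 1.0 / mass


@njit(cache=False)
def _mc_rate(mu, s, V_L, V_T, Delta_T, V_peak, V_r, tau_m,
             dt, t_max_ms, target_spikes, seed):
    """Euler-Maruyama estimate of the stationary EIF rate (spikes/ms)."""
    np.random.seed(seed)
    V = V_r
    sq = np.sqrt(s * dt)
    n_max = int(t_max_ms / dt)
    count = 0
    step = 0
    for step in range(n_max):
        Vc = V if V < V_peak else V_peak
        F = (-(V - V_L) + Delta_T * np.exp((Vc - V_T) / Delta_T)) / tau_m + mu
        V += dt * F + sq * np.random.normal()
        if V >= V_peak:
            V = V_r
            count += 1
            if count >= target_spikes and (step + 1) * dt >= 1000.0:
                break
    return count / ((step + 1) * dt)


def eif_transfer_rate(mu: float, s: float, params: NeuronParams,
                      settings: SolverSettings | None = None,
                      tau_m: float | None = None) -> float:
    """EIF transfer function F(mu, s) in spikes/s.

    mu is the infinitesimal mean (mV/ms) and s the infinitesimal
    variance (mV^2/ms) of the white-noise input.  ``tau_m`` defaults to
    the excitatory membrane time constant.
    """
    if s <= 0:
        raise ValueError("infinitesimal variance s must be > 0")
    if settings is None:
        settings = SolverSettings()
    if tau_m is None:
        tau_m = params.tau_m_E
    r = _fp_rate(mu, s, params.V_L, params.V_T, params.Delta_T,
                 params.V_peak, params.V_r, tau_m,
                 settings.V_lb, settings.dV)
    return 1000.0 * r


def eif_mc_rate(mu: float, s: float, params: NeuronParams,
                tau_m: float | None = None, dt: float = 0.01,
                t_max_ms: float = 2_000_000.0, target_spikes: int = 3000,
                seed: int = 12345) -> float:
    """Monte-Carlo EIF rate (spikes/s) from a long Euler-Maruyama run.

    Simulates until ``target_spikes`` spikes (at least 1 s) or
    ``t_max_ms`` of simulated time, whichever comes first.
    """
    if s <= 0:
        raise ValueError("infinitesimal variance s must be > 0")
    if tau_m is None:
        tau_m = params.tau_m_E
    r = _mc_rate(mu, s, params.V_L, params.V_T, params.Delta_T,
                 params.V_peak, params.V_r, tau_m,
                 dt, t_max_ms, target_spikes, seed)
    return 1000.0 * r


def population_inputs(nu: np.ndarray, cfg: MeanFieldConfig
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Infinitesimal input moments (mu_alpha, s_alpha) per population.

    ``nu`` holds the Q cluster rates followed by the inhibitory rate, in
    spikes/s.  Returns (mu, s, terms) where mu and s have length Q+1 (in
    mV/ms and mV^2/ms) and ``terms`` is a (Q+1, 4) breakdown of the mean
    into own-cluster, other-cluster, inhibitory and external parts.
    """
    nu = np.asarray(nu, dtype=float)
    Q = cfg.Q
    if nu.size != Q + 1:
        raise ValueError(f"rate vector must have length Q+1 = {Q + 1}")
    if np.any(nu < 0):
        raise ValueError("rates must be nonnegative")
    nu_ms = nu / 1000.0                     # spikes/ms
    nE, nI = nu_ms[:Q], nu_ms[Q]
    cEE = cfg.N_E / Q * cfg.p_EE
    Ew1, Ew2 = cfg.mu_plus, cfg.mu_plus**2 + cfg.sigma_plus**2
    Em1, Em2 = cfg.w_minus, cfg.w_minus**2
    sum_all = nE.sum()

    mu = np.empty(Q + 1)
    s = np.empty(Q + 1)
    terms = np.zeros((Q + 1, 4))
    for k in range(Q):
        own = cEE * Ew1 * nE[k]
        other = cEE * Em1 * (sum_all - nE[k])
        inh = cfg.N_I * cfg.p_EI * cfg.w_EI * nI
        terms[k] = (own, other, inh, cfg.h_ext_E)
        mu[k] = own + other + inh + cfg.h_ext_E
        s[k] = (cEE * Ew2 * nE[k] + cEE * Em2 * (sum_all - nE[k])
                + cfg.N_I * cfg.p_EI * cfg.w_EI**2 * nI)
    ex = cfg.N_E / Q * cfg.p_IE * cfg.w_IE * sum_all
    inh = cfg.N_I * cfg.p_II * cfg.w_II * nI
    terms[Q] = (0.0, ex, inh, cfg.h_ext_I)
    mu[Q] = ex + inh + cfg.h_ext_I
    s[Q] = (cfg.N_E / Q * cfg.p_IE * cfg.w_IE**2 * sum_all
            + cfg.N_I * cfg.p_II * cfg.w_II**2 * nI)
    return mu, s, terms


_S_FLOOR = 1e-9  # transfer function needs strictly positive variance


def _transfer_vec(mu, s, cfg: MeanFieldConfig, settings: SolverSettings,
                  distinct: list[list[int]]) -> np.ndarray:
    """Evaluate F on the distinct population groups only."""
    Q = cfg.Q
    out = np.empty(Q + 1)
    for group in distinct:
        k = group[0]
        tau = cfg.neuron.tau_m_E if k < Q else cfg.neuron.tau_m_I
        r = eif_transfer_rate(mu[k], max(s[k], _S_FLOOR), cfg.neuron,
                              settings, tau_m=tau)
        for i in group:
            out[i] = r
    return out


def _equilibrate_inhibition(nu: np.ndarray, cfg: MeanFieldConfig,
                            settings: SolverSettings,
                            hi: float = 1000.0) -> float:
    """Self-consistent inhibitory rate at fixed excitatory rates.

    g(nu_I) = nu_I - F_I(nu_I) is monotonically increasing because
    self-inhibition (w_II < 0) makes F_I decreasing in nu_I, so the root
    is unique and bracketed by [0, hi].
    """
    from scipy.optimize import brentq

    Q = cfg.Q
    work = nu.copy()

    def g(nu_I: float) -> float:
        work[Q] = nu_I
        mu, s, _ = population_inputs(work, cfg)
        return nu_I - eif_transfer_rate(mu[Q], max(s[Q], _S_FLOOR),
                                        cfg.neuron, settings,
                                        tau_m=cfg.neuron.tau_m_I)

    if g(0.0) >= 0.0:
        return 0.0
    return float(brentq(g, 0.0, hi, xtol=settings.tol * 1e-2))


def solve_self_consistent(cfg: MeanFieldConfig,
                          settings: SolverSettings | None = None,
                          ansatz: str = "one_active",
                          init: np.ndarray | tuple | None = None
                          ) -> RateSolution:
    """Damped fixed-point solution of nu = F(mu(nu), s(nu)).

    ansatz "uniform" constrains all Q cluster rates to be equal (two
    unknowns); "one_active" lets cluster 0 differ from the remaining
    Q-1 identical clusters (three unknowns).  ``init`` gives the initial
    rates as (active, inactive, inhibitory) or (E, I) in spikes/s; by
    default (50, 3, 5) and (3, 5) respectively, i.e. the high-activity
    basin — pass a low initial active rate to probe coexistence.
    """
    if settings is None:
        settings = SolverSettings()
    Q = cfg.Q
    if ansatz == "uniform":
        groups = [list(range(Q)), [Q]]
        if init is None:
            init = (3.0, 5.0)
        nu0 = np.array([init[0]] * Q + [init[1]], dtype=float)
    elif ansatz == "one_active":
        groups = [[0], list(range(1, Q)), [Q]] if Q > 1 else [[0], [Q]]
        if init is None:
            init = (50.0, 3.0, 5.0)
        if Q > 1:
            nu0 = np.array([init[0]] + [init[1]] * (Q - 1) + [init[2]])
        else:
            nu0 = np.array([init[0], init[-1]], dtype=float)
    else:
        raise ValueError(f"unknown ansatz {ansatz!r}")

    nu = nu0.astype(float)
    d = settings.damping
    e_groups = [g for g in groups if g[-1] != Q]
    residual = np.inf
    it = 0
    for it in range(1, settings.max_iter + 1):
        # inhibition is fast: equilibrate nu_I at the current E rates
        # before each excitatory update (adiabatic elimination), which
        # keeps the recurrent-inhibition feedback from lagging the
        # excitatory loop and destabilizing the iteration
        nu[Q] = _equilibrate_inhibition(nu, cfg, settings)
        mu, s, _ = population_inputs(nu, cfg)
        F = _transfer_vec(mu, s, cfg, settings, groups)
        residual = float(np.max(np.abs(nu - F)))
        if residual < settings.tol:
            nu = F
            break
        for g in e_groups:
            for i in g:
                nu[i] = (1.0 - d) * nu[i] + d * F[i]
        if np.max(nu) > 1e4:   # runaway: no bounded solution on this branch
            residual = np.inf
            break
    mu, s, _ = population_inputs(nu, cfg)
    return RateSolution(nu=nu, mu=mu, s=s,
                        converged=residual < settings.tol,
                        residual=residual, n_iter=it, ansatz=ansatz)


def landscape(mu_grid: np.ndarray, sigma_grid: np.ndarray,
              cfg: MeanFieldConfig, settings: SolverSettings | None = None,
              active_margin: float = 1.0) -> dict:
    """Active-cluster rate over the (mu_plus, sigma_plus) plane.

    For each accessible grid point the one-active ansatz is solved from
    a high and a low initial active-cluster rate; the larger converged
    active rate is reported.  A point is in the active phase when the
    active/inactive rate difference exceeds ``active_margin`` spikes/s;
    the instability boundary is the lowest active mu at each sigma.
    Cells with sigma > sigma_max(mu) are masked as forbidden.
    """
    import dataclasses

    if settings is None:
        settings = SolverSettings()
    mu_grid = np.asarray(mu_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    nm, ns = mu_grid.size, sigma_grid.size
    active = np.full((ns, nm), np.nan)
    inactive = np.full((ns, nm), np.nan)
    converged = np.zeros((ns, nm), dtype=bool)
    forbidden = np.zeros((ns, nm), dtype=bool)
    is_active = np.zeros((ns, nm), dtype=bool)
    for a, sig in enumerate(sigma_grid):
        for b, mu in enumerate(mu_grid):
            if sig > sigma_max(mu, cfg.w_max):
                forbidden[a, b] = True
                continue
            c = dataclasses.replace(cfg, mu_plus=float(mu),
                                    sigma_plus=float(sig))
            best = None
            for init in ((50.0, 3.0, 5.0), (1.0, 3.0, 5.0)):
                sol = solve_self_consistent(c, settings, "one_active", init)
                if sol.converged and (best is None
                                      or sol.nu[0] > best.nu[0]):
                    best = sol
            if best is None:
                continue
            converged[a, b] = True
            active[a, b] = best.nu[0]
            inactive[a, b] = best.nu[1] if cfg.Q > 1 else best.nu[0]
            is_active[a, b] = (active[a, b] - inactive[a, b]) > active_margin
    boundary = np.full(ns, np.nan)
    for a in range(ns):
        hits = np.flatnonzero(is_active[a] & ~forbidden[a])
        if hits.size:
            boundary[a] = mu_grid[hits[0]]
    return {
        "mu_grid": mu_grid,
        "sigma_grid": sigma_grid,
        "active_rate": active,
        "inactive_rate": inactive,
        "converged": converged,
        "forbidden": forbidden,
        "is_active": is_active,
        "boundary_mu": boundary,
    }


def landscape_to_frame(land: dict):
    """Flatten a landscape to a tidy table (one row per grid cell)."""
    import pandas as pd

    mu, sg = np.meshgrid(land["mu_grid"], land["sigma_grid"])
    return pd.DataFrame({
        "mu": mu.ravel(),
        "sigma": sg.ravel(),
        "active_rate": land["active_rate"].ravel(),
        "inactive_rate": land["inactive_rate"].ravel(),
        "converged": land["converged"].ravel(),
        "forbidden": land["forbidden"].ravel(),
        "is_active": land["is_active"].ravel(),
    })
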