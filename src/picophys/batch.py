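"""Dynamic Monod batch model with substrate-affinity heterogeneity.

The closed picoliter reactor is described by the standard batch material
balance

    dX/dt =  mu(S) * X
    dS/dt = -mu(S) / Y_X,S * X
    dP/dt =  r_P(S) * X,        r_P = mu * (1/(Y_X,S * M_S) - 1/M_X)

with mu(S) the Monod rate and the product pool P a single Cmol-lumped
state supplied by the carbon-balance closure.  Total carbon
``X/M_X + S/M_S + P`` is a linear invariant of the right-hand side and is
conserved along every trajectory.

Cell-to-cell heterogeneity enters through the substrate affinity only: an
ensemble samples per-phenotype KS values from the observed (truncated
normal) KS distribution while sharing mu_max and the stoichiometry, and the
spread of the resulting trajectories maps the physiological space the
population can occupy.

Integration is fixed-step classical 4th-order Runge-Kutta (default step
0.001 h); the substrate is floored at zero on exhaustion and growth stops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from picophys.kinetics import KsDistribution, MonodParams
from picophys.stoichiometry import StoichiometrySet

__all__ = [
    "BatchState", "BatchTrajectory", "BatchModel", "EnsembleSpec",
    "simulate_batch", "simulate_ensemble", "phenotype_space_summary",
]


@dataclass(frozen=True)
class BatchState:
    """State of the batch reactor: time (h), biomass X (g/L), substrate S
    (g/L), lumped product P (Cmol/L)."""

    t: float = 0.0
    x: float = 0.0
    s: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.s < 0 or self.p < 0:
            raise ValueError("state variables must be nonnegative")


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble definition: KS heterogeneity around shared kinetics.

    Per-phenotype KS values are drawn from a normal distribution truncated
    at zero with the given mean and SD; mu_max and the stoichiometry are
    shared across members.
    """

    ks_distribution: KsDistribution
    n_members: int
    seed: int
    monod: MonodParams
    stoich: StoichiometrySet

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


class BatchTrajectory:
    """Time series of one simulated batch phenotype."""

    def __init__(self, t: np.ndarray, x: np.ndarray, s: np.ndarray,
                 p: np.ndarray, monod: MonodParams, stoich: StoichiometrySet,
                 member_id: int = 0):
        self.t, self.x, self.s, self.p = t, x, s, p
        self.monod, self.stoich = monod, stoich
        self.member_id = member_id

    @property
    def total_carbon(self) -> np.ndarray:
        """Cmol/L of carbon in biomass + substrate + products at each time."""
        return (self.x / self.stoich.m_x_cmol
                + self.s / self.stoich.m_s_cmol + self.p)

    @property
    def exhaustion_time(self) -> float:
        """First time the substrate falls below 1e-6 of its initial value
        (NaN if it never does within the simulated horizon)."""
        if self.s[0] <= 0:
            return float(self.t[0])
        idx = np.flatnonzero(self.s <= 1e-6 * self.s[0])
        return float(self.t[idx[0]]) if idx.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "member_id": self.member_id, "t_h": self.t, "x_g_L": self.x,
            "s_g_L": self.s, "p_cmol_L": self.p})


def _rates(x: float, s: float, monod: MonodParams, stoich: StoichiometrySet
           ) -> tuple[float, float, float]:
    if s <= 0:
        return 0.0, 0.0, 0.0
    mu = monod.mu_max * s / (monod.ks + s)
    q_s_cmol = mu / (stoich.y_xs * stoich.m_s_cmol)
    r_p = q_s_cmol - mu / stoich.m_x_cmol
    return mu * x, -(mu / stoich.y_xs) * x, r_p * x


def simulate_batch(initial: BatchState, monod: MonodParams,
                   stoich: StoichiometrySet, t_end: float, dt: float = 0.001,
                   member_id: int = 0) -> BatchTrajectory:
    """Integrate the batch balance with fixed-step RK4.

    Raises
    ------
    ValueError
        If any state changes by more than 10% relative within one step
        (the step is too coarse for the dynamics; reduce ``dt``).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    n = int(round(t_end / dt)) + 1
    t = np.linspace(0.0, t_end, n) + initial.t
    x = np.empty(n); s = np.empty(n); p = np.empty(n)
    x[0], s[0], p[0] = initial.x, initial.s, initial.p
    for i in range(n - 1):
        xi, si, pi = x[i], s[i], p[i]
        k1 = _rates(xi, si, monod, stoich)
        k2 = _rates(xi + dt / 2 * k1[0], si + dt / 2 * k1[1], monod, stoich)
        k3 = _rates(xi + dt / 2 * k2[0], si + dt / 2 * k2[1], monod, stoich)
        k4 = _rates(xi + dt * k3[0], si + dt * k3[1], monod, stoich)
        dx = dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        ds = dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        dp = dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if xi > 0 and abs(dx) > 0.1 * xi:
            raise ValueError(
                f"step too large at t = {t[i]:.3f} h: biomass changed by "
                f"{abs(dx) / xi:.1%} in one step; reduce dt")
        x[i + 1] = xi + dx
        p[i + 1] = pi + dp
        s_next = si + ds
        if s_next <= 0:
            # substrate exhausted within the step: close the carbon balance
            # by converting exactly the remaining substrate
            frac = si / -ds if ds < 0 else 0.0
            x[i + 1] = xi + dx * frac
            p[i + 1] = pi + dp * frac
            s_next = 0.0
        s[i + 1] = s_next
    return BatchTrajectory(t, x, s, p, monod, stoich, member_id)


def simulate_ensemble(spec: EnsembleSpec, initial: BatchState, t_end: float,
                      dt: float = 0.001) -> list[BatchTrajectory]:
    """One batch trajectory per KS phenotype sampled from the distribution.

    Draws are from the zero-truncated normal with the distribution's mean
    and SD using a seeded generator, so the ensemble is reproducible.
    """
    dist = spec.ks_distribution
    if dist.sd > 0:
        a = -dist.mean / dist.sd  # truncation at zero in standard units
        rng = np.random.default_rng(spec.seed)
        ks_draws = truncnorm.rvs(a, np.inf, loc=dist.mean, scale=dist.sd,
                                 size=spec.n_members, random_state=rng)
    else:
        ks_draws = np.full(spec.n_members, dist.mean)
    if np.any(ks_draws <= 0):
        raise ValueError("non-positive ks draw after truncation")
    return [
        simulate_batch(initial,
                       MonodParams(spec.monod.mu_max, float(ks), "mean"),
                       spec.stoich, t_end, dt, member_id=i)
        for i, ks in enumerate(ks_draws)
    ]


def phenotype_space_summary(trajectories: list[BatchTrajectory]) -> pd.DataFrame:
    """Time-resolved quantile envelopes over an ensemble of trajectories.

    Returns a long-format table with min, 5%, median, 95% and max envelopes
    for X, S and P at every time point of the common grid.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    t0 = trajectories[0].t
    for tr in trajectories[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
            raise ValueError("trajectories must share a common time grid")
    qs = [0.0, 0.05, 0.5, 0.95, 1.0]
    names = ["min", "q05", "median", "q95", "max"]
    out = {"t_h": t0}
    for var in ("x", "s", "p"):
        stack = np.stack([getattr(tr, var) for tr in trajectories])
        quantiles = np.quantile(stack, qs, axis=0)
        for name, row in zip(names, quantiles):
            out[f"{var}_{name}"] = row
    return pd.DataFrame(out)


class BatchModel:
    """Mechanistic batch-reactor model bundling kinetics and stoichiometry.

    A convenience front end mirroring the fitted-model idiom: construct
    from a Monod parameter set and a closed stoichiometry, then
    ``simulate`` a single phenotype or ``simulate_ensemble`` across the KS
    distribution.
    """

    def __init__(self, monod: MonodParams, stoich: StoichiometrySet,
                 dt: float = 0.001):
        self.monod = monod
        self.stoich = stoich
        self.dt = dt

    def simulate(self, initial: BatchState, t_end: float) -> BatchTrajectory:
        return simulate_batch(initial, self.monod, self.stoich, t_end, self.dt)

    def simulate_ensemble(self, ks_distribution: KsDistribution,
                          initial: BatchState, t_end: float,
                          n_members: int = 200, seed: int = 0
                          ) -> list[BatchTrajectory]:
        spec = EnsembleSpec(ks_distribution, n_members, seed,
                            self.monod, self.stoich)
        return simulate_ensemble(spec, initial, t_end, self.dt)

    def spec_json(self) -> str:
        """Model specification (parameters, solver settings) as JSON."""
        return json.dumps({
            "monod": {"mu_max_per_h": self.monod.mu_max,
                      "ks_g_per_L": self.monod.ks},
            "stoichiometry": asdict(self.stoich),
            "solver": {"method": "rk4_fixed_step", "dt_h": self.dt},
        }, indent=2)
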