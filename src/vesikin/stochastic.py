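"""Single-release-site stochastic simulation by thinning.

Independent cross-check of the deterministic ODE solution: the release
site is simulated as a continuous-time Markov chain with time-varying
rates Q(ca(t), g7(t)) using Lewis thinning against a uniform dominating
rate. syt7 occupancy is a deterministic, shared quantity in the model, so
g7(t) is pre-integrated and interpolated. The mean cumulative fusion count
over many replicates estimates the ODE's F(t) for one site.

This module is an oracle for tests; the production path is
:func:`vesikin.kinetics.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import build_rate_components, steady_state
from .params import ModelParameters
from .states import N_STATES, N_SYT7
from .transient import CaTransient, build_transient


@dataclass(frozen=True)
class StochasticResult:
    """Fusion counts per replicate at ``t_end`` and the summary statistics."""

    fusions: np.ndarray
    t_end: float

    @property
    def mean(self) -> float:
        return float(self.fusions.mean())

    @property
    def sem(self) -> float:
        return float(self.fusions.std(ddof=1) / np.sqrt(self.fusions.size))


def _g7_interpolant(params: ModelParameters, transient: CaTransient, t_end: float):
    comp = build_rate_components(params)
    M7cT = comp.syt7_const.T
    M7onT = comp.syt7_on.T
    f7pow = params.syt7.f ** np.arange(N_SYT7)

    from .kinetics import syt7_steady_state

    S0 = syt7_steady_state(params.ca_rest, params)

    def rhs(t, S):
        ca = transient(t)
        return M7cT @ S + ca * (M7onT @ S)

    grid = np.arange(0.0, t_end + 5e-6, 1e-5)
    sol = solve_ivp(rhs, (0.0, t_end), S0, method="LSODA",
                    rtol=1e-8, atol=1e-10, max_step=1e-4, t_eval=grid)
    if not sol.success:
        raise RuntimeError(f"syt7 pre-integration failed: {sol.message}")
    g7 = sol.y.T @ f7pow
    return grid, g7


def simulate_single_site_mc(
    params: ModelParameters,
    transient: CaTransient | None = None,
    genotype: str = "wt",
    n_replicates: int = 10_000,
    t_end: float | None = None,
    seed: int = 12345,
) -> StochasticResult:
    """Monte-Carlo fusion counts of one release site over a Ca²⁺ transient.

    Replicates start from the resting steady-state distribution and evolve
    by thinning: candidate event times arrive at the uniform dominating
    rate Λ (the maximum possible exit rate over states, peak [Ca²⁺] and
    peak syt7 catalysis) and are accepted with probability equal to the
    state's current exit rate over Λ. Fusion = any docked → empty jump.
    Vectorized across replicates; fully determined by ``seed``.
    """
    p = params.with_genotype(genotype)
    if transient is None:
        transient = build_transient(p)
    if t_end is None:
        t_end = max(transient.ap_onsets) + p.protocol.tail

    comp = build_rate_components(p)
    grid, g7_grid = _g7_interpolant(p, transient, t_end)
    ca_grid = transient(grid)
    ca_max = float(ca_grid.max())
    g7_max = float(g7_grid.max())

    exit_const = -np.diag(comp.const)
    exit_on = -np.diag(comp.on)
    exit_dock = -np.diag(comp.dock)
    lam = float((exit_const + ca_max * exit_on + g7_max * exit_dock).max()) * 1.05

    # off-diagonal rate blocks, row-indexed by current state
    R_const = comp.const.copy()
    R_on = comp.on.copy()
    R_dock = comp.dock.copy()
    for R in (R_const, R_on, R_dock):
        np.fill_diagonal(R, 0.0)

    sp_docked = np.zeros(N_STATES, dtype=bool)
    sp_docked[6:] = True
    sp_empty = np.zeros(N_STATES, dtype=bool)
    sp_empty[:3] = True

    rng = np.random.default_rng(seed)
    pi0, _ = steady_state(p, p.ca_rest)
    prob0 = pi0 / pi0.sum()
    states = rng.choice(N_STATES, size=n_replicates, p=prob0)
    t = np.zeros(n_replicates)
    fusions = np.zeros(n_replicates, dtype=np.int64)

    while True:
        act = t < t_end
        if not act.any():
            break
        t[act] += rng.exponential(1.0 / lam, act.sum())
        idx = np.nonzero(act & (t < t_end))[0]
        if idx.size == 0:
            continue
        s = states[idx]
        ca = np.asarray(transient(t[idx]))
        g7 = np.interp(t[idx], grid, g7_grid)
        rows = R_const[s] + ca[:, None] * R_on[s] + g7[:, None] * R_dock[s]
        total = rows.sum(axis=1)
        accept = rng.uniform(size=idx.size) * lam < total
        if not accept.any():
            continue
        ai = idx[accept]
        rows_a = rows[accept]
        total_a = total[accept]
        v = rng.uniform(size=ai.size) * total_a
        dest = (rows_a.cumsum(axis=1) > v[:, None]).argmax(axis=1)
        fused = sp_docked[states[ai]] & sp_empty[dest]
        fusions[ai] += fused
        states[ai] = dest
    return StochasticResult(fusions=fusions, t_end=float(t_end))
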