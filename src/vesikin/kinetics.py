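"""Transition rates, intensity matrix, steady states, and ODE simulation.

The release site is a continuous-time Markov chain on 24 states (see
:mod:`vesikin.states`) whose generator Q depends on the instantaneous free
[Ca²⁺] and on the syt7 Ca²⁺-occupancy distribution. Transitions:

* tethering  E[d2] → T[d2]  (k_tet)  and untethering T → E (k_untet);
* docking    T[d2] → D[d2,0] and undocking D[d2,s1] → T[d2], both scaled by
  the syt7 catalysis factor  g7 = Σ_s7 S[s7]·f7^s7  (syt7 lowers the docking
  energy barrier symmetrically, so equilibria are untouched);
* fusion     D[d2,s1] → E[d2]  at  f(d2,s1) = l+ · f1^s1 · f2^d2, preserving
  the site's Doc2α state;
* Ca²⁺ binding/unbinding on Doc2α (any site state) and syt1 (docked only),
  with the shared five-ion budget clamping on-rates of docked states:
  available syt1 slots = min(n1 − s1, 5 − (d2+s1)), Doc2α slots on a docked
  site = min(n2 − d2, 5 − (d2+s1)). Off-rate from m bound ions is
  m·k−·b^(m−1).

syt7 occupancy S[0..2] follows its own 3-state master equation driven by
[Ca²⁺] only; it is integrated jointly with the site states and the
cumulative fusion count F.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

from .params import ModelParameters, SensorParams
from .states import (
    ION_BUDGET,
    N_D2,
    N_S1,
    N_STATES,
    N_SYT7,
    ReleaseSiteStateSpace,
    enumerate_states,
)
from .transient import CaTransient, build_transient


# ---------------------------------------------------------------------------
# elementary rates

def fusion_rate(d2: int, s1: int, params: ModelParameters) -> float:
    """Fusion rate (s⁻¹) of a docked vesicle with d2 ions on Doc2α, s1 on syt1."""
    if not 0 <= d2 <= 2:
        raise ValueError(f"d2 must be in 0..2, got {d2}")
    if not 0 <= s1 <= 5:
        raise ValueError(f"s1 must be in 0..5, got {s1}")
    return params.l_plus * params.syt1.f ** s1 * params.doc2.f ** d2


def syt7_catalysis(syt7_occupancy, params: ModelParameters) -> float:
    """g7 = Σ_s7 S[s7]·f7^s7, the factor scaling docking and undocking."""
    S = np.asarray(syt7_occupancy, dtype=float)
    return float(S @ params.syt7.f ** np.arange(N_SYT7))


def docking_rates(syt7_occupancy, params: ModelParameters) -> tuple[float, float]:
    """(docking, undocking) rates in s⁻¹ for a given syt7 occupancy distribution."""
    S = np.asarray(syt7_occupancy, dtype=float)
    if np.any(S < 0) or abs(S.sum() - 1.0) > 1e-6:
        raise ValueError("syt7 occupancy must be a normalized distribution")
    g7 = syt7_catalysis(S, params)
    return params.k_docking * g7, params.k_undocking * g7


def _off_rate(sensor: SensorParams, m: int) -> float:
    """Unbinding rate from a state with m ions bound: m·k−·b^(m−1)."""
    if m <= 0:
        return 0.0
    return m * sensor.k_minus * sensor.b ** (m - 1)


def ca_binding_rates(
    sensor: str,
    occupied: int,
    context: tuple[int, int] | None,
    ca: float,
    params: ModelParameters,
) -> tuple[float, float]:
    """(on, off) Ca²⁺ rates (s⁻¹) for one sensor in a given site context.

    ``context`` is the (d2, s1) pair of a docked site — used to clamp
    on-rates by the shared ion budget — or None for empty/tethered sites
    (and always for syt7, which lives on the release site independently).
    """
    if ca < 0:
        raise ValueError("ca must be non-negative")
    if sensor == "syt7":
        p = params.syt7
        slots = p.n - occupied
    elif sensor == "doc2":
        p = params.doc2
        slots = p.n - occupied
        if context is not None:
            d2, s1 = context
            slots = min(slots, ION_BUDGET - (d2 + s1))
    elif sensor == "syt1":
        p = params.syt1
        if context is None:
            raise ValueError("syt1 binds Ca2+ only on docked vesicles")
        d2, s1 = context
        slots = min(p.n - occupied, ION_BUDGET - (d2 + s1))
    else:
        raise ValueError(f"unknown sensor {sensor!r}")
    if not 0 <= occupied <= p.n:
        raise ValueError(f"occupancy {occupied} out of range for {sensor}")
    slots = max(slots, 0)
    return slots * p.k_plus * ca, _off_rate(p, occupied)


# ---------------------------------------------------------------------------
# intensity-matrix assembly

@dataclass(frozen=True)
class RateComponents:
    """Decomposition Q(ca, S) = const + ca·on + g7(S)·dock.

    Each component carries its own diagonal (−row sums), so any
    non-negative combination is again a proper generator.
    """

    const: np.ndarray
    on: np.ndarray       # per-µM Ca²⁺-binding rates
    dock: np.ndarray     # docking/undocking at unit catalysis
    fusion_vec: np.ndarray
    syt7_const: np.ndarray
    syt7_on: np.ndarray

    def combine(self, ca: float, g7: float) -> np.ndarray:
        return self.const + ca * self.on + g7 * self.dock

    def syt7_generator(self, ca: float) -> np.ndarray:
        return self.syt7_const + ca * self.syt7_on


def _set_diag(Q: np.ndarray) -> np.ndarray:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_rate_components(params: ModelParameters) -> RateComponents:
    sp = enumerate_states()
    const = np.zeros((N_STATES, N_STATES))
    on = np.zeros((N_STATES, N_STATES))
    dock = np.zeros((N_STATES, N_STATES))
    fusion_vec = np.zeros(N_STATES)

    for d2 in range(N_D2):
        e, t = sp.empty_index(d2), sp.tethered_index(d2)
        const[e, t] += params.k_tet
        const[t, e] += params.k_untet
        dock[t, sp.docked_index(d2, 0)] += params.k_docking

        # Doc2α transitions on empty/tethered sites: no budget clamp
        for i in (e, t):
            if d2 < params.doc2.n:
                on[i, i + 1] += (params.doc2.n - d2) * params.doc2.k_plus
            if d2 > 0:
                const[i, i - 1] += _off_rate(params.doc2, d2)

    for d2 in range(N_D2):
        for s1 in range(N_S1):
            i = sp.docked_index(d2, s1)
            dock[i, sp.tethered_index(d2)] += params.k_undocking
            f = fusion_rate(d2, s1, params)
            const[i, sp.empty_index(d2)] += f
            fusion_vec[i] = f
            # syt1 Ca²⁺ binding (budget-clamped) and unbinding
            slots1 = min(params.syt1.n - s1, ION_BUDGET - (d2 + s1))
            if slots1 > 0:
                on[i, sp.docked_index(d2, s1 + 1)] += slots1 * params.syt1.k_plus
            if s1 > 0:
                const[i, sp.docked_index(d2, s1 - 1)] += _off_rate(params.syt1, s1)
            # Doc2α on docked sites (budget-clamped)
            if d2 < params.doc2.n:
                slots2 = min(params.doc2.n - d2, ION_BUDGET - (d2 + s1))
                if slots2 > 0:
                    on[i, sp.docked_index(d2 + 1, s1)] += slots2 * params.doc2.k_plus
            if d2 > 0:
                const[i, sp.docked_index(d2 - 1, s1)] += _off_rate(params.doc2, d2)

    # Budget-violating docked states (d2+s1 > 5) have no inbound rates by the
    # clamps above; zeroing their outbound rows too makes their dynamics
    # identically zero, so they stay at exactly zero occupancy instead of
    # accumulating solver-level noise.
    forbidden = sp.forbidden_mask
    for M in (const, on, dock):
        M[forbidden, :] = 0.0
        M[:, forbidden] = 0.0

    syt7_const = np.zeros((N_SYT7, N_SYT7))
    syt7_on = np.zeros((N_SYT7, N_SYT7))
    for s7 in range(N_SYT7):
        if s7 < params.syt7.n:
            syt7_on[s7, s7 + 1] += (params.syt7.n - s7) * params.syt7.k_plus
        if s7 > 0:
            syt7_const[s7, s7 - 1] += _off_rate(params.syt7, s7)

    return RateComponents(
        const=_set_diag(const),
        on=_set_diag(on),
        dock=_set_diag(dock),
        fusion_vec=fusion_vec,
        syt7_const=_set_diag(syt7_const),
        syt7_on=_set_diag(syt7_on),
    )


def build_intensity_matrix(
    ca: float, syt7_occupancy, params: ModelParameters
) -> np.ndarray:
    """Generator Q over the 24 site states at one instant.

    Element (i, j), i ≠ j, is the i → j transition rate in s⁻¹; rows sum
    to zero.
    """
    if ca < 0:
        raise ValueError("ca must be non-negative")
    S = np.asarray(syt7_occupancy, dtype=float)
    if np.any(S < 0) or abs(S.sum() - 1.0) > 1e-6:
        raise ValueError("syt7 occupancy must be a normalized distribution")
    comp = build_rate_components(params)
    return comp.combine(ca, syt7_catalysis(S, params))


# ---------------------------------------------------------------------------
# steady states

def syt7_steady_state(ca: float, params: ModelParameters) -> np.ndarray:
    """Stationary syt7 occupancy by detailed balance of the binding chain.

    S[1]/S[0] = 2·[Ca]·k7+/k7−,  S[2]/S[1] = [Ca]·k7+/(2·b7·k7−); the
    unnormalized chain starts at S[0] = 1 and is then normalized.
    """
    p = params.syt7
    s = np.empty(N_SYT7)
    s[0] = 1.0
    s[1] = s[0] * 2.0 * ca * p.k_plus / p.k_minus
    s[2] = s[1] * ca * p.k_plus / (2.0 * p.b * p.k_minus)
    return s / s.sum()


def steady_state(
    params: ModelParameters, ca: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary site occupancies (scaled to n_sites) and syt7 occupancy.

    The site distribution is the one-dimensional null space of Qᵀ; see
    :func:`steady_state_expm` for the matrix-exponential cross-check.
    """
    ca = params.ca_rest if ca is None else ca
    S = syt7_steady_state(ca, params)
    Q = build_intensity_matrix(ca, S, params)
    # restrict to reachable states: the budget-violating docked states are
    # rate-isolated and would each contribute a spurious null direction
    allowed = ~enumerate_states().forbidden_mask
    ns = linalg.null_space(Q[np.ix_(allowed, allowed)].T, rcond=1e-10)
    if ns.shape[1] != 1:
        raise RuntimeError(
            f"intensity matrix has a {ns.shape[1]}-dimensional null space; "
            "expected exactly one stationary distribution"
        )
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    v = np.clip(v, 0.0, None)
    pi = np.zeros(N_STATES)
    pi[allowed] = v / v.sum() * params.n_sites
    return pi, S


def steady_state_expm(
    params: ModelParameters, ca: float | None = None, t: float = 1000.0
) -> np.ndarray:
    """Site steady state as π_i·e^{Qt} with all sites initially empty (E[0]).

    Mirrors the long-time matrix-exponential construction; used as an
    independent check on the null-space solve.
    """
    ca = params.ca_rest if ca is None else ca
    S = syt7_steady_state(ca, params)
    Q = build_intensity_matrix(ca, S, params)
    pi0 = np.zeros(N_STATES)
    pi0[0] = params.n_sites
    return pi0 @ linalg.expm(Q * t)


# ---------------------------------------------------------------------------
# simulation

@dataclass(frozen=True)
class Trajectory:
    """Time-resolved output of one simulation.

    Attributes
    ----------
    t : array (n,)
        Output times, s.
    occupancies : array (n, 24)
        Sites in each release-site state (sums to n_sites).
    syt7 : array (n, 3)
        syt7 occupancy fractions (sum to 1).
    fused : array (n,)
        Cumulative fused vesicles F(t).
    """

    t: np.ndarray
    occupancies: np.ndarray
    syt7: np.ndarray
    fused: np.ndarray
    params: ModelParameters
    genotype: str = "wt"
    ap_onsets: tuple[float, ...] = ()

    @cached_property
    def state_space(self) -> ReleaseSiteStateSpace:
        return enumerate_states()

    @property
    def docked(self) -> np.ndarray:
        return self.occupancies[:, self.state_space.docked_mask].sum(axis=1)

    @property
    def tethered(self) -> np.ndarray:
        return self.occupancies[:, self.state_space.tethered_mask].sum(axis=1)

    @property
    def empty(self) -> np.ndarray:
        return self.occupancies[:, self.state_space.empty_mask].sum(axis=1)

    def fused_at(self, t) -> np.ndarray:
        """Linear interpolation of cumulative fusion at arbitrary times."""
        return np.interp(t, self.t, self.fused)

    def docked_at(self, t) -> np.ndarray:
        return np.interp(t, self.t, self.docked)

    def release_rate(self) -> np.ndarray:
        """Instantaneous release rate Σ f(d2,s1)·D[d2,s1] at output times."""
        comp = build_rate_components(self.params.with_genotype(self.genotype))
        return self.occupancies @ comp.fusion_vec

    def to_frame(self):
        import pandas as pd

        sp = self.state_space
        data = {"time_s": self.t}
        for j, lab in enumerate(sp.labels):
            data[lab] = self.occupancies[:, j]
        for j, lab in enumerate(sp.syt7_labels):
            data[lab] = self.syt7[:, j]
        data["F_cumulative"] = self.fused
        return pd.DataFrame(data)


class SolverError(RuntimeError):
    """ODE integration failed; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:.6g} s)")
        self.last_time = last_time


def simulate(
    params: ModelParameters,
    transient: CaTransient | None = None,
    genotype: str = "wt",
    t_end: float | None = None,
    rtol: float = 1e-5,
    atol: float = 1e-5,
    max_step: float = 1e-5,
    output_dt: float = 2e-5,
) -> Trajectory:
    """Integrate the release-site system over a Ca²⁺ transient.

    Starts from the resting steady state (at ``params.ca_rest``) and solves
    the joint 28-dimensional ODE (24 site states, 3 syt7 states, cumulative
    fusion F) with a stiff implicit solver (LSODA, analytic Jacobian).
    ``genotype`` applies the knockout presets: ``doc2_ko`` → k2+ = 0,
    ``syt7_ko`` → f7 = 1, ``dko`` → both.

    Output is sampled on a uniform grid of spacing ``output_dt`` (default
    20 µs, i.e. 50 kHz, the grid the quantification stage uses).
    """
    p = params.with_genotype(genotype)
    if transient is None:
        transient = build_transient(p)
    if t_end is None:
        t_end = max(transient.ap_onsets) + p.protocol.tail

    comp = build_rate_components(p)
    QcT = comp.const.T.copy()
    QonT = comp.on.T.copy()
    QdT = comp.dock.T.copy()
    M7cT = comp.syt7_const.T.copy()
    M7onT = comp.syt7_on.T.copy()
    fvec = comp.fusion_vec
    f7pow = p.syt7.f ** np.arange(N_SYT7)

    pi0, S0 = steady_state(p, p.ca_rest)
    y0 = np.concatenate([pi0, S0, [0.0]])

    def rhs(t, y):
        occ = y[:N_STATES]
        S = y[N_STATES:N_STATES + N_SYT7]
        ca = transient(t)
        g7 = float(S @ f7pow)
        dy = np.empty_like(y)
        dy[:N_STATES] = QcT @ occ + ca * (QonT @ occ) + g7 * (QdT @ occ)
        dy[N_STATES:N_STATES + N_SYT7] = M7cT @ S + ca * (M7onT @ S)
        dy[-1] = fvec @ occ
        return dy

    def jac(t, y):
        occ = y[:N_STATES]
        S = y[N_STATES:N_STATES + N_SYT7]
        ca = transient(t)
        g7 = float(S @ f7pow)
        J = np.zeros((y.size, y.size))
        J[:N_STATES, :N_STATES] = QcT + ca * QonT + g7 * QdT
        dock_occ = QdT @ occ
        J[:N_STATES, N_STATES:N_STATES + N_SYT7] = dock_occ[:, None] * f7pow[None, :]
        J[N_STATES:N_STATES + N_SYT7, N_STATES:N_STATES + N_SYT7] = M7cT + ca * M7onT
        J[-1, :N_STATES] = fvec
        return J

    t_eval = np.arange(0.0, t_end + output_dt / 2, output_dt)
    t_eval[-1] = min(t_eval[-1], t_end)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        t_eval=t_eval,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SolverError(f"ODE solver failed: {sol.message}", last)

    occ = sol.y[:N_STATES].T
    S = sol.y[N_STATES:N_STATES + N_SYT7].T
    F = sol.y[-1]
    return Trajectory(
        t=sol.t,
        occupancies=occ,
        syt7=S,
        fused=F,
        params=params,
        genotype=genotype,
        ap_onsets=tuple(transient.ap_onsets),
    )
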