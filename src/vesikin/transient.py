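"""Deterministic free-Ca²⁺ transient driving the model.

Each action potential contributes a narrow synchronous Gaussian (peak
``amplitude_ap`` µM at onset + 1.5 ms, sd 0.2 ms, peak-height scaled) and a
residual component

    A · exp(−(t − t0)/tau) · (t − t0) / ((t − t0) + km)     for t ≥ t0,

with onset ``t0`` at AP onset + 1.6 ms; the hyperbolic factor smooths the
rise near ``t0``. Residuals of successive APs sum linearly. A basal
concentration ``ca_rest`` is added to the whole transient, which is
evaluated analytically on demand so ODE solvers may take arbitrary steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters


@dataclass(frozen=True)
class CaTransient:
    """Free [Ca²⁺](t) in µM for a train of APs; callable on scalars/arrays."""

    ap_onsets: tuple[float, ...]
    amplitude_ap: float
    gauss_mean: float
    gauss_sd: float
    amplitude_residual: float
    tau_residual: float
    km_smooth: float
    t0_offset: float
    ca_rest: float

    def synchronous(self, t):
        """Sum of per-AP synchronous Gaussian components (µM)."""
        t = np.asarray(t, dtype=float)
        onsets = np.asarray(self.ap_onsets)
        dt = t[..., None] - onsets - self.gauss_mean
        return self.amplitude_ap * np.exp(-0.5 * (dt / self.gauss_sd) ** 2).sum(axis=-1)

    def residual(self, t):
        """Sum of per-AP residual components (µM); zero before each onset."""
        t = np.asarray(t, dtype=float)
        onsets = np.asarray(self.ap_onsets)
        u = t[..., None] - onsets - self.t0_offset
        u = np.where(u > 0.0, u, 0.0)
        comp = (
            self.amplitude_residual
            * np.exp(-u / self.tau_residual)
            * u / (u + self.km_smooth)
        )
        return np.where(u > 0.0, comp, 0.0).sum(axis=-1)

    def __call__(self, t):
        out = self.ca_rest + self.synchronous(t) + self.residual(t)
        if np.ndim(t) == 0:
            return float(out)
        return out


def build_transient(
    params: ModelParameters,
    n_aps: int | None = None,
    freq: float | None = None,
) -> CaTransient:
    """Build the transient for ``n_aps`` APs at ``freq`` Hz.

    AP onsets sit at k/freq, k = 0..n_aps−1. Defaults come from
    ``params.protocol``.
    """
    n_aps = params.protocol.n_aps if n_aps is None else n_aps
    freq = params.protocol.freq if freq is None else freq
    if n_aps < 1:
        raise ValueError("need at least one AP")
    if freq <= 0:
        raise ValueError("frequency must be positive")
    onsets = tuple(k / freq for k in range(n_aps))
    return CaTransient(
        ap_onsets=onsets,
        amplitude_ap=params.amplitude_ap,
        gauss_mean=params.gauss_mean,
        gauss_sd=params.gauss_sd,
        amplitude_residual=params.amplitude_residual,
        tau_residual=params.tau_residual,
        km_smooth=params.km_smooth,
        t0_offset=params.t0_offset,
        ca_rest=params.ca_rest,
    )
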