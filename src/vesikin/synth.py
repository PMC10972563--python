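"""Synthetic optical traces and evoked-current trains with ground truth.

Emulates the signal structure of the real recordings well enough to test
every analysis stage without data: per-bouton ΔF/F₀ series at 100 Hz with
Gaussian baseline noise and events shaped as an instant rise (within one
frame) followed by exponential decay; and train currents built from phasic
biexponential responses plus a slowly accumulating tonic component whose
charge is known in closed form. All randomness flows from a single seed
through numpy's default PCG64 generator, so identical specs give
bit-identical output.

The generators do not emulate photobleaching, movie-level noise structure,
or multiquantal amplitude statistics of real boutons; recovery of ground
truth here demonstrates correctness of the quantification code, not
field-data performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import simulate
from .params import ModelParameters
from .traces import BIN_WIDTH, CurrentTrace, FluorescenceTrace, StimProtocol

EVENT_TRUTH_COLUMNS = [
    "bouton", "frame", "time_s", "stimulus", "amplitude", "peak_ms", "bin", "klass",
]


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic data set.

    Fluorescence defaults mimic a medium-affinity glutamate sensor: 10 ms
    frames, 500 ms baseline, ~100 ms decay kernel. The low-affinity variant
    used for trains decays faster (~30 ms); set ``kernel_tau=0.03``.
    Asynchronous latencies default to an exponential of 20 ms mean truncated
    to (10, 100] ms after the stimulus.
    """

    seed: int = 0
    n_boutons: int = 100
    frame_period: float = 10e-3       # s
    baseline_len: float = 0.5         # s before the first stimulus
    record_tail: float = 0.3          # s after the last stimulus
    noise_sd: float = 0.02            # ΔF/F₀ units
    kernel_tau: float = 0.1           # s, event decay constant
    p_sync: float = 0.64              # per-stimulus synchronous event probability
    p_async: float = 0.36             # per-stimulus asynchronous event probability
    amp_mean: float = 1.0             # ΔF/F₀
    amp_sd: float = 0.2
    async_latency_mean: float = 20e-3     # s, exponential mean
    async_latency_range: tuple[float, float] = (10e-3, 100e-3)
    protocol: StimProtocol = field(default_factory=lambda: StimProtocol((0.5,)))

    # evoked-current side
    epsc_fs: float = 10e3             # Hz
    epsc_amp: float = 300.0           # pA, first-response phasic peak
    epsc_depression: float = 0.9      # per-stimulus geometric amplitude factor
    epsc_tau_rise: float = 0.5e-3     # s
    epsc_tau_decay: float = 5e-3      # s
    tonic_shape: str = "ramp"         # "none" | "ramp" | "saturating"
    tonic_peak: float = 100.0         # pA, magnitude reached by the tonic build-up
    tonic_tau: float = 0.5            # s, for the saturating shape
    epsc_noise_sd: float = 0.0        # pA

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# fluorescence

def _frame_grid(spec: SynthSpec) -> np.ndarray:
    t_end = spec.protocol.onsets[-1] + spec.record_tail
    n = int(round(t_end / spec.frame_period)) + 1
    return np.arange(n) * spec.frame_period


def render_events(
    frame_times: np.ndarray,
    events: pd.DataFrame,
    kernel_tau: float,
    n_boutons: int,
) -> np.ndarray:
    """Noiseless ΔF/F₀ traces from a ground-truth event table.

    Each event adds ``amplitude · exp(−(t − t_event)/tau)`` from its frame
    onward (instant rise within one frame). This renderer defines the
    generator's forward model, so truth tables and noiseless traces are
    consistent by construction.
    """
    out = np.zeros((n_boutons, frame_times.size))
    for b, i, amp in zip(events["bouton"], events["frame"], events["amplitude"]):
        tail = frame_times[i:] - frame_times[i]
        out[int(b), int(i):] += amp * np.exp(-tail / kernel_tau)
    return out


def _truth_row(spec: SynthSpec, frames, b, i, amp, onset, k):
    rel = frames[i] - onset
    b_idx = int(np.ceil(rel / BIN_WIDTH - 1e-9))
    return {
        "bouton": b,
        "frame": int(i),
        "time_s": float(frames[i]),
        "stimulus": k + 1,
        "amplitude": float(amp),
        "peak_ms": float(rel * 1e3),
        "bin": b_idx,
        "klass": "synchronous" if b_idx <= 1 else "asynchronous",
    }


def _truncated_exp(rng, mean, lo, hi):
    """Inverse-CDF sample of an exponential truncated to (lo, hi]."""
    u = rng.uniform()
    c_lo = 1.0 - np.exp(-lo / mean)
    c_hi = 1.0 - np.exp(-hi / mean)
    return -mean * np.log(1.0 - (c_lo + u * (c_hi - c_lo)))


def synth_iglu(spec: SynthSpec) -> tuple[FluorescenceTrace, pd.DataFrame]:
    """Synthesize per-bouton ΔF/F₀ traces and their ground-truth events.

    Per bouton and stimulus, a synchronous event occurs with probability
    ``p_sync`` at the first frame after onset, and an asynchronous event
    with probability ``p_async`` at a truncated-exponential latency.
    Amplitudes are Gaussian (clipped at 20% of the mean).
    """
    rng = spec.rng()
    frames = _frame_grid(spec)
    onsets = np.asarray(spec.protocol.onsets)
    isi = spec.protocol.isi
    lat_lo, lat_hi = spec.async_latency_range
    if np.isfinite(isi):
        # keep the frame-snapped event strictly before the next onset
        lat_hi = min(lat_hi, isi - spec.frame_period)

    rows = []
    for b in range(spec.n_boutons):
        for k, o in enumerate(onsets):
            if rng.uniform() < spec.p_sync:
                i = int(np.searchsorted(frames, o + 1e-12))
                amp = max(rng.normal(spec.amp_mean, spec.amp_sd), 0.2 * spec.amp_mean)
                rows.append(_truth_row(spec, frames, b, i, amp, o, k))
            if rng.uniform() < spec.p_async:
                lat = _truncated_exp(rng, spec.async_latency_mean, lat_lo, lat_hi)
                i = int(np.searchsorted(frames, o + lat - 1e-12))
                if i < frames.size:
                    amp = max(rng.normal(spec.amp_mean, spec.amp_sd), 0.2 * spec.amp_mean)
                    rows.append(_truth_row(spec, frames, b, i, amp, o, k))
    truth = pd.DataFrame(rows, columns=EVENT_TRUTH_COLUMNS)
    clean = render_events(frames, truth, spec.kernel_tau, spec.n_boutons)
    noisy = clean + spec.noise_sd * rng.standard_normal(clean.shape)
    trace = FluorescenceTrace(
        frames, noisy, baseline_window=(0.0, spec.baseline_len), kind="dff"
    )
    return trace, truth


# ---------------------------------------------------------------------------
# evoked currents

def _phasic_kernel(t, tau_rise, tau_decay):
    """Unit-peak biexponential conductance waveform (0 for t < 0)."""
    if tau_rise <= 0:
        w = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay), 0.0)
        return w
    w = np.where(
        t >= 0,
        np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise),
        0.0,
    )
    t_peak = (
        tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    )
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return w / peak


def tonic_envelope(spec: SynthSpec, t) -> np.ndarray:
    """Tonic current component (pA, ≤ 0) at times ``t``."""
    t = np.asarray(t, dtype=float)
    o0 = spec.protocol.onsets[0]
    train_len = spec.protocol.n_stimuli * spec.protocol.isi
    u = np.clip(t - o0, 0.0, None)
    if spec.tonic_shape == "none":
        return np.zeros_like(t)
    if spec.tonic_shape == "ramp":
        return -spec.tonic_peak * np.minimum(u / train_len, 1.0)
    if spec.tonic_shape == "saturating":
        return -spec.tonic_peak * (1.0 - np.exp(-u / spec.tonic_tau))
    raise ValueError(f"unknown tonic shape {spec.tonic_shape!r}")


def analytic_tonic_charge(spec: SynthSpec) -> float:
    """Exact integral (pC) of −envelope over the tonic measurement window.

    The window matches the analyzer's: from 1 ms before the first stimulus
    to 1 ms before the would-be next stimulus after the last.
    """
    from .traces import TAIL_OFFSET

    onsets = np.asarray(spec.protocol.onsets)
    isi = spec.protocol.isi
    o0 = onsets[0]
    t0 = onsets[0] - TAIL_OFFSET
    t1 = onsets[-1] - TAIL_OFFSET + isi
    train_len = spec.protocol.n_stimuli * isi
    R = spec.tonic_peak
    if spec.tonic_shape == "none":
        return 0.0
    if spec.tonic_shape == "ramp":
        # envelope magnitude R·u/train_len up to u = train_len, then R
        u1 = t1 - o0
        ramp_end = min(u1, train_len)
        area = R * ramp_end**2 / (2.0 * train_len)
        if u1 > train_len:
            area += R * (u1 - train_len)
        return float(area)
    if spec.tonic_shape == "saturating":
        u1 = t1 - o0
        tau = spec.tonic_tau
        return float(R * (u1 + tau * (np.exp(-u1 / tau) - 1.0)))
    raise ValueError(f"unknown tonic shape {spec.tonic_shape!r}")


def synth_epsc(spec: SynthSpec) -> tuple[CurrentTrace, dict]:
    """Synthesize a train current: phasic responses + tonic build-up + noise.

    Returns the trace and a ground-truth dict with the per-stimulus phasic
    amplitudes, the tonic envelope callable, and the analytic tonic charge.
    """
    rng = spec.rng()
    onsets = np.asarray(spec.protocol.onsets)
    isi = spec.protocol.isi if spec.protocol.n_stimuli > 1 else 0.05
    t_end = onsets[-1] + isi
    t = np.arange(0.0, t_end + 0.5 / spec.epsc_fs, 1.0 / spec.epsc_fs)
    amps = spec.epsc_amp * spec.epsc_depression ** np.arange(onsets.size)
    current = np.zeros_like(t)
    for o, a in zip(onsets, amps):
        current -= a * _phasic_kernel(t - o, spec.epsc_tau_rise, spec.epsc_tau_decay)
    current += tonic_envelope(spec, t)
    if spec.epsc_noise_sd > 0:
        current = current + spec.epsc_noise_sd * rng.standard_normal(t.shape)
    trace = CurrentTrace(t, current, tuple(onsets))
    truth = {
        "phasic_amplitudes": amps,
        "tonic_envelope": lambda tt: tonic_envelope(spec, tt),
        "tonic_charge_pC": analytic_tonic_charge(spec),
        "onsets": tuple(onsets),
    }
    return trace, truth


def synth_epsc_single(
    q_fast: float,
    q_slow: float,
    tau_fast: float,
    tau_slow: float,
    fs: float = 50e3,
    onset: float = 0.1,
    duration: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CurrentTrace:
    """Single-sweep current whose cumulative charge is exactly biexponential.

    I(t) = −(q_fast/τ_fast·e^{−t/τ_fast} + q_slow/τ_slow·e^{−t/τ_slow})
    for t after the stimulus (instant rise), so the charge decomposition's
    model holds exactly; used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / fs)
    u = t - onset
    current = np.where(
        u >= 0,
        -(
            q_fast / tau_fast * np.exp(-np.maximum(u, 0) / tau_fast)
            + q_slow / tau_slow * np.exp(-np.maximum(u, 0) / tau_slow)
        ),
        0.0,
    )
    if noise_sd > 0:
        current = current + noise_sd * rng.standard_normal(t.shape)
    return CurrentTrace(t, current, (onset,))


# ---------------------------------------------------------------------------
# model-driven optical forward model

def model_driven_synth(
    params: ModelParameters,
    genotype: str = "wt",
    gain: float = 1.0,
    noise_sd: float = 0.02,
    n_boutons: int = 100,
    sites_per_bouton: float = 10.0,
    seed: int = 0,
    spec: SynthSpec | None = None,
    **simulate_kwargs,
) -> tuple[FluorescenceTrace, pd.DataFrame]:
    """Push a model simulation through the optical forward model.

    The simulated cumulative fusion count is binned per imaging frame; each
    bouton draws a Poisson number of fusions per frame with mean
    ``ΔF_frame · sites_per_bouton / n_sites`` and a frame with c ≥ 1
    fusions becomes one (possibly multiquantal) event of amplitude
    ``gain · c``. Closes the loop model → measurement → quantification.
    """
    if spec is None:
        spec = SynthSpec(seed=seed, n_boutons=n_boutons, noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    traj = simulate(params, genotype=genotype, **simulate_kwargs)

    start = spec.baseline_len
    onsets = start + np.asarray(traj.ap_onsets)
    protocol = StimProtocol(tuple(onsets))
    n_frames = int(round((start + traj.t[-1]) / spec.frame_period)) + 1
    frames = np.arange(n_frames) * spec.frame_period

    # expected fusions per frame per bouton, from the model's cumulative count
    edges_model = frames - start
    F_edges = np.where(edges_model >= 0, traj.fused_at(np.clip(edges_model, 0, None)), 0.0)
    lam = np.diff(F_edges, prepend=0.0) * (sites_per_bouton / params.n_sites)
    lam = np.clip(lam, 0.0, None)

    rows = []
    if gain > 0:
        counts = rng.poisson(lam[None, :].repeat(spec.n_boutons, axis=0))
        for b, i in zip(*np.nonzero(counts)):
            t_i = frames[i]
            k = int(np.searchsorted(onsets, t_i + 1e-12) - 1)
            if k < 0:
                continue
            rows.append(
                _truth_row(spec, frames, int(b), int(i), gain * counts[b, i], onsets[k], k)
            )
    truth = pd.DataFrame(rows, columns=EVENT_TRUTH_COLUMNS)
    clean = render_events(frames, truth, spec.kernel_tau, spec.n_boutons)
    noisy = clean + spec.noise_sd * rng.standard_normal(clean.shape)
    trace = FluorescenceTrace(
        frames, noisy, baseline_window=(0.0, spec.baseline_len), kind="dff"
    )
    truth.attrs["protocol"] = protocol
    return trace, truth
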