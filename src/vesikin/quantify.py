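"""Per-stimulus metrics of a simulated trajectory and one-at-a-time sweeps.

Quantification mirrors the procedure used to read out the model: the
cumulative fusion count is linearly interpolated onto a dense uniform grid
(50 kHz by default), release rates are forward differences on that grid,
the peak rate of each stimulus is the maximum over its inter-stimulus
window, and release later than 5 ms after a stimulus onset (up to the next
onset) counts as asynchronous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import SolverError, Trajectory, simulate
from .params import ModelParameters, set_flat
from .transient import build_transient

AR_ONSET = 5e-3           # s after stimulus onset; later release is asynchronous
DOCK_OFFSETS = (5e-3, 11e-3, 15e-3)   # docked-count readout offsets after each AP


def release_rate_series(
    traj: Trajectory, fs: float = 50e3
) -> tuple[np.ndarray, np.ndarray]:
    """Release rate (vesicles/s) on a uniform grid of sampling rate ``fs``.

    Cumulative fusion is linearly interpolated at ``fs`` and forward
    differences are multiplied by the sampling rate; the rate at the last
    grid point repeats the final difference so the series has the grid's
    length.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    t0, t1 = traj.t[0], traj.t[-1]
    if t1 - t0 < 1.0 / fs:
        raise ValueError("trajectory shorter than one sample interval")
    grid = np.arange(t0, t1, 1.0 / fs)
    F = traj.fused_at(grid)
    rate = np.empty_like(F)
    rate[:-1] = np.diff(F) * fs
    rate[-1] = rate[-2] if rate.size > 1 else 0.0
    return grid, rate


@dataclass(frozen=True)
class StimulusMetrics:
    """Per-stimulus readouts of one simulation.

    ``table`` has one row per stimulus: peak release rate, synchronous and
    asynchronous release counts, cumulative asynchronous count, docked
    counts at fixed offsets after the AP, and the 5–15 ms docking recovery.
    """

    table: pd.DataFrame
    depression_ratio: float
    ar_total: float
    genotype: str = "wt"

    @property
    def peak_rates(self) -> np.ndarray:
        return self.table["peak_rate"].to_numpy()

    @property
    def async_counts(self) -> np.ndarray:
        return self.table["async_count"].to_numpy()


def per_stimulus_metrics(
    traj: Trajectory,
    onsets=None,
    fs: float = 50e3,
) -> StimulusMetrics:
    """Compute per-stimulus metrics from a trajectory.

    For stimulus k with onset o_k and inter-stimulus interval Δ (taken from
    consecutive onsets; the last window also spans Δ):

    * peak rate: max release rate on [o_k, o_k + Δ);
    * synchronous count: F(o_k + 5 ms) − F(o_k);
    * asynchronous count: F(o_k + Δ) − F(o_k + 5 ms);
    * docked at +5/+11/+15 ms, and recovery = docked(+15 ms) − docked(+5 ms).
    """
    onsets = np.asarray(traj.ap_onsets if onsets is None else onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("no stimulus onsets")
    isi = onsets[1] - onsets[0] if onsets.size > 1 else traj.t[-1] - onsets[0]
    grid, rate = release_rate_series(traj, fs)

    rows = []
    cum_async = 0.0
    for k, o in enumerate(onsets):
        w = (grid >= o) & (grid < o + isi)
        peak = float(rate[w].max()) if w.any() else 0.0
        f0, f5, f_end = traj.fused_at([o, o + AR_ONSET, o + isi])
        sync = float(f5 - f0)
        asyn = float(f_end - f5)
        cum_async += asyn
        docked = traj.docked_at([o + dt for dt in DOCK_OFFSETS])
        try:
            flux = _dock_flux(traj, o + 5e-3, o + 15e-3)
        except ValueError:
            flux = np.nan
        rows.append(
            {
                "stimulus": k + 1,
                "onset_s": float(o),
                "peak_rate": peak,
                "sync_count": sync,
                "async_count": asyn,
                "cum_async": cum_async,
                "docked_5ms": float(docked[0]),
                "docked_11ms": float(docked[1]),
                "docked_15ms": float(docked[2]),
                "dock_recovery_5_15ms": float(docked[2] - docked[0]),
                "dock_flux_5_15ms": flux,
            }
        )
    table = pd.DataFrame(rows)
    peaks = table["peak_rate"].to_numpy()
    depression = float(peaks[-1] / peaks[0]) if peaks[0] > 0 else np.nan
    return StimulusMetrics(
        table=table,
        depression_ratio=depression,
        ar_total=cum_async,
        genotype=traj.genotype,
    )


def docking_recovery(
    traj: Trajectory,
    ap_index: int = 0,
    window: tuple[float, float] = (5e-3, 15e-3),
) -> float:
    """Net change in the docked pool between ``window`` offsets after one AP."""
    o = traj.ap_onsets[ap_index]
    lo, hi = window
    d = traj.docked_at([o + lo, o + hi])
    return float(d[1] - d[0])


def docking_flux(
    traj: Trajectory,
    ap_index: int = 0,
    window: tuple[float, float] = (5e-3, 15e-3),
) -> float:
    """Number of vesicles docking in ``window`` after one AP.

    Cumulative docking events — the integral of the syt7-catalyzed docking
    rate times the tethered pool — as opposed to the *net* pool change of
    :func:`docking_recovery`, which subtracts undocking and fusion losses.
    This is the quantity the model tuning targets: large for WT and the
    Doc2α knockout, near zero without syt7 catalysis.
    """
    o = traj.ap_onsets[ap_index]
    return _dock_flux(traj, o + window[0], o + window[1])


def _dock_flux(traj: Trajectory, t_lo: float, t_hi: float) -> float:
    p = traj.params.with_genotype(traj.genotype)
    m = (traj.t >= t_lo) & (traj.t <= t_hi)
    if m.sum() < 2:
        raise ValueError("window contains too few trajectory samples")
    f7pow = p.syt7.f ** np.arange(traj.syt7.shape[1])
    g7 = traj.syt7[m] @ f7pow
    return float(np.trapezoid(g7 * p.k_docking * traj.tethered[m], traj.t[m]))


# ---------------------------------------------------------------------------
# parameter sweep

HEADLINE_METRICS = ("docking_5_15_ap1", "ar_total", "peak_rate_ap1", "depression_ratio")


def _headline(metrics: StimulusMetrics) -> dict[str, float]:
    t = metrics.table
    return {
        "docking_5_15_ap1": float(t["dock_flux_5_15ms"].iloc[0]),
        "ar_total": metrics.ar_total,
        "peak_rate_ap1": float(t["peak_rate"].iloc[0]),
        "depression_ratio": metrics.depression_ratio,
    }


def default_multipliers(n: int = 13) -> np.ndarray:
    """Log-spaced multipliers spanning one-tenth to tenfold."""
    return np.logspace(-1, 1, n)


def parameter_sweep(
    params: ModelParameters,
    names,
    multipliers=None,
    genotype: str = "wt",
    metrics=HEADLINE_METRICS,
    **simulate_kwargs,
) -> pd.DataFrame:
    """One-at-a-time sweep of flat-named parameters over a multiplier grid.

    Each cell re-simulates with a single parameter scaled and records the
    headline metrics; failures are recorded per cell (status column) and
    the sweep continues. Returns a long-format frame with columns
    parameter, multiplier, metric, value, status.
    """
    if multipliers is None:
        multipliers = default_multipliers()
    rows = []
    baseline_flat = {}
    from .params import _to_flat  # baseline values for the swept names

    flat = _to_flat(params)
    for name in names:
        if name not in flat:
            raise KeyError(f"unknown parameter {name!r}")
        if flat[name] <= 0:
            raise ValueError(f"cannot sweep non-positive parameter {name!r}")
        baseline_flat[name] = flat[name]

    for name in names:
        for mult in multipliers:
            status = "ok"
            values: dict[str, float] = {}
            try:
                p = set_flat(params, name, baseline_flat[name] * float(mult))
                traj = simulate(p, genotype=genotype, **simulate_kwargs)
                values = _headline(per_stimulus_metrics(traj))
            except (SolverError, ValueError) as exc:
                status = f"failed: {exc}"
            for metric in metrics:
                rows.append(
                    {
                        "parameter": name,
                        "multiplier": float(mult),
                        "metric": metric,
                        "value": values.get(metric, np.nan),
                        "status": status,
                    }
                )
    return pd.DataFrame(rows)
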