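"""Model parameters and configuration I/O.

All quantities are stored internally in seconds and µM. The canonical
parameter table mixes ms and s for the Ca²⁺-transient timing constants;
conversion happens in :func:`load_parameters` / :func:`dump_parameters`,
which speak the flat-file convention (ms for ``gauss_mean``, ``gauss_sd``,
``km``, ``t0``; s for ``tau``).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import yaml

GENOTYPES = ("wt", "doc2_ko", "syt7_ko", "dko")


@dataclass(frozen=True)
class SensorParams:
    """Ca²⁺-binding parameters of one sensor (syt1, Doc2α or syt7).

    Parameters
    ----------
    n : int
        Ion-binding capacity (number of Ca²⁺ binding sites).
    k_plus : float
        Association rate constant, µM⁻¹ s⁻¹.
    k_minus : float
        Dissociation rate constant, s⁻¹. If ``kd`` is supplied this is
        derived as ``k_plus * kd``; a conflicting explicit value loses and
        triggers a warning.
    kd : float or None
        Dissociation constant, µM (optional).
    b : float
        Cooperativity factor applied to successive unbinding steps,
        0 < b ≤ 1.
    f : float
        Per-ion multiplier on the rate the sensor modulates (fusion for
        syt1/Doc2α, docking/undocking for syt7).
    """

    n: int
    k_plus: float
    k_minus: float | None = None
    kd: float | None = None
    b: float = 0.5
    f: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sensor capacity must be >= 1, got {self.n}")
        if self.k_plus < 0:
            raise ValueError("k_plus must be non-negative")
        if not (0.0 < self.b <= 1.0):
            raise ValueError(f"cooperativity factor b must be in (0, 1], got {self.b}")
        if self.f <= 0:
            raise ValueError("rate multiplier f must be positive")
        if self.kd is not None:
            derived = self.k_plus * self.kd
            if self.k_minus is not None and abs(self.k_minus - derived) > 1e-9 * max(derived, 1.0):
                warnings.warn(
                    f"k_minus={self.k_minus} inconsistent with k_plus*kd={derived}; "
                    "using the value derived from kd",
                    stacklevel=2,
                )
            object.__setattr__(self, "k_minus", derived)
        if self.k_minus is None:
            raise ValueError("either k_minus or kd must be given")
        if self.k_minus < 0:
            raise ValueError("k_minus must be non-negative")


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol: ``n_aps`` action potentials at ``freq`` Hz.

    ``tail`` is how far the simulation runs past the last AP onset; the
    default equals one 20-Hz inter-stimulus interval so the last stimulus
    window is complete.
    """

    n_aps: int = 10
    freq: float = 20.0
    tail: float = 0.05

    def __post_init__(self) -> None:
        if self.n_aps < 1:
            raise ValueError("protocol needs at least one AP")
        if self.freq <= 0:
            raise ValueError("stimulation frequency must be positive")

    @property
    def isi(self) -> float:
        """Inter-stimulus interval (s)."""
        return 1.0 / self.freq

    @property
    def onsets(self) -> tuple[float, ...]:
        return tuple(k / self.freq for k in range(self.n_aps))

    @property
    def t_end(self) -> float:
        return (self.n_aps - 1) / self.freq + self.tail


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the release-site model.

    Times in s, concentrations in µM, first-order rates in s⁻¹, second-order
    rates in µM⁻¹ s⁻¹.
    """

    n_sites: int = 200
    k_tet: float = 7.0
    k_untet: float = 7.0
    k_docking: float = 5.0
    k_undocking: float = 5.0
    l_plus: float = 3.5e-4

    # Ca2+ transient
    amplitude_ap: float = 30.0          # µM, synchronous Gaussian peak
    amplitude_residual: float = 0.75    # µM
    tau_residual: float = 0.2           # s
    km_smooth: float = 0.1e-3           # s
    ca_rest: float = 0.05               # µM
    t0_offset: float = 1.6e-3           # s, residual onset after AP onset
    gauss_mean: float = 1.5e-3          # s, synchronous peak after AP onset
    gauss_sd: float = 0.2e-3            # s

    syt1: SensorParams = field(
        default_factory=lambda: SensorParams(n=5, k_plus=140.0, k_minus=4000.0, b=0.5, f=27.98)
    )
    doc2: SensorParams = field(
        default_factory=lambda: SensorParams(n=2, k_plus=28.0, kd=1.5, b=0.5, f=16.0)
    )
    syt7: SensorParams = field(
        default_factory=lambda: SensorParams(n=2, k_plus=28.0, kd=1.5, b=0.5, f=10.0)
    )

    protocol: Protocol = field(default_factory=Protocol)

    def __post_init__(self) -> None:
        for name in ("n_sites", "k_tet", "k_untet", "k_docking", "k_undocking",
                     "l_plus", "amplitude_ap", "amplitude_residual",
                     "tau_residual", "km_smooth", "gauss_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ca_rest < 0:
            raise ValueError("ca_rest must be non-negative")

    def with_genotype(self, genotype: str) -> "ModelParameters":
        """Return a copy with the knockout preset applied.

        ``doc2_ko`` zeroes the Doc2α association rate; ``syt7_ko`` sets the
        syt7 per-ion docking multiplier to 1 (Ca²⁺ binding still occurs but
        has no effect); ``dko`` applies both.
        """
        g = genotype.lower().replace("-", "_")
        if g == "wt":
            return self
        if g == "doc2_ko":
            return replace(self, doc2=replace(self.doc2, k_plus=0.0, kd=None))
        if g == "syt7_ko":
            return replace(self, syt7=replace(self.syt7, f=1.0))
        if g == "dko":
            return self.with_genotype("doc2_ko").with_genotype("syt7_ko")
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


def default_parameters() -> ModelParameters:
    """The canonical parameter set (all defaults)."""
    return ModelParameters()


# ---------------------------------------------------------------------------
# flat-file representation

_MS = 1e-3

_SENSOR_KEYS = {"syt1": "1", "doc2": "2", "syt7": "7"}


def _to_flat(p: ModelParameters) -> dict[str, Any]:
    d: dict[str, Any] = {
        "n_sites": p.n_sites,
        "k_tet": p.k_tet,
        "k_untet": p.k_untet,
        "k_docking": p.k_docking,
        "k_undocking": p.k_undocking,
        "l_plus": p.l_plus,
        "amplitude": p.amplitude_ap,
        "residual_amplitude": p.amplitude_residual,
        "tau": p.tau_residual,
        "km": p.km_smooth / _MS,
        "ca_rest": p.ca_rest,
        "t0": p.t0_offset / _MS,
        "gauss_mean": p.gauss_mean / _MS,
        "gauss_sd": p.gauss_sd / _MS,
        "n_aps": p.protocol.n_aps,
        "freq": p.protocol.freq,
    }
    for attr, suff in _SENSOR_KEYS.items():
        s: SensorParams = getattr(p, attr)
        d[f"n_{suff}"] = s.n
        d[f"k_{suff}_plus"] = s.k_plus
        d[f"k_{suff}_minus"] = s.k_minus
        if s.kd is not None:
            d[f"kd_{suff}"] = s.kd
        d[f"b_{suff}"] = s.b
        d[f"f_{suff}"] = s.f
    return d


def _from_flat(d: dict[str, Any]) -> ModelParameters:
    base = default_parameters()
    d = dict(d)

    def pop(key: str, default: Any) -> Any:
        return d.pop(key, default)

    sensors = {}
    for attr, suff in _SENSOR_KEYS.items():
        s: SensorParams = getattr(base, attr)
        kd = pop(f"kd_{suff}", s.kd)
        k_minus = pop(f"k_{suff}_minus", None)
        if kd is None and k_minus is None:
            k_minus = s.k_minus
        sensors[attr] = SensorParams(
            n=int(pop(f"n_{suff}", s.n)),
            k_plus=float(pop(f"k_{suff}_plus", s.k_plus)),
            k_minus=None if k_minus is None else float(k_minus),
            kd=None if kd is None else float(kd),
            b=float(pop(f"b_{suff}", s.b)),
            f=float(pop(f"f_{suff}", s.f)),
        )
    proto = Protocol(
        n_aps=int(pop("n_aps", base.protocol.n_aps)),
        freq=float(pop("freq", base.protocol.freq)),
        tail=float(pop("tail", base.protocol.tail)),
    )
    params = ModelParameters(
        n_sites=int(pop("n_sites", base.n_sites)),
        k_tet=float(pop("k_tet", base.k_tet)),
        k_untet=float(pop("k_untet", base.k_untet)),
        k_docking=float(pop("k_docking", base.k_docking)),
        k_undocking=float(pop("k_undocking", base.k_undocking)),
        l_plus=float(pop("l_plus", base.l_plus)),
        amplitude_ap=float(pop("amplitude", base.amplitude_ap)),
        amplitude_residual=float(pop("residual_amplitude", base.amplitude_residual)),
        tau_residual=float(pop("tau", base.tau_residual)),
        km_smooth=float(pop("km", base.km_smooth / _MS)) * _MS,
        ca_rest=float(pop("ca_rest", base.ca_rest)),
        t0_offset=float(pop("t0", base.t0_offset / _MS)) * _MS,
        gauss_mean=float(pop("gauss_mean", base.gauss_mean / _MS)) * _MS,
        gauss_sd=float(pop("gauss_sd", base.gauss_sd / _MS)) * _MS,
        **sensors,
        protocol=proto,
    )
    if d:
        raise ValueError(f"unknown parameter keys: {sorted(d)}")
    return params


def load_parameters(path: str) -> ModelParameters:
    """Load a flat YAML/JSON key-value parameter file; missing keys default."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("parameter file must be a flat mapping")
    return _from_flat(data)


def dump_parameters(params: ModelParameters, path: str | None = None) -> str:
    """Serialize parameters to the flat YAML convention; return the text."""
    text = yaml.safe_dump(_to_flat(params), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def set_flat(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one flat-named parameter replaced.

    Accepts the same keys as the flat file (``f_2``, ``k_docking``,
    ``amplitude`` ...). Sensor ``kd`` entries are dropped when the
    corresponding ``k_minus`` is set directly, and ``k_minus`` is re-derived
    when ``kd`` or ``k_plus`` is set.
    """
    flat = _to_flat(params)
    if name not in flat:
        raise KeyError(f"unknown parameter {name!r}")
    flat[name] = value
    for suff in _SENSOR_KEYS.values():
        if name == f"k_{suff}_minus":
            flat.pop(f"kd_{suff}", None)
        elif name in (f"kd_{suff}", f"k_{suff}_plus") and f"kd_{suff}" in flat:
            flat.pop(f"k_{suff}_minus", None)
    return _from_flat(flat)


SWEEPABLE_DEFAULT = (
    "f_2", "f_7", "k_tet", "k_docking", "amplitude", "residual_amplitude", "tau",
)
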