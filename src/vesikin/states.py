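"""Enumeration of release-site and syt7 state spaces.

A release site is empty (``E[d2]``), holds a tethered vesicle (``T[d2]``)
or a docked vesicle (``D[d2,s1]``), where ``d2`` counts Ca²⁺ ions on Doc2α
(0–2) and ``s1`` ions on syt1 (0–5). Docked states with ``d2 + s1 > 5``
violate the shared five-ion budget; they are kept in the enumeration so the
state vector has its canonical dimension of 24, but the kinetics give them
no inbound Ca²⁺-binding rate and they stay unoccupied.

The ordering is fixed — E[0..2], T[0..2], then D[d2,s1] row-major with d2
outer — so intensity matrices and trajectories are bit-comparable between
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_D2 = 3          # Doc2α occupancies 0..2
N_S1 = 6          # syt1 occupancies 0..5
ION_BUDGET = 5    # max total ions on syt1 + Doc2α of a docked site
N_STATES = 2 * N_D2 + N_D2 * N_S1   # 24
N_SYT7 = 3

SYT7_LABELS = tuple(f"S[{s7}]" for s7 in range(N_SYT7))


def _labels() -> tuple[str, ...]:
    out = [f"E[{d2}]" for d2 in range(N_D2)]
    out += [f"T[{d2}]" for d2 in range(N_D2)]
    out += [f"D[{d2},{s1}]" for d2 in range(N_D2) for s1 in range(N_S1)]
    return tuple(out)


@dataclass(frozen=True)
class ReleaseSiteStateSpace:
    """Ordered label ↔ index bijection over the 24 release-site states."""

    labels: tuple[str, ...] = field(default_factory=_labels)

    def __post_init__(self) -> None:
        if len(self.labels) != N_STATES:
            raise ValueError(f"expected {N_STATES} states, got {len(self.labels)}")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def syt7_labels(self) -> tuple[str, ...]:
        return SYT7_LABELS

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def label(self, i: int) -> str:
        return self.labels[i]

    # -- structured indexing -------------------------------------------------
    @staticmethod
    def empty_index(d2: int) -> int:
        _check_d2(d2)
        return d2

    @staticmethod
    def tethered_index(d2: int) -> int:
        _check_d2(d2)
        return N_D2 + d2

    @staticmethod
    def docked_index(d2: int, s1: int) -> int:
        _check_d2(d2)
        if not 0 <= s1 < N_S1:
            raise ValueError(f"s1 must be in 0..{N_S1 - 1}, got {s1}")
        return 2 * N_D2 + d2 * N_S1 + s1

    # -- masks ---------------------------------------------------------------
    @property
    def empty_mask(self) -> np.ndarray:
        m = np.zeros(N_STATES, dtype=bool)
        m[:N_D2] = True
        return m

    @property
    def tethered_mask(self) -> np.ndarray:
        m = np.zeros(N_STATES, dtype=bool)
        m[N_D2:2 * N_D2] = True
        return m

    @property
    def docked_mask(self) -> np.ndarray:
        m = np.zeros(N_STATES, dtype=bool)
        m[2 * N_D2:] = True
        return m

    @property
    def forbidden_mask(self) -> np.ndarray:
        """Docked states whose total bound-ion count exceeds the budget."""
        m = np.zeros(N_STATES, dtype=bool)
        for d2 in range(N_D2):
            for s1 in range(N_S1):
                if d2 + s1 > ION_BUDGET:
                    m[self.docked_index(d2, s1)] = True
        return m

    def docked_ions(self) -> list[tuple[int, int]]:
        """(d2, s1) pairs in enumeration order for the docked block."""
        return [(d2, s1) for d2 in range(N_D2) for s1 in range(N_S1)]


def _check_d2(d2: int) -> None:
    if not 0 <= d2 < N_D2:
        raise ValueError(f"d2 must be in 0..{N_D2 - 1}, got {d2}")


def enumerate_states() -> ReleaseSiteStateSpace:
    """Return the canonical state space (pure; identical on every call)."""
    return ReleaseSiteStateSpace()
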