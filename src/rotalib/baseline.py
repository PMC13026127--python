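"""Dunbrack-style backbone-dependent frequency baseline.

Each chi angle is reduced to one of the three canonical states g+ / t / g-
(near +60, 180 and -60 degrees), residues are binned on the 10-degree phi/psi
grid, and prediction returns the circular-mean chi vector of the most
frequent state tuple in the residue's bin.  No backbone interpolation is
applied.  Terminal non-rotameric chi angles are binned with the same 3-state
rule; this is a documented simplification of published conventions.

State boundaries: g+ = [0, 120), t = [120, 180] u (-180, -120), g- = [-120, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .context import bin_angle
from .geometry import ChiSet, NCHI, wrap_angle

__all__ = ["chi_state", "BaselineTable", "build_baseline", "predict_baseline",
           "STATE_NAMES"]

#: Lexicographic tie-break order g+ < t < g-.
STATE_NAMES = ("g+", "t", "g-")


class BaselineError(ValueError):
    pass


def chi_state(angle: float) -> int:
    """Canonical state index of one chi angle (0 = g+, 1 = t, 2 = g-)."""
    a = wrap_angle(angle)
    if 0.0 <= a < 120.0:
        return 0
    if a >= 120.0 or a < -120.0:
        return 1
    return 2


@dataclass
class _StateEntry:
    count: int = 0
    sin_sum: np.ndarray | None = None
    cos_sum: np.ndarray | None = None

    def add(self, chi: np.ndarray) -> None:
        rad = np.radians(chi)
        if self.sin_sum is None:
            self.sin_sum = np.zeros_like(rad)
            self.cos_sum = np.zeros_like(rad)
        self.sin_sum += np.sin(rad)
        self.cos_sum += np.cos(rad)
        self.count += 1

    def mean_chi(self) -> np.ndarray:
        return np.array([wrap_angle(np.degrees(np.arctan2(s, c)))
                         for s, c in zip(self.sin_sum, self.cos_sum)])


@dataclass
class BaselineTable:
    """(aa, phi-bin, psi-bin) -> {state tuple -> counts and running means}."""

    bin_width: float = 10.0
    table: dict = field(default_factory=dict)

    def bin_of(self, phi: float, psi: float) -> tuple[int, int]:
        return (bin_angle(phi, self.bin_width), bin_angle(psi, self.bin_width))


def build_baseline(train: Sequence, bin_width: float = 10.0) -> BaselineTable:
    """Accumulate state-tuple frequencies per (aa, phi-bin, psi-bin)."""
    if not train:
        raise BaselineError("empty training set")
    tab = BaselineTable(bin_width=bin_width)
    for res in train:
        if res.aa_type not in NCHI:
            continue
        if res.phi is None or res.psi is None:
            continue
        chi = np.asarray(res.chi, dtype=float)
        states = tuple(chi_state(c) for c in chi)
        key = (res.aa_type,) + tab.bin_of(res.phi, res.psi)
        entry = tab.table.setdefault(key, {}).setdefault(states, _StateEntry())
        entry.add(chi)
    return tab


def predict_baseline(table: BaselineTable, aa: str, phi: float,
                     psi: float) -> ChiSet | None:
    """Mean chi of the most frequent state tuple, or None when out of grid.

    Ties are broken by lexicographic state order (g+ < t < g-).
    """
    key = (aa,) + table.bin_of(phi, psi)
    entry = table.table.get(key)
    if not entry:
        return None
    best = min(entry.items(), key=lambda kv: (-kv[1].count, kv[0]))
    return ChiSet(aa, tuple(best[1].mean_chi()))
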