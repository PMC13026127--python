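"""Discretized context grids: periodic phi/psi axes, optional categorical
features, and the non-sequential spatial-contact descriptor.

A context vector x = (x1, ..., xd) locates a residue on a regular grid:
periodic angle axes cover (-180, 180] in uniform bins (default width 10
degrees), categorical axes index an ordered label list.  The optional
``global_bins`` set restricts the prediction domain to bins observed anywhere
in the training corpus, so sparsely trained amino acids can still be queried
at any backbone configuration the corpus supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "AxisSpec",
    "ContextGrid",
    "bin_angle",
    "encode_context",
    "nearest_contact_class",
    "HYDROPHOBIC_AA",
    "DEFAULT_CLASS_MAP",
    "NO_CONTACT",
    "backbone_grid",
    "backbone_contact_grid",
]

#: Reserved category for residues with no spatial contact within the radius.
NO_CONTACT = "none"

#: Default binary biochemical classification of contact residues.
HYDROPHOBIC_AA = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"})

DEFAULT_CLASS_MAP: dict[str, str] = {}


def _default_class_map() -> dict[str, str]:
    aas = ("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
           "SER THR TRP TYR VAL").split()
    return {aa: ("hydrophobic" if aa in HYDROPHOBIC_AA else "non_hydrophobic")
            for aa in aas}


DEFAULT_CLASS_MAP.update(_default_class_map())


class ContextError(ValueError):
    pass


@dataclass(frozen=True)
class AxisSpec:
    """One dimension of the context grid."""

    name: str
    kind: str  # "periodic_angle" | "categorical"
    bin_width: float | None = None
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "periodic_angle":
            if not self.bin_width or abs(360.0 / self.bin_width - round(360.0 / self.bin_width)) > 1e-9:
                raise ContextError(f"axis {self.name}: bin width must divide 360")
        elif self.kind == "categorical":
            if len(self.categories) < 2:
                raise ContextError(f"axis {self.name}: need >= 2 categories")
        else:
            raise ContextError(f"unknown axis kind {self.kind!r}")

    @property
    def n_bins(self) -> int:
        if self.kind == "periodic_angle":
            return int(round(360.0 / self.bin_width))
        return len(self.categories)

    @property
    def periodic(self) -> bool:
        return self.kind == "periodic_angle"

    def category_index(self, label: str) -> int:
        try:
            return self.categories.index(label)
        except ValueError:
            raise ContextError(
                f"axis {self.name}: unknown category {label!r}") from None


@dataclass
class ContextGrid:
    """Ordered axes plus the optional global support of observed bins."""

    axes: tuple[AxisSpec, ...]
    global_bins: set[tuple[int, ...]] | None = None

    def __post_init__(self):
        self.axes = tuple(self.axes)
        if self.global_bins is not None:
            for b in self.global_bins:
                self._check(b)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(ax.n_bins for ax in self.axes)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def _check(self, x: tuple[int, ...]) -> None:
        if len(x) != len(self.axes):
            raise ContextError("bin vector length != number of axes")
        for xi, ax in zip(x, self.axes):
            if not (0 <= int(xi) < ax.n_bins):
                raise ContextError(f"bin index {xi} out of range on {ax.name}")

    def contains(self, x: tuple[int, ...]) -> bool:
        """Whether x is in the (global) prediction domain."""
        self._check(x)
        return self.global_bins is None or tuple(int(v) for v in x) in self.global_bins

    def set_global_bins(self, bins: Iterable[tuple[int, ...]]) -> None:
        self.global_bins = {tuple(int(v) for v in b) for b in bins}
        for b in self.global_bins:
            self._check(b)


def backbone_grid(bin_width: float = 10.0) -> ContextGrid:
    """The plain (phi, psi) grid of a classical backbone-dependent library."""
    return ContextGrid((AxisSpec("phi", "periodic_angle", bin_width),
                        AxisSpec("psi", "periodic_angle", bin_width)))


def backbone_contact_grid(bin_width: float = 10.0,
                          categories: Sequence[str] = ("hydrophobic",
                                                       "non_hydrophobic",
                                                       NO_CONTACT)) -> ContextGrid:
    """(phi, psi, contact-class) grid used for the context-conditioned model."""
    return ContextGrid((AxisSpec("phi", "periodic_angle", bin_width),
                        AxisSpec("psi", "periodic_angle", bin_width),
                        AxisSpec("contact", "categorical",
                                 categories=tuple(categories))))


def bin_angle(angle: float, width: float = 10.0) -> int:
    """Half-open periodic binning: index = floor((wrap(angle)+180)/width).

    Bins are [lo, lo+width); +180 wraps onto the first bin.
    """
    n = int(round(360.0 / width))
    if abs(360.0 / width - n) > 1e-9:
        raise ContextError("bin width must divide 360")
    return int(np.floor((wrap_angle(angle) + 180.0) / width)) % n


def encode_context(residue, grid: ContextGrid,
                   contact_class: str | None = None) -> tuple[int, ...]:
    """Map a residue to its bin vector x on ``grid``.

    ``contact_class`` must be supplied (or present as ``residue.contact_class``)
    exactly when the grid has a categorical axis.
    """
    x: list[int] = []
    for ax in grid.axes:
        if ax.kind == "periodic_angle":
            val = getattr(residue, ax.name, None)
            if val is None:
                raise ContextError(f"residue lacks defined {ax.name}")
            x.append(bin_angle(val, ax.bin_width))
        else:
            label = contact_class
            if label is None:
                label = getattr(residue, "contact_class", None)
            if label is None:
                raise ContextError(
                    f"grid axis {ax.name} requires a contact class")
            x.append(ax.category_index(label))
    return tuple(x)


def _residue_atoms(residue, sidechain_only: bool) -> np.ndarray:
    atoms: list[np.ndarray] = []
    if not sidechain_only:
        atoms.extend(np.asarray(v, float) for v in residue.backbone_atoms.values())
    atoms.extend(np.asarray(v, float) for v in residue.sidechain_atoms.values())
    if not atoms:
        raise ContextError("residue has no coordinates")
    return np.array(atoms)


def nearest_contact_class(residue, structure_residues: Sequence,
                          radius: float = 5.5,
                          class_map: Mapping[str, str] = DEFAULT_CLASS_MAP,
                          exclude_window: int = 1,
                          query_atoms: str = "sidechain") -> str:
    """Biochemical class of the spatially nearest non-sequential residue.

    Candidates exclude the query itself and its sequence neighbours within
    ``exclude_window`` positions on the same chain.  Distance is the minimum
    heavy-atom distance from the query's sidechain atoms (or all atoms when
    ``query_atoms='all'``) to any heavy atom of the candidate.  The closed
    ball is used: a contact at exactly ``radius`` counts.  Returns the
    reserved class ``"none"`` when no candidate lies within the radius.
    """
    q = _residue_atoms(residue, sidechain_only=(query_atoms == "sidechain"))
    best_d = np.inf
    best_aa = None
    for other in structure_residues:
        if other is residue:
            continue
        if (other.chain_id == residue.chain_id
                and abs(other.seq_index - residue.seq_index) <= exclude_window):
            continue
        o = _residue_atoms(other, sidechain_only=False)
        d = float(np.sqrt(
            np.min(np.sum((q[:, None, :] - o[None, :, :]) ** 2, axis=2))))
        if d < best_d:
            best_d, best_aa = d, other.aa_type
    if best_aa is None or best_d > radius:
        return NO_CONTACT
    return class_map.get(best_aa, "non_hydrophobic")
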