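"""Sidechain geometry: dihedral measurement, canonical-frame reconstruction,
conformation RMSD and circular arithmetic.

All angles are degrees wrapped to (-180, 180]; coordinates are Angstroms in a
right-handed frame.  Sidechain conformations are expressed in a shared
canonical backbone frame (N, CA, C at fixed ideal positions) so that the RMSD
between two conformations of the same amino acid depends on their chi angles
only and needs no superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NCHI",
    "CHI_ATOMS",
    "SIDECHAIN_ATOMS",
    "BACKBONE_ATOMS",
    "STANDARD_AA",
    "ChiSet",
    "Conformation3D",
    "wrap_angle",
    "dihedral",
    "chi_angles",
    "build_sidechain_atoms",
    "reconstruct_sidechain",
    "conformation_rmsd",
    "circular_mean",
    "canonical_backbone_frame",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, undefined circular mean, ...)."""


BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Number of chi dihedrals per standard amino acid (GLY/ALA have none and are
#: never modelled as rotameric).
NCHI: dict[str, int] = {
    "ARG": 4, "LYS": 4,
    "GLN": 3, "GLU": 3, "MET": 3,
    "ASN": 2, "ASP": 2, "HIS": 2, "ILE": 2, "LEU": 2,
    "PHE": 2, "PRO": 2, "TRP": 2, "TYR": 2,
    "CYS": 1, "SER": 1, "THR": 1, "VAL": 1,
}

STANDARD_AA = tuple(sorted(NCHI))

#: IUPAC chi-defining atom quadruples.  TRP chi2 runs to CD1.
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ARG": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "GLU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "LYS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")),
    "MET": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "PRO": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
}

# Sidechain internal-coordinate table (Engh-Huber-like ideal values).
# Each entry: atom -> (ref_a, ref_b, ref_c, bond A, angle deg, torsion spec)
# placing `atom` bonded to ref_c with angle(ref_b, ref_c, atom) and dihedral
# (ref_a, ref_b, ref_c, atom).  Torsion spec is either ("chi", k) meaning the
# k-th chi (1-based), ("chi+", k, offset) meaning chi_k plus a fixed branch
# offset, or ("fix", value) for rigid-group atoms.  The chi-bearing atom of
# each quadruple in CHI_ATOMS is placed with exactly that quadruple as its
# NeRF reference, so measurement round-trips reconstruction exactly.
_Z = {
    "ARG": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2)),
        ("NE", "CB", "CG", "CD", 1.460, 112.0, ("chi", 3)),
        ("CZ", "CG", "CD", "NE", 1.330, 124.2, ("chi", 4)),
        ("NH1", "CD", "NE", "CZ", 1.330, 120.0, ("fix", 0.0)),
        ("NH2", "CD", "NE", "CZ", 1.330, 120.0, ("fix", 180.0)),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.520, 112.6, ("chi", 1)),
        ("OD1", "CA", "CB", "CG", 1.230, 120.8, ("chi", 2)),
        ("ND2", "CA", "CB", "CG", 1.330, 116.4, ("chi+", 2, 180.0)),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.520, 112.6, ("chi", 1)),
        ("OD1", "CA", "CB", "CG", 1.250, 118.4, ("chi", 2)),
        ("OD2", "CA", "CB", "CG", 1.250, 118.4, ("chi+", 2, 180.0)),
    ],
    "CYS": [
        ("SG", "N", "CA", "CB", 1.810, 114.4, ("chi", 1)),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
        ("CD", "CA", "CB", "CG", 1.520, 112.6, ("chi", 2)),
        ("OE1", "CB", "CG", "CD", 1.230, 120.8, ("chi", 3)),
        ("NE2", "CB", "CG", "CD", 1.330, 116.4, ("chi+", 3, 180.0)),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
        ("CD", "CA", "CB", "CG", 1.520, 112.6, ("chi", 2)),
        ("OE1", "CB", "CG", "CD", 1.250, 118.4, ("chi", 3)),
        ("OE2", "CB", "CG", "CD", 1.250, 118.4, ("chi+", 3, 180.0)),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.500, 113.8, ("chi", 1)),
        ("ND1", "CA", "CB", "CG", 1.380, 122.7, ("chi", 2)),
        ("CD2", "CA", "CB", "CG", 1.360, 131.1, ("chi+", 2, 180.0)),
        ("CE1", "CB", "CG", "ND1", 1.320, 109.3, ("fix", 180.0)),
        ("NE2", "CB", "CG", "CD2", 1.370, 107.2, ("fix", 180.0)),
    ],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1)),
        ("CG2", "N", "CA", "CB", 1.530, 110.5, ("chi+", 1, 122.0)),
        ("CD1", "CA", "CB", "CG1", 1.510, 113.8, ("chi", 2)),
    ],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1)),
        ("CD1", "CA", "CB", "CG", 1.520, 110.5, ("chi", 2)),
        ("CD2", "CA", "CB", "CG", 1.520, 110.5, ("chi+", 2, 122.0)),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2)),
        ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi", 3)),
        ("NZ", "CG", "CD", "CE", 1.490, 111.9, ("chi", 4)),
    ],
    "MET": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
        ("SD", "CA", "CB", "CG", 1.800, 112.7, ("chi", 2)),
        ("CE", "CB", "CG", "SD", 1.790, 100.2, ("chi", 3)),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.500, 113.8, ("chi", 1)),
        ("CD1", "CA", "CB", "CG", 1.390, 120.7, ("chi", 2)),
        ("CD2", "CA", "CB", "CG", 1.390, 120.7, ("chi+", 2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.390, 120.7, ("fix", 180.0)),
        ("CE2", "CB", "CG", "CD2", 1.390, 120.7, ("fix", 180.0)),
        ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, ("fix", 0.0)),
    ],
    "PRO": [
        ("CG", "N", "CA", "CB", 1.490, 104.5, ("chi", 1)),
        ("CD", "CA", "CB", "CG", 1.500, 106.1, ("chi", 2)),
    ],
    "SER": [
        ("OG", "N", "CA", "CB", 1.420, 111.1, ("chi", 1)),
    ],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.430, 109.6, ("chi", 1)),
        ("CG2", "N", "CA", "CB", 1.520, 110.5, ("chi+", 1, 120.0)),
    ],
    "TRP": [
        ("CG", "N", "CA", "CB", 1.500, 113.8, ("chi", 1)),
        ("CD1", "CA", "CB", "CG", 1.370, 127.0, ("chi", 2)),
        ("CD2", "CA", "CB", "CG", 1.430, 126.6, ("chi+", 2, 180.0)),
        ("NE1", "CB", "CG", "CD1", 1.380, 110.2, ("fix", 180.0)),
        ("CE2", "CB", "CG", "CD2", 1.410, 107.2, ("fix", 180.0)),
        ("CE3", "CB", "CG", "CD2", 1.400, 133.9, ("fix", 0.0)),
        ("CZ2", "CG", "CD2", "CE2", 1.400, 122.4, ("fix", 180.0)),
        ("CZ3", "CG", "CD2", "CE3", 1.390, 118.8, ("fix", 180.0)),
        ("CH2", "CD2", "CE2", "CZ2", 1.370, 117.5, ("fix", 0.0)),
    ],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.500, 113.8, ("chi", 1)),
        ("CD1", "CA", "CB", "CG", 1.390, 120.7, ("chi", 2)),
        ("CD2", "CA", "CB", "CG", 1.390, 120.7, ("chi+", 2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.390, 120.7, ("fix", 180.0)),
        ("CE2", "CB", "CG", "CD2", 1.390, 120.7, ("fix", 180.0)),
        ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, ("fix", 0.0)),
        ("OH", "CD1", "CE1", "CZ", 1.380, 120.0, ("fix", 180.0)),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.520, 110.5, ("chi", 1)),
        ("CG2", "N", "CA", "CB", 1.520, 110.5, ("chi+", 1, 122.0)),
    ],
}

#: Heavy sidechain atoms, CB first, in deterministic placement order.
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    aa: ("CB",) + tuple(row[0] for row in rows) for aa, rows in _Z.items()
}

# CB placement off the backbone: bond CA-CB 1.530 A, angle N-CA-CB 110.5 deg,
# improper dihedral C-N-CA-CB ~ 122.6 deg (L-amino acid handedness).
_CB_PARAMS = (1.530, 110.5, 122.6)


@dataclass(frozen=True)
class ChiSet:
    """An ordered chi vector for one amino acid."""

    aa_type: str
    chi: tuple[float, ...]

    def __post_init__(self):
        n = NCHI.get(self.aa_type)
        if n is None:
            raise GeometryError(f"{self.aa_type} has no chi angles")
        if len(self.chi) != n:
            raise GeometryError(
                f"{self.aa_type} needs {n} chi angles, got {len(self.chi)}")
        object.__setattr__(self, "chi", tuple(wrap_angle(c) for c in self.chi))


@dataclass(frozen=True)
class Conformation3D:
    """Sidechain heavy atoms of one residue in the canonical backbone frame."""

    aa_type: str
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.atom_names), 3):
            raise GeometryError("coords shape does not match atom names")
        object.__setattr__(self, "coords", coords)


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Looking down the p2->p3 bond, a clockwise rotation of the far bond
    relative to the near bond is positive.  Result in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear or coincident points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF: place d with |cd|=bond, angle(b,c,d)=angle, dihedral(a,b,c,d)=torsion."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def canonical_backbone_frame() -> dict[str, np.ndarray]:
    """Ideal N, CA, C positions shared by all reconstructed conformations."""
    n = np.zeros(3)
    ca = np.array([1.458, 0.0, 0.0])
    ang = np.radians(180.0 - 111.2)
    c = ca + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    return {"N": n, "CA": ca, "C": c}


_CANONICAL = canonical_backbone_frame()


def build_sidechain_atoms(aa_type: str, chi: Sequence[float],
                          n: np.ndarray, ca: np.ndarray,
                          c: np.ndarray) -> dict[str, np.ndarray]:
    """Place all heavy sidechain atoms given an arbitrary backbone N/CA/C."""
    if aa_type not in _Z:
        raise GeometryError(f"no sidechain template for {aa_type}")
    chi = [wrap_angle(x) for x in chi]
    if len(chi) != NCHI[aa_type]:
        raise GeometryError(f"{aa_type} expects {NCHI[aa_type]} chi angles")
    pos: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                  "CA": np.asarray(ca, float),
                                  "C": np.asarray(c, float)}
    bond, angle, tors = _CB_PARAMS
    pos["CB"] = _place_atom(pos["C"], pos["N"], pos["CA"], bond, angle, tors)
    for name, ra, rb, rc, bnd, ang, spec in _Z[aa_type]:
        if spec[0] == "chi":
            tor = chi[spec[1] - 1]
        elif spec[0] == "chi+":
            tor = chi[spec[1] - 1] + spec[2]
        else:
            tor = spec[1]
        pos[name] = _place_atom(pos[ra], pos[rb], pos[rc], bnd, ang, tor)
    return {k: v for k, v in pos.items() if k not in ("N", "CA", "C")}


def reconstruct_sidechain(aa_type: str, chis: "ChiSet | Sequence[float]") -> Conformation3D:
    """Deterministically rebuild the sidechain in the canonical frame.

    The same chi vector always yields identical coordinates, so two
    conformations can be compared by RMSD without superposition.
    """
    chi = chis.chi if isinstance(chis, ChiSet) else tuple(chis)
    atoms = build_sidechain_atoms(aa_type, chi, _CANONICAL["N"],
                                  _CANONICAL["CA"], _CANONICAL["C"])
    names = SIDECHAIN_ATOMS[aa_type]
    coords = np.array([atoms[a] for a in names])
    return Conformation3D(aa_type, names, coords)


def chi_angles(residue) -> ChiSet:
    """Measure the chi vector of a residue record from its atom coordinates."""
    aa = residue.aa_type
    if aa not in CHI_ATOMS:
        raise GeometryError(f"{aa} is not a rotameric amino acid")
    atoms: dict[str, np.ndarray] = {}
    atoms.update(residue.backbone_atoms)
    atoms.update(residue.sidechain_atoms)
    chis = []
    for quad in CHI_ATOMS[aa]:
        try:
            pts = [atoms[name] for name in quad]
        except KeyError as exc:
            raise GeometryError(f"{aa} missing atom {exc} for chi") from exc
        chis.append(dihedral(*pts))
    return ChiSet(aa, tuple(chis))


def conformation_rmsd(a: Conformation3D, b: Conformation3D) -> float:
    """RMSD over matched heavy atoms in the shared canonical frame (no fit)."""
    if a.aa_type != b.aa_type:
        raise GeometryError("RMSD requires identical amino-acid types")
    if a.atom_names != b.atom_names:
        raise GeometryError("atom sets differ")
    d = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def circular_mean(angles: Sequence[float],
                  weights: Sequence[float] | None = None) -> float:
    """Weighted circular mean of angles in degrees, wrapped to (-180, 180]."""
    ang = np.radians(np.asarray(angles, dtype=float))
    if ang.size == 0:
        raise GeometryError("circular mean of empty set")
    if weights is None:
        w = np.ones_like(ang)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be nonnegative with positive sum")
    s = float(np.sum(w * np.sin(ang)))
    c = float(np.sum(w * np.cos(ang)))
    if np.hypot(s, c) / w.sum() < 1e-12:
        raise GeometryError("circular mean undefined (zero resultant)")
    return wrap_angle(np.degrees(np.arctan2(s, c)))
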