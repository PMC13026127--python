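"""Synthetic test-bed generators: planted rotamer clusters, smooth
ground-truth probability fields over phi/psi, toy contact structures and
polypeptide chains for parser round-trips.

Every generator is seed-deterministic and verifies its planted properties
(separations, distances) after construction rather than assuming them.
Angular noise is wrapped normal, a close stand-in for a von Mises at the
small widths used here (sigma <= 30 degrees).  Backbone phi/psi are sampled
uniformly on the torus by default so every grid bin can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import default_threshold
from .geometry import (NCHI, build_sidechain_atoms,
                       canonical_backbone_frame, conformation_rmsd,
                       reconstruct_sidechain, wrap_angle, _place_atom)
from .structure_io import ResidueRecord

__all__ = [
    "GroundTruthField",
    "make_field",
    "sample_residues",
    "PlantedClusters",
    "planted_clusters",
    "planted_contact_structure",
    "build_chain_records",
]


class SyntheticError(ValueError):
    pass


def _per_diff(a, b):
    """Periodic difference in degrees, in [-180, 180)."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0


@dataclass
class GroundTruthField:
    """Smooth ground-truth rotamer probabilities over the phi/psi torus.

    Each rotamer's unnormalized weight surface is a constant base plus
    periodic Gaussian bumps; weights are normalized across rotamers at every
    (phi, psi) point.
    """

    aa_type: str
    rotamer_chis: np.ndarray          # (k, n_chi) mean chi per rotamer
    bumps: list                        # per rotamer: list of (phi0, psi0, width, amp)
    base: float
    noise_sigma: float                 # degrees, chi noise
    seed: int
    categories: tuple[str, ...] | None = None

    @property
    def n_rotamers(self) -> int:
        return len(self.rotamer_chis)

    def weights_at(self, phi, psi) -> np.ndarray:
        """Normalized rotamer weights at (phi, psi); vectorized over inputs."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        w = np.empty((self.n_rotamers,) + phi.shape)
        for r, blist in enumerate(self.bumps):
            acc = np.full(phi.shape, self.base)
            for (p0, s0, width, amp) in blist:
                d2 = _per_diff(phi, p0) ** 2 + _per_diff(psi, s0) ** 2
                acc = acc + amp * np.exp(-d2 / (2.0 * width * width))
            w[r] = acc
        return w / w.sum(axis=0, keepdims=True)

    def weights_on_grid(self, bin_width: float = 10.0) -> np.ndarray:
        """(k, n, n) field evaluated at bin centers."""
        n = int(round(360.0 / bin_width))
        centers = -180.0 + bin_width * (np.arange(n) + 0.5)
        pp, ss = np.meshgrid(centers, centers, indexing="ij")
        return self.weights_at(pp, ss)


def make_field(aa_type: str, n_rotamers: int, bump_spec: dict | None = None,
               seed: int = 0,
               categories: Sequence[str] | None = None) -> GroundTruthField:
    """Reproducible ground-truth field with well-separated rotamer chi means.

    Rotamer chi1 means are spread around the circle at least 60 degrees
    apart; bump centers/widths/amplitudes come from ``bump_spec`` (keys
    ``n_bumps``, ``width``, ``amp``, ``base``, ``noise_sigma``) or defaults.
    """
    if n_rotamers < 2:
        raise SyntheticError("need at least 2 rotamers")
    spec = {"n_bumps": 2, "width": 60.0, "amp": 4.0, "base": 0.25,
            "noise_sigma": 8.0}
    spec.update(bump_spec or {})
    rng = np.random.default_rng(seed)
    nchi = NCHI[aa_type]
    # chi1 means evenly spaced (separation >= 60 deg guaranteed for k <= 6)
    if n_rotamers > 6:
        raise SyntheticError("at most 6 rotamers keeps chi separation >= 60")
    start = rng.uniform(-180.0, 180.0)
    step = 360.0 / n_rotamers
    chis = np.zeros((n_rotamers, nchi))
    chis[:, 0] = [wrap_angle(start + r * step) for r in range(n_rotamers)]
    for k in range(1, nchi):
        chis[:, k] = rng.uniform(-180.0, 180.0, size=n_rotamers)
    sep = np.abs(_per_diff(chis[:, None, 0], chis[None, :, 0]))
    np.fill_diagonal(sep, 360.0)
    assert sep.min() >= 60.0 - 1e-6
    bumps = []
    for _ in range(n_rotamers):
        blist = []
        for _ in range(int(spec["n_bumps"])):
            blist.append((rng.uniform(-180, 180), rng.uniform(-180, 180),
                          spec["width"] * rng.uniform(0.7, 1.3),
                          spec["amp"] * rng.uniform(0.5, 1.5)))
        bumps.append(blist)
    return GroundTruthField(aa_type=aa_type, rotamer_chis=chis, bumps=bumps,
                            base=float(spec["base"]),
                            noise_sigma=float(spec["noise_sigma"]), seed=seed,
                            categories=tuple(categories) if categories else None)


def sample_residues(field: GroundTruthField, n: int, seed: int = 0,
                    chain_size: int = 1000,
                    chain_prefix: str = "S",
                    with_coordinates: bool = True,
                    return_labels: bool = False):
    """Draw residues from the field: phi/psi uniform on the torus, rotamer
    from the local weights, chi = rotamer mean + wrapped normal noise.

    Residues are grouped into synthetic chains of ``chain_size`` so
    chain-level splitting can be exercised.  Coordinates are reconstructed in
    the canonical frame so structure-level code paths run.
    """
    if n < 1:
        raise SyntheticError("n must be >= 1")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-180.0, 180.0, size=n)
    psi = rng.uniform(-180.0, 180.0, size=n)
    w = field.weights_at(phi, psi)          # (k, n)
    u = rng.uniform(size=n)
    labels = (np.cumsum(w, axis=0) < u[None, :]).sum(axis=0)
    labels = np.minimum(labels, field.n_rotamers - 1)
    noise = rng.normal(0.0, field.noise_sigma,
                       size=(n, field.rotamer_chis.shape[1]))
    frame = canonical_backbone_frame()
    o_pos = _place_atom(frame["N"], frame["CA"], frame["C"], 1.23, 120.5, 0.0)
    records = []
    for i in range(n):
        chi = tuple(wrap_angle(c) for c in
                    field.rotamer_chis[labels[i]] + noise[i])
        rec = ResidueRecord(
            aa_type=field.aa_type,
            chain_id=f"{chain_prefix}{i // chain_size}",
            seq_index=i % chain_size + 1,
            phi=float(phi[i]), psi=float(psi[i]), chi=chi)
        if with_coordinates:
            conf = reconstruct_sidechain(field.aa_type, chi)
            rec.backbone_atoms = {"N": frame["N"].copy(),
                                  "CA": frame["CA"].copy(),
                                  "C": frame["C"].copy(), "O": o_pos.copy()}
            rec.sidechain_atoms = dict(zip(conf.atom_names, conf.coords))
        if field.categories:
            rec.contact_class = field.categories[
                int(rng.integers(len(field.categories)))]
        records.append(rec)
    if return_labels:
        return records, labels
    return records


@dataclass
class PlantedClusters:
    aa_type: str
    records: list
    conformations: list
    labels: np.ndarray
    center_chis: np.ndarray
    threshold: float
    min_center_rmsd: float


def planted_clusters(aa_type: str, k: int, separation: float = 3.0,
                     spread: float = 3.0, n_per: int = 100,
                     seed: int = 0, max_tries: int = 500) -> PlantedClusters:
    """k chi-space centers with pairwise centroid RMSD >= separation * t,
    each surrounded by n_per members with wrapped-Gaussian chi noise.

    The separation is verified on the reconstructed centroids (assert, not
    assume); construction retries until it holds or fails loudly.
    """
    if k < 1:
        raise SyntheticError("k must be >= 1")
    t = default_threshold(aa_type)
    target = separation * t
    rng = np.random.default_rng(seed)
    nchi = NCHI[aa_type]
    centers = None
    for _ in range(max_tries):
        cand = rng.uniform(-180.0, 180.0, size=(k, nchi))
        confs = [reconstruct_sidechain(aa_type, c) for c in cand]
        ok = True
        dmin = np.inf
        for i in range(k):
            for j in range(i + 1, k):
                d = conformation_rmsd(confs[i], confs[j])
                dmin = min(dmin, d)
                if d < target:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            centers = cand
            min_rmsd = dmin if k > 1 else np.inf
            break
    if centers is None:
        raise SyntheticError(
            f"could not plant {k} centers at separation {separation}t "
            f"for {aa_type} in {max_tries} tries")
    labels = np.repeat(np.arange(k), n_per)
    noise = rng.normal(0.0, spread, size=(k * n_per, nchi))
    chis = np.array([centers[l] + noise[i] for i, l in enumerate(labels)])
    chis = np.vectorize(wrap_angle)(chis)
    records = []
    conformations = []
    for i, chi in enumerate(chis):
        records.append(ResidueRecord(
            aa_type=aa_type, chain_id="P", seq_index=i + 1,
            phi=float(rng.uniform(-180, 180)),
            psi=float(rng.uniform(-180, 180)), chi=tuple(chi)))
        conformations.append(reconstruct_sidechain(aa_type, chi))
    return PlantedClusters(aa_type, records, conformations, labels, centers,
                           t, float(min_rmsd))


def build_chain_records(aa_seq: Sequence[str],
                        phi_psi: Sequence[tuple[float, float]],
                        chis: Sequence[Sequence[float]],
                        chain_id: str = "A",
                        start_index: int = 1) -> list[ResidueRecord]:
    """Build a real polypeptide chain (NeRF continuation, omega = 180) whose
    parsed phi/psi/chi round-trip the requested values.

    The first residue's phi and the last residue's psi are geometric inputs
    only (they are undefined on re-parsing, as at real chain termini).
    """
    n = len(aa_seq)
    if not (n == len(phi_psi) == len(chis)):
        raise SyntheticError("sequence, torsions and chis must align")
    frame = canonical_backbone_frame()
    bb = []  # list of dicts N, CA, C
    cur = {k: v.copy() for k, v in frame.items()}
    bb.append(cur)
    for i in range(1, n):
        prev = bb[-1]
        psi_prev = phi_psi[i - 1][1]
        n_new = _place_atom(prev["N"], prev["CA"], prev["C"],
                            1.329, 116.2, psi_prev)
        ca_new = _place_atom(prev["CA"], prev["C"], n_new, 1.458, 121.7, 180.0)
        c_new = _place_atom(prev["C"], n_new, ca_new, 1.525, 111.2,
                            phi_psi[i][0])
        bb.append({"N": n_new, "CA": ca_new, "C": c_new})
    records = []
    for i, aa in enumerate(aa_seq):
        b = bb[i]
        psi_i = phi_psi[i][1]
        o = _place_atom(b["N"], b["CA"], b["C"], 1.231, 120.5,
                        wrap_angle(psi_i + 180.0))
        side = build_sidechain_atoms(aa, chis[i], b["N"], b["CA"], b["C"])
        records.append(ResidueRecord(
            aa_type=aa, chain_id=chain_id, seq_index=start_index + i,
            backbone_atoms={"N": b["N"], "CA": b["CA"], "C": b["C"], "O": o},
            sidechain_atoms=side,
            phi=None if i == 0 else phi_psi[i][0],
            psi=None if i == n - 1 else psi_i,
            chi=tuple(wrap_angle(c) for c in chis[i])))
    return records


def planted_contact_structure(query_aa: str = "SER",
                              contact_aa: str = "LEU",
                              distance: float = 4.0,
                              seed: int = 0) -> tuple[ResidueRecord, list]:
    """Toy structure with a planted nearest contact at an exact distance.

    A 4-residue chain (query second) is laid out with residues spaced far
    apart so only deliberate contacts are possible, plus one spatial
    neighbour of type ``contact_aa`` translated so its minimal heavy-atom
    distance to the query sidechain equals ``distance`` within 0.01 A.
    Returns (query record, all records including the query).
    """
    if distance <= 2.0:
        raise SyntheticError("distance must exceed 2 A")
    rng = np.random.default_rng(seed)
    frame = canonical_backbone_frame()

    def _make(aa, chain, idx, offset):
        off = np.asarray(offset, dtype=float)
        chi = tuple(rng.uniform(-170, 170, NCHI[aa]))
        conf = reconstruct_sidechain(aa, chi)
        o = _place_atom(frame["N"], frame["CA"], frame["C"], 1.23, 120.5, 0.0)
        return ResidueRecord(
            aa_type=aa, chain_id=chain, seq_index=idx,
            backbone_atoms={k: frame[k] + off for k in ("N", "CA", "C")}
            | {"O": o + off},
            sidechain_atoms={nm: xyz + off
                             for nm, xyz in zip(conf.atom_names, conf.coords)},
            phi=-60.0, psi=-45.0, chi=chi)

    chain = [_make("VAL", "A", 1, (0, 30, 0)),
             _make(query_aa, "A", 2, (0, 0, 0)),
             _make("THR", "A", 3, (0, -30, 0)),
             _make("ASN", "A", 4, (0, -60, 0))]
    query = chain[1]
    contact = _make(contact_aa, "B", 1, (25, 0, 0))
    q = np.array(list(query.sidechain_atoms.values()))
    for _ in range(20):
        o = np.array(list(contact.backbone_atoms.values())
                     + list(contact.sidechain_atoms.values()))
        d2 = np.sum((q[:, None, :] - o[None, :, :]) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        cur = float(np.sqrt(d2[i, j]))
        if abs(cur - distance) < 0.005:
            break
        u = (o[j] - q[i]) / cur
        shift = (distance - cur) * u
        for amap in (contact.backbone_atoms, contact.sidechain_atoms):
            for k in amap:
                amap[k] = amap[k] + shift
    o = np.array(list(contact.backbone_atoms.values())
                 + list(contact.sidechain_atoms.values()))
    final = float(np.sqrt(np.min(
        np.sum((q[:, None, :] - o[None, :, :]) ** 2, axis=2))))
    if abs(final - distance) > 0.01:
        raise SyntheticError("could not realize planted contact distance")
    return query, chain + [contact]
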