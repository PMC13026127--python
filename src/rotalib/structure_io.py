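"""Structure reading, residue extraction, dataset splitting and file formats.

Residues are read from PDB/mmCIF (first model, altloc 'A' or blank, heavy
atoms only), kept only when every backbone and sidechain heavy atom is
present and phi/psi are defined, and carried as ResidueRecord objects with
measured chi vectors.  Drop reasons are counted and logged.

Also implements the residue-table TSV dialect and the "RDL v1" plain-text
library format holding rotamer definitions and the raw/smoothed/posterior
tensors of a built model.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import RotamerCluster, RotamerSet
from .context import AxisSpec, ContextGrid
from .geometry import (BACKBONE_ATOMS, NCHI, SIDECHAIN_ATOMS, ChiSet,
                       chi_angles, dihedral, reconstruct_sidechain)

__all__ = [
    "ResidueRecord",
    "DatasetSplit",
    "parse_structure",
    "filter_complete",
    "split_dataset",
    "write_residue_tsv",
    "read_residue_tsv",
    "write_pdb",
    "write_library",
    "read_library",
]

log = logging.getLogger(__name__)


class StructureIOError(ValueError):
    pass


@dataclass
class ResidueRecord:
    """One observed residue with coordinates, torsions and measured chi."""

    aa_type: str
    chain_id: str
    seq_index: int
    backbone_atoms: dict[str, np.ndarray] = field(default_factory=dict)
    sidechain_atoms: dict[str, np.ndarray] = field(default_factory=dict)
    phi: float | None = None
    psi: float | None = None
    chi: tuple[float, ...] = ()
    icode: str = ""
    contact_class: str | None = None

    def is_complete(self) -> bool:
        """All heavy atoms present (when coordinates exist), phi/psi defined,
        and a full chi vector for a rotameric amino acid."""
        if self.aa_type not in NCHI:
            return False
        if self.phi is None or self.psi is None:
            return False
        if len(self.chi) != NCHI[self.aa_type]:
            return False
        if any(c is None or not np.isfinite(c) for c in self.chi):
            return False
        if self.backbone_atoms or self.sidechain_atoms:
            if not all(a in self.backbone_atoms for a in BACKBONE_ATOMS):
                return False
            if not all(a in self.sidechain_atoms
                       for a in SIDECHAIN_ATOMS[self.aa_type]):
                return False
        return True


@dataclass
class DatasetSplit:
    train: list[ResidueRecord]
    set_a: list[ResidueRecord]
    set_b: list[ResidueRecord]
    seed: int


# ---------------------------------------------------------------------------
# structure parsing (gemmi)

_ALTLOC_OK = ("", "\0", "A")


def parse_structure(path, fmt: str | None = None,
                    keep_incomplete: bool = False) -> list[ResidueRecord]:
    """Extract rotameric residues with measured phi/psi/chi from a structure.

    First model only; altloc 'A' or blank; hydrogens ignored; GLY/ALA and
    non-standard residues skipped; residues missing any heavy atom or with
    undefined phi/psi (chain termini) are dropped unless ``keep_incomplete``.
    Drop counts by reason are logged.
    """
    import gemmi

    path = str(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
        else:
            st = gemmi.read_structure(path)
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise StructureIOError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureIOError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    records: list[ResidueRecord] = []
    dropped: Counter = Counter()
    for chain in model:
        # per-chain atom maps in order, for phi/psi from neighbours
        residues = list(chain)
        atom_maps: list[dict[str, np.ndarray]] = []
        for res in residues:
            amap: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                if atom.altloc not in _ALTLOC_OK:
                    continue
                amap.setdefault(atom.name,
                                np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
            atom_maps.append(amap)

        def _bonded(i: int, j: int) -> bool:
            a, b = atom_maps[i], atom_maps[j]
            if "C" not in a or "N" not in b:
                return False
            return float(np.linalg.norm(a["C"] - b["N"])) < 2.0

        for i, res in enumerate(residues):
            name = res.name.upper()
            if name in ("GLY", "ALA"):
                dropped["no_chi_aa"] += 1
                continue
            if name not in NCHI:
                dropped["nonstandard"] += 1
                continue
            amap = atom_maps[i]
            if not all(a in amap for a in BACKBONE_ATOMS):
                dropped["missing_backbone"] += 1
                continue
            phi = psi = None
            if i > 0 and _bonded(i - 1, i):
                prev = atom_maps[i - 1]
                phi = dihedral(prev["C"], amap["N"], amap["CA"], amap["C"])
            if i + 1 < len(residues) and _bonded(i, i + 1):
                nxt = atom_maps[i + 1]
                psi = dihedral(amap["N"], amap["CA"], amap["C"], nxt["N"])
            side = {a: amap[a] for a in SIDECHAIN_ATOMS[name] if a in amap}
            rec = ResidueRecord(
                aa_type=name, chain_id=chain.name,
                seq_index=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                backbone_atoms={a: amap[a] for a in BACKBONE_ATOMS},
                sidechain_atoms=side, phi=phi, psi=psi)
            if len(side) < len(SIDECHAIN_ATOMS[name]):
                dropped["missing_sidechain"] += 1
                if keep_incomplete:
                    records.append(rec)
                continue
            rec.chi = chi_angles(rec).chi
            if phi is None or psi is None:
                dropped["undefined_phi_psi"] += 1
                if keep_incomplete:
                    records.append(rec)
                continue
            records.append(rec)
    if dropped:
        log.info("%s: kept %d residues, dropped %s", path, len(records),
                 dict(dropped))
    return records


def filter_complete(records: Sequence[ResidueRecord]) -> list[ResidueRecord]:
    """Keep only complete rotameric residues with defined phi and psi."""
    kept = [r for r in records if r.is_complete()]
    log.info("filter_complete: %d / %d retained", len(kept), len(records))
    return kept


def split_dataset(records: Sequence[ResidueRecord], n_chains_a: int,
                  n_per_aa_b: int, seed: int) -> DatasetSplit:
    """Chain-level Set A, per-amino-acid-instance Set B, remainder = train.

    Set A takes every residue of ``n_chains_a`` randomly chosen chains;
    Set B draws ``n_per_aa_b`` instances per amino-acid type from the
    remaining chains.  The three sets are pairwise disjoint.
    """
    rng = np.random.default_rng(seed)
    chains = sorted({r.chain_id for r in records})
    if len(chains) < n_chains_a + 1:
        raise StructureIOError(
            f"need more than {n_chains_a} chains, have {len(chains)}")
    a_chains = set(rng.choice(chains, size=n_chains_a, replace=False))
    set_a = [r for r in records if r.chain_id in a_chains]
    pool = [r for r in records if r.chain_id not in a_chains]
    by_aa: dict[str, list[int]] = {}
    for i, r in enumerate(pool):
        by_aa.setdefault(r.aa_type, []).append(i)
    b_idx: set[int] = set()
    for aa in sorted({r.aa_type for r in records}):
        idxs = by_aa.get(aa, [])
        if len(idxs) < n_per_aa_b:
            raise StructureIOError(
                f"insufficient {aa} instances outside Set A: "
                f"{len(idxs)} < {n_per_aa_b}")
        b_idx.update(rng.choice(idxs, size=n_per_aa_b, replace=False).tolist())
    set_b = [pool[i] for i in sorted(b_idx)]
    train = [pool[i] for i in range(len(pool)) if i not in b_idx]
    return DatasetSplit(train=train, set_a=set_a, set_b=set_b, seed=seed)


# ---------------------------------------------------------------------------
# residue-table TSV

_TSV_COLS = ["aa", "chain", "resseq", "phi", "psi",
             "chi1", "chi2", "chi3", "chi4"]


def write_residue_tsv(records: Sequence[ResidueRecord], path) -> None:
    rows = []
    has_contact = any(r.contact_class is not None for r in records)
    for r in records:
        chi = list(r.chi) + [None] * (4 - len(r.chi))
        row = {"aa": r.aa_type, "chain": r.chain_id,
               "resseq": r.seq_index, "phi": r.phi, "psi": r.psi,
               "chi1": chi[0], "chi2": chi[1], "chi3": chi[2],
               "chi4": chi[3]}
        if has_contact:
            row["contact"] = r.contact_class
        rows.append(row)
    cols = _TSV_COLS + (["contact"] if has_contact else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_residue_tsv(path) -> list[ResidueRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    missing = set(_TSV_COLS) - set(df.columns)
    if missing:
        raise StructureIOError(f"TSV missing columns: {sorted(missing)}")
    has_contact = "contact" in df.columns
    records = []
    for row in df.itertuples(index=False):
        aa = row.aa
        n = NCHI.get(aa, 0)
        chi = tuple(float(getattr(row, f"chi{k+1}")) for k in range(n)
                    if pd.notna(getattr(row, f"chi{k+1}")))
        records.append(ResidueRecord(
            aa_type=aa, chain_id=str(row.chain), seq_index=int(row.resseq),
            phi=None if pd.isna(row.phi) else float(row.phi),
            psi=None if pd.isna(row.psi) else float(row.psi),
            chi=chi,
            contact_class=(str(row.contact) if has_contact
                           and pd.notna(row.contact) else None)))
    return records


_ROT_COLS = ["aa", "rotamer_id", "n_members", "mean_internal_rmsd",
             "threshold", "chi1", "chi2", "chi3", "chi4"]


def write_rotamers_tsv(rotamer_sets: Mapping[str, RotamerSet], path) -> None:
    """Rotamer definitions as TSV (one row per cluster)."""
    rows = []
    for aa in sorted(rotamer_sets):
        rs = rotamer_sets[aa]
        for cl in rs.clusters:
            chi = list(cl.canonical_chi.chi) + [None] * (4 - len(cl.canonical_chi.chi))
            rows.append({"aa": aa, "rotamer_id": cl.rotamer_id,
                         "n_members": cl.member_count,
                         "mean_internal_rmsd": cl.mean_internal_rmsd,
                         "threshold": rs.threshold,
                         "chi1": chi[0], "chi2": chi[1], "chi3": chi[2],
                         "chi4": chi[3]})
    pd.DataFrame(rows, columns=_ROT_COLS).to_csv(path, sep="\t", index=False)


def read_rotamers_tsv(path) -> dict[str, RotamerSet]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, RotamerSet] = {}
    for aa, sub in df.groupby("aa"):
        clusters = []
        for row in sub.sort_values("rotamer_id").itertuples(index=False):
            chis = tuple(float(getattr(row, f"chi{k+1}"))
                         for k in range(NCHI[aa])
                         if pd.notna(getattr(row, f"chi{k+1}")))
            clusters.append(RotamerCluster(
                rotamer_id=int(row.rotamer_id),
                canonical_chi=ChiSet(aa, chis),
                centroid_conformation=reconstruct_sidechain(aa, chis),
                member_count=int(row.n_members),
                mean_internal_rmsd=float(row.mean_internal_rmsd)))
        out[aa] = RotamerSet(aa, clusters, threshold=float(sub.threshold.iloc[0]))
    return out


# ---------------------------------------------------------------------------
# minimal PDB writing (test fixtures)

_ELEMENT = {"N": "N", "C": "C", "O": "O", "S": "S"}


def write_pdb(records: Sequence[ResidueRecord], path) -> None:
    """Write records (grouped by chain, in order) as a minimal PDB file."""
    lines = []
    serial = 1
    last_chain = None
    for r in records:
        if last_chain is not None and r.chain_id != last_chain:
            lines.append("TER")
        last_chain = r.chain_id
        for name, xyz in list(r.backbone_atoms.items()) + \
                list(r.sidechain_atoms.items()):
            el = _ELEMENT.get(name[0], name[0])
            aname = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {aname}{'':1s}{r.aa_type:>3s} "
                f"{r.chain_id:1s}{r.seq_index:4d}{r.icode or '':1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mmcif(records: Sequence[ResidueRecord], path,
                entry_id: str = "SYNT") -> None:
    """Write records as a minimal mmCIF atom_site loop.

    mmCIF is free-format, so coordinates keep 10 decimals; use this writer
    when torsions must survive a file round-trip essentially exactly
    (fixed-column PDB quantizes coordinates to 0.001 A).
    """
    lines = [
        f"data_{entry_id}",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 1
    for r in records:
        for name, xyz in list(r.backbone_atoms.items()) + \
                list(r.sidechain_atoms.items()):
            el = _ELEMENT.get(name[0], name[0])
            lines.append(
                f"ATOM {serial} {el} {name} . {r.aa_type} {r.chain_id} 1 "
                f"{r.seq_index} {r.icode or '?'} "
                f"{xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f} 1.00 0.00 "
                f"{r.seq_index} {r.chain_id} 1")
            serial += 1
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RDL v1 library format

_RDL_HEADER = "# RDL v1"


def _axis_str(ax: AxisSpec) -> str:
    if ax.kind == "periodic_angle":
        return f"{ax.name}:periodic_angle:{ax.bin_width!r}"
    return f"{ax.name}:categorical:{','.join(ax.categories)}"


def _axis_parse(s: str) -> AxisSpec:
    name, kind, rest = s.split(":", 2)
    if kind == "periodic_angle":
        return AxisSpec(name, kind, float(rest))
    return AxisSpec(name, kind, categories=tuple(rest.split(",")))


def write_library(models: Mapping[str, "object"], path,
                  extra_meta: Mapping[str, str] | None = None) -> None:
    """Serialize built CountModels (one or more amino acids, shared grid)."""
    models = dict(models)
    if not models:
        raise StructureIOError("no models to write")
    first = next(iter(models.values()))
    grid = first.grid
    d = grid.ndim
    lines = [_RDL_HEADER, "[meta]", "format_version=1"]
    lines.append(f"alpha={first.alpha!r}")
    lines.append(f"fill_missing_only={int(first.fill_missing_only)}")
    if first.kernel is not None:
        lines.append("radius=" + ",".join(str(r) for r in first.kernel.radii))
        lines.append("sigma=" + ",".join(repr(s) for s in first.kernel.sigmas))
    lines.append("axes=" + "|".join(_axis_str(ax) for ax in grid.axes))
    for k, v in (extra_meta or {}).items():
        lines.append(f"{k}={v}")
    if grid.global_bins is not None:
        lines.append("[global_bins]")
        for b in sorted(grid.global_bins):
            lines.append("\t".join(str(v) for v in b))
    lines.append("[rotamers]")
    lines.append("aa\trotamer_id\tn_members\tmean_internal_rmsd\tthreshold"
                 "\tprior\tchi1\tchi2\tchi3\tchi4")
    for aa in sorted(models):
        m = models[aa]
        for cl in m.rotamers.clusters:
            chi = list(cl.canonical_chi.chi) + [""] * (4 - len(cl.canonical_chi.chi))
            chi = [repr(c) if c != "" else "" for c in chi]
            lines.append("\t".join([
                aa, str(cl.rotamer_id), str(cl.member_count),
                repr(float(cl.mean_internal_rmsd)),
                repr(float(m.rotamers.threshold)),
                repr(float(m.prior[cl.rotamer_id]))] + chi))
    lines.append("[probabilities]")
    xcols = "\t".join(f"x{i+1}" for i in range(d))
    lines.append(f"aa\t{xcols}\trotamer_id\traw_count\tsmoothed_count\tposterior")
    for aa in sorted(models):
        m = models[aa]
        for x in np.ndindex(*grid.shape):
            for r in range(m.n_rotamers):
                idx = (r,) + x
                lines.append("\t".join(
                    [aa] + [str(v) for v in x] +
                    [str(r), repr(float(m.raw_counts[idx])),
                     repr(float(m.smoothed_counts[idx])),
                     "%.10g" % m.posterior[idx]]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_baseline(table, path) -> None:
    """Serialize a 3-state frequency baseline as an RDL v1 [baseline] section."""
    from .baseline import STATE_NAMES

    lines = [_RDL_HEADER, "[meta]", "format_version=1",
             f"bin_width={table.bin_width!r}", "[baseline]",
             "aa\tphi_bin\tpsi_bin\tstates\tcount\tchi1\tchi2\tchi3\tchi4"]
    for key in sorted(table.table):
        aa, bp, bs = key
        for states in sorted(table.table[key]):
            e = table.table[key][states]
            chi = list(e.mean_chi()) + [""] * (4 - len(states))
            chi = [repr(float(c)) if c != "" else "" for c in chi]
            lines.append("\t".join(
                [aa, str(bp), str(bs),
                 ",".join(STATE_NAMES[s] for s in states), str(e.count)]
                + chi))
    Path(path).write_text("\n".join(lines) + "\n")


def is_baseline_library(path) -> bool:
    return "[baseline]" in Path(path).read_text()


def read_baseline(path):
    """Read a [baseline] section back into a BaselineTable.

    Per-state circular sums are rebuilt from the stored mean and count, so
    predictions round-trip exactly."""
    from .baseline import STATE_NAMES, BaselineTable, _StateEntry

    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _RDL_HEADER:
        raise StructureIOError(f"{path}: not an RDL v1 file")
    section = None
    meta: dict[str, str] = {}
    tab = None
    for line in text[1:]:
        if not line.strip():
            continue
        if line.startswith("["):
            section = line.strip()
            continue
        if section == "[meta]":
            k, _, v = line.partition("=")
            meta[k] = v
        elif section == "[baseline]":
            if line.startswith("aa\t"):
                continue
            if tab is None:
                tab = BaselineTable(bin_width=float(meta.get("bin_width", 10.0)))
            row = line.split("\t")
            aa, bp, bs, states_s, count = row[:5]
            states = tuple(STATE_NAMES.index(s) for s in states_s.split(","))
            chis = np.array([float(c) for c in row[5:5 + len(states)]])
            e = _StateEntry()
            n = int(count)
            rad = np.radians(chis)
            e.count = n
            e.sin_sum = n * np.sin(rad)
            e.cos_sum = n * np.cos(rad)
            tab.table.setdefault((aa, int(bp), int(bs)), {})[states] = e
    if tab is None:
        raise StructureIOError(f"{path}: no [baseline] section")
    return tab


def read_library(path) -> dict[str, "object"]:
    """Read an RDL v1 file back into per-amino-acid CountModels."""
    from .model import CountModel, SmoothingKernel

    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _RDL_HEADER:
        raise StructureIOError(f"{path}: not an RDL v1 file")
    section = None
    meta: dict[str, str] = {}
    global_bins: list[tuple[int, ...]] = []
    rot_rows: list[list[str]] = []
    prob_rows: list[list[str]] = []
    for line in text[1:]:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("["):
            section = line.strip()
            continue
        if section == "[meta]":
            k, _, v = line.partition("=")
            meta[k] = v
        elif section == "[global_bins]":
            global_bins.append(tuple(int(v) for v in line.split("\t")))
        elif section == "[rotamers]":
            if line.startswith("aa\t"):
                continue
            rot_rows.append(line.split("\t"))
        elif section == "[probabilities]":
            if line.startswith("aa\t"):
                continue
            prob_rows.append(line.split("\t"))
    axes = tuple(_axis_parse(s) for s in meta["axes"].split("|"))
    grid = ContextGrid(axes)
    if global_bins:
        grid.set_global_bins(global_bins)
    alpha = float(meta["alpha"])
    fmo = bool(int(meta.get("fill_missing_only", "0")))
    kernel = None
    if "radius" in meta:
        kernel = SmoothingKernel(
            tuple(int(v) for v in meta["radius"].split(",")),
            tuple(float(v) for v in meta["sigma"].split(",")),
            tuple(ax.periodic for ax in axes))
    d = grid.ndim
    # rotamer sets
    per_aa_rot: dict[str, list] = {}
    thresholds: dict[str, float] = {}
    priors: dict[str, dict[int, float]] = {}
    for row in rot_rows:
        aa, rid, nmem, rmsd, thr, prior = row[:6]
        chis = tuple(float(c) for c in row[6:] if c != "")
        cl = RotamerCluster(
            rotamer_id=int(rid), canonical_chi=ChiSet(aa, chis),
            centroid_conformation=reconstruct_sidechain(aa, chis),
            member_count=int(nmem), mean_internal_rmsd=float(rmsd))
        per_aa_rot.setdefault(aa, []).append(cl)
        thresholds[aa] = float(thr)
        priors.setdefault(aa, {})[int(rid)] = float(prior)
    models: dict[str, CountModel] = {}
    for aa, clusters in per_aa_rot.items():
        clusters.sort(key=lambda c: c.rotamer_id)
        rs = RotamerSet(aa, clusters, threshold=thresholds[aa])
        shape = (len(clusters),) + grid.shape
        raw = np.zeros(shape)
        smoothed = np.zeros(shape)
        post = np.zeros(shape)
        models[aa] = CountModel(
            aa_type=aa, grid=grid, rotamers=rs, raw_counts=raw,
            smoothed_counts=smoothed, alpha=alpha,
            prior=np.array([priors[aa][c.rotamer_id] for c in clusters]),
            posterior=post, kernel=kernel, fill_missing_only=fmo)
    for row in prob_rows:
        aa = row[0]
        x = tuple(int(v) for v in row[1:1 + d])
        r = int(row[1 + d])
        m = models[aa]
        idx = (r,) + x
        m.raw_counts[idx] = float(row[2 + d])
        m.smoothed_counts[idx] = float(row[3 + d])
        m.posterior[idx] = float(row[4 + d])
    return models
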