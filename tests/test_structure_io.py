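"""Parsing, completeness filtering, splitting, and file-format round trips."""

import numpy as np
import pytest

from rotalib import context as ctx
from rotalib import model as mdl
from rotalib import structure_io as sio
from rotalib import synthetic as syn
from rotalib.structure_io import ResidueRecord, StructureIOError
from tests.conftest import make_rotamer_set


def _chain(chain_id="A", start=1):
    chis = [(-60.0, 170.0), (55.0,), (-65.0, 160.0, 50.0), (62.0, -170.0),
            (-58.0, 95.0)]
    aas = ["LEU", "SER", "GLU", "ILE", "PHE"]
    tors = [(-60, -45), (-70, 130), (-120, 140), (-100, 120), (-65, -40)]
    return aas, tors, chis, syn.build_chain_records(aas, tors, chis,
                                                    chain_id=chain_id,
                                                    start_index=start)


def test_pdb_parse_roundtrip_modest_precision(tmp_path):
    """PDB fixed columns quantize coordinates to 1e-3 A; chi survive to ~0.1 deg."""
    aas, tors, chis, recs = _chain()
    p = tmp_path / "toy.pdb"
    sio.write_pdb(recs, p)
    parsed = sio.parse_structure(p)
    # termini lack phi or psi and are dropped
    assert [r.aa_type for r in parsed] == aas[1:-1]
    for r, want in zip(parsed, chis[1:-1]):
        for a, b in zip(r.chi, want):
            assert min(abs(a - b), 360 - abs(a - b)) < 0.1


def test_mmcif_parse_roundtrip_exact(tmp_path):
    """Full-precision mmCIF fixture round-trips chi within 1e-6 degrees."""
    aas, tors, chis, recs = _chain()
    p = tmp_path / "toy.cif"
    sio.write_mmcif(recs, p)
    parsed = sio.parse_structure(p)
    assert [r.aa_type for r in parsed] == aas[1:-1]
    for r, want, (phi, psi) in zip(parsed, chis[1:-1], tors[1:-1]):
        assert r.phi == pytest.approx(phi, abs=1e-6)
        assert r.psi == pytest.approx(psi, abs=1e-6)
        for a, b in zip(r.chi, want):
            assert min(abs(a - b), 360 - abs(a - b)) < 1e-6


def test_parse_drops_incomplete_sidechain(tmp_path):
    aas, tors, chis, recs = _chain()
    del recs[2].sidechain_atoms["OE1"]  # GLU missing a terminal oxygen
    p = tmp_path / "broken.cif"
    sio.write_mmcif(recs, p)
    parsed = sio.parse_structure(p)
    assert "GLU" not in [r.aa_type for r in parsed]


def test_parse_missing_file():
    with pytest.raises(StructureIOError):
        sio.parse_structure("/nonexistent/file.pdb")


def test_filter_complete_planted_defects():
    field = syn.make_field("SER", 2, seed=0)
    recs = syn.sample_residues(field, 10, seed=1)
    recs[0].phi = None                      # chain start
    recs[3].psi = None                      # chain end
    del recs[5].sidechain_atoms["OG"]       # missing heavy atom
    kept = sio.filter_complete(recs)
    assert len(kept) == 7
    assert recs[0] not in kept and recs[3] not in kept and recs[5] not in kept


def test_filter_complete_removes_nonrotameric():
    rec = ResidueRecord(aa_type="GLY", chain_id="A", seq_index=1,
                        phi=-60.0, psi=-45.0, chi=())
    assert sio.filter_complete([rec]) == []


class TestSplitDataset:
    def _corpus(self):
        field = syn.make_field("SER", 2, seed=3)
        recs = syn.sample_residues(field, 200, seed=4, chain_size=40,
                                   with_coordinates=False)
        field2 = syn.make_field("LEU", 2, seed=5)
        recs += syn.sample_residues(field2, 200, seed=6, chain_size=40,
                                    chain_prefix="L", with_coordinates=False)
        return recs

    def test_disjoint_and_conserved(self):
        recs = self._corpus()
        split = sio.split_dataset(recs, n_chains_a=2, n_per_aa_b=20, seed=9)
        ids = lambda rs: {id(r) for r in rs}
        assert not (ids(split.train) & ids(split.set_a))
        assert not (ids(split.train) & ids(split.set_b))
        assert not (ids(split.set_a) & ids(split.set_b))
        assert len(split.train) + len(split.set_a) + len(split.set_b) == len(recs)
        # set A is whole chains, sharing none with the others
        a_chains = {r.chain_id for r in split.set_a}
        assert all(r.chain_id not in a_chains
                   for r in split.train + split.set_b)

    def test_per_aa_counts(self):
        recs = self._corpus()
        split = sio.split_dataset(recs, n_chains_a=1, n_per_aa_b=20, seed=9)
        for aa in ("SER", "LEU"):
            n_b = sum(1 for r in split.set_b if r.aa_type == aa)
            assert n_b == 20
            total = sum(1 for r in recs if r.aa_type == aa)
            rest = sum(1 for r in split.train + split.set_a
                       if r.aa_type == aa)
            assert rest == total - 20

    def test_deterministic(self):
        recs = self._corpus()
        s1 = sio.split_dataset(recs, 2, 10, seed=42)
        s2 = sio.split_dataset(recs, 2, 10, seed=42)
        assert [id(r) for r in s1.train] == [id(r) for r in s2.train]
        assert [id(r) for r in s1.set_b] == [id(r) for r in s2.set_b]

    def test_insufficient_instances(self):
        recs = self._corpus()
        with pytest.raises(StructureIOError, match="SER|LEU"):
            sio.split_dataset(recs, n_chains_a=2, n_per_aa_b=5000, seed=0)


def test_residue_tsv_roundtrip(tmp_path):
    field = syn.make_field("GLN", 3, seed=8,
                           categories=("hydrophobic", "non_hydrophobic"))
    recs = syn.sample_residues(field, 25, seed=9, with_coordinates=False)
    p = tmp_path / "residues.tsv"
    sio.write_residue_tsv(recs, p)
    back = sio.read_residue_tsv(p)
    assert len(back) == len(recs)
    for a, b in zip(recs, back):
        assert a.aa_type == b.aa_type
        assert a.chain_id == b.chain_id and a.seq_index == b.seq_index
        assert a.phi == pytest.approx(b.phi) and a.psi == pytest.approx(b.psi)
        assert np.allclose(a.chi, b.chi)
        assert a.contact_class == b.contact_class


def _small_model(aa="SER", seed=1, n=400, contact=False):
    cats = ("hydrophobic", "non_hydrophobic", "none") if contact else None
    field = syn.make_field(aa, 3, seed=seed, categories=cats)
    recs = syn.sample_residues(field, n, seed=seed + 1, with_coordinates=False)
    grid = ctx.backbone_contact_grid() if contact else ctx.backbone_grid()
    grid.set_global_bins({ctx.encode_context(r, grid) for r in recs})
    rset = make_rotamer_set(aa, field.rotamer_chis, 0.35)
    return mdl.build_model(recs, grid, rset)


def test_library_roundtrip_bitwise(tmp_path):
    m = _small_model()
    p1 = tmp_path / "lib.rdl"
    sio.write_library({"SER": m}, p1)
    back = sio.read_library(p1)["SER"]
    assert np.array_equal(m.raw_counts, back.raw_counts)
    assert np.array_equal(m.smoothed_counts, back.smoothed_counts)
    assert np.max(np.abs(m.posterior - back.posterior)) < 1e-9
    assert back.alpha == m.alpha
    assert back.grid.global_bins == m.grid.global_bins
    got = [(c.rotamer_id, c.canonical_chi.chi, c.member_count)
           for c in back.rotamers.clusters]
    want = [(c.rotamer_id, c.canonical_chi.chi, c.member_count)
            for c in m.rotamers.clusters]
    assert got == want
    # write -> read -> write is byte-identical
    p2 = tmp_path / "lib2.rdl"
    sio.write_library({"SER": back}, p2)
    assert p1.read_text() == p2.read_text()


def test_library_roundtrip_contact_grid(tmp_path):
    m = _small_model(contact=True)
    p = tmp_path / "lib3.rdl"
    sio.write_library({"SER": m}, p)
    back = sio.read_library(p)["SER"]
    assert back.grid.shape == (36, 36, 3)
    assert np.array_equal(m.raw_counts, back.raw_counts)


def test_baseline_library_roundtrip(tmp_path):
    from rotalib.baseline import build_baseline, predict_baseline
    field = syn.make_field("LEU", 3, seed=15)
    recs = syn.sample_residues(field, 500, seed=16, with_coordinates=False)
    tab = build_baseline(recs)
    p = tmp_path / "baseline.rdl"
    sio.write_baseline(tab, p)
    assert sio.is_baseline_library(p)
    back = sio.read_baseline(p)
    assert back.bin_width == tab.bin_width
    assert set(back.table) == set(tab.table)
    for r in recs[:50]:
        a = predict_baseline(tab, "LEU", r.phi, r.psi)
        b = predict_baseline(back, "LEU", r.phi, r.psi)
        assert (a is None) == (b is None)
        if a is not None:
            np.testing.assert_allclose(a.chi, b.chi, atol=1e-9)


def test_rotamers_tsv_roundtrip(tmp_path):
    rset = make_rotamer_set("LEU", [(-60.0, 170.0), (60.0, 60.0)], 0.4,
                            counts=[10, 5])
    p = tmp_path / "rot.tsv"
    sio.write_rotamers_tsv({"LEU": rset}, p)
    back = sio.read_rotamers_tsv(p)["LEU"]
    assert back.threshold == 0.4
    assert [c.canonical_chi.chi for c in back.clusters] == \
        [c.canonical_chi.chi for c in rset.clusters]
    assert [c.member_count for c in back.clusters] == [10, 5]
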