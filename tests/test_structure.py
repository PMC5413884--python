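"""PDB parsing and active-site geometry on constructed models."""

from pathlib import Path

import numpy as np
import pytest

from fernhnl.structure import (
    Atom,
    StructureModel,
    ligand_contacts,
    polar_distance,
    read_pdb,
    select_atoms,
    water_chain,
    write_pdb,
)
from fernhnl.synthetic import SitePreset, generate_toy_structure


def _atom(record, serial, name, resname, resnum, x, y, z, element, chain="A"):
    return Atom(record, serial, name, resname, chain, resnum, x, y, z, element)


# ------------------------------------------------------------------- parsing
def test_toy_fixture_atom_count_and_resolution(toy_model):
    # ligand (4) + residue mimics (10) + 5 waters
    assert len(toy_model.atoms) == 19
    assert toy_model.resolution == pytest.approx(1.85)
    assert len(toy_model.waters) == 5


def test_parser_keeps_first_altloc(tmp_path):
    pdb = (
        "ATOM      1  CA AALA A   1      0.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      2  CA BALA A   1      1.000   0.000   0.000  0.50  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "altloc.pdb"
    p.write_text(pdb)
    model = read_pdb(p)
    assert len(model.atoms) == 1
    assert model.atoms[0].x == pytest.approx(0.0)


def test_parser_reports_malformed_line_number(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text("ATOM      1  CA  ALA A   1      0.000   bad     0.000\nEND\n")
    with pytest.raises(ValueError, match=":1:"):
        read_pdb(p)


def test_write_read_round_trip_preserves_coordinates(toy_model, tmp_path):
    p = tmp_path / "rt.pdb"
    write_pdb(toy_model, p)
    again = read_pdb(p)
    assert again.resolution == pytest.approx(toy_model.resolution)
    for a, b in zip(toy_model.atoms, again.atoms):
        assert (a.x, a.y, a.z) == pytest.approx((b.x, b.y, b.z), abs=1e-3)
        assert (a.name, a.resname, a.resnum) == (b.name, b.resname, b.resnum)


# ------------------------------------------------------------------ contacts
def test_contacts_within_cutoff_only():
    model = StructureModel(
        [
            _atom("HETATM", 1, "N1", "LIG", 900, 0.0, 0.0, 0.0, "N"),
            _atom("ATOM", 2, "CB", "VAL", 44, 3.0, 0.0, 0.0, "C"),
            _atom("ATOM", 3, "CB", "PHE", 71, 6.0, 0.0, 0.0, "C"),
        ]
    )
    rep = ligand_contacts(model, "LIG", cutoff=4.0)
    assert [(r.resname, r.resnum) for r in rep.residues] == [("VAL", 44)]
    assert rep.residues[0].min_distance == pytest.approx(3.0)


def test_zero_cutoff_gives_empty_report(toy_model):
    rep = ligand_contacts(toy_model, "MXN", cutoff=0.0)
    assert rep.residues == [] and rep.polar == []


def test_missing_ligand_error_names_available_groups(toy_model):
    with pytest.raises(ValueError, match="MXN"):
        ligand_contacts(toy_model, "BEZ")


def test_toy_site_contacts_include_catalytic_residues(toy_model):
    rep = ligand_contacts(toy_model, "MXN", cutoff=4.0)
    found = {(r.resname, r.resnum) for r in rep.residues}
    assert {("ARG", 69), ("ASP", 85), ("TYR", 101)} <= found
    assert ("ALA", 164) not in found  # placed at 8 A
    dists = [r.min_distance for r in rep.residues]
    assert dists == sorted(dists)
    # polar sublist is within the hydrogen-bond ceiling
    assert all(p.distance <= 3.6 for p in rep.polar)


# ------------------------------------------------------------ polar distances
def test_polar_distance_simple_pair():
    model = StructureModel(
        [
            _atom("HETATM", 1, "N1", "LIG", 900, 0.0, 0.0, 0.0, "N"),
            _atom("ATOM", 2, "OD1", "ASP", 85, 0.0, 0.0, 2.9, "O"),
        ]
    )
    d = polar_distance(model, dict(resname="LIG"), dict(resname="ASP"))
    assert d == pytest.approx(2.9)


def test_polar_distance_takes_minimum_over_selection():
    model = StructureModel(
        [
            _atom("HETATM", 1, "N1", "LIG", 900, 0.0, 0.0, 0.0, "N"),
            _atom("ATOM", 2, "NH1", "ARG", 69, 3.5, 0.0, 0.0, "N"),
            _atom("ATOM", 3, "NH2", "ARG", 69, 4.4, 0.0, 0.0, "N"),
        ]
    )
    d = polar_distance(
        model, dict(resname="LIG"), dict(resname="ARG", names=["NE", "NH1", "NH2"])
    )
    assert d == pytest.approx(3.5)


def test_polar_distance_empty_selection_errors(toy_model):
    with pytest.raises(ValueError, match="selection"):
        polar_distance(toy_model, dict(resname="MXN"), dict(resname="HIS"))


def test_toy_preset_distances_are_recovered(toy_model):
    d_arg = polar_distance(
        toy_model,
        dict(resname="MXN", names=["N1"]),
        dict(resname="ARG", resnum=69, names=["NE", "NH1", "NH2"]),
    )
    d_asp = polar_distance(
        toy_model,
        dict(resname="MXN", names=["N1"]),
        dict(resname="ASP", resnum=85, names=["OD1", "OD2"]),
    )
    assert d_arg == pytest.approx(3.5, abs=1e-6)
    assert d_asp == pytest.approx(2.9, abs=1e-6)


def test_geometry_invariant_under_rigid_motion(toy_model):
    theta = 0.7
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    moved = toy_model.transformed(rot, np.array([10.0, -5.0, 3.0]))
    sel_a = dict(resname="MXN", names=["N1"])
    sel_b = dict(resname="ARG", resnum=69, names=["NH1", "NH2"])
    assert polar_distance(moved, sel_a, sel_b) == pytest.approx(
        polar_distance(toy_model, sel_a, sel_b), abs=1e-9
    )
    rep0 = ligand_contacts(toy_model, "MXN")
    rep1 = ligand_contacts(moved, "MXN")
    assert [(r.resnum, r.min_distance) for r in rep0.residues] == [
        (r.resnum, r.min_distance) for r in rep1.residues
    ]


# ----------------------------------------------------------------- water chain
START = dict(resname="TYR", resnum=101, names=["OH"])


def test_five_water_chain_in_order(toy_model):
    chain = water_chain(toy_model, START)
    assert len(chain) == 5
    assert [w.serial for w in chain] == sorted(w.serial for w in chain)
    steps = [
        float(np.linalg.norm(a.pos - b.pos)) for a, b in zip(chain, chain[1:])
    ]
    assert all(s == pytest.approx(2.8, abs=1e-6) for s in steps)


def test_spacing_beyond_step_limit_gives_single_water(tmp_path):
    p = tmp_path / "toy4.pdb"
    p.write_text(generate_toy_structure(n_waters=5, spacing=4.0))
    chain = water_chain(read_pdb(p), START)
    assert len(chain) == 1


def test_no_waters_gives_empty_chain(tmp_path):
    p = tmp_path / "toy0.pdb"
    p.write_text(generate_toy_structure(n_waters=0))
    assert water_chain(read_pdb(p), START) == []


def test_branch_point_prefers_nearer_then_lower_serial():
    atoms = [
        _atom("ATOM", 1, "OH", "TYR", 101, 0.0, 0.0, 0.0, "O"),
        _atom("HETATM", 10, "O", "HOH", 301, 1.0, 0.0, 0.0, "O"),
        _atom("HETATM", 11, "O", "HOH", 302, 1.0, 2.0, 0.0, "O"),  # 2.0 away
        _atom("HETATM", 12, "O", "HOH", 303, 1.0, -3.0, 0.0, "O"),  # 3.0 away
    ]
    chain = water_chain(StructureModel(atoms), dict(resname="TYR"), max_step=3.5)
    # the nearer continuation (302) wins; 303 is then out of step range
    assert [w.serial for w in chain] == [10, 11]
    # exact tie broken by lower serial
    tie = [
        _atom("ATOM", 1, "OH", "TYR", 101, 0.0, 0.0, 0.0, "O"),
        _atom("HETATM", 20, "O", "HOH", 301, 1.0, 0.0, 0.0, "O"),
        _atom("HETATM", 22, "O", "HOH", 303, 1.0, 2.0, 0.0, "O"),
        _atom("HETATM", 21, "O", "HOH", 302, 1.0, -2.0, 0.0, "O"),
    ]
    chain = water_chain(StructureModel(tie), dict(resname="TYR"), max_step=3.5)
    assert [w.serial for w in chain][:2] == [20, 21]


def test_surface_termination_stops_exposed_walk():
    # a cluster of protein atoms near the first water only; later waters are
    # solvent-exposed
    atoms = [_atom("ATOM", 1, "OH", "TYR", 101, 0.0, 0.0, 0.0, "O")]
    serial = 2
    for i in range(30):
        atoms.append(
            _atom("ATOM", serial, "CB", "VAL", 10 + i, -1.5 - 0.01 * i, 0.0, 0.0, "C")
        )
        serial += 1
    for j, x in enumerate([1.0, 4.0, 7.0, 10.0]):
        atoms.append(_atom("HETATM", serial, "O", "HOH", 301 + j, x, 0.0, 0.0, "O"))
        serial += 1
    model = StructureModel(atoms)
    full = water_chain(model, dict(resname="TYR"), max_step=3.5)
    assert len(full) == 4
    stopped = water_chain(
        model, dict(resname="TYR"), max_step=3.5, surface_neighbor_count=4
    )
    assert len(stopped) < 4
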