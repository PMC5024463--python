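"""Structure parsing, secondary structure, accessibility, contacts and
mechanism verdicts."""

import io
import os
import tempfile
import warnings

import numpy as np
import pytest

from inframe.geometry import GeometrySpec, build_geometry
from inframe.mechanism import (
    LOOP_ELEMENT_MIN_SEPARATION,
    MechanismVerdict,
    ResidueAnnotation,
    Unassessable,
    annotate_structure,
    classify_mechanism,
    detect_interchain_contacts,
    helix_register_shift,
)
from inframe.secondary import assign_secondary_structure, classify_strand_position
from inframe.structure import StructureParseError, parse_structure
from inframe.surface import atom_sasa, compute_rsa

warnings.filterwarnings("ignore", module="mdtraj")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  CA AALA B   1       9.000   0.000   0.000  0.40  0.00           C
ATOM      4  CA BALA B   1       9.500   0.000   0.000  0.60  0.00           C
ATOM      5  P    DA C   1       0.000   9.000   0.000  1.00  0.00           P
ATOM      6  OP1  DA C   1       1.000   9.500   0.000  1.00  0.00           O
ATOM      7  O   HOH D   1       5.000   5.000   5.000  1.00  0.00           O
END
"""


def test_parse_chain_classes_and_waters():
    s = parse_structure(_MINI_PDB)
    classes = {c.chain_id: c.molecular_class for c in s.chains}
    assert classes == {"A": "protein", "B": "protein", "C": "nucleic"}  # water dropped


def test_altloc_resolved_to_highest_occupancy():
    s = parse_structure(_MINI_PDB)
    b = s.get_chain("B")
    assert len(b.residues[0].atoms) == 1
    assert b.residues[0].atoms[0].xyz[0] == pytest.approx(9.5)  # occ 0.60 wins


def test_empty_input_errors():
    with pytest.raises(StructureParseError):
        parse_structure("")
    with pytest.raises(StructureParseError):
        parse_structure("HEADER    NOTHING\nEND\n")


def test_malformed_coordinate_reports_line():
    bad = _MINI_PDB.replace("   1.460", "   1.4x0")
    with pytest.raises(StructureParseError, match="line 2"):
        parse_structure(bad)


def test_generated_pdb_roundtrip(sheet_pdb):
    """Generated fixtures re-parse losslessly at 3-decimal precision."""
    s = parse_structure(sheet_pdb)
    rewritten = sheet_pdb.splitlines()
    atoms1 = [
        (c.chain_id, r.seq_num, a.name, *np.round(a.xyz, 3))
        for c in s.chains for r in c.residues for a in r.atoms
    ]
    s2 = parse_structure("\n".join(rewritten) + "\n")
    atoms2 = [
        (c.chain_id, r.seq_num, a.name, *np.round(a.xyz, 3))
        for c in s2.chains for r in c.residues for a in r.atoms
    ]
    assert atoms1 == atoms2 and len(atoms1) > 100


# ---------------------------------------------------------------------------
# secondary structure vs reference DSSP
# ---------------------------------------------------------------------------


def _dssp_reference(pdb_text: str) -> list[str]:
    import mdtraj as md

    with tempfile.NamedTemporaryFile(suffix=".pdb", mode="w", delete=False) as fh:
        fh.write(pdb_text)
        path = fh.name
    try:
        traj = md.load(path)
        out = md.compute_dssp(traj, simplified=True)[0]
    finally:
        os.unlink(path)
    return ["C" if x == "NA" else x for x in out]


def _my_states(pdb_text: str) -> list[str]:
    s = parse_structure(pdb_text)
    ss = assign_secondary_structure(s)
    return [
        ss.state(c.chain_id, i)
        for c in s.protein_chains()
        for i in range(len(c.residues))
    ]


@pytest.mark.parametrize(
    "kind,params,n",
    [
        ("ideal_helix", {}, 20),
        ("beta_sheet", {"n_strands": 2}, 8),
        ("beta_hairpin", {"tail_length": 4}, 8),
    ],
)
def test_secondary_structure_matches_dssp_interior(kind, params, n):
    """>= 95 % agreement with a reference DSSP on interior residues."""
    pdb = build_geometry(GeometrySpec(kind=kind, n_residues=n, params=params))
    mine = _my_states(pdb)
    ref = _dssp_reference(pdb)
    assert len(mine) == len(ref)
    # interior residues: two or more positions from each chain terminus
    s = parse_structure(pdb)
    interior = []
    offset = 0
    for c in s.protein_chains():
        ln = len(c.residues)
        interior.extend(range(offset + 2, offset + ln - 2))
        offset += ln
    agree = sum(mine[i] == ref[i] for i in interior)
    assert agree / len(interior) >= 0.95


def test_ideal_helix_interior_is_helix(helix_pdb):
    states = _my_states(helix_pdb)
    assert all(s == "H" for s in states[2:-2])


def test_isolated_extended_chain_is_coil():
    from inframe.geometry import STRAND_PHI, STRAND_PSI, _build_chain, write_pdb

    chain = _build_chain("A" * 12, [(STRAND_PHI, STRAND_PSI)] * 12)
    states = _my_states(write_pdb([("A", chain)]))
    assert set(states) == {"C"}  # no partner strand, no hydrogen bonds


def test_missing_backbone_flagged_as_coil(helix_pdb):
    # drop all O atoms of residue 10 from the helix
    lines = [
        l for l in helix_pdb.splitlines()
        if not (l.startswith("ATOM") and l[21] == "A" and int(l[22:26]) == 10
                and l[12:16].strip() == "O")
    ]
    s = parse_structure("\n".join(lines) + "\n")
    ss = assign_secondary_structure(s)
    assert ("A", 9) in ss.missing_backbone
    assert ss.state("A", 9) == "C"


# ---------------------------------------------------------------------------
# strand topology
# ---------------------------------------------------------------------------


def test_three_strand_sheet_edge_central(sheet_annotations):
    s, _ = sheet_annotations
    ss = assign_secondary_structure(s)
    assert classify_strand_position(ss, "B", 3) == "central"
    assert classify_strand_position(ss, "A", 3) == "edge"
    assert classify_strand_position(ss, "C", 3) == "edge"


def test_helix_residue_not_in_sheet(helix_pdb):
    s = parse_structure(helix_pdb)
    ss = assign_secondary_structure(s)
    assert classify_strand_position(ss, "A", 10) == "not_in_sheet"


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------


def test_isolated_atom_sasa_analytic():
    for elem, r in (("C", 1.7), ("N", 1.55), ("O", 1.52), ("S", 1.8)):
        area = atom_sasa(np.zeros((1, 3)), [elem])[0]
        assert area == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=1e-12)


def test_fully_caged_atom_has_zero_sasa():
    # octahedral cage of large atoms tight around a central C
    d = 2.0
    cage = np.array(
        [[d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0], [0, 0, d], [0, 0, -d],
         [d, d, d], [d, d, -d], [d, -d, d], [d, -d, -d],
         [-d, d, d], [-d, d, -d], [-d, -d, d], [-d, -d, -d]]
    )
    coords = np.vstack([[0.0, 0.0, 0.0], cage])
    areas = atom_sasa(coords, ["C"] + ["S"] * len(cage))
    assert areas[0] == 0.0


def test_sasa_non_increasing_when_atoms_added(rng):
    coords = rng.uniform(-4, 4, size=(12, 3))
    elems = ["C"] * 12
    before = atom_sasa(coords, elems)
    extra = np.vstack([coords, rng.uniform(-4, 4, size=(4, 3))])
    after = atom_sasa(extra, elems + ["C"] * 4)
    assert np.all(after[:12] <= before + 1e-9)


def test_sasa_matches_independent_oracle(rng):
    """Random clusters agree with biotite's Shrake-Rupley within 3 %."""
    import biotite.structure as struc

    for _ in range(5):
        n = int(rng.integers(5, 15))
        coords = rng.uniform(-5, 5, size=(n, 3))
        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * n)
        arr.atom_name = np.array(["CA"] * n)
        arr.res_name = np.array(["ALA"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
        mine = atom_sasa(coords, ["C"] * n)
        total_ref, total_mine = float(ref.sum()), float(mine.sum())
        assert abs(total_mine - total_ref) / total_ref < 0.03


def test_rsa_clipped_and_surface_flag(helix_pdb):
    s = parse_structure(helix_pdb)
    rsa = compute_rsa(s)
    for v in rsa.values():
        assert v["rsa"] is None or 0.0 <= v["rsa"] <= 1.0
    # terminal residues of an isolated helix are clearly exposed
    assert rsa[("A", 0)]["is_surface"]


# ---------------------------------------------------------------------------
# contacts and salt bridges
# ---------------------------------------------------------------------------


def _two_atom_pdb(d: float) -> str:
    return (
        "ATOM      1  NH1 ARG A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        f"ATOM      2  OP1  DA B   1    {d:8.3f}   0.000   0.000  1.00  0.00           O\n"
        "END\n"
    )


def test_salt_bridge_at_3_2_angstrom():
    s = parse_structure(_two_atom_pdb(3.2))
    partners, bridges = detect_interchain_contacts(s, "A", 0)
    assert partners == {"B"}
    assert len(bridges) == 1 and bridges[0].distance == pytest.approx(3.2)
    assert bridges[0].partner_atom == "OP1"


def test_contact_but_no_salt_bridge_at_4_3():
    s = parse_structure(_two_atom_pdb(4.3))
    partners, bridges = detect_interchain_contacts(s, "A", 0)
    assert partners == {"B"} and bridges == []


def test_no_contact_at_10_angstrom():
    s = parse_structure(_two_atom_pdb(10.0))
    partners, bridges = detect_interchain_contacts(s, "A", 0)
    assert partners == set() and bridges == []


def test_salt_bridge_symmetric_across_chains():
    pdb = (
        "ATOM      1  NZ  LYS A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  OE1 GLU B   1       3.500   0.000   0.000  1.00  0.00           O\n"
        "END\n"
    )
    s = parse_structure(pdb)
    _, ab = detect_interchain_contacts(s, "A", 0)
    _, ba = detect_interchain_contacts(s, "B", 0)
    assert len(ab) == len(ba) == 1
    assert ab[0].distance == ba[0].distance


def test_dna_fixture_has_planted_salt_bridge(dna_pdb):
    s = parse_structure(dna_pdb)
    arg_pos = next(
        i for i, r in enumerate(s.get_chain("A").residues) if r.name == "ARG"
    )
    partners, bridges = detect_interchain_contacts(s, "A", arg_pos)
    assert partners == {"B"} and len(bridges) >= 1


# ---------------------------------------------------------------------------
# register shift
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n,shift,disruptive",
    [(0, 0.0, False), (1, 100.0, True), (18, 0.0, False), (3, 300.0, True), (36, 0.0, False)],
)
def test_helix_register_shift(n, shift, disruptive):
    got_shift, got_flag = helix_register_shift(n)
    assert got_shift == shift and got_flag == disruptive


def test_register_shift_rejects_negative():
    with pytest.raises(ValueError):
        helix_register_shift(-1)


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------


def test_rule_order_beta_sheet_first(sheet_annotations):
    _, ann = sheet_annotations
    v = classify_mechanism([("A", 3)], ann, 1)
    assert v.category == "probably" and v.mechanisms == ("beta_sheet_disruption",)
    assert "edge" in v.evidence["strand_positions"]
    v = classify_mechanism([("B", 3)], ann, 7)
    assert "central" in v.evidence["strand_positions"]


def test_helix_interface_register_rule(coil_pdb):
    s = parse_structure(coil_pdb)
    ann = annotate_structure(s)
    v = classify_mechanism([("A", 10)], ann, 1)
    assert v.category == "probably"
    assert v.mechanisms == ("helix_register_shift",)
    assert v.evidence["register_shift_degrees"] == 100.0


def test_binding_site_rule(dna_pdb):
    s = parse_structure(dna_pdb)
    ann = annotate_structure(s)
    arg_pos = next(i for i, r in enumerate(s.get_chain("A").residues) if r.name == "ARG")
    v = classify_mechanism([("A", arg_pos)], ann, 1)
    assert v.category == "probably" and v.mechanisms == ("binding_site_disruption",)
    assert v.evidence["salt_bridge_distance"] <= 4.0


def test_remote_surface_loop_unlikely(hairpin_annotations):
    _, ann = hairpin_annotations
    v = classify_mechanism([("A", 24)], ann, 1)
    assert v.category == "unlikely" and v.mechanisms == ("none",)
    assert v.evidence["min_element_distance"] >= LOOP_ELEMENT_MIN_SEPARATION


def test_loop_adjacent_to_strand_unclear(hairpin_annotations):
    _, ann = hairpin_annotations
    v = classify_mechanism([("A", 8)], ann, 1)
    assert v.category == "unclear" and v.mechanisms == ("packing_loss",)


def test_unmapped_residues_unassessable(sheet_annotations):
    _, ann = sheet_annotations
    out = classify_mechanism([("Z", 99)], ann, 1)
    assert isinstance(out, Unassessable)
    out = classify_mechanism([], ann, 1)
    assert isinstance(out, Unassessable)


def test_verdict_invariants_over_random_annotations(rng):
    """classify_mechanism is total and its outputs satisfy the verdict
    invariants for arbitrary annotation combinations."""
    for _ in range(300):
        n_aff = int(rng.integers(1, 4))
        ann = {}
        keys = []
        for i in range(n_aff):
            ss_state = "HEC"[int(rng.integers(0, 3))]
            strand_pos = (
                ["edge", "central"][int(rng.integers(0, 2))] if ss_state == "E" else "not_in_sheet"
            )
            a = ResidueAnnotation(
                chain_id="A", chain_pos=i, seq_num=i + 1, residue_name="ALA",
                ss_state=ss_state, rsa=float(rng.uniform(0, 1)),
                is_surface=bool(rng.random() < 0.5),
                strand_position=strand_pos,
                interface_partner_chains=set("B") if rng.random() < 0.3 else set(),
                salt_bridges=[],
                element_distance=int(rng.integers(0, 8)),
                helix_has_interface=bool(rng.random() < 0.5),
            )
            ann[("A", i)] = a
            keys.append(("A", i))
        v = classify_mechanism(keys, ann, int(rng.integers(0, 4)))
        assert isinstance(v, MechanismVerdict)
        assert v.category in ("probably", "unclear", "unlikely")
        if v.category == "probably":
            assert v.mechanisms != ("none",)
        if v.category == "unlikely":
            assert v.mechanisms == ("none",)
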