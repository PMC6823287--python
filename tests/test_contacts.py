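"""Typed contact detectors against planted geometry and brute-force oracles."""

import numpy as np
import pytest

from subspec.contacts import (
    HBOND_MM, SALT_BRIDGE, HYDROPHOBIC, WATER_BRIDGE, LIGAND_POLAR,
    INTRA_SEGMENT, INTER_SEGMENT, INTER_CHAIN, UNASSIGNED,
    SegmentMap, hydrogen_bonds, salt_bridges, hydrophobic_contacts,
    water_bridges, ligand_polar_contacts, generic_contacts, label_context,
)
from subspec.struct_geom import parse_structure
from subspec.synthetic_data import (
    StructureSimSpec, gen_toy_structure, PdbBuilder,
)


def two_residue_pdb(res_a, res_b):
    """res_x: (resname, {atom: xyz})"""
    b = PdbBuilder()
    for i, (resname, atoms) in enumerate((res_a, res_b), start=1):
        for name, xyz in atoms.items():
            b.atom(name, resname, "A", i, np.asarray(xyz, float))
    return parse_structure(b.text())


# --- hydrogen bonds ---------------------------------------------------------

def test_backbone_pair_within_cutoff_detected():
    s = two_residue_pdb(
        ("GLY", {"N": (0, 0, 0), "CA": (1.4, 0, 0), "C": (2, 1.2, 0),
                 "O": (3.2, 1.3, 0)}),
        ("GLY", {"N": (3.2, 1.3, 2.9), "CA": (4.4, 1.5, 3.3),
                 "C": (5, 2.5, 3.3), "O": (6.2, 2.5, 3.3)}))
    # adjacent residues are excluded for MM pairs; renumber to separate
    s.residues[1].number = 5
    hb = hydrogen_bonds(s, [s.residues[0]], [s.residues[1]])
    assert any(i.type == HBOND_MM and i.distance == pytest.approx(2.9)
               for i in hb)


def test_pair_just_beyond_cutoff_ignored():
    s = two_residue_pdb(
        ("GLY", {"N": (0, 0, 0), "O": (1.5, 0, 0)}),
        ("GLY", {"N": (0, 0, 3.6), "O": (1.5, 0, 3.6)}))
    s.residues[1].number = 5
    assert hydrogen_bonds(s, [s.residues[0]], [s.residues[1]]) == []


def test_helix_finds_exactly_planted_i_i4_pairs(helix):
    structure, truth = helix
    prot = structure.protein_residues()
    hb = hydrogen_bonds(structure, prot, prot)
    got = sorted((min(i.res_a[1], i.res_b[1]), max(i.res_a[1], i.res_b[1]))
                 for i in hb)
    assert got == sorted(tuple(p) for p in truth["hbond_pairs"])
    assert all(i.type == HBOND_MM for i in hb)


def test_hbonds_symmetric_in_selections(helix):
    structure, _ = helix
    a = structure.protein_residues()[:6]
    b = structure.protein_residues()[6:]
    fwd = {(i.res_a, i.res_b, i.atom_a, i.atom_b)
           for i in hydrogen_bonds(structure, a, b)}
    rev = {(i.res_a, i.res_b, i.atom_a, i.atom_b)
           for i in hydrogen_bonds(structure, b, a)}
    assert fwd == rev


# --- salt bridges -----------------------------------------------------------

@pytest.mark.parametrize("distance,expected,strong", [
    (3.2, 1, True),
    (5.5, 1, False),
    (6.5, 0, None),
])
def test_ion_pair_recipe(distance, expected, strong):
    toy = gen_toy_structure(StructureSimSpec("ion_pair", distance=distance))
    s = parse_structure(toy.pdb_text)
    prot = s.protein_residues()
    sb = salt_bridges(s, prot, prot)
    assert len(sb) == expected
    if expected:
        assert sb[0].strong is strong
        assert toy.truth["salt_bridge"]


def test_uncharged_partner_not_a_salt_bridge():
    s = two_residue_pdb(
        ("ASP", {"OD1": (0, 0, 0), "OD2": (1.0, 1.0, 0), "CG": (0.6, 0.5, 0)}),
        ("SER", {"OG": (3.0, 0, 0), "CB": (4.0, 0, 0)}))
    assert salt_bridges(s, s.residues[:1], s.residues[1:]) == []


# --- hydrophobic ------------------------------------------------------------

def test_apolar_sidechain_carbons_contact():
    s = two_residue_pdb(
        ("LEU", {"CD1": (0, 0, 0), "CG": (-1.4, 0, 0)}),
        ("ILE", {"CD1": (4.0, 0, 0), "CG1": (5.4, 0, 0)}))
    hc = hydrophobic_contacts(s, s.residues[:1], s.residues[1:])
    assert len(hc) == 1 and hc[0].distance == pytest.approx(4.0)


def test_polar_partner_excluded_from_hydrophobic():
    s = two_residue_pdb(
        ("LEU", {"CD1": (0, 0, 0)}),
        ("SER", {"CB": (4.0, 0, 0)}))
    assert hydrophobic_contacts(s, s.residues[:1], s.residues[1:]) == []


def test_two_helix_bundle_count_matches_brute_force(helix):
    """Generic heavy-atom contacts across two stacked helices equal the full
    distance-matrix enumeration."""
    structure, _ = helix
    b = PdbBuilder()
    for r, a in structure.atoms():
        b.atom(a.name, r.name, "A", r.number, a.coord)
    for r, a in structure.atoms():
        b.atom(a.name, r.name, "B", r.number, a.coord + np.array([0, 5.5, 0]))
    s2 = parse_structure(b.text())
    sel_a = s2.select(chain="A")
    sel_b = s2.select(chain="B")
    got = generic_contacts(s2, sel_a, sel_b, cutoff=4.5)

    # oracle: all-pairs distance matrix, collapse to residue pairs
    pairs = set()
    for ra in sel_a:
        for rb in sel_b:
            for aa in ra.atoms.values():
                for ab in rb.atoms.values():
                    if np.linalg.norm(aa.coord - ab.coord) <= 4.5:
                        pairs.add((ra.key, rb.key))
    assert {(i.res_a, i.res_b) for i in got} == pairs


# --- water bridges & ligand contacts ---------------------------------------

def test_pocket_water_bridges_match_truth(pocket):
    structure, truth = pocket
    prot = structure.protein_residues()
    wb = water_bridges(structure, prot, structure.ligands("4IP"))
    got = {(i.res_a[:2], i.water[:2], i.atom_b) for i in wb}
    want = {(tuple(x["residue"]), tuple(x["water"]), x["ligand_atom"])
            for x in truth["water_bridges"]}
    assert got == want
    assert len({i.water for i in wb}) == truth["n_bridging_waters"]


def test_water_near_protein_only_is_no_bridge(pocket):
    structure, _ = pocket
    prot = structure.protein_residues()
    wb = water_bridges(structure, prot, structure.ligands("4IP"))
    assert ("W", 2, "") not in {i.water for i in wb}


def test_pocket_polar_residues_match_truth(pocket):
    structure, truth = pocket
    lp = ligand_polar_contacts(structure, "4IP")
    got = sorted({i.res_a[:2] for i in lp})
    assert got == sorted(tuple(x) for x in truth["polar_contact_residues"])


def test_missing_ligand_error_names_available_codes(pocket):
    structure, _ = pocket
    with pytest.raises(ValueError, match="4IP"):
        ligand_polar_contacts(structure, "I3P")


def test_carbon_only_proximity_is_not_polar():
    b = PdbBuilder()
    b.atom("CB", "ALA", "A", 1, np.array([0.0, 0, 0]))
    b.atom("C1", "LIG", "L", 1, np.array([3.0, 0, 0]), het=True, element="C")
    b.atom("O1", "LIG", "L", 1, np.array([9.0, 0, 0]), het=True, element="O")
    s = parse_structure(b.text())
    assert ligand_polar_contacts(s, "LIG") == []


# --- invariance and monotonicity -------------------------------------------

def test_detectors_invariant_under_rigid_motion(pocket):
    structure, _ = pocket
    theta = 1.1
    rot = np.array([[np.cos(theta), 0, np.sin(theta)],
                    [0, 1, 0],
                    [-np.sin(theta), 0, np.cos(theta)]])
    b = PdbBuilder()
    for r, a in structure.atoms():
        b.atom(a.name, r.name, r.chain_id, r.number,
               rot @ a.coord + np.array([-4.0, 9.0, 2.0]),
               het=r.hetero, element=a.element)
    moved = parse_structure(b.text())

    def signature(s):
        prot = s.protein_residues()
        lp = ligand_polar_contacts(s, "4IP")
        wb = water_bridges(s, prot, s.ligands("4IP"))
        return ({(i.res_a, i.atom_a, i.atom_b) for i in lp},
                {(i.res_a, i.water) for i in wb})
    assert signature(structure) == signature(moved)


def test_shrinking_cutoff_yields_subset(helix):
    structure, _ = helix
    prot = structure.protein_residues()
    wide = {(i.res_a, i.res_b, i.atom_a, i.atom_b)
            for i in hydrogen_bonds(structure, prot, prot, cutoff=3.5)}
    narrow = {(i.res_a, i.res_b, i.atom_a, i.atom_b)
              for i in hydrogen_bonds(structure, prot, prot, cutoff=3.0)}
    assert narrow <= wide
    for ia in hydrogen_bonds(structure, prot, prot, cutoff=3.0):
        assert ia.distance <= 3.0


# --- context labeling -------------------------------------------------------

SEGMENTS = SegmentMap(
    segments={"PH": ("A", 1, 6), "linker": ("A", 7, 9), "helixC": ("A", 10, 12)},
    partner_chains={"B": "Arf6"},
)


def test_label_context_classes(helix):
    structure, _ = helix
    prot = structure.protein_residues()
    labeled = label_context(hydrogen_bonds(structure, prot, prot), SEGMENTS)
    by_pair = {}
    for ia in labeled:
        lo = min(ia.res_a[1], ia.res_b[1])
        hi = max(ia.res_a[1], ia.res_b[1])
        by_pair[(lo, hi)] = ia
    assert by_pair[(1, 5)].context == INTRA_SEGMENT          # both in PH
    assert by_pair[(3, 7)].context == INTER_SEGMENT          # PH x linker
    assert set(by_pair[(3, 7)].context_pair) == {"PH", "linker"}


def test_inter_chain_uses_partner_names():
    b = PdbBuilder()
    b.atom("O", "GLY", "A", 2, np.array([0.0, 0, 0]))
    b.atom("N", "GLY", "B", 40, np.array([2.9, 0, 0]))
    s = parse_structure(b.text())
    labeled = label_context(
        hydrogen_bonds(s, s.select(chain="A"), s.select(chain="B")), SEGMENTS)
    assert labeled[0].context == INTER_CHAIN
    assert "Arf6" in labeled[0].context_pair


def test_unassigned_residue_kept():
    seg = SegmentMap(segments={"PH": ("A", 1, 3)})
    b = PdbBuilder()
    b.atom("O", "GLY", "A", 2, np.array([0.0, 0, 0]))
    b.atom("N", "GLY", "A", 99, np.array([2.9, 0, 0]))
    s = parse_structure(b.text())
    labeled = label_context(hydrogen_bonds(s, s.residues, s.residues), seg)
    assert labeled and labeled[0].context == UNASSIGNED
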