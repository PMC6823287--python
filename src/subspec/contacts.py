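"""Typed residue-residue and residue-ligand contact detection.

Heavy-atom, distance-only criteria (the inputs carry no hydrogens):

* hydrogen bonds — donor N/O to acceptor N/O within 3.5 A, classified
  main-main / main-side / side-side by backbone membership of the two atoms;
  main-main pairs between sequence neighbours (|i-j| < 2) are covalently
  constrained and skipped;
* salt bridges — side-chain charged-group atoms (Asp/Glu carboxylate x
  Lys/Arg/His nitrogen) within 6.0 A, flagged "strong" at <= 4.0 A;
* hydrophobic contacts — side-chain carbons of apolar residues within 5.0 A,
  one record per residue pair at the closest atom pair;
* water bridges — protein polar atom and ligand O/P atom both within 3.5 A
  of the same ordered water oxygen;
* ligand polar contacts — protein N/O within 3.5 A of a ligand O/P atom;
* generic contacts — any heavy-atom pair within 4.5 A, for interface
  membership robustness checks.

``label_context`` places each contact in a segment map (named residue
ranges: domains, linkers, helices, partner chains) as intra-segment,
inter-segment or inter-chain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import yaml

from .struct_geom import Structure, Residue

# interaction type tags
HBOND_MM = "HBOND_MM"
HBOND_MS = "HBOND_MS"
HBOND_SS = "HBOND_SS"
SALT_BRIDGE = "SALT_BRIDGE"
HYDROPHOBIC = "HYDROPHOBIC"
WATER_BRIDGE = "WATER_BRIDGE"
LIGAND_POLAR = "LIGAND_POLAR"
GENERIC_CONTACT = "GENERIC_CONTACT"

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
BACKBONE_POLAR = {"N", "O", "OXT"}

# side-chain donor/acceptor heavy atoms per residue chemistry
SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

CHARGED_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}, "HIS": {"ND1", "NE2"},
}
ACIDIC = {"ASP", "GLU"}
BASIC = {"LYS", "ARG", "HIS"}

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP",
                        "PRO", "TYR"}

# contexts
INTRA_SEGMENT = "INTRA_SEGMENT"
INTER_SEGMENT = "INTER_SEGMENT"
INTER_CHAIN = "INTER_CHAIN"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class Interaction:
    type: str
    res_a: tuple  # residue key (chain, number, icode)
    resname_a: str
    atom_a: str
    res_b: tuple
    resname_b: str
    atom_b: str
    distance: float
    water: tuple | None = None   # bridging water residue key
    strong: bool = False         # salt bridges at <= 4.0 A
    context: str | None = None
    context_pair: tuple[str, str] | None = None

    @property
    def residue_pair(self) -> frozenset:
        return frozenset((self.res_a, self.res_b))


def _donors(res: Residue) -> list:
    out = []
    if not res.hetero and "N" in res.atoms:
        out.append(res.atoms["N"])
    for name in SIDECHAIN_DONORS.get(res.name, ()):
        if name in res.atoms:
            out.append(res.atoms[name])
    return out


def _acceptors(res: Residue) -> list:
    out = []
    if not res.hetero:
        for name in BACKBONE_POLAR - {"N"}:
            if name in res.atoms:
                out.append(res.atoms[name])
    for name in SIDECHAIN_ACCEPTORS.get(res.name, ()):
        if name in res.atoms:
            out.append(res.atoms[name])
    return out


def _dist(a, b) -> float:
    return float(np.linalg.norm(a.coord - b.coord))


def _sequence_adjacent(res_a: Residue, res_b: Residue) -> bool:
    return (res_a.chain_id == res_b.chain_id
            and abs(res_a.number - res_b.number) < 2)


def _hbond_type(atom_a: str, atom_b: str) -> str:
    a_bb = atom_a in BACKBONE_POLAR
    b_bb = atom_b in BACKBONE_POLAR
    if a_bb and b_bb:
        return HBOND_MM
    if a_bb or b_bb:
        return HBOND_MS
    return HBOND_SS


def hydrogen_bonds(structure: Structure, sel_a: Sequence[Residue],
                   sel_b: Sequence[Residue], cutoff: float = 3.5) -> list[Interaction]:
    """Donor-acceptor heavy-atom pairs within the cutoff, both directions.

    Symmetric in the two selections; at most one record per (residue pair,
    atom pair). Main-main pairs between residues adjacent in sequence are
    skipped (their N/O separation is fixed by the peptide bond).
    """
    out: dict[tuple, Interaction] = {}
    for ra, rb in itertools.product(sel_a, sel_b):
        if ra.key == rb.key:
            continue
        for donor_res, acceptor_res in ((ra, rb), (rb, ra)):
            for d in _donors(donor_res):
                for acc in _acceptors(acceptor_res):
                    dist = _dist(d, acc)
                    if dist > cutoff:
                        continue
                    btype = _hbond_type(d.name, acc.name)
                    if btype == HBOND_MM and _sequence_adjacent(donor_res, acceptor_res):
                        continue
                    key = (frozenset((donor_res.key, acceptor_res.key)),
                           frozenset(((donor_res.key, d.name),
                                      (acceptor_res.key, acc.name))))
                    if key not in out or dist < out[key].distance:
                        out[key] = Interaction(
                            type=btype,
                            res_a=donor_res.key, resname_a=donor_res.name,
                            atom_a=d.name,
                            res_b=acceptor_res.key, resname_b=acceptor_res.name,
                            atom_b=acc.name, distance=dist)
    return sorted(out.values(), key=lambda i: (i.res_a, i.res_b, i.atom_a, i.atom_b))


def salt_bridges(structure: Structure, sel_a: Sequence[Residue],
                 sel_b: Sequence[Residue], cutoff: float = 6.0,
                 strong_cutoff: float = 4.0) -> list[Interaction]:
    """Acidic-basic side-chain charged-atom pairs within the cutoff.

    One record per residue pair at the closest charged-atom pair; records
    at or below ``strong_cutoff`` carry ``strong=True``.
    """
    best: dict[frozenset, Interaction] = {}
    for ra, rb in itertools.product(sel_a, sel_b):
        if ra.key == rb.key:
            continue
        pair_types = {ra.name in ACIDIC and rb.name in BASIC,
                      ra.name in BASIC and rb.name in ACIDIC}
        if True not in pair_types:
            continue
        for a_name in CHARGED_ATOMS.get(ra.name, ()):
            if a_name not in ra.atoms:
                continue
            for b_name in CHARGED_ATOMS.get(rb.name, ()):
                if b_name not in rb.atoms:
                    continue
                dist = _dist(ra.atoms[a_name], rb.atoms[b_name])
                if dist > cutoff:
                    continue
                pair = frozenset((ra.key, rb.key))
                if pair not in best or dist < best[pair].distance:
                    best[pair] = Interaction(
                        type=SALT_BRIDGE,
                        res_a=ra.key, resname_a=ra.name, atom_a=a_name,
                        res_b=rb.key, resname_b=rb.name, atom_b=b_name,
                        distance=dist, strong=dist <= strong_cutoff)
    return sorted(best.values(), key=lambda i: (i.res_a, i.res_b))


def hydrophobic_contacts(structure: Structure, sel_a: Sequence[Residue],
                         sel_b: Sequence[Residue],
                         cutoff: float = 5.0) -> list[Interaction]:
    """Side-chain carbon pairs of apolar residues within the cutoff; one
    record per residue pair (closest atoms kept)."""
    best: dict[frozenset, Interaction] = {}
    for ra, rb in itertools.product(sel_a, sel_b):
        if ra.key == rb.key:
            continue
        if ra.name not in HYDROPHOBIC_RESIDUES or rb.name not in HYDROPHOBIC_RESIDUES:
            continue
        for aa in ra.atoms.values():
            if aa.element != "C" or aa.name in BACKBONE_ATOMS:
                continue
            for ab in rb.atoms.values():
                if ab.element != "C" or ab.name in BACKBONE_ATOMS:
                    continue
                dist = _dist(aa, ab)
                if dist > cutoff:
                    continue
                pair = frozenset((ra.key, rb.key))
                if pair not in best or dist < best[pair].distance:
                    best[pair] = Interaction(
                        type=HYDROPHOBIC,
                        res_a=ra.key, resname_a=ra.name, atom_a=aa.name,
                        res_b=rb.key, resname_b=rb.name, atom_b=ab.name,
                        distance=dist)
    return sorted(best.values(), key=lambda i: (i.res_a, i.res_b))


def _polar_atoms(res: Residue) -> list:
    return [a for a in res.atoms.values() if a.element in ("N", "O")]


def water_bridges(structure: Structure, sel_protein: Sequence[Residue],
                  sel_ligand: Sequence[Residue],
                  cutoff: float = 3.5) -> list[Interaction]:
    """Protein-water-ligand polar triples through one ordered water oxygen."""
    out = []
    waters = structure.waters()
    for w in waters:
        w_o = next((a for a in w.atoms.values() if a.element == "O"), None)
        if w_o is None:
            continue
        prot_near = [(r, a) for r in sel_protein for a in _polar_atoms(r)
                     if _dist(a, w_o) <= cutoff]
        lig_near = [(r, a) for r in sel_ligand for a in r.atoms.values()
                    if a.element in ("O", "P") and _dist(a, w_o) <= cutoff]
        for (pr, pa), (lr, la) in itertools.product(prot_near, lig_near):
            out.append(Interaction(
                type=WATER_BRIDGE,
                res_a=pr.key, resname_a=pr.name, atom_a=pa.name,
                res_b=lr.key, resname_b=lr.name, atom_b=la.name,
                distance=max(_dist(pa, w_o), _dist(la, w_o)),
                water=w.key))
    return sorted(out, key=lambda i: (i.res_a, i.res_b, i.water))


def ligand_polar_contacts(structure: Structure, ligand_code: str,
                          cutoff: float = 3.5,
                          sel_protein: Sequence[Residue] | None = None
                          ) -> list[Interaction]:
    """Protein N/O atoms within the cutoff of ligand O/P atoms.

    One record per (protein residue, ligand atom) pair at the closest
    protein atom. Raises if the ligand code is absent, naming the HET codes
    that are present.
    """
    ligands = structure.ligands(ligand_code)
    if not ligands:
        available = sorted({r.name for r in structure.ligands()})
        raise ValueError(
            f"ligand {ligand_code!r} not found; available HET codes: {available}")
    if sel_protein is None:
        sel_protein = structure.protein_residues()
    best: dict[tuple, Interaction] = {}
    for lig in ligands:
        for la in lig.atoms.values():
            if la.element not in ("O", "P"):
                continue
            for r in sel_protein:
                for pa in _polar_atoms(r):
                    dist = _dist(pa, la)
                    if dist > cutoff:
                        continue
                    key = (r.key, lig.key, la.name)
                    if key not in best or dist < best[key].distance:
                        best[key] = Interaction(
                            type=LIGAND_POLAR,
                            res_a=r.key, resname_a=r.name, atom_a=pa.name,
                            res_b=lig.key, resname_b=lig.name, atom_b=la.name,
                            distance=dist)
    return sorted(best.values(), key=lambda i: (i.res_a, i.res_b, i.atom_b))


def generic_contacts(structure: Structure, sel_a: Sequence[Residue],
                     sel_b: Sequence[Residue],
                     cutoff: float = 4.5) -> list[Interaction]:
    """Any heavy-atom pair within the cutoff; one record per residue pair."""
    best: dict[frozenset, Interaction] = {}
    for ra, rb in itertools.product(sel_a, sel_b):
        if ra.key == rb.key:
            continue
        for aa in ra.atoms.values():
            for ab in rb.atoms.values():
                dist = _dist(aa, ab)
                if dist > cutoff:
                    continue
                pair = frozenset((ra.key, rb.key))
                if pair not in best or dist < best[pair].distance:
                    best[pair] = Interaction(
                        type=GENERIC_CONTACT,
                        res_a=ra.key, resname_a=ra.name, atom_a=aa.name,
                        res_b=rb.key, resname_b=rb.name, atom_b=ab.name,
                        distance=dist)
    return sorted(best.values(), key=lambda i: (i.res_a, i.res_b))


@dataclass
class SegmentMap:
    """Named residue ranges (chain, start, end) plus named partner chains."""

    segments: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    partner_chains: dict[str, str] = field(default_factory=dict)  # chain id -> name

    def __post_init__(self):
        if len(self.segments) != len(set(self.segments)):
            raise ValueError("segment names must be unique")

    @classmethod
    def from_yaml(cls, stream) -> "SegmentMap":
        d = yaml.safe_load(stream) or {}
        segments = {name: (v["chain"], int(v["start"]), int(v["end"]))
                    for name, v in d.get("segments", {}).items()}
        partners = {str(v): str(k) for k, v in d.get("partner_chains", {}).items()}
        return cls(segments=segments, partner_chains=partners)

    def segment_of(self, residue_key: tuple) -> str | None:
        chain, number = residue_key[0], residue_key[1]
        for name, (seg_chain, start, end) in self.segments.items():
            if chain == seg_chain and start <= number <= end:
                return name
        return None

    def partner_of(self, chain: str) -> str:
        return self.partner_chains.get(chain, chain)


def label_context(interactions: Iterable[Interaction],
                  segment_map: SegmentMap) -> list[Interaction]:
    """Attach segment/chain context to every interaction.

    Inter-chain contacts are labeled with the partner names of the two
    chains; within a chain, contacts crossing segment boundaries become
    inter-segment; residues outside any named segment are kept as
    UNASSIGNED.
    """
    out = []
    for ia in interactions:
        chain_a, chain_b = ia.res_a[0], ia.res_b[0]
        if chain_a != chain_b:
            out.append(replace(ia, context=INTER_CHAIN,
                               context_pair=(segment_map.partner_of(chain_a),
                                             segment_map.partner_of(chain_b))))
            continue
        seg_a = segment_map.segment_of(ia.res_a)
        seg_b = segment_map.segment_of(ia.res_b)
        if seg_a is None or seg_b is None:
            out.append(replace(ia, context=UNASSIGNED,
                               context_pair=(seg_a or UNASSIGNED,
                                             seg_b or UNASSIGNED)))
        elif seg_a == seg_b:
            out.append(replace(ia, context=INTRA_SEGMENT,
                               context_pair=(seg_a, seg_b)))
        else:
            out.append(replace(ia, context=INTER_SEGMENT,
                               context_pair=(seg_a, seg_b)))
    return out


def write_interactions_tsv(interactions: Iterable[Interaction],
                           stream: TextIO) -> None:
    stream.write("type\tchainA\tresA\tresnameA\tatomA\t"
                 "chainB\tresB\tresnameB\tatomB\tdistance\tcontext\tpair\n")
    for ia in interactions:
        pair = "|".join(ia.context_pair) if ia.context_pair else ""
        stream.write(
            f"{ia.type}\t{ia.res_a[0]}\t{ia.res_a[1]}\t{ia.resname_a}\t{ia.atom_a}\t"
            f"{ia.res_b[0]}\t{ia.res_b[1]}\t{ia.resname_b}\t{ia.atom_b}\t"
            f"{ia.distance:.2f}\t{ia.context or ''}\t{pair}\n")
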