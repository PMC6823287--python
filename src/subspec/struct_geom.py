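"""Structure parsing and solvent accessibility.

A lightweight PDB reader (ATOM/HETATM fixed columns, first model, highest-
occupancy altloc, hydrogens dropped) feeds a from-scratch Shrake-Rupley
solvent-accessible surface area computation: each heavy atom carries a
sphere of radius vdW + probe (probe 1.4 angstrom, a water), sampled with a
deterministic golden-spiral point set; the accessible area is the sphere
area times the fraction of sample points not occluded by any neighbouring
atom's expanded sphere. Per-residue relative solvent accessibility (RSA, %)
divides the summed residue area by a theoretical maximum for that residue
type in an extended Gly-X-Gly context; residues at or below 7% RSA are
flagged buried.

The quadrature is RNG-free, so areas are bit-stable across runs; they are
rotation/translation invariant up to the point-set discretisation (< 0.5%).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
from scipy.spatial import cKDTree

WATER_NAMES = {"HOH", "WAT", "DOD"}

# element-based van der Waals radii (angstrom); heavy atoms only
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW = 1.70

# theoretical maximum all-atom ASA per residue type (Gly-X-Gly, angstrom^2),
# Tien et al. theoretical column
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,)
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    hetero: bool
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_ligand(self) -> bool:
        return self.hetero and not self.is_water


class Structure:
    """Chains -> residues -> heavy atoms, author numbering preserved."""

    def __init__(self, residues: list[Residue]):
        self.residues = residues
        self._by_key = {r.key: r for r in residues}

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def get(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        return self._by_key.get((chain_id, number, icode))

    def select(self, chain: str | None = None, het: bool | None = None,
               water: bool | None = None, resname: str | None = None) -> list[Residue]:
        out = []
        for r in self.residues:
            if chain is not None and r.chain_id != chain:
                continue
            if het is not None and r.hetero != het:
                continue
            if water is not None and r.is_water != water:
                continue
            if resname is not None and r.name != resname:
                continue
            out.append(r)
        return out

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.hetero]

    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    def ligands(self, code: str | None = None) -> list[Residue]:
        ligs = [r for r in self.residues if r.is_ligand]
        if code is not None:
            ligs = [r for r in ligs if r.name == code]
        return ligs

    def atoms(self, residues: Iterable[Residue] | None = None):
        """Flat (residue, atom) pairs in file order."""
        pool = self.residues if residues is None else residues
        for r in pool:
            for a in r.atoms.values():
                yield r, a

    def coordinates(self) -> np.ndarray:
        return np.array([a.coord for _, a in self.atoms()])


def _infer_element(atom_name: str, record_element: str) -> str:
    el = record_element.strip().upper()
    if el and el != "X":
        return el
    # fall back to the atom-name convention: first alphabetic character of the
    # name, skipping leading digits (e.g. "1HB"); two-letter names are rare
    # among heavy atoms in standard residues
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def parse_structure(pdb_stream: TextIO | str, model: int = 1) -> Structure:
    """Parse PDB-format text into a Structure.

    Keeps only the requested model, drops hydrogens, resolves alternate
    locations by highest occupancy (ties go to altloc 'A', then file order),
    and retains HETATM records with their hetero flag.
    """
    if isinstance(pdb_stream, str):
        pdb_stream = io.StringIO(pdb_stream)

    residues: dict[tuple, Residue] = {}
    current_model = 1
    saw_atom = False
    for line in pdb_stream:
        rec = line[:6]
        if rec.startswith("MODEL"):
            try:
                current_model = int(line[10:14])
            except ValueError:
                current_model = 1
            continue
        if rec.startswith("ENDMDL"):
            current_model = None
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if current_model is None or current_model != model:
            # after ENDMDL of the wanted model we may still see other models
            if current_model is None:
                current_model = model + 1  # sentinel: past requested model
            continue
        saw_atom = rec == "ATOM  " or saw_atom
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip()
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        occ_raw = line[54:60].strip()
        occupancy = float(occ_raw) if occ_raw else 1.0
        element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
        if element == "H" or element == "D":
            continue
        key = (chain, resseq, icode)
        res = residues.get(key)
        if res is None:
            res = Residue(chain_id=chain, number=resseq, icode=icode,
                          name=resname, hetero=(rec == "HETATM"))
            residues[key] = res
        atom = Atom(name=name, element=element,
                    coord=np.array([x, y, z], dtype=float),
                    occupancy=occupancy, altloc=altloc)
        existing = res.atoms.get(name)
        if existing is None:
            res.atoms[name] = atom
        else:
            # altloc resolution: highest occupancy wins; tie prefers 'A'
            if (atom.occupancy, atom.altloc == "A") > (
                    existing.occupancy, existing.altloc == "A"):
                res.atoms[name] = atom

    if not saw_atom:
        raise ValueError("no ATOM records found")
    return Structure([r for r in residues.values() if r.atoms])


def golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _local_frame(origin: np.ndarray,
                 neighbour_coords: list[np.ndarray]) -> np.ndarray:
    """Orthonormal frame built from an atom's nearest occluding neighbours.

    Orienting each atom's quadrature lattice in a neighbour-derived frame
    makes the exposed/occluded decision co-rotate with the structure, so the
    computed areas are invariant under rigid motion up to coordinate
    rounding — a shared world-frame lattice would instead drift. The frame
    is deterministic: neighbours arrive distance-sorted with index
    tie-breaks. Atoms with no or only collinear neighbours fall back to a
    fixed axis choice (their area barely depends on orientation).
    """
    if not neighbour_coords:
        return np.eye(3)
    e1 = neighbour_coords[0] - origin
    e1 = e1 / np.linalg.norm(e1)
    e2 = None
    for c in neighbour_coords[1:]:
        v = c - origin
        v = v - (v @ e1) * e1
        n = np.linalg.norm(v)
        if n > 1e-6:
            e2 = v / n
            break
    if e2 is None:
        v = np.zeros(3)
        v[int(np.argmin(np.abs(e1)))] = 1.0
        v = v - (v @ e1) * e1
        e2 = v / np.linalg.norm(v)
    return np.column_stack([e1, e2, np.cross(e1, e2)])


@dataclass
class SasaResult:
    atom_area: list[float]                      # parallel to atom order
    atom_index: list[tuple[tuple, str]]         # (residue key, atom name)
    residue_area: dict[tuple, float]            # residue key -> summed area
    rsa: dict[tuple, float]                     # residue key -> RSA percent
    unreferenced: set[tuple]                    # residues lacking a max-ASA entry

    @property
    def total_area(self) -> float:
        return float(sum(self.atom_area))


def shrake_rupley(structure: Structure, probe: float = 1.4,
                  n_points: int = 960,
                  include_het: bool = True,
                  include_water: bool = False) -> SasaResult:
    """Per-atom and per-residue solvent-accessible surface area.

    Waters are excluded from the atom set by default (NACCESS-like); ligands
    are kept. Neighbour candidates come from a KD-tree at the maximum
    possible contact radius, so occlusion is exact with respect to the point
    set.
    """
    pool: list[Residue] = []
    for r in structure.residues:
        if r.is_water and not include_water:
            continue
        if r.is_ligand and not include_het:
            continue
        pool.append(r)

    keys, names, coords, radii = [], [], [], []
    for r, a in structure.atoms(pool):
        keys.append(r.key)
        names.append(a.name)
        coords.append(a.coord)
        radii.append(VDW_RADII.get(a.element, DEFAULT_VDW) + probe)
    if not coords:
        raise ValueError("structure has no atoms to analyse")
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    sphere = golden_spiral(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        neighbours.sort(
            key=lambda j: (float(np.sum((coords[j] - coords[i]) ** 2)), j))
        frame = _local_frame(coords[i], [coords[j] for j in neighbours])
        pts = coords[i] + radii[i] * (sphere @ frame.T)
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * exposed.mean()

    residue_area: dict[tuple, float] = {}
    for key, area in zip(keys, areas):
        residue_area[key] = residue_area.get(key, 0.0) + float(area)

    rsa: dict[tuple, float] = {}
    unreferenced: set[tuple] = set()
    for r in pool:
        ref = MAX_ASA.get(r.name)
        if ref is None:
            unreferenced.add(r.key)
            continue
        rsa[r.key] = 100.0 * residue_area.get(r.key, 0.0) / ref

    return SasaResult(
        atom_area=[float(a) for a in areas],
        atom_index=list(zip(keys, names)),
        residue_area=residue_area,
        rsa=rsa,
        unreferenced=unreferenced,
    )


def relative_accessibility(sasa: SasaResult) -> dict[tuple, float]:
    """Residue key -> RSA percent (residues without a reference are omitted)."""
    return dict(sasa.rsa)


def buried_set(rsa_map: Mapping[tuple, float], cutoff: float = 7.0) -> set[tuple]:
    """Residues with RSA <= cutoff (inclusive)."""
    return {key for key, rsa in rsa_map.items() if rsa <= cutoff}


def write_sasa_tsv(structure: Structure, sasa: SasaResult, stream: TextIO,
                   cutoff: float = 7.0) -> None:
    stream.write("chain\tresnum\tresname\tarea\tRSA\tburied\n")
    for r in structure.residues:
        if r.key not in sasa.residue_area:
            continue
        rsa = sasa.rsa.get(r.key)
        rsa_s = f"{rsa:.2f}" if rsa is not None else ""
        buried = int(rsa is not None and rsa <= cutoff)
        stream.write(f"{r.chain_id}\t{r.number}\t{r.name}\t"
                     f"{sasa.residue_area[r.key]:.2f}\t{rsa_s}\t{buried}\n")
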