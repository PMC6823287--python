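"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Three generators make the pipeline testable without any database access:

* ``gen_alignment_pair`` — a pair of subfamily alignments plus their stacked
  combined alignment, with a planted class per column (shared-conserved,
  specific to either or both subfamilies, or variable). Planted specific
  columns are constructed so no cross-subfamily exclusion can fire at zero
  noise: the opposing subfamily mixes residues that share no Clustal strong
  or weak group with the planted residue, none above the 50% veto level.
* ``gen_annotation_set`` — domain-annotation tables matching a two-domain
  architecture, with defect entries each violating exactly one rejection
  rule, plus near-duplicate sequences for clustering tests.
* ``gen_toy_structure`` — small PDB files with geometry planted at stated
  distances: an ideal alpha-helix (i -> i+4 backbone hydrogen bonds), an
  extended strand pair, an Asp/Arg ion pair at a chosen separation, a fully
  enclosed atom (zero accessible surface), and a ligand pocket with polar
  contacts and water bridges.

All generators take a seed, are byte-deterministic for a fixed seed, and
return machine-readable truth alongside the data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .specificity import STRONG_GROUPS, WEAK_GROUPS, AMINO_ACIDS

# ---------------------------------------------------------------------------
# alignment pairs with planted column classes
# ---------------------------------------------------------------------------

PLANT_CLASSES = ("SHARED_CONSERVED", "DA_SPECIFIC_A", "DA_SPECIFIC_B",
                 "DA_SPECIFIC_BOTH", "VARIABLE")


def _groups_of(residue: str) -> list[frozenset]:
    return [g for g in STRONG_GROUPS + WEAK_GROUPS if residue in g]


def _compatible(res_a: str, res_b: str) -> bool:
    """True when the two residues share a strong or weak group (or are equal)."""
    if res_a == res_b:
        return True
    return any(res_b in g for g in _groups_of(res_a))


def _incompatible_pool(avoid: Sequence[str], k: int) -> list[str]:
    """k residues, mutually incompatible and incompatible with all of
    ``avoid`` — a mixture of them can never be conserved at residue, strong
    or weak group level, and never trips a same-type veto for ``avoid``."""
    candidates = [r for r in AMINO_ACIDS
                  if not any(_compatible(r, a) for a in avoid)]
    for combo in itertools.combinations(candidates, k):
        if all(not _compatible(x, y) for x, y in itertools.combinations(combo, 2)):
            return list(combo)
    raise ValueError(f"no {k} mutually incompatible residues avoiding {avoid}")


@dataclass
class AlignmentSimSpec:
    """Study conditions for one simulated subfamily alignment pair.

    ``column_classes`` assigns a planted class per column; ``noise`` is the
    per-cell probability of replacing the planted residue with a uniform
    random one, ``gap_rate`` the per-cell gap probability, and
    ``conservation_level`` the planted fraction of sequences carrying the
    conserved residue in conserved columns.
    """

    n_seqs_a: int = 10
    n_seqs_b: int = 10
    column_classes: Sequence[str] = ()
    noise: float = 0.0
    gap_rate: float = 0.0
    conservation_level: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for rate in (self.noise, self.gap_rate, self.conservation_level):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        for cls in self.column_classes:
            if cls not in PLANT_CLASSES:
                raise ValueError(f"unknown planted class {cls!r}")
        if self.conservation_level < 0.85:
            raise ValueError(
                "planted conservation level below 0.85 can never be "
                "recovered at the 85% threshold")


def _conserved_column(rng: np.random.Generator, n: int, residue: str,
                      level: float, filler: list[str]) -> list[str]:
    """n cells conserving ``residue`` at >= level, rest from filler."""
    n_cons = max(int(math.ceil(level * n)), 1)
    cells = [residue] * n_cons
    for i in range(n - n_cons):
        cells.append(filler[i % len(filler)])
    rng.shuffle(cells)
    return cells


def _mixed_column(rng: np.random.Generator, n: int, pool: list[str]) -> list[str]:
    """Balanced mixture of mutually incompatible residues: max residue share
    <= ceil(n/len(pool))/n and no conserved strong/weak group."""
    cells = [pool[i % len(pool)] for i in range(n)]
    rng.shuffle(cells)
    return cells


@dataclass
class AlignmentPair:
    sa_a: list[tuple[str, str]]        # (seq_id, aligned string)
    sa_b: list[tuple[str, str]]
    csa: list[tuple[str, str]]         # stacked: A rows then B rows
    truth: list[str]                   # planted class per column (1-based idx+1)

    def fasta(self, which: str) -> str:
        rows = {"A": self.sa_a, "B": self.sa_b, "CSA": self.csa}[which]
        return "".join(f">{sid}\n{s}\n" for sid, s in rows)


def gen_alignment_pair(spec: AlignmentSimSpec) -> AlignmentPair:
    """Generate SA_A, SA_B and their stacked combined alignment with truth.

    The combined alignment is the row-stack of the two subfamily alignments
    (no re-alignment), so the column correspondence is the identity — the
    shifted-column case is exercised by a dedicated fixture elsewhere.
    """
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.n_seqs_a, spec.n_seqs_b
    cols_a: list[list[str]] = []
    cols_b: list[list[str]] = []
    truth: list[str] = []

    aa = list(AMINO_ACIDS)
    for cls in spec.column_classes:
        if cls == "SHARED_CONSERVED":
            res = aa[rng.integers(len(aa))]
            filler = _incompatible_pool([res], 3)
            col_a = _conserved_column(rng, n_a, res, spec.conservation_level, filler)
            col_b = _conserved_column(rng, n_b, res, spec.conservation_level, filler)
        elif cls == "DA_SPECIFIC_A":
            res = aa[rng.integers(len(aa))]
            pool = _incompatible_pool([res], 3)
            col_a = _conserved_column(rng, n_a, res, spec.conservation_level, pool)
            col_b = _mixed_column(rng, n_b, pool)
        elif cls == "DA_SPECIFIC_B":
            res = aa[rng.integers(len(aa))]
            pool = _incompatible_pool([res], 3)
            col_a = _mixed_column(rng, n_a, pool)
            col_b = _conserved_column(rng, n_b, res, spec.conservation_level, pool)
        elif cls == "DA_SPECIFIC_BOTH":
            res_a = aa[rng.integers(len(aa))]
            res_b = _incompatible_pool([res_a], 1)[0]
            fill_a = _incompatible_pool([res_a], 2)
            fill_b = _incompatible_pool([res_b], 2)
            col_a = _conserved_column(rng, n_a, res_a, spec.conservation_level, fill_a)
            col_b = _conserved_column(rng, n_b, res_b, spec.conservation_level, fill_b)
        else:  # VARIABLE
            pool = _incompatible_pool([], 4)
            col_a = _mixed_column(rng, n_a, pool)
            col_b = _mixed_column(rng, n_b, pool)
        cols_a.append(col_a)
        cols_b.append(col_b)
        truth.append(cls)

    def apply_noise(cols: list[list[str]], n_rows: int) -> list[list[str]]:
        for col in cols:
            for i in range(n_rows):
                if spec.noise and rng.random() < spec.noise:
                    col[i] = aa[rng.integers(len(aa))]
                if spec.gap_rate and rng.random() < spec.gap_rate:
                    col[i] = "-"
        return cols

    cols_a = apply_noise(cols_a, n_a)
    cols_b = apply_noise(cols_b, n_b)

    def to_rows(cols: list[list[str]], n_rows: int, prefix: str):
        return [(f"{prefix}{i+1:03d}",
                 "".join(cols[c][i] for c in range(len(cols))))
                for i in range(n_rows)]

    sa_a = to_rows(cols_a, n_a, "A")
    sa_b = to_rows(cols_b, n_b, "B")
    return AlignmentPair(sa_a=sa_a, sa_b=sa_b, csa=sa_a + sa_b, truth=truth)


def default_column_classes(n_cols: int = 40,
                           rng: np.random.Generator | None = None) -> list[str]:
    """A balanced planted-class layout cycling through all five classes."""
    base = list(PLANT_CLASSES)
    classes = [base[i % len(base)] for i in range(n_cols)]
    if rng is not None:
        rng.shuffle(classes)
    return classes


# ---------------------------------------------------------------------------
# domain-annotation sets with planted defects
# ---------------------------------------------------------------------------

#: two-domain query emulating a Sec7-then-PH architecture; lengths bracket
#: the family's typical extent (Sec7 ~195 aa, PH ~120 aa, short linker)
DEFAULT_QUERY_PARAMS = dict(
    domain_order=["Sec7", "PH"],
    length_bounds={"Sec7": (150, 250), "PH": (100, 140)},
    linker_refs=[8],
    n_ext_ref=5,
    c_ext_ref=10,
    relaxation=20,
)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    aa = AMINO_ACIDS
    return "".join(aa[i] for i in rng.integers(len(aa), size=n))


@dataclass
class AnnotationSet:
    table_tsv: str
    fasta: str
    truth: dict[str, str | None]        # protein id -> expected reason (None = accept)
    duplicate_pairs: list[tuple[str, str]]  # (original, near-duplicate)


def gen_annotation_set(n_clean: int = 10,
                       defects: dict[str, int] | None = None,
                       n_duplicates: int = 2,
                       seed: int = 0) -> AnnotationSet:
    """A TSV + FASTA panel of clean and defective architecture entries.

    ``defects`` maps reason codes to counts; each defective entry violates
    exactly its own rule against the default Sec7/PH query. Near-duplicates
    of clean sequences (>= 95% identity, a few point substitutions) are
    appended for redundancy-clustering tests.
    """
    from .arch_select import (WRONG_ORDER, EXTRA_DOMAIN, OVERLAP,
                              PARTIAL_DOMAIN, LONG_INSERTION, LONG_EXTENSION,
                              FRAGMENT)
    if defects is None:
        defects = {code: 1 for code in (WRONG_ORDER, EXTRA_DOMAIN, OVERLAP,
                                        PARTIAL_DOMAIN, LONG_INSERTION,
                                        LONG_EXTENSION, FRAGMENT)}
    rng = np.random.default_rng(seed)
    q = DEFAULT_QUERY_PARAMS
    rows: list[str] = []
    seqs: dict[str, str] = {}
    truth: dict[str, str | None] = {}
    dup_pairs: list[tuple[str, str]] = []

    def clean_layout():
        len1 = int(rng.integers(*q["length_bounds"]["Sec7"]))
        len2 = int(rng.integers(*q["length_bounds"]["PH"]))
        linker = q["linker_refs"][0] + int(rng.integers(-5, 6))
        n_ext = q["n_ext_ref"] + int(rng.integers(0, 6))
        c_ext = q["c_ext_ref"] + int(rng.integers(0, 6))
        s1, e1 = n_ext + 1, n_ext + len1
        s2, e2 = e1 + linker + 1, e1 + linker + len2
        total = e2 + c_ext
        return (s1, e1), (s2, e2), total

    def emit(pid, hits, total, reason, fragment=False):
        for dom, s, e in hits:
            frag = "\t1" if fragment else "\t0"
            rows.append(f"{pid}\t{dom}\t{s}\t{e}{frag}")
        seqs[pid] = _random_seq(rng, total)
        truth[pid] = reason

    for i in range(n_clean):
        (s1, e1), (s2, e2), total = clean_layout()
        emit(f"CLEAN{i+1:02d}", [("Sec7", s1, e1), ("PH", s2, e2)], total, None)

    counter = 0
    for code, count in defects.items():
        for _ in range(count):
            counter += 1
            pid = f"DEF{counter:02d}_{code}"
            (s1, e1), (s2, e2), total = clean_layout()
            if code == WRONG_ORDER:
                # PH first, Sec7 second
                hits = [("PH", s1, s1 + 119), ("Sec7", s1 + 130, s1 + 130 + 194)]
                emit(pid, hits, s1 + 130 + 194 + 10, code)
            elif code == EXTRA_DOMAIN:
                mid_s = e1 + 3
                mid_e = mid_s + 40
                s2b = mid_e + 5
                e2b = s2b + 119
                emit(pid, [("Sec7", s1, e1), ("X", mid_s, mid_e),
                           ("PH", s2b, e2b)], e2b + 10, code)
            elif code == OVERLAP:
                emit(pid, [("Sec7", s1, e1), ("PH", e1 - 5, e1 - 5 + 119)],
                     e1 + 130, code)
            elif code == PARTIAL_DOMAIN:
                emit(pid, [("Sec7", s1, e1), ("PH", s2, s2 + 49)],
                     s2 + 60, code)
            elif code == LONG_INSERTION:
                gap = q["linker_refs"][0] + q["relaxation"] + 30
                s2b = e1 + gap + 1
                emit(pid, [("Sec7", s1, e1), ("PH", s2b, s2b + 119)],
                     s2b + 130, code)
            elif code == LONG_EXTENSION:
                emit(pid, [("Sec7", s1, e1), ("PH", s2, e2)],
                     e2 + q["c_ext_ref"] + q["relaxation"] + 40, code)
            elif code == FRAGMENT:
                emit(pid, [("Sec7", s1, e1), ("PH", s2, e2)], total, code,
                     fragment=True)
            else:
                raise ValueError(f"unknown defect code {code!r}")

    clean_ids = [pid for pid in truth if truth[pid] is None]
    for i in range(min(n_duplicates, len(clean_ids))):
        src = clean_ids[i]
        seq = list(seqs[src])
        n_mut = max(1, int(0.02 * len(seq)))   # >= 98% identity
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        for p in pos:
            current = seq[p]
            choices = [a for a in AMINO_ACIDS if a != current]
            seq[p] = choices[int(rng.integers(len(choices)))]
        dup_id = f"{src}_DUP"
        seqs[dup_id] = "".join(seq)
        dup_pairs.append((src, dup_id))

    table = "protein_id\tdomain\tstart\tend\tfragment\n" + "\n".join(rows) + "\n"
    fasta = "".join(f">{pid}\n{s}\n" for pid, s in seqs.items())
    return AnnotationSet(table_tsv=table, fasta=fasta, truth=truth,
                         duplicate_pairs=dup_pairs)


# ---------------------------------------------------------------------------
# toy structures with planted geometry
# ---------------------------------------------------------------------------

def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, xyz, occupancy: float = 1.0,
              element: str | None = None) -> str:
    el = element or name.strip()[0]
    nm = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record:<6s}{serial:>5d} {nm} {resname:>3s} {chain}{resseq:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{0.0:6.2f}"
            f"          {el:>2s}\n")


class PdbBuilder:
    def __init__(self):
        self.lines: list[str] = []
        self.serial = 0

    def atom(self, name, resname, chain, resseq, xyz, het=False,
             occupancy=1.0, element=None):
        self.serial += 1
        rec = "HETATM" if het else "ATOM"
        self.lines.append(_pdb_line(rec, self.serial, name, resname, chain,
                                    resseq, xyz, occupancy, element))

    def text(self) -> str:
        return "".join(self.lines) + "END\n"


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension reference frame: position atom d from internal
    coordinates (bond c-d, angle b-c-d, torsion a-b-c-d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# backbone internal coordinates (angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _backbone_chain(n_res: int, phi: float, psi: float,
                    omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Poly-backbone (N, CA, C, O per residue) at fixed dihedrals."""
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = place_atom(np.array([-1.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, 0.0)
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = residues[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, omega)
        c = place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: torsion N-CA-C-O = psi + 180
    for res in residues:
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              _B_C_O, _A_CA_C_O, psi + 180.0)
    return residues


@dataclass
class StructureSimSpec:
    recipe: str                      # ideal_helix | strand_pair | ion_pair |
                                     # enclosed_atom | pocket_with_ligand_and_waters
    n_res: int = 12                  # ideal_helix / strand_pair length
    distance: float = 3.2            # ion_pair charged-atom separation
    seed: int = 0


@dataclass
class ToyStructure:
    pdb_text: str
    truth: dict


def _helix(spec: StructureSimSpec) -> ToyStructure:
    # dihedrals from the alpha-helical basin, chosen so the i -> i+4
    # N..O separation (~2.8 A) is cleanly inside the 3.5 A cutoff while
    # every other offset (i+2 ~3.7, i+3 ~3.9, i+5 ~4.2 A) stays outside
    residues = _backbone_chain(spec.n_res, phi=-74.0, psi=-41.0)
    b = PdbBuilder()
    for i, res in enumerate(residues, start=1):
        for name in ("N", "CA", "C", "O"):
            b.atom(name, "GLY", "A", i, res[name])
    # planted pattern: backbone N(i+4)..O(i) pairs within 3.5 A; the
    # construction keeps N(i+3)..O(i) beyond the cutoff
    pairs = []
    for i in range(len(residues) - 4):
        d = float(np.linalg.norm(residues[i + 4]["N"] - residues[i]["O"]))
        if d <= 3.5:
            pairs.append((i + 1, i + 5, round(d, 3)))
    truth = {"recipe": "ideal_helix",
             "hbond_pairs": [[a, c] for a, c, _ in pairs],
             "distances": {f"{a}-{c}": d for a, c, d in pairs}}
    return ToyStructure(b.text(), truth)


def _strand_pair(spec: StructureSimSpec) -> ToyStructure:
    n = max(spec.n_res, 4)
    strand_a = _backbone_chain(n, phi=-120.0, psi=120.0)
    strand_b = _backbone_chain(n, phi=-120.0, psi=120.0)
    offset = np.array([0.0, 4.8, 0.0])
    b = PdbBuilder()
    for i, res in enumerate(strand_a, start=1):
        for name in ("N", "CA", "C", "O"):
            b.atom(name, "GLY", "A", i, res[name])
    for i, res in enumerate(strand_b, start=1):
        for name in ("N", "CA", "C", "O"):
            b.atom(name, "GLY", "B", i, res[name] + offset)
    # truth: enumerate N..O cross-strand pairs by direct distance
    cross = []
    for i, ra in enumerate(strand_a, start=1):
        for j, rb in enumerate(strand_b, start=1):
            d1 = float(np.linalg.norm(ra["N"] - (rb["O"] + offset)))
            d2 = float(np.linalg.norm((rb["N"] + offset) - ra["O"]))
            if d1 <= 3.5:
                cross.append((("A", i, "N"), ("B", j, "O"), round(d1, 3)))
            if d2 <= 3.5:
                cross.append((("B", j, "N"), ("A", i, "O"), round(d2, 3)))
    truth = {"recipe": "strand_pair",
             "hbonds": [[list(a), list(c), d] for a, c, d in cross]}
    return ToyStructure(b.text(), truth)


def _ion_pair(spec: StructureSimSpec) -> ToyStructure:
    d = spec.distance
    b = PdbBuilder()
    # ASP A1: backbone stub pointing -x, carboxylate at origin
    asp = {
        "N": (-4.5, 1.2, 0.0), "CA": (-3.8, 0.0, 0.0), "C": (-4.5, -1.2, 0.0),
        "O": (-5.7, -1.2, 0.0), "CB": (-2.3, 0.0, 0.0), "CG": (-1.2, 0.6, 0.0),
        "OD1": (0.0, 0.0, 0.0), "OD2": (-1.2, 1.85, 0.0),
    }
    for name, xyz in asp.items():
        b.atom(name, "ASP", "A", 1, np.array(xyz))
    # ARG A2: guanidinium with NH1 at (d, 0, 0), backbone stub beyond
    arg = {
        "NH1": (d, 0.0, 0.0), "CZ": (d + 1.33, 0.0, 0.0),
        "NH2": (d + 2.0, 1.1, 0.0), "NE": (d + 2.0, -1.1, 0.0),
        "CD": (d + 3.4, -1.3, 0.0), "CG": (d + 4.2, 0.0, 0.0),
        "CB": (d + 5.6, 0.0, 0.0), "CA": (d + 6.4, 1.3, 0.0),
        "N": (d + 7.8, 1.3, 0.0), "C": (d + 6.0, 2.7, 0.0),
        "O": (d + 6.8, 3.7, 0.0),
    }
    for name, xyz in arg.items():
        b.atom(name, "ARG", "A", 2, np.array(xyz))
    truth = {"recipe": "ion_pair", "distance": d,
             "salt_bridge": d <= 6.0, "strong": d <= 4.0}
    return ToyStructure(b.text(), truth)


# 14 shell directions: octahedron faces + cube corners
_SHELL_DIRS = [np.array(v, dtype=float) for v in [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1)]]


def _enclosed_atom(spec: StructureSimSpec) -> ToyStructure:
    b = PdbBuilder()
    b.atom("C", "ALA", "A", 1, np.zeros(3))
    for i, v in enumerate(_SHELL_DIRS, start=1):
        xyz = 2.0 * v / np.linalg.norm(v)
        b.atom(f"C{i}", "SHL", "B", i, xyz, element="C")
    truth = {"recipe": "enclosed_atom", "central": ["A", 1],
             "central_sasa": 0.0}
    return ToyStructure(b.text(), truth)


def _pocket(spec: StructureSimSpec) -> ToyStructure:
    b = PdbBuilder()
    # ligand: phosphate-like core with five oxygens on axes
    lig = {"P1": (0, 0, 0), "O1": (2, 0, 0), "O2": (-2, 0, 0),
           "O3": (0, 2, 0), "O4": (0, -2, 0), "O5": (0, 0, -2)}
    for name, xyz in lig.items():
        b.atom(name, "4IP", "L", 1, np.array(xyz, dtype=float),
               het=True, element=name[0])

    def residue(resname, resseq, side_atoms, direction):
        """Side-chain atoms as given; minimal backbone further out along
        ``direction`` so it stays outside every cutoff."""
        u = np.array(direction, dtype=float)
        u /= np.linalg.norm(u)
        anchor = max(np.dot(np.array(x), u) for _, x in side_atoms)
        base = (anchor + 4.0) * u
        for name, xyz in side_atoms:
            b.atom(name, resname, "A", resseq, np.array(xyz, dtype=float))
        for name, shift in (("CA", 0.0), ("N", 1.2), ("C", -1.2), ("O", -2.4)):
            perp = np.array([u[1], -u[0], 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.array([1.0, 0.0, 0.0])
            b.atom(name, resname, "A", resseq, base + shift * perp)

    # direct polar contacts to the ligand (planted distances)
    residue("LYS", 1, [("NZ", (4.7, 0, 0))], (1, 0, 0))          # 2.7 to O1
    residue("ARG", 2, [("NH1", (-5.0, 0, 0))], (-1, 0, 0))       # 3.0 to O2
    residue("THR", 3, [("OG1", (0, 5.2, 0))], (0, 1, 0))         # 3.2 to O3
    residue("GLN", 4, [("NE2", (0, -4.8, 0))], (0, -1, 0))       # 2.8 to O4
    # water-bridged residues (no direct ligand contact)
    residue("SER", 5, [("OG", (0, 3.0, -6.0))], (0, 0.5, -1))
    residue("TYR", 6, [("OH", (-1.5, 0, 6.0))], (-0.25, 0, 1))
    waters = {
        1: (0.0, 1.5, -4.5),    # bridges SER5 OG (2.12 A) and ligand O5 (2.92 A)
        2: (0.0, -7.5, 0.0),    # near GLN4 only — no bridge
        3: (-0.5, 0.0, 3.3),    # bridges TYR6 OH (2.88 A) and ligand P1 (3.34 A)
    }
    for i, xyz in waters.items():
        b.atom("O", "HOH", "W", i, np.array(xyz), het=True, element="O")

    truth = {
        "recipe": "pocket_with_ligand_and_waters",
        "ligand_code": "4IP",
        "polar_contact_residues": [["A", 1], ["A", 2], ["A", 3], ["A", 4]],
        "water_bridges": [
            {"residue": ["A", 5], "water": ["W", 1], "ligand_atom": "O5"},
            {"residue": ["A", 6], "water": ["W", 3], "ligand_atom": "P1"},
        ],
        "n_waters": 3,
        "n_bridging_waters": 2,
    }
    return ToyStructure(b.text(), truth)


_RECIPES = {
    "ideal_helix": _helix,
    "strand_pair": _strand_pair,
    "ion_pair": _ion_pair,
    "enclosed_atom": _enclosed_atom,
    "pocket_with_ligand_and_waters": _pocket,
}


def gen_toy_structure(spec: StructureSimSpec) -> ToyStructure:
    """PDB text plus planted-interaction truth for one recipe."""
    try:
        recipe = _RECIPES[spec.recipe]
    except KeyError:
        raise ValueError(
            f"unknown recipe {spec.recipe!r}; choose from {sorted(_RECIPES)}"
        ) from None
    return recipe(spec)
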