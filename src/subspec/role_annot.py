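"""Per-residue structural/functional role assembly.

For each subfamily-specific residue the pipeline answers: does it touch a
neighbouring domain, a linker, a partner protein, or a bound ligand
("interacts", a direct role)? Or does it hold in place, through intraprotein
contacts, a residue that does ("maintains", a second-shell role)? Direct
always wins: a residue in the interface is never simultaneously reported as
second shell for the same partner, and every second-shell record names the
interface residue it acts through.

When several conformers of the same protein are available the same
machinery reports, per conformer, whether a residue participates in
interdomain/interchain contacts, and ``conformer_diff`` lists the unique
residue pairs (interaction type ignored) lost or gained between two
conformers within a region of interest — the contact rearrangements that
accompany, e.g., re-orientation of a C-terminal helix between functional
forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from .contacts import (
    Interaction, SegmentMap,
    INTER_SEGMENT, INTER_CHAIN, INTRA_SEGMENT, UNASSIGNED,
    WATER_BRIDGE, LIGAND_POLAR,
)


@dataclass
class RoleRecord:
    """Roles of one residue: direct partners, second-shell partners (with the
    interface residue mediating each), and per-conformer participation."""

    residue: tuple            # residue key (chain, number, icode)
    resname: str
    da_specific: bool = True
    direct: dict[str, set[str]] = field(default_factory=dict)       # partner -> types
    second_shell: dict[str, set[tuple]] = field(default_factory=dict)  # partner -> via keys
    conformers: dict[str, bool] = field(default_factory=dict)

    def has_role(self) -> bool:
        return bool(self.direct or self.second_shell)


def _partner_of(ia: Interaction, residue: tuple, focal_segment: str) -> str | None:
    """Name the partner a contact connects ``residue`` to, or None for a
    contact that stays inside the focal segment / is unassigned."""
    if ia.type in (LIGAND_POLAR, WATER_BRIDGE):
        # ligand partner named by the HET code of the ligand side
        return ia.resname_b if ia.res_b != residue else ia.resname_a
    if ia.context == INTER_CHAIN and ia.context_pair:
        a_side = ia.res_a == residue
        return ia.context_pair[1] if a_side else ia.context_pair[0]
    if ia.context == INTER_SEGMENT and ia.context_pair:
        a_side = ia.res_a == residue
        other = ia.context_pair[1] if a_side else ia.context_pair[0]
        mine = ia.context_pair[0] if a_side else ia.context_pair[1]
        if mine == focal_segment:
            return other
    return None


def assign_direct_roles(
    da_residues: Mapping[tuple, str],
    interactions: Sequence[Interaction],
    focal_segment: str = "PH",
) -> dict[tuple, RoleRecord]:
    """Direct roles: the residue itself appears in a contact that leaves the
    focal segment (inter-segment, inter-chain, or to a ligand/water bridge).

    ``da_residues`` maps residue keys to residue names; interactions must be
    context-labeled. Returns one RoleRecord per input residue (possibly
    roleless).
    """
    records = {key: RoleRecord(residue=key, resname=name)
               for key, name in da_residues.items()}
    for ia in interactions:
        for residue in (ia.res_a, ia.res_b):
            if residue not in records:
                continue
            partner = _partner_of(ia, residue, focal_segment)
            if partner is None:
                continue
            records[residue].direct.setdefault(partner, set()).add(ia.type)
    return records


def direct_contactors(
    interactions: Sequence[Interaction], focal_segment: str = "PH"
) -> dict[str, set[tuple]]:
    """All residues (not just subfamily-specific ones) with a direct contact
    to each partner; the pool second-shell roles are traced through."""
    out: dict[str, set[tuple]] = {}
    for ia in interactions:
        for residue in (ia.res_a, ia.res_b):
            partner = _partner_of(ia, residue, focal_segment)
            if partner is not None:
                out.setdefault(partner, set()).add(residue)
    return out


def second_shell_roles(
    records: dict[tuple, RoleRecord],
    interactions: Sequence[Interaction],
    contactors: Mapping[str, set[tuple]],
) -> dict[tuple, RoleRecord]:
    """Second-shell ("maintains") roles.

    A residue gains a second-shell role for partner P via residue v when it
    is not itself a direct contactor of P but shares any intraprotein
    interaction (intra- or inter-segment within the chain) with v, a direct
    contactor of P. One hop only; direct wins.
    """
    intra = [ia for ia in interactions
             if ia.context in (INTRA_SEGMENT, INTER_SEGMENT, UNASSIGNED)]
    neighbours: dict[tuple, set[tuple]] = {}
    for ia in intra:
        neighbours.setdefault(ia.res_a, set()).add(ia.res_b)
        neighbours.setdefault(ia.res_b, set()).add(ia.res_a)

    for key, rec in records.items():
        for partner, members in contactors.items():
            if key in members or partner in rec.direct:
                continue
            vias = neighbours.get(key, set()) & members
            if vias:
                rec.second_shell.setdefault(partner, set()).update(vias)
    return records


def conformer_membership(
    da_residues: Mapping[tuple, str],
    per_conformer: Mapping[str, Sequence[Interaction]],
    focal_segment: str = "PH",
) -> dict[tuple, RoleRecord]:
    """Flag, per conformer, whether each residue holds a direct
    interdomain/interchain role there.

    All conformers must address residues with the same numbering; residues
    named in ``da_residues`` need not appear in every conformer (a missing
    residue simply never gains the flag).
    """
    records = {key: RoleRecord(residue=key, resname=name)
               for key, name in da_residues.items()}
    for conformer, interactions in per_conformer.items():
        direct = assign_direct_roles(da_residues, interactions, focal_segment)
        for key, rec in records.items():
            participates = bool(direct[key].direct)
            rec.conformers[conformer] = participates
            for partner, types in direct[key].direct.items():
                rec.direct.setdefault(f"{conformer}:{partner}", set()).update(types)
    return records


@dataclass
class ConformerDiff:
    """Unique residue pairs present in the first conformer's contact set but
    not the second (lost) and vice versa (gained), within a region."""

    name_1: str
    name_2: str
    lost: set[frozenset]
    gained: set[frozenset]
    region: tuple[str, ...]


def _region_pairs(interactions: Sequence[Interaction],
                  segment_map: SegmentMap,
                  region: Sequence[str]) -> set[frozenset]:
    region_set = set(region)
    pairs = set()
    for ia in interactions:
        seg_a = segment_map.segment_of(ia.res_a)
        seg_b = segment_map.segment_of(ia.res_b)
        if seg_a in region_set or seg_b in region_set:
            pairs.add(ia.residue_pair)
    return pairs


def conformer_diff(
    interactions_1: Sequence[Interaction],
    interactions_2: Sequence[Interaction],
    segment_map: SegmentMap,
    region: Sequence[str],
    name_1: str = "conformer_1",
    name_2: str = "conformer_2",
) -> ConformerDiff:
    """Residue-pair-level contact differences between two conformers.

    Interactions collapse to unordered residue pairs regardless of type (a
    pair trading an H-bond for a hydrophobic contact is neither lost nor
    gained); only pairs with at least one member inside the named region
    segments count. Both structures must share residue numbering.
    """
    if not region:
        raise ValueError("region selection must name at least one segment")
    pairs_1 = _region_pairs(interactions_1, segment_map, region)
    pairs_2 = _region_pairs(interactions_2, segment_map, region)
    return ConformerDiff(
        name_1=name_1, name_2=name_2,
        lost=pairs_1 - pairs_2, gained=pairs_2 - pairs_1,
        region=tuple(region),
    )


def render_role_table(
    records: Iterable[RoleRecord],
    partner_categories: Mapping[str, Sequence[str]],
) -> list[dict[str, str]]:
    """One row per residue; columns group partners into named categories
    (e.g. interdomain / partner protein / phosphoinositide).

    Cell text reads "Interacts with X" for direct roles and "Maintains
    interaction with X (via Y)" for second-shell ones; residues without any
    role read "Role unknown" in a dedicated column.
    """
    rows = []
    for rec in sorted(records, key=lambda r: (r.residue[0], r.residue[1])):
        row: dict[str, str] = {
            "residue": f"{rec.resname}-{rec.residue[1]}",
        }
        for category, partners in partner_categories.items():
            phrases = []
            for p in partners:
                if p in rec.direct:
                    phrases.append(f"Interacts with {p}")
                elif p in rec.second_shell:
                    vias = ", ".join(
                        f"{v[0]}:{v[1]}" for v in sorted(rec.second_shell[p]))
                    phrases.append(f"Maintains interaction with {p} (via {vias})")
            row[category] = "; ".join(phrases)
        row["note"] = "" if rec.has_role() else "Role unknown"
        rows.append(row)
    return rows


def write_role_table(rows: list[dict[str, str]], stream: TextIO) -> None:
    if not rows:
        stream.write("residue\tnote\n")
        return
    cols = list(rows[0])
    stream.write("\t".join(cols) + "\n")
    for row in rows:
        stream.write("\t".join(row.get(c, "") for c in cols) + "\n")
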