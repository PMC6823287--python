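"""Classification of alignment columns by subfamily-specific conservation.

Given the column profiles of two subfamily alignments (related through a
column map to a combined alignment), each position is assigned one class:

* ``SHARED_CONSERVED`` — conserved in both subfamilies with the same residue
  or conservatively substituted within overlapping strong groups; these
  positions characterize the whole domain family, not a subfamily.
* ``DA_SPECIFIC_A`` / ``DA_SPECIFIC_B`` — conserved (>= 85% by default, as a
  single residue or a strong group) in one subfamily while the other
  subfamily neither conserves the same residue/type above 50% nor is
  semi-conservatively substituted toward it.
* ``DA_SPECIFIC_BOTH`` — each subfamily conserves its own, different,
  residue/type (e.g. Ser in one, Val in the other).
* ``NONSPECIFIC`` — everything else.

Conservative substitution follows the Clustal-X convention: "strong" groups
(score > 0.5 in the Gonnet series) and "weak" groups (score <= 0.5). Gaps
count in every denominator — a gap is evidence of non-conservation — so
columns with more than ~15% gaps can never reach the 85% threshold.

Positions whose reference-structure residue is buried (relative solvent
accessibility <= 7% by default) are excluded from the reported set: buried
residues conserve for fold integrity, not subfamily-specific function.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .config import Thresholds, DEFAULT_THRESHOLDS
from .msa_io import Alignment, ResidueRef

# Clustal-X conservative-substitution groups
STRONG_GROUPS = [frozenset(g) for g in
                 ["STA", "NEQK", "NHQK", "NDEQ", "QHRK",
                  "MILV", "MILF", "HY", "FYW"]]
WEAK_GROUPS = [frozenset(g) for g in
               ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
                "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY"]]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConservedStatus(str, Enum):
    CONSERVED_RESIDUE = "CONSERVED_RESIDUE"
    CONSERVED_GROUP = "CONSERVED_GROUP"
    SEMI_CONSERVED = "SEMI_CONSERVED"
    NOT_CONSERVED = "NOT_CONSERVED"


class ColumnClass(str, Enum):
    SHARED_CONSERVED = "SHARED_CONSERVED"
    DA_SPECIFIC_A = "DA_SPECIFIC_A"
    DA_SPECIFIC_B = "DA_SPECIFIC_B"
    DA_SPECIFIC_BOTH = "DA_SPECIFIC_BOTH"
    NONSPECIFIC = "NONSPECIFIC"


@dataclass
class ColumnProfile:
    """Conservation summary of one alignment column.

    Fractions use the total row count as denominator (gaps included), so
    ``f_res + gap_fraction <= 1``. Ties on the majority residue break
    alphabetically for determinism.
    """

    counts: Counter
    n_rows: int
    majority: str | None
    f_res: float
    best_strong: frozenset | None
    f_grp: float
    best_weak: frozenset | None
    f_weak: float
    gap_fraction: float

    def fraction_of(self, residue: str) -> float:
        return self.counts.get(residue, 0) / self.n_rows

    def group_fraction(self, group: frozenset) -> float:
        return sum(n for r, n in self.counts.items() if r in group) / self.n_rows


def profile_column(column: str) -> ColumnProfile:
    """Profile one column string (one char per row; '-' is a gap)."""
    n = len(column)
    counts = Counter(ch for ch in column if ch != "-")
    gaps = n - sum(counts.values())
    if counts:
        best_n = max(counts.values())
        majority = min(r for r, c in counts.items() if c == best_n)
        f_res = best_n / n
    else:
        majority, f_res = None, 0.0

    def best_group(groups):
        best, best_f = None, 0.0
        for g in groups:
            f = sum(c for r, c in counts.items() if r in g) / n
            if f > best_f:
                best, best_f = g, f
        return best, best_f

    best_strong, f_grp = best_group(STRONG_GROUPS)
    best_weak, f_weak = best_group(WEAK_GROUPS)
    return ColumnProfile(
        counts=counts, n_rows=n, majority=majority, f_res=f_res,
        best_strong=best_strong, f_grp=f_grp,
        best_weak=best_weak, f_weak=f_weak,
        gap_fraction=gaps / n,
    )


def profile_columns(alignment: Alignment) -> list[ColumnProfile]:
    """Profiles for every column, 1-based column c at index c-1."""
    return [profile_column(alignment.column(c)) for c in range(1, alignment.n_cols + 1)]


def conserved_status(
    profile: ColumnProfile, threshold: float = 0.85
) -> ConservedStatus:
    """Rank a column's conservation: residue, strong group, weak group, none.

    The threshold is inclusive (>=), matching the "more than or equal to 85%"
    criterion; the three levels are checked in order of strength.
    """
    if profile.f_res >= threshold:
        return ConservedStatus.CONSERVED_RESIDUE
    if profile.f_grp >= threshold:
        return ConservedStatus.CONSERVED_GROUP
    if profile.f_weak >= threshold:
        return ConservedStatus.SEMI_CONSERVED
    return ConservedStatus.NOT_CONSERVED


def _strong_groups_of(residue: str) -> list[frozenset]:
    return [g for g in STRONG_GROUPS if residue in g]


def _same_type(res_a: str, res_b: str) -> bool:
    """Same residue, or members of a common strong group."""
    if res_a == res_b:
        return True
    return any(res_b in g for g in _strong_groups_of(res_a))


@dataclass
class Classification:
    column_class: ColumnClass
    rationale: str


def _excluded_by_other(
    maj: str, other: ColumnProfile, other_status: ConservedStatus,
    cross_max: float,
) -> str | None:
    """Cross-subfamily veto for a candidate subfamily-specific column.

    The candidate's conserved residue is disqualified when the other
    subfamily (a) conserves the same residue above ``cross_max``, (b)
    conserves, above ``cross_max``, a single residue of the same type
    (sharing a strong group), or (c) is semi-conservatively substituted
    within a weak group containing the candidate residue. Returns the fired
    clause's description or None.
    """
    if other.fraction_of(maj) > cross_max:
        return f"other side holds {maj} at {other.fraction_of(maj):.2f} > {cross_max}"
    if other.majority is not None and other.majority != maj:
        f_other = other.fraction_of(other.majority)
        if f_other > cross_max and _same_type(maj, other.majority):
            return (f"other side holds same-type {other.majority} at "
                    f"{f_other:.2f} > {cross_max}")
    if other_status is ConservedStatus.SEMI_CONSERVED:
        for g in WEAK_GROUPS:
            if maj in g and other.group_fraction(g) >= 0.85:
                return f"other side semi-conserved in weak group {''.join(sorted(g))}"
    return None


def classify_position(
    profile_a: ColumnProfile,
    profile_b: ColumnProfile,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Classification:
    """Classify one mapped column pair. Symmetric under (A, B) exchange up to
    the A/B label swap."""
    t = thresholds.conservation
    cross = thresholds.cross_family_max
    status_a = conserved_status(profile_a, t)
    status_b = conserved_status(profile_b, t)
    cons_a = status_a in (ConservedStatus.CONSERVED_RESIDUE, ConservedStatus.CONSERVED_GROUP)
    cons_b = status_b in (ConservedStatus.CONSERVED_RESIDUE, ConservedStatus.CONSERVED_GROUP)

    if cons_a and cons_b:
        if profile_a.majority == profile_b.majority:
            return Classification(
                ColumnClass.SHARED_CONSERVED,
                f"both conserve {profile_a.majority}",
            )
        if (status_a is ConservedStatus.CONSERVED_GROUP
                and status_b is ConservedStatus.CONSERVED_GROUP
                and profile_a.best_strong and profile_b.best_strong
                and profile_a.best_strong & profile_b.best_strong):
            g = "".join(sorted(profile_a.best_strong & profile_b.best_strong))
            return Classification(
                ColumnClass.SHARED_CONSERVED,
                f"both group-conserved with overlap {g}",
            )

    cand_a = cand_b = False
    veto_a = veto_b = None
    if cons_a and profile_a.majority is not None:
        veto_a = _excluded_by_other(profile_a.majority, profile_b, status_b, cross)
        cand_a = veto_a is None
    if cons_b and profile_b.majority is not None:
        veto_b = _excluded_by_other(profile_b.majority, profile_a, status_a, cross)
        cand_b = veto_b is None

    if cand_a and cand_b:
        return Classification(
            ColumnClass.DA_SPECIFIC_BOTH,
            f"A conserves {profile_a.majority}, B conserves {profile_b.majority}",
        )
    if cand_a:
        return Classification(
            ColumnClass.DA_SPECIFIC_A, f"A conserves {profile_a.majority}; no veto"
        )
    if cand_b:
        return Classification(
            ColumnClass.DA_SPECIFIC_B, f"B conserves {profile_b.majority}; no veto"
        )
    reasons = []
    if veto_a:
        reasons.append(f"A vetoed: {veto_a}")
    if veto_b:
        reasons.append(f"B vetoed: {veto_b}")
    if not reasons:
        reasons.append("neither side conserved")
    return Classification(ColumnClass.NONSPECIFIC, "; ".join(reasons))


@dataclass
class PositionRecord:
    """One classified combined-alignment column with provenance."""

    combined_col: int
    col_a: int
    col_b: int
    classification: Classification
    reference: ResidueRef | None = None
    rsa: float | None = None
    excluded_buried: bool = False
    unmapped_to_structure: bool = False


def classify_alignment_pair(
    profiles_a: list[ColumnProfile],
    profiles_b: list[ColumnProfile],
    map_a: Mapping[int, int | None],
    map_b: Mapping[int, int | None],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[PositionRecord]:
    """Classify every combined column mapped into both subfamily alignments.

    ``map_a``/``map_b`` take a combined column to its subfamily column (or
    None); unmapped columns are skipped — classification requires both
    profiles.
    """
    records = []
    for c in sorted(map_a):
        ca, cb = map_a.get(c), map_b.get(c)
        if ca is None or cb is None:
            continue
        cls = classify_position(profiles_a[ca - 1], profiles_b[cb - 1], thresholds)
        records.append(PositionRecord(combined_col=c, col_a=ca, col_b=cb,
                                      classification=cls))
    return records


def apply_burial_filter(
    records: Iterable[PositionRecord],
    rsa_by_residue: Mapping[int, float],
    column_to_residue: Mapping[int, ResidueRef | None],
    cutoff: float = 7.0,
) -> tuple[list[PositionRecord], list[PositionRecord]]:
    """Split classified columns into retained and buried-excluded.

    ``rsa_by_residue`` maps reference residue numbers to relative solvent
    accessibility (percent); ``column_to_residue`` maps combined columns onto
    the reference structure. Buried means RSA <= cutoff (inclusive). Columns
    with no structure residue pass through flagged ``unmapped_to_structure``.
    The excluded list keeps each column's class for reporting.
    """
    retained, excluded = [], []
    for rec in records:
        ref = column_to_residue.get(rec.combined_col)
        rec.reference = ref
        if ref is None or ref.number not in rsa_by_residue:
            rec.unmapped_to_structure = True
            retained.append(rec)
            continue
        rec.rsa = rsa_by_residue[ref.number]
        if rec.rsa <= cutoff:
            rec.excluded_buried = True
            excluded.append(rec)
        else:
            retained.append(rec)
    return retained, excluded


def write_position_table(records: Iterable[PositionRecord], stream) -> None:
    stream.write("combined_col\tsubA_col\tsubB_col\tclass\trationale\t"
                 "ref_residue\tRSA\texcluded\n")
    for r in records:
        ref = f"{r.reference.amino_acid}-{r.reference.number}" if r.reference else ""
        rsa = f"{r.rsa:.1f}" if r.rsa is not None else ""
        stream.write(
            f"{r.combined_col}\t{r.col_a}\t{r.col_b}\t"
            f"{r.classification.column_class.value}\t{r.classification.rationale}\t"
            f"{ref}\t{rsa}\t{int(r.excluded_buried)}\n"
        )
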