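"""Selection of homologues sharing a query domain architecture.

A multidomain protein's domain architecture (DA) is the ordered list of
domain families along its sequence. Given per-protein domain annotations
(e.g. mapped from Pfam hits) this module keeps only proteins whose DA matches
a query architecture exactly — same domains, same order, no overlaps, domain
lengths within the extremes seen in the family seed alignment, and linkers /
terminal extensions within a fixed relaxation (20 residues by default) of the
query's reference values — and then collapses redundancy with a greedy
90%-identity clustering, so that near-identical database entries (often the
same protein with a few extra terminal residues) contribute once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import yaml
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

# rejection reason codes
WRONG_ORDER = "WRONG_ORDER"
EXTRA_DOMAIN = "EXTRA_DOMAIN"
OVERLAP = "OVERLAP"
PARTIAL_DOMAIN = "PARTIAL_DOMAIN"
LONG_INSERTION = "LONG_INSERTION"
LONG_EXTENSION = "LONG_EXTENSION"
FRAGMENT = "FRAGMENT"

REASON_CODES = (
    WRONG_ORDER,
    EXTRA_DOMAIN,
    OVERLAP,
    PARTIAL_DOMAIN,
    LONG_INSERTION,
    LONG_EXTENSION,
    FRAGMENT,
)


@dataclass(frozen=True)
class DomainHit:
    """One domain annotated on a sequence, 1-based inclusive coordinates."""

    domain_name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinAnnotation:
    """A protein sequence plus its ordered domain hits."""

    protein_id: str
    sequence: str
    hits: list[DomainHit] = field(default_factory=list)
    fragment: bool = False

    def __post_init__(self):
        self.hits = sorted(self.hits, key=lambda h: h.start)
        for h in self.hits:
            if self.sequence and h.end > len(self.sequence):
                raise ValueError(
                    f"{self.protein_id}: hit {h.domain_name} ends at {h.end} "
                    f"beyond sequence length {len(self.sequence)}"
                )


@dataclass
class ArchitectureQuery:
    """The architecture to match.

    domain_order       ordered domain names, e.g. ["Sec7", "PH"]
    length_bounds      per domain: (min_len, max_len) from the seed-alignment
                       shortest/longest members
    linker_refs        reference inter-domain linker lengths (len = n_domains-1)
    n_ext_ref, c_ext_ref  reference unannotated N-/C-terminal extension lengths
    relaxation         residues of slack on linkers and extensions
    """

    domain_order: list[str]
    length_bounds: Mapping[str, tuple[int, int]]
    linker_refs: list[int]
    n_ext_ref: int = 0
    c_ext_ref: int = 0
    relaxation: int = 20

    def __post_init__(self):
        if not self.domain_order:
            raise ValueError("query needs at least one domain")
        if self.relaxation < 0:
            raise ValueError("relaxation must be >= 0")
        if len(self.linker_refs) != len(self.domain_order) - 1:
            raise ValueError("need one linker reference per inter-domain gap")
        for name in self.domain_order:
            lo, hi = self.length_bounds[name]
            if lo > hi:
                raise ValueError(f"{name}: min_len {lo} > max_len {hi}")

    @classmethod
    def from_yaml(cls, stream) -> "ArchitectureQuery":
        d = yaml.safe_load(stream)
        bounds = {k: tuple(v) for k, v in d["length_bounds"].items()}
        return cls(
            domain_order=list(d["domain_order"]),
            length_bounds=bounds,
            linker_refs=list(d["linker_refs"]),
            n_ext_ref=int(d.get("n_ext_ref", 0)),
            c_ext_ref=int(d.get("c_ext_ref", 0)),
            relaxation=int(d.get("relaxation", 20)),
        )


@dataclass
class SelectionReport:
    accepted: set[str] = field(default_factory=set)
    rejected: dict[str, str] = field(default_factory=dict)

    def record(self, protein_id: str, ok: bool, reason: str | None) -> None:
        if ok:
            self.accepted.add(protein_id)
        else:
            self.rejected[protein_id] = reason


class DomainTableError(ValueError):
    """Malformed domain-annotation table."""


def parse_domain_table(
    table_stream: TextIO | str,
    fasta_stream: TextIO | str | None = None,
) -> tuple[list[ProteinAnnotation], list[str]]:
    """Parse a TSV of domain hits plus an optional companion FASTA.

    The table has a header line ``protein_id  domain  start  end`` with an
    optional fifth ``fragment`` column (truthy values: 1/true/yes). Returns
    the annotations (hits sorted by start) and the list of protein ids found
    in the table but missing from the FASTA.
    """
    if isinstance(table_stream, str):
        table_stream = io.StringIO(table_stream)
    sequences: dict[str, str] = {}
    if fasta_stream is not None:
        if isinstance(fasta_stream, str):
            fasta_stream = io.StringIO(fasta_stream)
        for rec in SeqIO.parse(fasta_stream, "fasta"):
            sequences[rec.id] = str(rec.seq).upper()

    lines = table_stream.read().splitlines()
    per_protein: dict[str, list[DomainHit]] = {}
    fragments: set[str] = set()
    order: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and fields[0] == "protein_id":
            continue
        if len(fields) < 4:
            raise DomainTableError(f"line {lineno}: expected >= 4 columns, got {len(fields)}")
        pid, dom, s_raw, e_raw = fields[:4]
        try:
            start, end = int(s_raw), int(e_raw)
        except ValueError:
            raise DomainTableError(
                f"line {lineno}: non-integer coordinates {s_raw!r}/{e_raw!r}"
            ) from None
        if end < start:
            raise DomainTableError(f"line {lineno}: end {end} < start {start}")
        if pid not in per_protein:
            per_protein[pid] = []
            order.append(pid)
        per_protein[pid].append(DomainHit(dom, start, end))
        if len(fields) >= 5 and fields[4].strip().lower() in {"1", "true", "yes"}:
            fragments.add(pid)

    missing = [pid for pid in order if fasta_stream is not None and pid not in sequences]
    annotations = [
        ProteinAnnotation(
            protein_id=pid,
            sequence=sequences.get(pid, ""),
            hits=per_protein[pid],
            fragment=pid in fragments,
        )
        for pid in order
    ]
    return annotations, missing


def _is_subsequence(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    it = iter(haystack)
    return all(x in it for x in needle)


def match_architecture(
    ann: ProteinAnnotation, query: ArchitectureQuery
) -> tuple[bool, str | None]:
    """Accept or reject one annotated protein against the query architecture.

    Returns ``(True, None)`` or ``(False, reason_code)``. Rejection is a
    result, not an error. Checks run in a fixed order: fragment flag, domain
    name sequence, overlaps, domain lengths, linker lengths, terminal
    extensions.
    """
    if ann.fragment:
        return False, FRAGMENT

    names = [h.domain_name for h in ann.hits]
    if names != query.domain_order:
        if _is_subsequence(query.domain_order, names):
            return False, EXTRA_DOMAIN
        return False, WRONG_ORDER

    for prev, nxt in zip(ann.hits, ann.hits[1:]):
        if nxt.start <= prev.end:
            return False, OVERLAP

    for hit in ann.hits:
        lo, hi = query.length_bounds[hit.domain_name]
        if not (lo <= hit.length <= hi):
            return False, PARTIAL_DOMAIN

    for i, (prev, nxt) in enumerate(zip(ann.hits, ann.hits[1:])):
        linker = nxt.start - prev.end - 1
        if abs(linker - query.linker_refs[i]) > query.relaxation:
            return False, LONG_INSERTION

    if ann.sequence:
        n_ext = ann.hits[0].start - 1
        c_ext = len(ann.sequence) - ann.hits[-1].end
        if abs(n_ext - query.n_ext_ref) > query.relaxation:
            return False, LONG_EXTENSION
        if abs(c_ext - query.c_ext_ref) > query.relaxation:
            return False, LONG_EXTENSION

    return True, None


def select_architecture(
    annotations: Iterable[ProteinAnnotation], query: ArchitectureQuery
) -> SelectionReport:
    """Run match_architecture over a set of annotations."""
    report = SelectionReport()
    for ann in annotations:
        ok, reason = match_architecture(ann, query)
        report.record(ann.protein_id, ok, reason)
    return report


_aligner: PairwiseAligner | None = None


def _get_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        _aligner = a
    return _aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity with a short-sequence denominator.

    Aligns with BLOSUM62 / affine gaps (open 10, extend 0.5) and divides the
    number of identical aligned pairs by the shorter ungapped length, so a
    sequence and the same sequence with a few extra terminal residues score
    1.0 — terminal extensions should not defeat redundancy removal. 'X'
    never counts as identical, even to itself.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _get_aligner().align(seq_a, seq_b)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        sub_a, sub_b = seq_a[a0:a1], seq_b[b0:b1]
        ident += sum(1 for x, y in zip(sub_a, sub_b) if x == y and x != "X")
    return ident / min(len(seq_a), len(seq_b))


def greedy_cluster(
    seqs: Mapping[str, str], cutoff: float = 0.90
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first clustering at an identity cutoff.

    Sequences are visited longest first (ties broken by id); each joins the
    first existing representative it exceeds ``cutoff`` identity with
    (strictly greater), otherwise it founds a new cluster. Returns the
    representative ids and a member -> representative map covering every
    input (representatives map to themselves).
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    ordered = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for sid in ordered:
        home = None
        for rep in reps:
            if pairwise_identity(seqs[sid], seqs[rep]) > cutoff:
                home = rep
                break
        if home is None:
            reps.append(sid)
            assignment[sid] = sid
        else:
            assignment[sid] = home
    return reps, assignment
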