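# Methods

This note documents the model behind each module, the default parameters and
why they were chosen, what the synthetic generators do and do not emulate,
the numerical choices, and known limitations.

## Model and assumptions

The pipeline compares two subfamilies of a domain family, where subfamily
membership is defined by domain architecture (DA): the exact ordered list of
domains along the protein. The core assumption is that residues under
subfamily-specific functional constraint appear as alignment columns that are
conserved within one DA subfamily while the other subfamily does not keep the
same residue or residue type. Structure enters twice: buried positions are
set aside (their conservation is more parsimoniously explained by folding
constraints), and the remaining candidates are annotated with roles derived
from atomic contacts — direct interaction with a partner, ligand or other
segment, or second-shell maintenance of a residue that does.

Sequences are assumed to be correctly aligned; the pipeline never realigns.
Structures are assumed to be single-model X-ray-like coordinate sets;
hydrogens are ignored throughout (heavy-atom model), so all contact
definitions are distance-only proxies without angular terms.

## Parameters (defaults in `subspec.config.Thresholds`)

| parameter | default | rationale |
|---|---|---|
| `conservation` | 0.85 | subfamily conservation threshold, inclusive; counts either a single residue or a Clustal-X strong group reaching the fraction. Gap cells count in the denominator, so heavily gapped columns cannot qualify. |
| `cross_family_max` | 0.50 | veto: a candidate is rejected when the other subfamily conserves the same residue, or a residue of the same strong-group type, in more than half of its sequences, or is itself weakly (semi-)conserved in a group containing the candidate residue. |
| `burial_rsa` | 7.0 | relative accessibility (%) at or below which a residue is buried; inclusive. |
| `hbond` | 3.5 Å | donor–acceptor N/O distance. Main-chain–main-chain pairs between sequence-adjacent residues of the same chain are excluded (those are covalent-geometry artifacts at this cutoff). |
| `salt_bridge` / `salt_bridge_strong` | 6.0 / 4.0 Å | charged-atom (Lys NZ, Arg NH*/NE, His ND1/NE2, Asp OD*, Glu OE*) distance; pairs at ≤ 4 Å are flagged strong. |
| `hydrophobic` | 5.0 Å | side-chain carbon–carbon distance between apolar residues. |
| `water_bridge` | 3.5 Å | both legs of a protein–water–ligand bridge through one ordered water oxygen. |
| `ligand_polar` | 3.5 Å | protein N/O to ligand N/O/P. |
| `generic_contact` | 4.5 Å | any heavy-atom pair, for conformer comparisons and neighbor graphs. |
| `identity_cutoff` | 0.90 | redundancy clustering: strict greater-than, longest-sequence-first greedy assignment (CD-HIT-like). Identity = identical aligned pairs / length of the shorter ungapped sequence, from a global BLOSUM62 alignment (gap open 10, extend 0.5). |
| `relaxation` | 20 | residues of slack allowed on linker lengths and terminal extensions before a protein is rejected as LONG_INSERTION / LONG_EXTENSION. |
| `sasa_probe` / `sasa_points` | 1.4 Å / 960 | water-probe radius; quadrature points per atom. |

Architecture rejection reasons are checked in a fixed order — FRAGMENT,
domain-name sequence (EXTRA_DOMAIN if the query order is a subsequence of the
hits, else WRONG_ORDER), OVERLAP, PARTIAL_DOMAIN, LONG_INSERTION,
LONG_EXTENSION — so each rejected protein carries exactly one reason code.

## Classification semantics

Per column and subfamily the profile records the majority residue fraction,
the best Clustal-X strong-group fraction and the best weak-group fraction
(gaps in the denominator of all three). Status is the strongest of
CONSERVED_RESIDUE, CONSERVED_GROUP, SEMI_CONSERVED (weak group), or
NOT_CONSERVED, all at the same inclusive threshold. A column is
SHARED_CONSERVED when both sides are conserved with the same majority residue
or with overlapping strong groups; DA_SPECIFIC to one side when that side is
conserved and the veto does not fire; DA_SPECIFIC_BOTH when both sides pass
with incompatible residues; NONSPECIFIC otherwise. Each classification
carries a human-readable rationale string.

## Solvent accessibility

Shrake–Rupley with a deterministic Fibonacci (golden-spiral) lattice of 960
points per atom, element-based van der Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80 Å) and a 1.4 Å probe. Occlusion candidates come from a
KD-tree at the maximum possible contact radius, so occlusion is exact with
respect to the point set. Each atom's lattice is oriented in a frame built
from its distance-sorted occluding neighbours; because the frame co-rotates
with the structure, computed areas are invariant under rigid motion up to
coordinate rounding (measured drift ≤ 0.1% on toy structures, versus up to
~0.8% with a fixed world-frame lattice). There is no randomness anywhere, so
results are bit-stable across runs. RSA uses theoretical Gly-X-Gly maximum
areas (Tien-style, all-atom); nonstandard residues are flagged as
unreferenced rather than scored. Waters are excluded from the SASA atom set
by default; ligands are included.

## Synthetic generators

The generators produce data where the right answer is known by construction,
which is what the test suite and the acceptance script score against.

- **Alignment pairs.** Each column is planted as one of VARIABLE,
  SHARED_CONSERVED, DA_SPECIFIC_A/B/BOTH. Specific columns draw the
  conserved residue for one side and fill the other side from a pool of
  mutually *incompatible* residues — no two sharing any strong or weak group
  — so that, at zero noise, non-conservation and the absence of a veto are
  guaranteed, and recovery must be exact. Requesting a planted conservation
  level below the 0.85 detection threshold is an error, not a silently
  unrecoverable dataset. Noise re-draws cells uniformly; gaps are inserted
  at a configurable rate.
- **Annotation panels.** A clean Sec7+PH-like architecture plus exactly one
  planted defect per rejection reason, and near-duplicate sequence pairs for
  the clustering path.
- **Toy structures.** Backbones are built by natural extension of reference
  frames (NeRF) from ideal bond geometry. The ideal-helix dihedrals
  (φ = −74°, ψ = −41°) are chosen so that only the i→i+4 N···O pair falls
  inside the 3.5 Å cutoff, with clear margins on i+2/i+3/i+5 — the planted
  hydrogen-bond list is therefore unambiguous. The pocket recipe places
  polar side-chain tips, an inositol-phosphate-like ligand and three waters
  at hand-chosen distances so the set of direct polar contacts and the two
  bridging waters are exact.

What the generators do **not** emulate: realistic substitution processes or
phylogenetic correlation between sequences (cells are i.i.d. given the
planted class), realistic side-chain packing or rotamers, crystallographic
noise, alternate conformations, or hydrogen positions. They exist to verify
the detectors, not to imitate nature.

## Numerical choices

- All identity and conservation comparisons that the thresholds define as
  inclusive use `>=`/`<=` exactly; the clustering cutoff is strictly `>`.
- Pairwise identities come from Biopython's `PairwiseAligner` (global,
  BLOSUM62, open −10, extend −0.5); the test suite checks it against an
  independently written Gotoh affine-gap dynamic program.
- SASA oracles in the tests are Monte-Carlo sphere quadratures with
  all-pairs occlusion; the per-residue comparison uses 10⁵ oracle points so
  the oracle's own noise sits well below the 2% band being asserted.
- Seeds are plain integers < 2³¹; every generator is deterministic given its
  seed (byte-identical outputs).

## Open design decisions

- The veto rule reads "conserved in the other subfamily" as *single-residue
  majority above 50%, or same strong-group type above 50%, or weak-group
  semi-conservation covering the candidate* — not as the strong-group
  fraction alone, which would make a 40/45 Lys/Glu split count as conserved
  Lys-type and erase the distinction the method is built on.
- RSA is all-atom (not side-chain-only), against theoretical maxima.
- Which structure to use for the burial filter is a per-analysis choice; the
  CLI takes it as an option rather than fixing one.

## Limitations

- Contact detection is distance-only; without hydrogens or angular criteria,
  hydrogen-bond and salt-bridge lists are permissive proxies for what a
  geometry-aware tool would report.
- The PDB reader handles single-model, fixed-width PDB text (first model,
  highest-occupancy altloc, hydrogens dropped); no mmCIF.
- Column mapping between combined and subfamily alignments is majority-vote
  per column over shared sequences; heavily gapped or ambiguous columns map
  to nothing rather than guessing.
- The 85% / 50% / 7% thresholds are conventions, not fitted quantities;
  sensitivity to them can be explored through `Thresholds`, and the test
  suite only asserts monotonicity (raising the conservation threshold can
  only shrink the specific set).
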