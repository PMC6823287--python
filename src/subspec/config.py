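"""Shared tunable thresholds.

All cutoffs the pipeline applies are collected here with their defaults so a
single object can be passed through the classification and contact stages and
round-tripped through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


@dataclass
class Thresholds:
    """Pipeline-wide cutoffs.

    conservation : fraction at or above which a column counts as conserved
        (single residue or conservative group), applied within each subfamily.
    cross_family_max : single-residue conservation in the *other* subfamily
        above which a candidate subfamily-specific column is vetoed when the
        residue is the same, or of the same type, as the candidate's.
    burial_rsa : relative solvent accessibility (percent) at or below which a
        residue is called buried and its column excluded.
    hbond, salt_bridge, salt_bridge_strong, hydrophobic, water_bridge,
    ligand_polar, generic_contact : heavy-atom distance cutoffs in angstroms
        for the contact detectors.
    identity_cutoff : pairwise identity above which two sequences are
        redundant for clustering.
    relaxation : residues of slack allowed on linker lengths and terminal
        extensions when matching a domain architecture.
    """

    conservation: float = 0.85
    cross_family_max: float = 0.50
    burial_rsa: float = 7.0
    hbond: float = 3.5
    salt_bridge: float = 6.0
    salt_bridge_strong: float = 4.0
    hydrophobic: float = 5.0
    water_bridge: float = 3.5
    ligand_polar: float = 3.5
    generic_contact: float = 4.5
    identity_cutoff: float = 0.90
    relaxation: int = 20
    sasa_probe: float = 1.4
    sasa_points: int = 960

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, stream) -> "Thresholds":
        data = yaml.safe_load(stream) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, stream) -> None:
        yaml.safe_dump(self.to_dict(), stream, sort_keys=True)


DEFAULT_THRESHOLDS = Thresholds()
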