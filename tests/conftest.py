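import numpy as np
import pytest

from subspec.synthetic_data import (
    StructureSimSpec, gen_toy_structure, gen_annotation_set,
)
from subspec.struct_geom import parse_structure


@pytest.fixture(scope="session")
def helix():
    toy = gen_toy_structure(StructureSimSpec("ideal_helix", n_res=12))
    return parse_structure(toy.pdb_text), toy.truth


@pytest.fixture(scope="session")
def pocket():
    toy = gen_toy_structure(StructureSimSpec("pocket_with_ligand_and_waters"))
    return parse_structure(toy.pdb_text), toy.truth


@pytest.fixture(scope="session")
def annotation_panel():
    return gen_annotation_set(n_clean=10, seed=11)


def brute_force_pairs(coords_a, coords_b, cutoff):
    """All index pairs within the cutoff, by the full distance matrix."""
    out = []
    for i, ca in enumerate(coords_a):
        for j, cb in enumerate(coords_b):
            if np.linalg.norm(np.asarray(ca) - np.asarray(cb)) <= cutoff:
                out.append((i, j))
    return out
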