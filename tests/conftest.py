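import numpy as np
import pytest

from inframe.geometry import GeometrySpec, build_geometry
from inframe.mechanism import annotate_structure
from inframe.structure import parse_structure


@pytest.fixture(scope="session")
def helix_pdb() -> str:
    return build_geometry(GeometrySpec(kind="ideal_helix", n_residues=20))


@pytest.fixture(scope="session")
def sheet_pdb() -> str:
    return build_geometry(
        GeometrySpec(kind="beta_sheet", n_residues=8, params={"n_strands": 3})
    )


@pytest.fixture(scope="session")
def hairpin_pdb() -> str:
    return build_geometry(
        GeometrySpec(kind="beta_hairpin", n_residues=8, params={"tail_length": 8})
    )


@pytest.fixture(scope="session")
def coil_pdb() -> str:
    return build_geometry(GeometrySpec(kind="coiled_coil_dimer", n_residues=22))


@pytest.fixture(scope="session")
def dna_pdb() -> str:
    return build_geometry(GeometrySpec(kind="protein_dna_complex", n_residues=15))


@pytest.fixture(scope="session")
def sheet_annotations(sheet_pdb):
    s = parse_structure(sheet_pdb)
    return s, annotate_structure(s)


@pytest.fixture(scope="session")
def hairpin_annotations(hairpin_pdb):
    s = parse_structure(hairpin_pdb)
    return s, annotate_structure(s)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160914)
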