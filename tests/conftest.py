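import numpy as np
import pytest

from mappitmap import (
    ReferenceConstruct,
    TransfectionPlate384,
    make_toy_structure,
    random_reference,
)
from mappitmap.plates import Mixture, WellAssignment, WellKind


@pytest.fixture(scope="session")
def tiny_ref() -> ReferenceConstruct:
    """Three-codon construct MAE used throughout the variant-calling tests."""
    return ReferenceConstruct(construct_id="tiny", cds="ATGGCTGAA")


@pytest.fixture(scope="session")
def ref50() -> ReferenceConstruct:
    """A reproducible 50-codon construct for library-scale tests."""
    return random_reference(50, seed=1234, residue_offset=101)


@pytest.fixture(scope="session")
def helix20():
    """20-residue ideal-helix toy structure (model + PDB text)."""
    return make_toy_structure(20)


def build_plate(
    plate_id: str,
    experiment_id: str,
    mixtures: dict[str, WellKind],
    bait_id: str = "bait",
) -> TransfectionPlate384:
    """Hand-build a valid 384 plate: each mixture gets one row's wells 1-8,
    wells 1-4 stimulated."""
    rows = "ABCDEFGHIJKLMNOP"
    wells: dict[str, WellAssignment] = {}
    mix_objs: dict[str, Mixture] = {}
    for i, (mix_id, kind) in enumerate(mixtures.items()):
        row = rows[i]
        for col in range(1, 9):
            wells[f"{row}{col}"] = WellAssignment(
                mixture_id=mix_id, stimulated=col <= 4
            )
        mix_objs[mix_id] = Mixture(
            mixture_id=mix_id,
            prey_id=mix_id if kind is WellKind.MUTANT else kind.value,
            bait_id=bait_id,
            kind=kind,
            source_plate="SRC",
            source_well=f"{row}1",
        )
    plate = TransfectionPlate384(
        plate_id=plate_id,
        experiment_id=experiment_id,
        wells=wells,
        mixtures=mix_objs,
    )
    plate.validate()
    return plate


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
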