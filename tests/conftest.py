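import numpy as np
import pytest

from ndjmap.genome import (
    ArmDefinition,
    ChromosomeMap,
    GeneticMapTable,
    CEN_TO_TEL,
    TEL_TO_CEN,
)


@pytest.fixture
def toy_map() -> ChromosomeMap:
    """Small metacentric chromosome: 10 Mb + 12 Mb arms around a 1 Mb gap.

    Left arm euchromatin [0, 8 Mb), right arm euchromatin [3 Mb, 12 Mb)
    in local coordinates.
    """
    return ChromosomeMap(
        name="toy2",
        shape="metacentric",
        gap_length=1_000_000,
        arms=(
            ArmDefinition("L", 10_000_000, TEL_TO_CEN, 8_000_000),
            ArmDefinition("R", 12_000_000, CEN_TO_TEL, 3_000_000),
        ),
    )


@pytest.fixture
def telo_map() -> ChromosomeMap:
    """X-like telocentric chromosome: 23 Mb, centromere at the high end,
    euchromatin [0, 21 Mb)."""
    return ChromosomeMap(
        name="toyX",
        shape="telocentric",
        arms=(ArmDefinition("X", 23_000_000, TEL_TO_CEN, 21_000_000),),
    )


@pytest.fixture
def linear_gmap() -> GeneticMapTable:
    """5 cM/Mb linear map on both toy arms."""
    return GeneticMapTable(
        {
            "L": ([0, 10_000_000], [0.0, 50.0]),
            "R": ([0, 12_000_000], [0.0, 60.0]),
            "X": ([0, 10_000_000], [0.0, 50.0]),
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
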