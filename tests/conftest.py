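import pytest

from deepsage.simulate import (
    SimulationConfig,
    simulate_libraries,
    simulate_transcriptome,
)
from deepsage.tags import Library, TagCountMatrix, count_tags

import pandas as pd


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale synthetic experiment: 800 transcripts, two organs."""
    config = SimulationConfig(
        seed=11,
        n_transcripts=800,
        organ_depths={"root": 30_000, "nodule": 20_000},
    )
    scene = simulate_transcriptome(config)
    reads, counts = simulate_libraries(scene)
    return scene, reads, counts


def matrix_from_counts(
    counts_by_library: dict[str, dict[str, int]],
    organs_conditions: dict[str, tuple[str, str]],
) -> TagCountMatrix:
    """Build a TagCountMatrix directly from a generator count table."""
    libraries = [
        Library(lib_id, organ, condition)
        for lib_id, (organ, condition) in organs_conditions.items()
    ]
    observations = [
        (lib_id, tag)
        for lib_id, tag_counts in counts_by_library.items()
        for tag, n in tag_counts.items()
        for _ in range(n)
    ]
    return count_tags(observations, libraries)


def default_organs_conditions(config: SimulationConfig) -> dict[str, tuple[str, str]]:
    out = {}
    for organ in config.organ_depths:
        out[f"{organ}-control"] = (organ, "control")
        out[f"{organ}-NaCl"] = (organ, "NaCl")
    return out


@pytest.fixture(scope="session")
def small_matrix(small_scene):
    scene, _, counts = small_scene
    return matrix_from_counts(counts, default_organs_conditions(scene.config))


@pytest.fixture()
def toy_matrix():
    """Four tags, two root libraries, hand-set counts."""
    libraries = [
        Library("ctl", "root", "control"),
        Library("str", "root", "NaCl"),
    ]
    seqs = {
        "STCa-1": "CATG" + "ACGT" * 5 + "AC",
        "STCa-2": "CATG" + "TTGACCA" * 3 + "T",
        "STCa-3": "CATG" + "GACTGACA" * 2 + "GACTGA",
        "STCa-4": "CATG" + "CCGTA" * 4 + "CG",
    }
    counts = pd.DataFrame(
        {"ctl": [50, 10, 0, 5], "str": [50, 30, 8, 1]},
        index=list(seqs),
    )
    return TagCountMatrix(counts, pd.Series(seqs), libraries)
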