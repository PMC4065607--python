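import numpy as np
import pytest

from megadesign.combinatorial import ModuleLibrary, ScreeningRecord
from megadesign.scaffold import (
    P5N3_POSITIONS,
    P11N4_POSITIONS,
    ProteinVariant,
    Target,
    build_palindrome,
    enumerate_region_space,
)
from megadesign.synthetic import default_ground_truth, generate_screening_dataset


@pytest.fixture(scope="session")
def tiny_world():
    """A small but complete simulated world: ground truth + screened pools."""
    model = default_ground_truth(seed=11)
    dataset = generate_screening_dataset(model, n_targets=8, seed=11)
    return model, dataset


def _library(region, residue_rows, seed=0):
    positions = P5N3_POSITIONS if region == "p5N3" else P11N4_POSITIONS
    space = enumerate_region_space("5N3" if region == "p5N3" else "11N4")
    rng = np.random.default_rng(seed)
    halves = [dict(zip(positions, row)) for row in residue_rows]
    acts = rng.uniform(0.0, 1.0, size=(len(halves), len(space)))
    return ModuleLibrary(region, halves, acts, space)


@pytest.fixture()
def tiny_libs():
    """Hand-built module libraries with three halves per side."""
    lib5 = _library("p5N3", ["QRRDI", "RYSDR", "KQRNI"], seed=1)
    lib11 = _library("p11N4", ["NSYQS", "KSRQT", "NKYHS"], seed=2)
    return lib5, lib11


@pytest.fixture()
def tiny_records(tiny_libs):
    """All 9 half-combinations screened on two GTAC-centered targets."""
    lib5, lib11 = tiny_libs
    targets = [
        build_palindrome("GTTGAGCTA", "AC"),
        build_palindrome("AAAGTCGAT", "AC"),
    ]
    rng = np.random.default_rng(3)
    records = []
    for t in targets:
        for h5 in lib5.halves:
            for h11 in lib11.halves:
                v = ProteinVariant.from_halves(h5, h11)
                active = bool(rng.random() < 0.4)
                act = float(rng.uniform(0.3, 1.0)) if active else 0.0
                records.append(ScreeningRecord(v, t, act, active, active))
    return records
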