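import numpy as np
import pytest

from aacs import ChannelSet, packaged_panel
from aacs.composition import ProteinRecord, count_residues
from aacs.embedding import PlasmaComponent, PlasmaComposition, ResidueCountVector


@pytest.fixture(scope="session")
def panel():
    return {r.id: r for r in packaged_panel()}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_composition(rng, n_proteins=10, n_channels=5, max_count=60):
    """A random sequence-free composition for embedding arithmetic tests."""
    chans = ChannelSet(("Lys", "Trp", "Tyr", "Cys_T", "Cys_R")[:n_channels])
    comps = []
    for i in range(n_proteins):
        counts = rng.integers(0, max_count, size=n_channels)
        if "Cys_R" in chans.channels:
            ct, cr = chans.index("Cys_T"), chans.index("Cys_R")
            counts[cr] = min(counts[cr], counts[ct])
        theta = float(rng.uniform(0.1, 500.0))
        comps.append(
            PlasmaComponent(ResidueCountVector(chans, tuple(int(c) for c in counts)),
                            theta, f"P{i}")
        )
    return PlasmaComposition(tuple(comps))


@pytest.fixture()
def toy_records():
    return [
        ProteinRecord("P1", "KKWYC", disulfide_bond_count=0),
        ProteinRecord("P2", "KWCCYY", disulfide_bond_count=1),
    ]
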