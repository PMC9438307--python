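import numpy as np
import pytest

from olfevo.simulate import (
    emit_genomes,
    make_reference_panel,
    simulate_coevolving_families,
    simulate_species_tree,
)


@pytest.fixture(scope="session")
def small_tree():
    return simulate_species_tree(6, 120.0, seed=101)


@pytest.fixture(scope="session")
def panel():
    return make_reference_panel(seed=202)


@pytest.fixture(scope="session")
def mining_fixture():
    """Two small genomes with planted loci of all four statuses."""
    rng = np.random.default_rng(42)
    tree = simulate_species_tree(2, 100.0, rng=rng)
    panel = make_reference_panel(rng=rng)
    histories = simulate_coevolving_families(
        tree,
        root_counts={"OR": 4, "TAAR": 3, "OlfC": 2, "ORA": 2},
        rng=rng,
    )
    genomes, truth = emit_genomes(
        histories,
        panel,
        subst_rate=0.10,
        pseudo_fraction=0.2,
        truncated_fraction=0.1,
        edge_fraction=0.1,
        rng=rng,
    )
    return {"tree": tree, "panel": panel, "histories": histories,
            "genomes": genomes, "truth": truth}
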