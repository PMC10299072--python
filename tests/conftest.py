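import pytest

from mitocomp.gene_order import load_reference_order
from mitocomp.synthetic import (
    DivergenceSpec,
    SyntheticSpec,
    TdrlEvent,
    evolve_set,
    generate_mitogenome,
)


@pytest.fixture(scope="session")
def reference_order():
    return load_reference_order()


@pytest.fixture(scope="session")
def default_genome():
    """One synthetic genome under the default (salticid-like) conditions."""
    return generate_mitogenome(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def shuffled_genome(reference_order):
    """Genome with one TDRL event swapping the adjacent trnN/trnL2 pair."""
    i = reference_order.names.index("trnN")
    spec = SyntheticSpec(seed=2, identifier="SYNSHUF",
                         tdrl_events=(TdrlEvent(i, i + 2, (False, True)),))
    return generate_mitogenome(spec)


@pytest.fixture(scope="session")
def evolved_set():
    """Root genome plus 4 tips diverged under omega=0.2, kappa=2."""
    spec = SyntheticSpec(
        seed=3,
        divergence=DivergenceSpec(n_taxa=4, branch_length=0.04,
                                  omega=0.2, kappa=2.0),
    )
    root = generate_mitogenome(spec)
    genomes, alignments = evolve_set(root, spec)
    return root, genomes, alignments
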