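import numpy as np
import pytest

from codonuse.simulate import (
    SyntheticSpec,
    generate_gene,
    known_answer_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    """Hand-constructed genes with analytically known metric values."""
    return known_answer_fixtures()


@pytest.fixture(scope="session")
def random_genes():
    """200 seeded synthetic genes spanning GC3 targets and bias strengths."""
    rng = np.random.default_rng(20260930)
    genes = []
    for i in range(200):
        spec = SyntheticSpec(
            median_protein_aa=120,
            sigma_log_aa=0.3,
            min_protein_aa=40,
            target_gc3=float(rng.uniform(0.35, 0.9)),
            bias_strength=float(rng.uniform(0.0, 2.5)),
        )
        genes.append(generate_gene(spec, rng=rng, gene_id=f"rand{i:03d}"))
    return genes
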