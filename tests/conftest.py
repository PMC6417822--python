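import numpy as np
import pytest

from genetriage.preprocess import Vocabulary
from genetriage.types import ConceptToken


@pytest.fixture(scope="session")
def small_vocab() -> Vocabulary:
    return Vocabulary(index={f"C{i}": i + 4 for i in range(30)})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_concepts(rng: np.random.Generator, n: int, pool: int = 40) -> list[ConceptToken]:
    """Concept sequence with random categories/flags, ids drawn from C0..C{pool}."""
    return [
        ConceptToken(
            f"C{rng.integers(0, pool)}",
            category_index=int(rng.integers(0, 136)),
            confidence=float(rng.uniform(0, 1)),
            is_gene_ontology=bool(rng.random() < 0.3),
            is_disease_ontology=bool(rng.random() < 0.3),
        )
        for _ in range(n)
    ]
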