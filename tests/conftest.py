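import numpy as np
import pytest

from conceptmap.embedding import LexicalHashEmbedder
from conceptmap.models import Domain, MappingRecord, MappingStatus, SourceConcept, TargetConcept, Vocabulary
from conceptmap.simulate import SyntheticConfig, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def toy_vocabulary():
    names = [
        "haemoglobin mass concentration in blood",
        "sodium substance concentration in serum",
        "potassium substance concentration in serum",
        "creatinine substance concentration in serum",
        "platelet count in blood",
    ]
    return Vocabulary(
        "TOY", [TargetConcept(f"T{i:03d}", n, "TOY") for i, n in enumerate(names)]
    )


@pytest.fixture
def toy_sources():
    return [
        SourceConcept("haemoglobin hb", "site1", Domain.LAB_TEST, 40),
        SourceConcept("fbc fbc hb", "site1", Domain.LAB_TEST, 25),
        SourceConcept("U SODIUM_RAND_363_61", "site2", Domain.LAB_TEST, 9),
        SourceConcept("plt count plt", "site2", Domain.LAB_TEST, 31),
    ]


@pytest.fixture
def toy_gold(toy_vocabulary, toy_sources):
    targets = [0, 0, 1, 4]
    return [
        MappingRecord(
            source=s,
            status=MappingStatus.MAPPED,
            target=toy_vocabulary.concepts[t],
            reviewer_id="tester",
        )
        for s, t in zip(toy_sources, targets)
    ]


@pytest.fixture
def small_backend():
    return LexicalHashEmbedder(dimension=128)


@pytest.fixture(scope="session")
def small_corpus():
    """Desk-scale corpus small enough for fast unit tests."""
    return generate_corpus(SyntheticConfig(n_targets=40, n_sites=3, seed=11))
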