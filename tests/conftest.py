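import numpy as np
import pytest

from ethoseq import BehaviorCatalogue, Ethogram, catalogue_preset
from ethoseq.catalogue import NONE_LABEL


@pytest.fixture(scope="session")
def resident_cat() -> BehaviorCatalogue:
    return catalogue_preset("resident_vs_female")


@pytest.fixture(scope="session")
def tiny_cat() -> BehaviorCatalogue:
    """Minimal two-behavior catalogue for hand-checkable examples."""
    return BehaviorCatalogue(
        labels=("eating", "grooming"),
        roles={"eating": "individual", "grooming": "individual"},
        colors={"eating": "black", "grooming": "purple"},
    )


def make_ethogram(labels, catalogue, **kwargs):
    return Ethogram(labels=tuple(labels), catalogue=catalogue, **kwargs)


@pytest.fixture(scope="session")
def random_ethogram_factory(resident_cat):
    """Random barcodes over the resident alphabet plus NONE."""

    def factory(rng: np.random.Generator, duration_s: int = 120, p_none: float = 0.3):
        pool = list(resident_cat.labels)
        labels = [
            NONE_LABEL if rng.random() < p_none else pool[rng.integers(len(pool))]
            for _ in range(duration_s)
        ]
        return make_ethogram(labels, resident_cat)

    return factory
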