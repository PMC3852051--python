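import pytest

from coevomap.io import AlignedFamily
from coevomap.model import ParalogMatchingModel
from coevomap.simulate import SynthConfig, generate


@pytest.fixture
def toy_families():
    """Two species, unbalanced paralog counts, hand-checkable sizes."""
    fam_a = AlignedFamily(
        "toyA",
        (
            ("a1_YEAST", "MKV-LT"),
            ("a2_YEAST", "MRVALT"),
            ("a3_HUMAN", "MKVALS"),
        ),
        {"a1_YEAST": "YEAST", "a2_YEAST": "YEAST", "a3_HUMAN": "HUMAN"},
    )
    fam_b = AlignedFamily(
        "toyB",
        (
            ("b1_YEAST", "ADEFGHI-"),
            ("b2_HUMAN", "ADEFGYIK"),
            ("b3_HUMAN", "AD-FGYIK"),
        ),
        {"b1_YEAST": "YEAST", "b2_HUMAN": "HUMAN", "b3_HUMAN": "HUMAN"},
    )
    return fam_a, fam_b


@pytest.fixture
def small_instance():
    """Synthetic two-species instance small enough to enumerate."""
    fam_a, fam_b, truth = generate(
        SynthConfig(
            n_species=2,
            paralogs_per_species=(2, 3),
            seq_length=80,
            decoy_rate_jitter=0.25,
            seed=42,
        )
    )
    return fam_a, fam_b, truth


@pytest.fixture
def small_model(small_instance):
    fam_a, fam_b, truth = small_instance
    return ParalogMatchingModel(fam_a, fam_b), truth


def random_small_config(rng, max_species=4, max_paralogs=4):
    """Random generator settings for enumeration-checkable instances."""
    return SynthConfig(
        n_species=int(rng.integers(1, max_species + 1)),
        paralogs_per_species=(1, int(rng.integers(1, max_paralogs + 1))),
        seq_length=int(rng.integers(20, 80)),
        shared_rate_range=(0.05, 0.6),
        decoy_rate_jitter=float(rng.uniform(0.0, 0.3)),
        indel_rate=0.05,
        seed=int(rng.integers(0, 2**31)),
    )
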