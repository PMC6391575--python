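"""Shared fixtures: the bundled scheme, hand-built statistics, and
session-scoped trained models on seeded synthetic corpora."""

from __future__ import annotations

import pathlib

import pytest
from hypothesis import settings

from mirslot import SlotStatistics, default_scheme, train
from mirslot.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

SLOTS = ["Species", "Precursor", "miRNA", "Let", "Order", "Conj", "Suffix", "Hairpin"]


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def exclusive_stats():
    """Statistics where every slot/symbol occurs only inside mentions.

    Matched-slot scores are exactly 100, all penalties are exactly 0 —
    the regime in which the printed worked-example decompositions are
    stated.
    """
    return SlotStatistics(
        slot_counts={s: [10.0, 0.0] for s in SLOTS},
        nonslot_counts={"-": [10.0, 0.0], ",": [10.0, 0.0], "/": [5.0, 0.0]},
    )


@pytest.fixture(scope="session")
def noiseless_corpus():
    return generate_corpus(GeneratorConfig(n_documents=30, noise_rate=0.0, seed=21))


@pytest.fixture(scope="session")
def noiseless_model(noiseless_corpus, scheme):
    return train(noiseless_corpus.documents, scheme)


@pytest.fixture(scope="session")
def noisy_corpus():
    return generate_corpus(GeneratorConfig(n_documents=45, noise_rate=0.05, seed=11))


@pytest.fixture(scope="session")
def noisy_model(noisy_corpus, scheme):
    return train(noisy_corpus.documents, scheme)


@pytest.fixture(scope="session")
def toy_family_path() -> str:
    from importlib import resources

    return str(resources.files("mirslot.data").joinpath("toy_family.txt"))


@pytest.fixture()
def tmp_family_file(tmp_path: pathlib.Path, noiseless_corpus) -> pathlib.Path:
    p = tmp_path / "family.txt"
    p.write_text(noiseless_corpus.family_file_text, encoding="utf-8")
    return p
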