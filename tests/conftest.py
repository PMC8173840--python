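"""Shared fixtures: seeded generators for small synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from endosift.seq_io import AMINO_ACIDS, SeqRecord


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_210_602)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def dna_record(rng) -> SeqRecord:
    return SeqRecord("contig1", random_dna(rng, 1000, gc=0.42))
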