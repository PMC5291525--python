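from __future__ import annotations

import numpy as np
import pytest

from zcc.io_formats import GenomeSequence

BASES = np.array(list("ACGT"))
AMBIG = np.array(list("NRYSWKM"))


def random_dna(rng: np.random.Generator, length: int, ambig_frac: float = 0.0) -> str:
    """Random DNA string, optionally salted with IUPAC ambiguity codes."""
    chars = BASES[rng.integers(0, 4, size=length)]
    if ambig_frac > 0 and length > 0:
        mask = rng.random(length) < ambig_frac
        chars = chars.copy()
        chars[mask] = AMBIG[rng.integers(0, len(AMBIG), size=int(mask.sum()))]
    return "".join(chars)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def make_seq():
    def _make(residues: str, genome_id: str = "test", topology: str = "circular") -> GenomeSequence:
        return GenomeSequence(genome_id=genome_id, residues=residues, topology=topology)

    return _make
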