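import numpy as np
import pandas as pd
import pytest

from lextrack.features import Alignment, Lexicon, LexiconEntry, PhonemeInterval, WordInterval
from lextrack.matchmismatch import MMDataset


def make_lexicon_from(specs: list[tuple[str, float]]) -> Lexicon:
    """Lexicon from (word, prior) pairs; phonemes are the word's letters."""
    return Lexicon(
        [LexiconEntry(word, tuple(word), prior) for word, prior in specs]
    )


@pytest.fixture
def toy_lexicon() -> Lexicon:
    """The four-word uniform lexicon {AB, ABC, AC, BA}."""
    return make_lexicon_from([("AB", 0.25), ("ABC", 0.25), ("AC", 0.25), ("BA", 0.25)])


@pytest.fixture
def toy_alignment() -> Alignment:
    """One word 'AB' spanning [0.1, 0.5) with phonemes A and B."""
    return Alignment(
        words=[WordInterval("AB", 0.1, 0.5)],
        phonemes=[
            PhonemeInterval("A", 0.1, 0.3, 0),
            PhonemeInterval("B", 0.3, 0.5, 0),
        ],
    )


def random_dataset(
    n: int, channels: int, streams: int, window: int, seed: int
) -> MMDataset:
    """Structureless examples for chance-level and plumbing tests."""
    rng = np.random.default_rng(seed)
    return MMDataset(
        eeg=rng.standard_normal((n, channels, window)).astype(np.float32),
        candidates=rng.standard_normal((n, 2, streams, window)).astype(np.float32),
        labels=rng.integers(0, 2, n),
        meta=pd.DataFrame({"subject": ["s"] * n, "condition": ["c"] * n}),
    )
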