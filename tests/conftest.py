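import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dphmm.msa_io import MultipleAlignment
from dphmm.phmm_core import ProfileHMM

PARAM_NAMES = (
    "match_logits", "insert_logits", "flank_n_logits", "flank_c_logits",
    "begin_logits", "match_trans_logits", "insert_trans_logits",
    "delete_trans_logits",
)


def random_hmm(rng: np.random.Generator, length: int, scale: float = 1.5) -> ProfileHMM:
    """A fully random (unstructured) profile HMM for oracle comparisons."""
    hmm = ProfileHMM.uniform(length)
    for name in PARAM_NAMES:
        arr = getattr(hmm, name)
        setattr(hmm, name, arr + rng.normal(0, scale, arr.shape))
    return hmm


def random_toy_msa(rng: np.random.Generator, max_rows: int = 6) -> MultipleAlignment:
    """A small random gapped alignment (rows de-gap to nonempty sequences)."""
    while True:
        n_rows = rng.integers(2, max_rows + 1)
        n_cols = rng.integers(2, 9)
        rows = []
        for _ in range(n_rows):
            row = "".join(
                rng.choice(list("ACDE-")) for _ in range(n_cols)
            )
            rows.append(row)
        if all(any(c != "-" for c in r) for r in rows):
            return MultipleAlignment(
                [f"s{i}" for i in range(n_rows)], rows
            )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
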