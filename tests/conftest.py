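"""Shared fixtures and independent oracles for the axokit test suite."""

from __future__ import annotations

import numpy as np
import pytest

from axokit import CANONICAL_RESIDUES, CLASS_LABELS, DEFAULT_SCHEME, ProteomeDB

LETTERS = sorted(CANONICAL_RESIDUES)


def brute_force_search(pattern, records, max_mismatches):
    """Independent per-window class-mismatch counter.

    Pure-Python reference for the vectorised scan: every window of every
    sequence is scored by direct set membership; non-canonical letters never
    match.  Returns sorted (seq_id, start, n_mismatches) triples.
    """
    k = len(pattern)
    hits = []
    for seq_id, seq in records.items():
        for start in range(len(seq) - k + 1):
            window = seq[start : start + k]
            nm = sum(1 for r, allowed in zip(window, pattern) if r not in allowed)
            if nm <= max_mismatches:
                hits.append((seq_id, start, nm))
    return sorted(hits)


def random_db(rng, n_sequences=20, length=200, prefix="r"):
    """Uniform-composition random protein database."""
    records = {}
    for i in range(n_sequences):
        draws = rng.integers(0, 20, size=length)
        records[f"{prefix}{i:03d}"] = "".join(LETTERS[d] for d in draws)
    return ProteomeDB(records=records, name="random")


def random_pattern(rng, min_len=3, max_len=15):
    """Random allowed-residue-set pattern over the default scheme classes."""
    k = int(rng.integers(min_len, max_len + 1))
    pattern = []
    for _ in range(k):
        u = rng.random()
        if u < 0.7:
            labels = [CLASS_LABELS[rng.integers(0, 4)]]
        elif u < 0.9:
            labels = list(rng.choice(CLASS_LABELS, size=2, replace=False))
        else:
            labels = list(CLASS_LABELS)
        pattern.append(DEFAULT_SCHEME.residues(labels))
    return pattern


@pytest.fixture
def rng():
    return np.random.default_rng(20231108)
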