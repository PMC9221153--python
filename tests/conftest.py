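"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gapmertox.datasets import negative_control_panel, negative_control_table


def dp_levenshtein(a: str, b: str) -> int:
    """Full dynamic-programming Levenshtein oracle (unit costs), written
    independently of the package implementation."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def pair_counting_auc(scores, toxic) -> float:
    """AUC by exhaustive Mann-Whitney pair enumeration: probability that a
    random toxic ASO scores lower than a random acceptable one, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    toxic = np.asarray(toxic, dtype=bool)
    tox = scores[toxic]
    acc = scores[~toxic]
    wins = 0.0
    for t in tox:
        for a in acc:
            if t < a:
                wins += 1.0
            elif t == a:
                wins += 0.5
    return wins / (len(tox) * len(acc))


def brute_force_offtarget(aso_bases, transcripts, max_mismatch):
    """Window-by-window off-target oracle: slide the reverse complement of
    the ASO over each transcript, counting mismatches per window."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    site = "".join(comp[b] for b in reversed(aso_bases))
    L = len(site)
    perfect = False
    n_partial = 0
    for seq in transcripts:
        best = L
        for i in range(len(seq) - L + 1):
            mm = sum(1 for x, y in zip(seq[i : i + L], site) if x != y)
            best = min(best, mm)
        if best == 0:
            perfect = True
        if best <= max_mismatch:
            n_partial += 1
    return perfect, n_partial / len(transcripts)


@pytest.fixture(scope="session")
def reference_panel():
    return negative_control_panel()


@pytest.fixture(scope="session")
def reference_table():
    return negative_control_table()
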