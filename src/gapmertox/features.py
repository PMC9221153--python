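"""Sequence features associated with acute neurotoxic potential.

The features are computed at the nucleobase level, ignoring the LNA/DNA
modification status of each position (sugar-modified and unmodified
nucleotides contribute to the neurotoxic potential to the same extent):

- ``n_a``, ``n_t``, ``n_c``, ``n_g``: counts of each nucleobase;
- ``g3`` / ``g5``: length of the guanine-free stretch counted inward from
  the 3' / 5' terminus (0 if the terminal base is G, the full length when
  the sequence contains no G);
- ``n_lna``, ``gap_length``: number of LNA positions and the number of DNA
  positions between the outermost LNA positions.

Levenshtein edit distance between base sequences (unit-cost substitutions,
insertions and deletions) supports the similarity analysis: similar
sequences tend to have similar calcium-oscillation scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional

import edlib
import numpy as np
import pandas as pd

from .gapmer import VALID_BASES, AsoPanel, AsoSequence

FEATURE_COLUMNS = [
    "length",
    "n_lna",
    "gap_length",
    "n_a",
    "n_t",
    "n_c",
    "n_g",
    "g3",
    "g5",
]


@dataclass(frozen=True)
class FeatureVector:
    """Per-ASO sequence features (see module docstring for definitions)."""

    n_a: int
    n_t: int
    n_c: int
    n_g: int
    g3: int
    g5: int
    length: int
    n_lna: int
    gap_length: int

    def __post_init__(self) -> None:
        if self.n_a + self.n_t + self.n_c + self.n_g != self.length:
            raise ValueError("base counts do not sum to length")
        if not (0 <= self.g3 <= self.length and 0 <= self.g5 <= self.length):
            raise ValueError("G-free stretch outside [0, length]")

    @classmethod
    def from_aso(cls, aso: AsoSequence) -> "FeatureVector":
        counts = count_nucleotides(aso)
        return cls(
            n_a=counts["A"],
            n_t=counts["T"],
            n_c=counts["C"],
            n_g=counts["G"],
            g3=g_free_stretch(aso, "three_prime"),
            g5=g_free_stretch(aso, "five_prime"),
            length=len(aso),
            n_lna=aso.n_lna,
            gap_length=gap_length(aso),
        )


def count_nucleotides(aso: AsoSequence) -> dict[str, int]:
    """Count each nucleobase; the four counts sum to the sequence length."""
    return {b: aso.bases.count(b) for b in "ATCG"}


def g_free_stretch(
    aso: AsoSequence, end: Literal["three_prime", "five_prime"]
) -> int:
    """Number of consecutive non-G bases starting at the named terminus.

    0 if the terminal base is G; the full length if the sequence contains
    no G at all.  Sequences are stored 5'->3', so the 3' stretch is counted
    from the last character inward.
    """
    if end == "three_prime":
        it = reversed(aso.bases)
    elif end == "five_prime":
        it = iter(aso.bases)
    else:
        raise ValueError(f"end must be three_prime or five_prime, got {end!r}")
    n = 0
    for b in it:
        if b == "G":
            break
        n += 1
    return n


def gap_length(aso: AsoSequence) -> int:
    """Number of DNA positions between the outermost LNA positions.

    For the canonical two-flank gapmer architecture this equals
    ``length - n_lna``.  With no LNA at all, the whole sequence is the gap.
    """
    flags = aso.lna
    if not any(flags):
        return len(aso)
    first = flags.index(True)
    last = len(flags) - 1 - flags[::-1].index(True)
    return sum(1 for i in range(first, last + 1) if not flags[i])


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance between two base strings (unit costs)."""
    for name, s in (("a", a), ("b", b)):
        if not set(s) <= VALID_BASES:
            raise ValueError(f"string {name!r} has characters outside ACGT")
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def feature_table(panel: AsoPanel) -> pd.DataFrame:
    """One feature row per ASO, in panel order, indexed by id."""
    rows = [FeatureVector.from_aso(a) for a in panel]
    return pd.DataFrame(
        {col: [getattr(r, col) for r in rows] for col in FEATURE_COLUMNS},
        index=pd.Index(panel.ids, name="id"),
    )


class SimilarityAssociation(NamedTuple):
    """Pairwise edit-distance vs score-difference table with its Spearman
    rank correlation."""

    pairs: pd.DataFrame  # columns: id_a, id_b, edit_distance, score_difference
    rho: float
    p_value: float
    exhaustive: bool


def similarity_score_association(
    panel: AsoPanel,
    score_column: str = "calcium_score",
    max_pairs: int = 100_000,
    seed: Optional[int] = 0,
) -> SimilarityAssociation:
    """Relate sequence similarity to score similarity across a panel.

    All (or, above ``max_pairs``, a seeded subsample of) unordered ASO pairs
    are tabulated with their Levenshtein distance and absolute score
    difference; the Spearman rank correlation of the two columns is
    returned.  A positive correlation means similar sequences have similar
    scores.
    """
    from .scoring_model import spearman_test  # local import avoids cycle

    if score_column not in panel.annotations.columns:
        raise ValueError(f"panel has no {score_column!r} annotation")
    scores = panel.annotations[score_column]
    scored = [a for a in panel if pd.notna(scores.loc[a.id])]
    if len(scored) < 2:
        raise ValueError("need at least 2 scored ASOs for pairwise analysis")

    n = len(scored)
    n_pairs = n * (n - 1) // 2
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    exhaustive = n_pairs <= max_pairs
    if not exhaustive:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_pairs, size=max_pairs, replace=False)
        all_pairs = [all_pairs[k] for k in idx]

    records = []
    for i, j in all_pairs:
        a, b = scored[i], scored[j]
        records.append(
            (
                a.id,
                b.id,
                levenshtein(a.bases, b.bases),
                abs(scores.loc[a.id] - scores.loc[b.id]),
            )
        )
    pairs = pd.DataFrame(
        records, columns=["id_a", "id_b", "edit_distance", "score_difference"]
    )
    if (
        pairs["edit_distance"].nunique() < 2
        or pairs["score_difference"].nunique() < 2
    ):
        rho, p = float("nan"), float("nan")
    else:
        rho, p = spearman_test(
            pairs["edit_distance"].to_numpy(),
            pairs["score_difference"].to_numpy(),
        )
    return SimilarityAssociation(pairs, rho, p, exhaustive)
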