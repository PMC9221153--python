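"""Design of negative-control gapmers with low acute neurotoxic potential.

The design rule combines what the sequence-score analysis teaches: G
nucleotides (especially toward the 3' end) raise acute neurotoxic
potential, A nucleotides lower it.  Candidates are therefore random
sequences over {A, C, T} (no G) whose A count roughly balances T+C, which
are then screened against a transcriptome so that (i) no transcript
contains a perfectly complementary binding site and (ii) fewer than a
configurable fraction of transcripts (default 0.1%) contain a partially
complementary site at up to a configurable number of mismatches (default
2, i.e. "fewer than three").  Complementarity is Hamming-style over the
reverse-complement alignment -- no gaps or bulges.  Surviving candidates
are scored with a fitted linear model and only designs above the score
cutoff (default 70) are emitted, ranked by descending score.

RNA targets are stored as DNA letters (U is T); complementarity is
computed A<->T, C<->G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import FeatureVector
from .gapmer import VALID_BASES, AsoSequence, reverse_complement
from .scoring_model import SequenceScoreResults, calculate_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transcriptome:
    """RNA sequences (stored as DNA letters, 5'->3') keyed by transcript id."""

    records: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("transcriptome must be non-empty")
        for tid, seq in self.records.items():
            if not set(seq) <= VALID_BASES:
                raise ValueError(f"transcript {tid!r} has non-ACGT characters")

    def __len__(self) -> int:
        return len(self.records)

    def items(self):
        return self.records.items()

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "Transcriptome":
        records = {
            r.id: str(r.seq).upper().replace("U", "T")
            for r in SeqIO.parse(str(path), "fasta")
        }
        return cls(records)

    def to_fasta(self, path: Union[str, Path]) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=i, description="") for i, s in self.items()],
            str(path),
            "fasta",
        )


class OffTargetResult(NamedTuple):
    """Outcome of screening one ASO against a transcriptome."""

    perfect_match: bool
    partial_fraction: float
    n_transcripts: int
    min_mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def offtarget_screen(
    aso: AsoSequence, txome: Transcriptome, max_mismatch: int = 2
) -> OffTargetResult:
    """Slide the ASO's reverse complement along every transcript, counting
    base mismatches per window (no gaps).

    A transcript harbours a binding region when some window matches with at
    most ``max_mismatch`` mismatches; ``partial_fraction`` is the fraction
    of transcripts with at least one such region, and ``perfect_match``
    flags any zero-mismatch window.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    site = _encode(reverse_complement(aso.bases))
    L = len(site)
    n_partial = 0
    perfect = False
    overall_min = L
    for tid, seq in txome.items():
        if len(seq) < L:
            raise ValueError(
                f"transcript {tid!r} shorter than ASO ({len(seq)} < {L})"
            )
        arr = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mismatches = (windows != site).sum(axis=1)
        tmin = int(mismatches.min())
        overall_min = min(overall_min, tmin)
        if tmin == 0:
            perfect = True
        if tmin <= max_mismatch:
            n_partial += 1
    return OffTargetResult(
        perfect_match=perfect,
        partial_fraction=n_partial / len(txome),
        n_transcripts=len(txome),
        min_mismatches=overall_min,
    )


@dataclass(frozen=True)
class DesignConstraints:
    """Constraints for negative-control candidate generation and filtering.

    - ``lengths``: allowed total lengths (nt);
    - ``flank_patterns``: allowed (5', 3') LNA flank sizes;
    - ``require_no_g``: candidates are drawn over {A, C, T};
    - ``balance_delta``: tolerance on abs(n_A - (n_T + n_C)) (default 4, the
      loosest value seen among the published designs);
    - ``max_mismatch`` / ``max_partial_fraction``: off-target screen limits
      ("fewer than three mismatches" -> 2; "<0.1% of transcripts" -> 0.001,
      counted per transcript record);
    - ``min_score``: calculated-score floor for emitted designs;
    - ``attempt_budget``: rejection-sampling cap.
    """

    lengths: tuple[int, ...] = (18, 20)
    flank_patterns: tuple[tuple[int, int], ...] = ((3, 3), (4, 4))
    require_no_g: bool = True
    balance_delta: int = 4
    max_mismatch: int = 2
    max_partial_fraction: float = 0.001
    min_score: float = 70.0
    attempt_budget: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.max_partial_fraction <= 1:
            raise ValueError("max_partial_fraction must be in (0, 1]")
        if self.max_mismatch < 0 or self.balance_delta < 0:
            raise ValueError("max_mismatch and balance_delta must be >= 0")
        for five, three in self.flank_patterns:
            if five + three >= min(self.lengths):
                raise ValueError(
                    f"flank pattern ({five},{three}) leaves no DNA gap at "
                    f"length {min(self.lengths)}"
                )


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_candidates(
    constraints: DesignConstraints,
    rng: np.random.Generator,
    start_index: int = 0,
) -> Iterator[AsoSequence]:
    """Endless stream of composition-valid candidates (before screening)."""
    alphabet = np.array(list("ACT" if constraints.require_no_g else "ACGT"))
    index = start_index
    for _ in range(constraints.attempt_budget):
        length = int(rng.choice(constraints.lengths))
        bases = "".join(rng.choice(alphabet, size=length))
        n_a = bases.count("A")
        if abs(n_a - (length - n_a - bases.count("G"))) > constraints.balance_delta:
            continue
        fits = [
            (f, t) for f, t in constraints.flank_patterns if f + t < length
        ]
        five, three = fits[rng.integers(len(fits))]
        lna = tuple(
            i < five or i >= length - three for i in range(length)
        )
        index += 1
        yield AsoSequence(id=f"nc{index:04d}", bases=bases, lna=lna)


def generate_candidates(
    constraints: DesignConstraints,
    n: int,
    seed: Union[int, np.random.Generator, None] = 0,
) -> list[AsoSequence]:
    """Draw ``n`` candidate gapmers satisfying the composition constraints
    by seeded rejection sampling (deterministic for a fixed seed)."""
    rng = _rng(seed)
    out = list()
    seen = set()
    for aso in _sample_candidates(constraints, rng):
        if aso.bases in seen:
            continue
        seen.add(aso.bases)
        out.append(aso)
        if len(out) == n:
            return out
    raise RuntimeError(
        f"rejection budget ({constraints.attempt_budget}) exhausted after "
        f"{len(out)} of {n} candidates; loosen the constraints"
    )


@dataclass
class DesignResult:
    """Ranked negative-control designs with their screen outcomes."""

    asos: list[AsoSequence]
    table: pd.DataFrame  # id, sequence, length, counts, score, screen cols


def design_negative_controls(
    model: SequenceScoreResults,
    txome: Transcriptome,
    constraints: Optional[DesignConstraints] = None,
    n: int = 13,
    seed: Union[int, np.random.Generator, None] = 0,
) -> DesignResult:
    """Generate ``n`` negative-control designs passing every filter:
    composition constraints, no perfect transcriptome complement, partial
    complements in fewer than ``max_partial_fraction`` of transcripts, and
    calculated score above ``min_score``; ranked by descending score.

    Emits a partial result with a warning when the attempt budget runs out
    before ``n`` designs are found.
    """
    constraints = constraints or DesignConstraints()
    rng = _rng(seed)
    kept: list[tuple[AsoSequence, float, OffTargetResult]] = []
    seen: set[str] = set()
    for aso in _sample_candidates(constraints, rng):
        if aso.bases in seen:
            continue
        seen.add(aso.bases)
        fv = FeatureVector.from_aso(aso)
        score = calculate_score(model, fv)
        if score <= constraints.min_score:
            continue
        screen = offtarget_screen(aso, txome, constraints.max_mismatch)
        if screen.perfect_match:
            continue
        if screen.partial_fraction >= constraints.max_partial_fraction:
            continue
        kept.append((aso, score, screen))
        if len(kept) == n:
            break
    if len(kept) < n:
        logger.warning(
            "found only %d of %d designs within the attempt budget",
            len(kept),
            n,
        )
    kept.sort(key=lambda t: -t[1])
    rows = []
    asos = []
    for aso, score, screen in kept:
        fv = FeatureVector.from_aso(aso)
        asos.append(aso)
        rows.append(
            {
                "id": aso.id,
                "sequence": aso.annotated,
                "length": fv.length,
                "n_a": fv.n_a,
                "n_t": fv.n_t,
                "n_c": fv.n_c,
                "n_g": fv.n_g,
                "calculated_score": score,
                "perfect_match": screen.perfect_match,
                "partial_fraction": screen.partial_fraction,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "id",
            "sequence",
            "length",
            "n_a",
            "n_t",
            "n_c",
            "n_g",
            "calculated_score",
            "perfect_match",
            "partial_fraction",
        ],
    ).set_index("id")
    return DesignResult(asos=asos, table=table)
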