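"""LNA/DNA gapmer sequences and panels.

A gapmer antisense oligonucleotide (ASO) is a short single-stranded DNA
oligonucleotide in which some positions carry a locked-nucleic-acid (LNA)
sugar modification -- typically the 5' and 3' flanks -- while the central
"gap" is plain DNA, supporting RNase H recruitment.  All ASOs handled here
have a full phosphorothioate (PS) backbone.

The textual dialect used throughout the package encodes the modification
pattern in letter case: uppercase = LNA, lowercase = DNA, written 5'->3',
e.g. ``TCCactaaccaatatAAC`` is an 18-mer with 3-nt LNA flanks.  Bases are
always the four DNA letters (T, never U); base-analog chemistry such as
LNA-5-methylcytosine is not modelled because every sequence feature used
downstream depends only on the four-letter base identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
MIN_LENGTH = 10
MAX_LENGTH = 25

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class GapmerParseError(ValueError):
    """Raised when an annotated gapmer string cannot be parsed."""


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement over the DNA alphabet (A<->T, C<->G)."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AsoSequence:
    """A single gapmer ASO: bases 5'->3' with per-position LNA/DNA flags.

    Parameters
    ----------
    id : str
        Unique label within a panel.
    bases : str
        Uppercase base string over {A, C, G, T}, 5'->3'.
    lna : tuple of bool
        Per-position flag, ``True`` where the sugar is LNA-modified.
    backbone : str
        Backbone chemistry tag; always ``"PS"`` here.
    """

    id: str
    bases: str
    lna: tuple[bool, ...]
    backbone: str = "PS"

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.lna):
            raise ValueError(
                f"{self.id}: bases ({len(self.bases)}) and modification flags "
                f"({len(self.lna)}) differ in length"
            )
        if not (MIN_LENGTH <= len(self.bases) <= MAX_LENGTH):
            raise ValueError(
                f"{self.id}: length {len(self.bases)} outside "
                f"[{MIN_LENGTH}, {MAX_LENGTH}]"
            )
        bad = [i for i, b in enumerate(self.bases) if b not in VALID_BASES]
        if bad:
            raise GapmerParseError(
                f"{self.id}: invalid base {self.bases[bad[0]]!r} at position "
                f"{bad[0] + 1}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_lna(self) -> int:
        return sum(self.lna)

    @property
    def annotated(self) -> str:
        """Case-annotated string: uppercase LNA, lowercase DNA."""
        return serialize_gapmer(self)


def parse_gapmer(text: str, id: str = "aso") -> AsoSequence:
    """Parse a case-annotated gapmer string (upper = LNA, lower = DNA).

    Raises
    ------
    GapmerParseError
        If a character is outside {A,C,G,T,a,c,g,t}; the 1-based position of
        the first offender is named.
    ValueError
        If the length falls outside the supported 10-25 nt range.
    """
    if not text:
        raise GapmerParseError(f"{id}: empty sequence")
    for i, ch in enumerate(text):
        if ch.upper() not in VALID_BASES:
            raise GapmerParseError(
                f"{id}: invalid character {ch!r} at position {i + 1}"
            )
    return AsoSequence(
        id=id,
        bases=text.upper(),
        lna=tuple(ch.isupper() for ch in text),
    )


def serialize_gapmer(aso: AsoSequence) -> str:
    """Inverse of :func:`parse_gapmer`: LNA positions uppercase, DNA lowercase."""
    return "".join(
        b if flag else b.lower() for b, flag in zip(aso.bases, aso.lna)
    )


class AsoPanel:
    """An ordered collection of ASOs with optional per-ASO annotations.

    Annotations (e.g. ``calcium_score`` in percent of control,
    ``tolerability_score`` on the 0-20 scale) are held in a DataFrame indexed
    by ASO id, aligned with the panel order.
    """

    def __init__(
        self,
        asos: Iterable[AsoSequence],
        annotations: Optional[pd.DataFrame] = None,
    ) -> None:
        self.asos: list[AsoSequence] = list(asos)
        ids = [a.id for a in self.asos]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ASO ids in panel: {dupes}")
        if annotations is None:
            annotations = pd.DataFrame(index=pd.Index(ids, name="id"))
        else:
            annotations = annotations.reindex(ids)
            annotations.index.name = "id"
        self.annotations = annotations

    def __len__(self) -> int:
        return len(self.asos)

    def __iter__(self) -> Iterator[AsoSequence]:
        return iter(self.asos)

    def __getitem__(self, key: str | int) -> AsoSequence:
        if isinstance(key, int):
            return self.asos[key]
        for a in self.asos:
            if a.id == key:
                return a
        raise KeyError(key)

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.asos]

    def to_dataframe(self) -> pd.DataFrame:
        """Panel as a table: id, annotated sequence, plus annotation columns."""
        df = pd.DataFrame(
            {"sequence": [a.annotated for a in self.asos]},
            index=pd.Index(self.ids, name="id"),
        )
        return df.join(self.annotations)


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    if suffix in (".tsv", ".csv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer panel format from {path.name!r}")


def read_panel(path: str | Path, format: Optional[str] = None) -> AsoPanel:
    """Read an ASO panel from FASTA (annotated gapmer strings as sequence
    lines) or TSV/CSV (columns: id, sequence, optional calcium_score and
    tolerability_score)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            logger.warning("empty panel file: %s", path)
        asos = [parse_gapmer(str(r.seq), id=r.id) for r in records]
        return AsoPanel(asos)
    if fmt in ("tsv", "csv"):
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype={"id": str})
        for col in ("id", "sequence"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        if df.empty:
            logger.warning("empty panel file: %s", path)
        asos = [
            parse_gapmer(seq, id=str(i))
            for i, seq in zip(df["id"], df["sequence"])
        ]
        ann_cols = [c for c in df.columns if c not in ("id", "sequence")]
        annotations = df.set_index("id")[ann_cols] if ann_cols else None
        return AsoPanel(asos, annotations)
    raise ValueError(f"unknown panel format {fmt!r}")


def write_panel(
    panel: AsoPanel, path: str | Path, format: Optional[str] = None
) -> None:
    """Write a panel as FASTA or TSV/CSV; output round-trips through
    :func:`read_panel`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(a.annotated), id=a.id, description="")
            for a in panel
        ]
        SeqIO.write(records, str(path), "fasta")
        return
    if fmt in ("tsv", "csv"):
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        panel.to_dataframe().to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown panel format {fmt!r}")
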