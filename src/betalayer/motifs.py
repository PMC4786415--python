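"""Sequence-level scanning for β-layer consensus motifs.

β-layers that recur in families of trimeric coiled-coil proteins leave a
recognizable sequence signature.  The core six-residue consensus is
[aliphatic]-A-T-K-[polar]-[DE]: an aliphatic residue in the heptad *a*
position, the A-T-(K) spanning the three strand residues, and acidic
capping.  Tandem β-layer pairs in a hexad spacing follow the 15-residue
consensus L-x-x-K-A-D-K-x-x-V-Y-T-K-x-E.

The residue classes used for the degenerate positions are a documented,
configurable choice: the aliphatic set {A,V,L,I,M} and a broad polar set
{S,T,N,Q,D,E,K,R,H,Y} that admits the known family instances (e.g. the
MATKDD repeat, with M aliphatic and D polar).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

ALIPHATIC = "AVLIM"
POLAR = "STNQDEKRHY"

PatternName = Literal["core_consensus", "tandem"]

_PATTERNS: dict[str, str] = {
    "core_consensus": f"[{ALIPHATIC}]ATK[{POLAR}][DE]",
    "tandem": "L..KADK..VYTK.E",
}


@dataclass(frozen=True)
class MotifMatch:
    """A motif occurrence; ``start`` is 1-based and inclusive."""

    sequence_id: str
    start: int
    matched_text: str
    pattern_name: str

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + len(self.matched_text) - 1


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"invalid amino-acid character {ch!r} at position {pos}"
            )
    return seq


def _scan(sequence: str, pattern_name: str, sequence_id: str) -> list[MotifMatch]:
    seq = _validate(sequence)
    pattern = _PATTERNS[pattern_name]
    # Lookahead so overlapping occurrences are all reported.
    rx = re.compile(f"(?=({pattern}))")
    return [
        MotifMatch(sequence_id, m.start() + 1, m.group(1), pattern_name)
        for m in rx.finditer(seq)
    ]


def scan_consensus(sequence: str, sequence_id: str = "") -> list[MotifMatch]:
    """All matches of the core β-layer consensus [aliphatic]-A-T-K-[polar]-[DE].

    >>> [m.start for m in scan_consensus("XXMATKDDXX".replace("X", "G"))]
    [3]
    """
    return _scan(sequence, "core_consensus", sequence_id)


def scan_tandem(sequence: str, sequence_id: str = "") -> list[MotifMatch]:
    """All matches of the tandem hexad β-layer consensus LxxKADKxxVYTKxE."""
    return _scan(sequence, "tandem", sequence_id)


def scan_fasta(
    path: str | Path, pattern: PatternName = "core_consensus"
) -> pd.DataFrame:
    """Scan every record of a FASTA file for a named motif pattern.

    Returns a table with one row per match: ``record_id``, ``start``,
    ``end`` (1-based inclusive), ``matched_text``, ``pattern``.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; use one of {sorted(_PATTERNS)}")
    rows: list[dict] = []
    for index, record in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(record.seq)
        try:
            matches = _scan(seq, pattern, record.id)
        except ValueError as exc:
            raise ValueError(f"record {index} ({record.id!r}): {exc}") from exc
        rows.extend(
            {
                "record_id": m.sequence_id,
                "start": m.start,
                "end": m.end,
                "matched_text": m.matched_text,
                "pattern": m.pattern_name,
            }
            for m in matches
        )
    return pd.DataFrame(
        rows, columns=["record_id", "start", "end", "matched_text", "pattern"]
    )


def matches_to_table(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    """Convert matches to the TSV-ready table layout used by the CLI."""
    return pd.DataFrame(
        [
            {
                "record_id": m.sequence_id,
                "start": m.start,
                "end": m.end,
                "matched_text": m.matched_text,
                "pattern": m.pattern_name,
            }
            for m in matches
        ],
        columns=["record_id", "start", "end", "matched_text", "pattern"],
    )
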