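"""Ingest per-residue functional-likelihood rankings and cut out the
predicted site as the top fraction of ranked residues.

Rankings arrive as a tab-separated file with header columns
``structure_id  chain  res_seq  icode  resname1  rank[  score]``.
Ranks must form a permutation of 1..N.  The rank column is authoritative;
the optional score column is carried through but never used for ordering.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

from .exceptions import FormatError, InputError
from .salsa_core import AMINO_ACIDS
from .structure_io import ProteinStructure, ResidueKey

__all__ = [
    "RankingEntry",
    "ResidueRanking",
    "PredictedSite",
    "read_rankings",
    "write_rankings",
    "select_top_fraction",
]


@dataclass(frozen=True)
class RankingEntry:
    key: ResidueKey
    code1: str
    rank: int
    score: float | None = None


@dataclass
class ResidueRanking:
    structure_id: str
    entries: list[RankingEntry]  # sorted by rank, ranks a permutation of 1..N

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.rank)
        ranks = [e.rank for e in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise FormatError(
                f"ranks for {self.structure_id!r} are not a permutation of 1..{len(ranks)}"
            )
        for e in self.entries:
            if e.code1 not in AMINO_ACIDS and e.code1 != "X":
                raise FormatError(f"unknown amino-acid letter {e.code1!r} at rank {e.rank}")

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, structure: ProteinStructure) -> None:
        """Check every ranked residue exists in its companion structure."""
        for e in self.entries:
            if structure.residue(e.key) is None:
                raise FormatError(
                    f"ranked residue {e.key} absent from structure {structure.structure_id!r}"
                )


@dataclass
class PredictedSite:
    """Residues inside the top-fraction cut of a ranking."""

    structure_id: str
    cutoff_fraction: float
    ordered_members: list[ResidueKey]  # in rank order

    @property
    def members(self) -> frozenset[ResidueKey]:
        return frozenset(self.ordered_members)

    def __len__(self) -> int:
        return len(self.ordered_members)


_HEADER = ["structure_id", "chain", "res_seq", "icode", "resname1", "rank"]


def read_rankings(path: str | os.PathLike) -> ResidueRanking:
    """Parse a rankings TSV into a validated :class:`ResidueRanking`."""
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty rankings file")
    header = lines[0].split("\t")
    if header[: len(_HEADER)] != _HEADER:
        raise FormatError(f"{path}: bad header {header!r}, expected {_HEADER}[, score]")
    has_score = len(header) > len(_HEADER) and header[len(_HEADER)] == "score"
    entries: list[RankingEntry] = []
    structure_id: str | None = None
    seen_ranks: set[int] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) < len(_HEADER):
            raise FormatError(f"{path}:{lineno}: expected at least {len(_HEADER)} columns")
        sid, chain, res_seq, icode, code1, rank = parts[: len(_HEADER)]
        if structure_id is None:
            structure_id = sid
        elif sid != structure_id:
            raise FormatError(f"{path}:{lineno}: mixed structure ids {structure_id!r}/{sid!r}")
        try:
            rank_i = int(rank)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer rank {rank!r}") from None
        if rank_i in seen_ranks:
            raise FormatError(f"{path}:{lineno}: duplicate rank {rank_i}")
        seen_ranks.add(rank_i)
        score = None
        if has_score and len(parts) > len(_HEADER) and parts[len(_HEADER)] != "":
            score = float(parts[len(_HEADER)])
        entries.append(
            RankingEntry(
                key=ResidueKey(chain, int(res_seq), icode if icode != "." else ""),
                code1=code1.upper(),
                rank=rank_i,
                score=score,
            )
        )
    if structure_id is None:
        raise FormatError(f"{path}: no ranking rows")
    return ResidueRanking(structure_id=structure_id, entries=entries)


def write_rankings(ranking: ResidueRanking, path: str | os.PathLike) -> None:
    has_score = any(e.score is not None for e in ranking.entries)
    header = _HEADER + (["score"] if has_score else [])
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for e in ranking.entries:
            row = [
                ranking.structure_id,
                e.key.chain_id,
                str(e.key.res_seq),
                e.key.icode,
                e.code1,
                str(e.rank),
            ]
            if has_score:
                row.append("" if e.score is None else repr(e.score))
            fh.write("\t".join(row) + "\n")


def select_top_fraction(ranking: ResidueRanking, fraction: float) -> PredictedSite:
    """Top ``ceil(fraction * N)`` residues by rank.

    Ceiling keeps any nonzero fraction from producing an empty site.
    """
    if not (0.0 < fraction <= 1.0):
        raise InputError(f"fraction must lie in (0, 1], got {fraction}")
    count = math.ceil(fraction * len(ranking))
    members = [e.key for e in ranking.entries[:count]]
    return PredictedSite(
        structure_id=ranking.structure_id,
        cutoff_fraction=fraction,
        ordered_members=members,
    )
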