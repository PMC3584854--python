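"""Site-match tables, consensus signatures, and BLOSUM62 scoring.

A site table has one row per structure and one column per spatial
position.  Each cell is either a residue (one-letter code, author number,
insertion code, and a flag saying whether the residue fell inside the
top-fraction prediction cut) or a gap.  Predicted residues are rendered
uppercase in the TSV serialization, unpredicted residues lowercase, and
gaps as ``-`` — the typography used throughout this package's reports.

Scoring convention
------------------
When a row (or a derived consensus) is used as a comparison target, a
residue contributes its actual amino-acid code if it was predicted and
``X`` otherwise; a gap in the query row contributes a fixed penalty
(default ``-3``).  The maximum (perfect-match) score of a signature is the
BLOSUM62 diagonal sum over the *actual* codes, regardless of predicted
status.  Percentages are raw/max rounded to the nearest integer, ties away
from zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .exceptions import InputError, IntegrityError

if TYPE_CHECKING:  # pragma: no cover
    from .local_alignment import PositionMap
    from .site_prediction import PredictedSite
    from .structure_io import ProteinStructure

__all__ = [
    "AMINO_ACIDS",
    "SalsaCell",
    "SalsaTable",
    "ConsensusPosition",
    "ConsensusSignature",
    "MatchScore",
    "ClassificationEntry",
    "ClassificationReport",
    "blosum62",
    "build_salsa_table",
    "derive_consensus",
    "signature_from_row",
    "score_match",
    "max_score",
    "classify_match",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Half-bit BLOSUM62 with the conventional X row/column, transcribed from the
# standard NCBI distribution.  Kept as text so the transcription can be
# diffed entrywise against an independent copy in the test suite.
_BLOSUM62_TEXT = """\
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  X
A  4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0  0
R -1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3 -1
N -2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3 -1
D -2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3 -1
C  0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1 -2
Q -1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2 -1
E -1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2 -1
G  0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3 -1
H -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3 -1
I -1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3 -1
L -1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1 -1
K -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2 -1
M -1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1 -1
F -2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1 -1
P -1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2 -2
S  1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2  0
T  0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0  0
W -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3 -2
Y -2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1 -1
V  0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4 -1
X  0 -1 -1 -1 -2 -1 -1 -1 -1 -1 -1 -1 -1 -1 -2  0  0 -2 -1 -1 -1
"""


def _parse_matrix(text: str) -> dict[tuple[str, str], int]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    table: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        row = parts[0]
        for col, value in zip(header, parts[1:]):
            table[(row, col)] = int(value)
    return table


_BLOSUM62 = _parse_matrix(_BLOSUM62_TEXT)


def blosum62(a: str, b: str) -> int:
    """Return the BLOSUM62 substitution score for one-letter codes *a*, *b*.

    The 20 standard amino acids plus ``X`` are accepted (case-insensitive).
    """
    key = (a.upper(), b.upper())
    try:
        return _BLOSUM62[key]
    except KeyError:
        raise InputError(f"unknown amino-acid code in pair {a!r}, {b!r}") from None


def round_half_away(x: float) -> int:
    """Nearest-integer rounding with ties away from zero (81.25 -> 81, -5.15 -> -5, 21.6 -> 22)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


_CELL_RE = re.compile(r"^([A-Za-z])(-?\d+)([A-Za-z']?)$")


@dataclass(frozen=True)
class SalsaCell:
    """One table cell: a residue with a predicted flag, or a gap."""

    code1: str = ""
    res_seq: int = 0
    icode: str = ""
    predicted: bool = False
    is_gap: bool = False

    @classmethod
    def gap(cls) -> "SalsaCell":
        return cls(is_gap=True)

    @classmethod
    def residue(cls, code1: str, res_seq: int, icode: str = "", predicted: bool = True) -> "SalsaCell":
        code = code1.upper()
        if len(code) != 1 or (code not in AMINO_ACIDS and code != "X"):
            raise InputError(f"invalid one-letter code {code1!r}")
        return cls(code1=code, res_seq=res_seq, icode=icode, predicted=predicted)

    def __str__(self) -> str:
        if self.is_gap:
            return "-"
        code = self.code1 if self.predicted else self.code1.lower()
        return f"{code}{self.res_seq}{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "SalsaCell":
        text = text.strip()
        if text in ("-", ""):
            return cls.gap()
        m = _CELL_RE.match(text)
        if m is None:
            raise InputError(f"unparseable cell {text!r}")
        code, num, icode = m.groups()
        return cls.residue(code, int(num), icode, predicted=code.isupper())


@dataclass
class SalsaTable:
    """Rows = structures, columns = spatial positions, cells = residue/gap."""

    structure_order: list[str]
    position_order: list[str]
    cells: dict[tuple[str, str], SalsaCell]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.structure_order:
            for pid in self.position_order:
                if (sid, pid) not in self.cells:
                    raise IntegrityError(f"missing cell for ({sid}, {pid})")

    def cell(self, structure_id: str, position_id: str) -> SalsaCell:
        try:
            return self.cells[(structure_id, position_id)]
        except KeyError:
            raise InputError(
                f"no cell for structure {structure_id!r}, position {position_id!r}"
            ) from None

    def row(self, structure_id: str, positions: Sequence[str] | None = None) -> list[SalsaCell]:
        if structure_id not in self.structure_order:
            raise InputError(f"unknown structure id {structure_id!r}")
        pids = self.position_order if positions is None else positions
        return [self.cell(structure_id, p) for p in pids]

    def to_tsv(self) -> str:
        lines = ["structure\t" + "\t".join(self.position_order)]
        if self.annotations:
            lines.append(
                "#annotation\t"
                + "\t".join(self.annotations.get(p, "") for p in self.position_order)
            )
        for sid in self.structure_order:
            lines.append(sid + "\t" + "\t".join(str(self.cell(sid, p)) for p in self.position_order))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "SalsaTable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise InputError("empty table")
        header = lines[0].rstrip("\n").split("\t")
        if header[0] != "structure":
            raise InputError("first header column must be 'structure'")
        positions = header[1:]
        annotations: dict[str, str] = {}
        structure_order: list[str] = []
        cells: dict[tuple[str, str], SalsaCell] = {}
        for line in lines[1:]:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#annotation":
                annotations = {p: a for p, a in zip(positions, parts[1:]) if a}
                continue
            sid = parts[0]
            if len(parts) - 1 != len(positions):
                raise InputError(f"row {sid!r} has {len(parts) - 1} cells, expected {len(positions)}")
            structure_order.append(sid)
            for pid, cell_text in zip(positions, parts[1:]):
                cells[(sid, pid)] = SalsaCell.parse(cell_text)
        return cls(structure_order, positions, cells, annotations)


@dataclass(frozen=True)
class ConsensusPosition:
    position_id: str
    code1: str
    support: int
    reference_count: int
    predicted: bool = True


@dataclass
class ConsensusSignature:
    """Per-position consensus amino-acid types with their support counts."""

    positions: list[ConsensusPosition]
    majority_threshold: float = 0.5

    def codes(self) -> str:
        return "".join(p.code1 for p in self.positions)

    def position_ids(self) -> list[str]:
        return [p.position_id for p in self.positions]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MatchScore:
    raw: int
    max: int
    percent: int
    per_position: list[tuple[str, str, str, int]]  # (position, query cell, consensus code, contribution)

    def to_dict(self) -> dict:
        return {
            "raw": self.raw,
            "max": self.max,
            "percent": self.percent,
            "per_position": [
                {"position": p, "query": q, "consensus": c, "contribution": s}
                for p, q, c, s in self.per_position
            ],
        }


def build_salsa_table(
    position_map: "PositionMap",
    sites: Iterable["PredictedSite"],
    structures: Iterable["ProteinStructure"],
) -> SalsaTable:
    """Fill a table from a spatial position map, marking predicted residues.

    Cells come from looking each mapped residue key up in its structure; a
    structure absent from a position yields a gap cell.
    """
    structs = {s.structure_id: s for s in structures}
    site_members = {s.structure_id: s.members for s in sites}
    structure_order = [sid for sid in position_map.structure_order if sid in structs]
    position_ids = [str(i + 1) for i in range(len(position_map.positions))]
    cells: dict[tuple[str, str], SalsaCell] = {}
    for pid, mapping in zip(position_ids, position_map.positions):
        for sid in structure_order:
            key = mapping.get(sid)
            if key is None:
                cells[(sid, pid)] = SalsaCell.gap()
                continue
            residue = structs[sid].residue(key)
            if residue is None:
                raise IntegrityError(f"position {pid} references unknown residue {key} in {sid}")
            predicted = key in site_members.get(sid, frozenset())
            cells[(sid, pid)] = SalsaCell.residue(
                residue.code1, residue.res_seq, residue.icode, predicted=predicted
            )
    return SalsaTable(structure_order, position_ids, cells)


def derive_consensus(
    table: SalsaTable,
    reference_rows: Sequence[str],
    majority_threshold: float = 0.5,
) -> ConsensusSignature:
    """Majority-rule consensus over the predicted residues of the reference rows.

    A position is retained iff more than ``majority_threshold`` of the
    reference rows carry a *predicted* residue of the modal amino-acid type
    (exact identity).  Modal ties drop the position.
    """
    if not reference_rows:
        raise InputError("reference_rows must be non-empty")
    if not (0.5 <= majority_threshold < 1.0):
        raise InputError("majority_threshold must lie in [0.5, 1)")
    for sid in reference_rows:
        if sid not in table.structure_order:
            raise InputError(f"reference row {sid!r} not in table")
    n_ref = len(reference_rows)
    retained: list[ConsensusPosition] = []
    for pid in table.position_order:
        counts: dict[str, int] = {}
        for sid in reference_rows:
            cell = table.cell(sid, pid)
            if not cell.is_gap and cell.predicted:
                counts[cell.code1] = counts.get(cell.code1, 0) + 1
        if not counts:
            continue
        best = max(counts.values())
        modal = [c for c, n in counts.items() if n == best]
        if len(modal) != 1:
            continue  # ambiguous column: drop rather than guess
        if best / n_ref > majority_threshold:
            retained.append(ConsensusPosition(pid, modal[0], best, n_ref))
    return ConsensusSignature(retained, majority_threshold)


def signature_from_row(table: SalsaTable, structure_id: str) -> ConsensusSignature:
    """Use a single table row as a comparison target.

    Unpredicted (lowercase) residues are kept: they count toward the
    perfect-match maximum with their actual code but are scored as ``X``
    when the row is used as a target.  Gap cells contribute no position.
    """
    positions = [
        ConsensusPosition(pid, cell.code1, int(cell.predicted), 1, predicted=cell.predicted)
        for pid in table.position_order
        for cell in (table.cell(structure_id, pid),)
        if not cell.is_gap
    ]
    return ConsensusSignature(positions)


def max_score(signature: ConsensusSignature) -> int:
    """Perfect-match score: BLOSUM62 diagonal sum over actual codes."""
    if not signature.positions:
        raise InputError("empty signature")
    return sum(blosum62(p.code1, p.code1) for p in signature.positions)


def score_match(
    query_row: Sequence[SalsaCell],
    signature: ConsensusSignature,
    gap_penalty: int = -3,
) -> MatchScore:
    """Score a query row against a signature, position by position.

    Residue cells score ``blosum62(target', query')`` where a residue's
    effective code is its actual code if predicted and ``X`` otherwise;
    gap cells contribute ``gap_penalty``.
    """
    if len(query_row) != len(signature.positions):
        raise InputError(
            f"query row has {len(query_row)} cells but signature has {len(signature.positions)} positions"
        )
    raw = 0
    per_position: list[tuple[str, str, str, int]] = []
    for cell, cons in zip(query_row, signature.positions):
        cons_code = cons.code1 if cons.predicted else "X"
        cons_label = cons.code1 if cons.predicted else cons.code1.lower()
        if cell.is_gap:
            contribution = gap_penalty
        else:
            query_code = cell.code1 if cell.predicted else "X"
            contribution = blosum62(cons_code, query_code)
        raw += contribution
        per_position.append((cons.position_id, str(cell), cons_label, contribution))
    maximum = max_score(signature)
    if maximum == 0:
        raise InputError("signature maximum is zero; percent undefined")
    percent = round_half_away(100.0 * raw / maximum)
    return MatchScore(raw=raw, max=maximum, percent=percent, per_position=per_position)


@dataclass
class ClassificationEntry:
    label: str
    score: MatchScore
    incompatible: bool


@dataclass
class ClassificationReport:
    ranked: list[ClassificationEntry]
    best: list[str]  # >1 label on a percent tie
    tie: bool

    def to_dict(self) -> dict:
        return {
            "ranked": [
                {"label": e.label, "percent": e.score.percent, "raw": e.score.raw,
                 "max": e.score.max, "incompatible": e.incompatible}
                for e in self.ranked
            ],
            "best": self.best,
            "tie": self.tie,
        }


def classify_match(scores: Mapping[str, MatchScore]) -> ClassificationReport:
    """Rank candidate signature matches by percent, flagging negatives.

    Sorting is stable, so equal percents preserve input order; a tie for
    the top percent is reported explicitly rather than broken.
    """
    if not scores:
        raise InputError("at least one candidate score required")
    ranked = sorted(scores.items(), key=lambda kv: -kv[1].percent)
    entries = [
        ClassificationEntry(label, score, incompatible=score.percent < 0)
        for label, score in ranked
    ]
    top = entries[0].score.percent
    best = [e.label for e in entries if e.score.percent == top]
    return ClassificationReport(entries, best, tie=len(best) > 1)
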