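"""Residue-level structure model, PDB input/output, and sequence identity.

Structures are reduced to one record per residue: identity, author
numbering (preserved verbatim so downstream tables carry labels like
``K105``), the CA coordinate, and a side-chain centroid used as the
residue's representative point for spatial matching.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .exceptions import EmptyStructureError, FormatError, InputError
from .salsa_core import blosum62

__all__ = [
    "ResidueKey",
    "ResidueRecord",
    "ProteinStructure",
    "read_pdb",
    "write_pdb",
    "pairwise_identity",
    "global_align",
]

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine, read as methionine
}

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}
_ONE_TO_THREE["X"] = "UNK"


class ResidueKey(NamedTuple):
    """Stable identifier of a residue within one structure."""

    chain_id: str
    res_seq: int
    icode: str


@dataclass(frozen=True)
class ResidueRecord:
    chain_id: str
    res_seq: int
    icode: str
    name3: str
    code1: str
    ca_coord: np.ndarray
    sidechain_centroid: np.ndarray

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.res_seq, self.icode)

    @property
    def label(self) -> str:
        return f"{self.code1}{self.res_seq}{self.icode}"


@dataclass
class ProteinStructure:
    """Ordered residues grouped by chain, with O(1) lookup by key."""

    structure_id: str
    residues: list[ResidueRecord]
    _index: dict[ResidueKey, ResidueRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyStructureError(f"structure {self.structure_id!r} has no residues")
        self._index = {}
        for r in self.residues:
            if r.key in self._index:
                raise FormatError(f"duplicate residue {r.key} in {self.structure_id!r}")
            self._index[r.key] = r

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: ResidueKey) -> ResidueRecord | None:
        return self._index.get(ResidueKey(*key))

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def sequence(self) -> str:
        return "".join(r.code1 for r in self.residues)

    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def ca_coords(self, keys: Sequence[ResidueKey] | None = None) -> np.ndarray:
        records = self.residues if keys is None else [self._index[ResidueKey(*k)] for k in keys]
        return np.array([r.ca_coord for r in records], dtype=float)

    def centroids(self, keys: Sequence[ResidueKey] | None = None) -> np.ndarray:
        records = self.residues if keys is None else [self._index[ResidueKey(*k)] for k in keys]
        return np.array([r.sidechain_centroid for r in records], dtype=float)


def read_pdb(path: str | os.PathLike, chain_filter: set[str] | None = None) -> ProteinStructure:
    """Read a PDB file into a residue-level model.

    Only the first MODEL is used; alternate locations are resolved to the
    highest-occupancy conformer (first encountered on ties); HETATM records
    are skipped except MSE, which is read as methionine.  Residues without a
    CA atom are excluded.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_structure = parser.get_structure("s", os.fspath(path))
    except Exception as exc:  # Bio.PDB raises bare exceptions on corrupt files
        raise InputError(f"unreadable PDB file {path}: {exc}") from exc
    try:
        model = next(bio_structure.get_models())
    except StopIteration:
        raise EmptyStructureError(f"{path}: no models") from None

    records: list[ResidueRecord] = []
    for chain in model:
        if chain_filter is not None and chain.id not in chain_filter:
            continue
        for residue in chain:
            hetflag, res_seq, icode = residue.id
            if hetflag not in (" ", "H_MSE"):
                continue
            name3 = residue.get_resname().strip()
            code1 = _THREE_TO_ONE.get(name3, "X")
            ca = residue["CA"].get_coord() if "CA" in residue else None
            if ca is None or not np.all(np.isfinite(ca)):
                continue
            sidechain = [
                atom.get_coord()
                for atom in residue.get_atoms()
                if atom.get_id() not in _BACKBONE_ATOMS and atom.element != "H"
            ]
            centroid = np.mean(sidechain, axis=0) if sidechain and code1 != "G" else np.asarray(ca)
            records.append(
                ResidueRecord(
                    chain_id=chain.id,
                    res_seq=res_seq,
                    icode=icode.strip(),
                    name3=name3,
                    code1=code1,
                    ca_coord=np.asarray(ca, dtype=float),
                    sidechain_centroid=np.asarray(centroid, dtype=float),
                )
            )
    if not records:
        raise EmptyStructureError(f"{path}: no usable residues (ATOM with CA)")
    structure_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return ProteinStructure(structure_id=structure_id, residues=records)


def write_pdb(structure: ProteinStructure, path: str | os.PathLike) -> None:
    """Write a minimal PDB file: CA per residue, plus CB when the side-chain
    centroid differs from CA."""
    lines: list[str] = []
    serial = 1

    def atom_line(name: str, r: ResidueRecord, xyz: np.ndarray, n: int) -> str:
        name_field = f" {name:<3s}"
        return (
            f"ATOM  {n:5d} {name_field}{'':1s}{r.name3:>3s} {r.chain_id:1s}"
            f"{r.res_seq:4d}{r.icode or ' ':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {name[0]:>2s}"
        )

    for r in structure.residues:
        lines.append(atom_line("CA", r, r.ca_coord, serial))
        serial += 1
        if not np.allclose(r.sidechain_centroid, r.ca_coord):
            lines.append(atom_line("CB", r, r.sidechain_centroid, serial))
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Global alignment (Needleman-Wunsch / Gotoh, affine gaps)
# ---------------------------------------------------------------------------

GAP_OPEN = -11  # cost of the first residue of a gap run
GAP_EXTEND = -1  # cost of each further residue

_NEG = (-(10 ** 9), 0, 0)


def global_align(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Optimal global alignment of two sequences under BLOSUM62 with affine
    gaps (open -11 applied to the first gap residue, extend -1 thereafter).

    Among score-optimal alignments the one maximizing (identities, aligned
    pairs) lexicographically is chosen, which makes the reported identity
    deterministic.  Returns aligned (index_a, index_b) pairs.
    """
    if not seq_a or not seq_b:
        raise InputError("sequences must be non-empty")
    m, n = len(seq_a), len(seq_b)
    # DP over lexicographic value tuples (score, identities, pairs); tuple
    # order is preserved under componentwise addition, so plain max is exact.
    M = [[_NEG] * (n + 1) for _ in range(m + 1)]
    X = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in seq_b (consumes a)
    Y = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in seq_a (consumes b)
    M[0][0] = (0, 0, 0)
    for i in range(1, m + 1):
        X[i][0] = (GAP_OPEN + (i - 1) * GAP_EXTEND, 0, 0)
    for j in range(1, n + 1):
        Y[0][j] = (GAP_OPEN + (j - 1) * GAP_EXTEND, 0, 0)
    for i in range(1, m + 1):
        ai = seq_a[i - 1]
        for j in range(1, n + 1):
            bj = seq_b[j - 1]
            step = (blosum62(ai, bj), int(ai == bj), 1)
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (prev[0] + step[0], prev[1] + step[1], prev[2] + step[2])
            xo = max(M[i - 1][j], Y[i - 1][j])
            X[i][j] = max(
                (xo[0] + GAP_OPEN, xo[1], xo[2]),
                (X[i - 1][j][0] + GAP_EXTEND, X[i - 1][j][1], X[i - 1][j][2]),
            )
            yo = max(M[i][j - 1], X[i][j - 1])
            Y[i][j] = max(
                (yo[0] + GAP_OPEN, yo[1], yo[2]),
                (Y[i][j - 1][0] + GAP_EXTEND, Y[i][j - 1][1], Y[i][j - 1][2]),
            )
    # Traceback; preference M > X > Y keeps the result deterministic.
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    state = "M"
    best = max(M[m][n], X[m][n], Y[m][n])
    for s, tab in (("M", M), ("X", X), ("Y", Y)):
        if tab[m][n] == best:
            state = s
            break
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            step = (blosum62(seq_a[i - 1], seq_b[j - 1]), int(seq_a[i - 1] == seq_b[j - 1]), 1)
            target = (M[i][j][0] - step[0], M[i][j][1] - step[1], M[i][j][2] - step[2])
            i, j = i - 1, j - 1
            for s, tab in (("M", M), ("X", X), ("Y", Y)):
                if tab[i][j] == target:
                    state = s
                    break
        elif state == "X":
            val = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            found = False
            for s, tab in (("M", M), ("Y", Y)):
                if (tab[i][j][0] + GAP_OPEN, tab[i][j][1], tab[i][j][2]) == val:
                    state = s
                    found = True
                    break
            if not found:
                state = "X"
        else:
            val = Y[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            found = False
            for s, tab in (("M", M), ("X", X)):
                if (tab[i][j][0] + GAP_OPEN, tab[i][j][1], tab[i][j][2]) == val:
                    state = s
                    found = True
                    break
            if not found:
                state = "Y"
    pairs.reverse()
    return pairs


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned pairs over the full alignment length.

    Alignment length counts gap columns: len_a + len_b - aligned_pairs.
    """
    pairs = global_align(seq_a, seq_b)
    identities = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    alignment_length = len(seq_a) + len(seq_b) - len(pairs)
    return identities / alignment_length


def one_to_three(code1: str) -> str:
    """One-letter to three-letter residue name (X -> UNK)."""
    try:
        return _ONE_TO_THREE[code1.upper()]
    except KeyError:
        raise InputError(f"unknown one-letter code {code1!r}") from None
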