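"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment by
exhaustive enumeration, superposition by rotation-grid search with
derivative-free refinement, and MSA positions by a direct column scan.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

GAP_OPEN, GAP_EXTEND = -11, -1


def enumerate_best_alignment(seq_a: str, seq_b: str, score_fn) -> tuple[int, int, int, float]:
    """Exhaustively enumerate every global alignment and return the
    lexicographic (score, identities, pairs) maximum plus the identity
    fraction identities / (len_a + len_b - pairs).

    Affine gap runs cost GAP_OPEN for the first residue, GAP_EXTEND after.
    Only feasible for short sequences.
    """
    best: tuple[int, int, int] | None = None
    stack = [(0, 0, 0, 0, 0, "")]  # i, j, score, identities, pairs, previous op
    while stack:
        i, j, score, ident, pairs, prev = stack.pop()
        if i == len(seq_a) and j == len(seq_b):
            value = (score, ident, pairs)
            if best is None or value > best:
                best = value
            continue
        if i < len(seq_a) and j < len(seq_b):
            stack.append((
                i + 1, j + 1,
                score + score_fn(seq_a[i], seq_b[j]),
                ident + int(seq_a[i] == seq_b[j]),
                pairs + 1, "M",
            ))
        if i < len(seq_a):
            stack.append((i + 1, j,
                          score + (GAP_EXTEND if prev == "X" else GAP_OPEN),
                          ident, pairs, "X"))
        if j < len(seq_b):
            stack.append((i, j + 1,
                          score + (GAP_EXTEND if prev == "Y" else GAP_OPEN),
                          ident, pairs, "Y"))
    assert best is not None
    score, ident, pairs = best
    return score, ident, pairs, ident / (len(seq_a) + len(seq_b) - pairs)


def _rmsd_for_rotation(rotvec: np.ndarray, P: np.ndarray, Q: np.ndarray) -> float:
    R = Rotation.from_rotvec(rotvec).as_matrix()
    d = P @ R.T - Q
    return float(np.sqrt((d ** 2).sum() / len(P)))


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray, n_grid: int = 14) -> float:
    """Minimum rmsd over rigid motions found by a coarse rotation grid plus
    local derivative-free refinement (translation handled by centering)."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    best_vec, best_val = np.zeros(3), _rmsd_for_rotation(np.zeros(3), P, Q)
    lin = np.linspace(-np.pi, np.pi, n_grid)
    for a in lin:
        for b in lin:
            for c in lin:
                vec = np.array([a, b, c])
                if np.linalg.norm(vec) > np.pi:
                    continue
                val = _rmsd_for_rotation(vec, P, Q)
                if val < best_val:
                    best_vec, best_val = vec, val
    result = minimize(
        _rmsd_for_rotation, best_vec, args=(P, Q),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
    )
    return float(min(best_val, result.fun))


def msa_column_positions(rows: list[tuple[str, str]], predicted: dict[str, set[int]]):
    """Column scan of an aligned set of (structure_id, aligned_seq) rows.

    ``predicted`` holds ungapped residue indices per structure.  Returns,
    per retained column, {structure_id: ungapped_index}.
    """
    n_cols = len(rows[0][1])
    counters = {sid: -1 for sid, _ in rows}
    positions = []
    for col in range(n_cols):
        mapping = {}
        hit = False
        for sid, seq in rows:
            if seq[col] == "-":
                continue
            counters[sid] += 1
            mapping[sid] = counters[sid]
            if counters[sid] in predicted.get(sid, set()):
                hit = True
        if mapping and hit:
            positions.append(mapping)
    return positions
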