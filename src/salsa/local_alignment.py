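"""Rigid-body superposition and spatial correspondence of predicted sites.

A family is aligned in a star topology: every structure is superposed onto
one reference via sequence-seeded iterative Kabsch fitting.  Predicted-site
residues are then clustered into spatial positions — the columns of the
downstream site table — by nearest-centroid assignment within a distance
threshold.  An externally produced multiple alignment can replace the
built-in correspondence entirely.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import AlignmentError, InputError
from .site_prediction import PredictedSite
from .structure_io import ProteinStructure, ResidueKey, global_align

__all__ = [
    "Superposition",
    "PositionMap",
    "kabsch_superpose",
    "seed_correspondence",
    "iterative_superpose",
    "map_site_positions",
    "import_msa_positions",
]

DEFAULT_TRIM_DISTANCE = 6.0
DEFAULT_POSITION_THRESHOLD = 4.0


@dataclass
class Superposition:
    """Least-squares rigid transform mapping mobile coordinates onto a reference."""

    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector
    rmsd: float
    pairs: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)  # (mobile, reference)
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0)


def kabsch_superpose(mobile_coords: np.ndarray, reference_coords: np.ndarray) -> Superposition:
    """Optimal proper rotation + translation of *mobile* onto *reference*.

    Standard SVD solution; a reflection in the raw SVD is corrected by
    flipping the smallest singular direction, so the rotation determinant is
    always +1.  Near-collinear point sets are flagged ``degenerate`` (the
    rotation about the common axis is then arbitrary) but still returned.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InputError(f"coordinate shapes differ or are not Nx3: {mob.shape} vs {ref.shape}")
    if mob.shape[0] < 3:
        raise InputError("at least 3 point pairs required")
    if not (np.all(np.isfinite(mob)) and np.all(np.isfinite(ref))):
        raise InputError("coordinates must be finite")
    mob_center = mob.mean(axis=0)
    ref_center = ref.mean(axis=0)
    P = mob - mob_center
    Q = ref - ref_center
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    translation = ref_center - R @ mob_center
    deviations = P @ R.T - Q
    rmsd = float(np.sqrt((deviations ** 2).sum() / mob.shape[0]))
    # collinearity: second singular value of either centered cloud ~ 0
    sv_mob = np.linalg.svd(P, compute_uv=False)
    sv_ref = np.linalg.svd(Q, compute_uv=False)
    scale = max(sv_mob[0], sv_ref[0], 1.0)
    degenerate = bool(sv_mob[1] < 1e-8 * scale or sv_ref[1] < 1e-8 * scale)
    return Superposition(rotation=R, translation=translation, rmsd=rmsd, degenerate=degenerate)


def seed_correspondence(a: ProteinStructure, b: ProteinStructure) -> list[tuple[ResidueKey, ResidueKey]]:
    """Residue pairing from a global sequence alignment of the two structures."""
    pairs = global_align(a.sequence(), b.sequence())
    keys_a, keys_b = a.keys(), b.keys()
    return [(keys_a[i], keys_b[j]) for i, j in pairs]


def iterative_superpose(
    mobile: ProteinStructure,
    reference: ProteinStructure,
    max_iter: int = 10,
    trim_distance: float = DEFAULT_TRIM_DISTANCE,
) -> Superposition:
    """Sequence-seeded Kabsch fit with iterative trimming of far CA pairs.

    Pairs whose CA-CA distance exceeds ``trim_distance`` after the current
    fit are dropped and the fit repeated until the pair set stabilizes or
    ``max_iter`` rounds have run.  Deterministic for fixed inputs.
    """
    pairs = seed_correspondence(mobile, reference)
    if len(pairs) < 3:
        raise AlignmentError(
            f"only {len(pairs)} seed pairs between {mobile.structure_id!r} and "
            f"{reference.structure_id!r}; need >= 3"
        )
    superposition: Superposition | None = None
    for _ in range(max_iter):
        mob_xyz = mobile.ca_coords([p[0] for p in pairs])
        ref_xyz = reference.ca_coords([p[1] for p in pairs])
        superposition = kabsch_superpose(mob_xyz, ref_xyz)
        superposition.pairs = list(pairs)
        distances = np.linalg.norm(superposition.apply(mob_xyz) - ref_xyz, axis=1)
        kept = [p for p, dist in zip(pairs, distances) if dist <= trim_distance]
        if len(kept) < 3:
            raise AlignmentError(
                f"fewer than 3 pairs survive trimming at {trim_distance} A between "
                f"{mobile.structure_id!r} and {reference.structure_id!r}"
            )
        if kept == pairs:
            break
        pairs = kept
    assert superposition is not None
    return superposition


@dataclass
class PositionMap:
    """Ordered spatial positions, each mapping structure id -> residue key (absent = gap)."""

    reference_id: str
    structure_order: list[str]
    positions: list[dict[str, ResidueKey]]
    threshold: float = DEFAULT_POSITION_THRESHOLD

    def __post_init__(self) -> None:
        seen: set[tuple[str, ResidueKey]] = set()
        for mapping in self.positions:
            for sid, key in mapping.items():
                item = (sid, ResidueKey(*key))
                if item in seen:
                    raise InputError(f"residue {key} of {sid!r} appears in two positions")
                seen.add(item)

    def occupancy(self) -> int:
        return sum(len(m) for m in self.positions)

    def to_tsv(self, structures: Mapping[str, ProteinStructure] | None = None,
               sites: Mapping[str, frozenset] | None = None) -> str:
        lines = ["position\tstructure_id\tchain\tres_seq\ticode\tcode1\tstatus"]
        for idx, mapping in enumerate(self.positions, start=1):
            for sid in self.structure_order:
                key = mapping.get(sid)
                if key is None:
                    lines.append(f"{idx}\t{sid}\t\t\t\t\tgap")
                    continue
                code1 = ""
                if structures is not None and sid in structures:
                    rec = structures[sid].residue(key)
                    code1 = rec.code1 if rec is not None else ""
                status = "predicted"
                if sites is not None and key not in sites.get(sid, frozenset()):
                    status = "unpredicted"
                lines.append(
                    f"{idx}\t{sid}\t{key.chain_id}\t{key.res_seq}\t{key.icode}\t{code1}\t{status}"
                )
        return "\n".join(lines) + "\n"


def _ordered_site_keys(structure: ProteinStructure, site: PredictedSite,
                       extras: Sequence[ResidueKey] = ()) -> list[ResidueKey]:
    """Site members (plus extras) in structure residue order."""
    wanted = set(site.members) | {ResidueKey(*k) for k in extras}
    return [k for k in structure.keys() if k in wanted]


def map_site_positions(
    structures: Sequence[ProteinStructure],
    sites: Sequence[PredictedSite],
    superpositions: Mapping[str, Superposition],
    reference_id: str | None = None,
    threshold: float = DEFAULT_POSITION_THRESHOLD,
    extra_residues: Mapping[str, Sequence[ResidueKey]] | None = None,
) -> PositionMap:
    """Cluster predicted-site residues into spatial positions.

    Each predicted residue of the reference (plus any ``extra_residues``,
    which admit literature-reported but unpredicted residues) anchors one
    position.  For every other structure the candidate residues — its own
    predicted set plus extras — are placed by minimum-total-distance
    assignment of side-chain centroids after superposition, accepting only
    pairs within ``threshold``.  Candidates matching no anchor are
    agglomerated greedily (closest first) into additional unanchored
    positions.  Ties are broken toward lower residue numbers.
    """
    struct_by_id = {s.structure_id: s for s in structures}
    site_by_id = {s.structure_id: s for s in sites}
    extras = {sid: list(keys) for sid, keys in (extra_residues or {}).items()}
    if reference_id is None:
        reference_id = structures[0].structure_id
    if reference_id not in struct_by_id:
        raise InputError(f"reference {reference_id!r} not among structures")
    reference = struct_by_id[reference_id]
    structure_order = [s.structure_id for s in structures]

    anchor_keys = _ordered_site_keys(reference, site_by_id[reference_id],
                                     extras.get(reference_id, ()))
    anchor_xyz = reference.centroids(anchor_keys) if anchor_keys else np.zeros((0, 3))

    positions: list[dict[str, ResidueKey]] = [{reference_id: k} for k in anchor_keys]
    leftovers: list[tuple[str, ResidueKey, np.ndarray]] = []

    for structure in structures:
        sid = structure.structure_id
        if sid == reference_id:
            continue
        candidates = _ordered_site_keys(structure, site_by_id[sid], extras.get(sid, ()))
        if not candidates:
            continue
        superposition = superpositions.get(sid, Superposition.identity())
        cand_xyz = superposition.apply(structure.centroids(candidates))
        assigned: set[int] = set()
        if anchor_keys:
            cost = np.linalg.norm(anchor_xyz[:, None, :] - cand_xyz[None, :, :], axis=2)
            # tiny residue-order epsilon makes exact-distance ties deterministic
            cost = cost + np.arange(len(candidates))[None, :] * 1e-9
            big = threshold * 1e6
            masked = np.where(cost <= threshold, cost, big)
            rows, cols = linear_sum_assignment(masked)
            for r, c in zip(rows, cols):
                if cost[r, c] <= threshold:
                    positions[r][sid] = candidates[c]
                    assigned.add(c)
        for idx, key in enumerate(candidates):
            if idx not in assigned:
                leftovers.append((sid, key, cand_xyz[idx]))

    positions.extend(_agglomerate(leftovers, threshold, structure_order))
    return PositionMap(
        reference_id=reference_id,
        structure_order=structure_order,
        positions=positions,
        threshold=threshold,
    )


def _agglomerate(
    leftovers: list[tuple[str, ResidueKey, np.ndarray]],
    threshold: float,
    structure_order: list[str],
) -> list[dict[str, ResidueKey]]:
    """Greedy closest-first clustering of unanchored residues into positions.

    Clusters never take two residues from the same structure; inter-cluster
    distance is the minimum over member pairs (single linkage).
    """
    clusters: list[list[tuple[str, ResidueKey, np.ndarray]]] = [[item] for item in leftovers]
    while len(clusters) > 1:
        best: tuple[float, int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                sids_i = {m[0] for m in clusters[i]}
                sids_j = {m[0] for m in clusters[j]}
                if sids_i & sids_j:
                    continue
                dist = min(
                    float(np.linalg.norm(a[2] - b[2]))
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if dist <= threshold and (best is None or dist < best[0]):
                    best = (dist, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]

    order = {sid: n for n, sid in enumerate(structure_order)}

    def sort_key(cluster: list[tuple[str, ResidueKey, np.ndarray]]) -> tuple:
        first = min(cluster, key=lambda m: (order[m[0]], m[1]))
        return (order[first[0]], first[1])

    clusters.sort(key=sort_key)
    return [{sid: key for sid, key, _ in cluster} for cluster in clusters]


def import_msa_positions(
    msa_path: str | os.PathLike,
    structures: Sequence[ProteinStructure],
    sites: Sequence[PredictedSite],
) -> PositionMap:
    """Derive positions from an externally produced aligned FASTA.

    Every MSA column holding at least one predicted residue becomes a
    position; gap characters become gaps.  Each ungapped MSA sequence must
    equal the corresponding structure's sequence exactly.
    """
    from Bio import AlignIO

    struct_by_id = {s.structure_id: s for s in structures}
    site_by_id = {s.structure_id: s.members for s in sites}
    try:
        alignment = AlignIO.read(os.fspath(msa_path), "fasta")
    except Exception as exc:
        raise InputError(f"unreadable alignment {msa_path}: {exc}") from exc

    rows: list[tuple[str, str]] = []
    for record in alignment:
        sid = record.id
        if sid not in struct_by_id:
            continue
        aligned = str(record.seq).upper()
        structure = struct_by_id[sid]
        ungapped = aligned.replace("-", "")
        native = structure.sequence()
        if ungapped != native:
            for pos, (x, y) in enumerate(zip(ungapped, native)):
                if x != y:
                    key = structure.residues[pos].key
                    raise InputError(
                        f"MSA sequence for {sid!r} diverges from structure at residue "
                        f"{key.chain_id}/{key.res_seq}{key.icode}: {x!r} vs {y!r}"
                    )
            raise InputError(
                f"MSA sequence for {sid!r} has length {len(ungapped)}, structure has {len(native)}"
            )
        rows.append((sid, aligned))
    if not rows:
        raise InputError("no MSA sequence matches any provided structure id")
    n_cols = {len(seq) for _, seq in rows}
    if len(n_cols) != 1:
        raise InputError("aligned sequences have unequal lengths")

    cursors = {sid: 0 for sid, _ in rows}
    positions: list[dict[str, ResidueKey]] = []
    for col in range(n_cols.pop()):
        mapping: dict[str, ResidueKey] = {}
        any_predicted = False
        for sid, seq in rows:
            if seq[col] == "-":
                continue
            key = struct_by_id[sid].residues[cursors[sid]].key
            cursors[sid] += 1
            mapping[sid] = key
            if key in site_by_id.get(sid, frozenset()):
                any_predicted = True
        if mapping and any_predicted:
            positions.append(mapping)
    return PositionMap(
        reference_id=rows[0][0],
        structure_order=[sid for sid, _ in rows],
        positions=positions,
        threshold=float("nan"),
    )
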