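"""Seeded toy families with planted sites, plus packaged worked-example tables.

The generator builds idealized helical-trace structures that share a
planted constellation of site residues at fixed geometry (with optional
Gaussian jitter and identity mutations), together with ranking files in
which the planted residues occupy the top ranks ahead of decoys.  Ground
truth — the planted position map — travels with the family, so the whole
pipeline can be exercised end to end without any external data.

``load_paper_fixture`` returns the packaged worked-example tables
(omdc_table2, gh16_table3, ech_table4, abdh_table5) as parsed site tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import InputError
from .local_alignment import PositionMap
from .salsa_core import AMINO_ACIDS, SalsaTable
from .site_prediction import RankingEntry, ResidueRanking, write_rankings
from .structure_io import ProteinStructure, ResidueKey, ResidueRecord, one_to_three, write_pdb

__all__ = [
    "SiteSpec",
    "FamilyTruth",
    "default_site_spec",
    "make_toy_family",
    "load_paper_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("omdc_table2", "gh16_table3", "ech_table4", "abdh_table5")

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN = np.deg2rad(100.0)


@dataclass
class SiteSpec:
    """A planted constellation: residue codes at fixed 3D geometry."""

    codes: str
    geometry: np.ndarray  # len(codes) x 3, Angstroms
    jitter_sigma: float = 0.0
    decoy_count: int = 20

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=float)
        if self.geometry.shape != (len(self.codes), 3):
            raise InputError(
                f"geometry shape {self.geometry.shape} does not match {len(self.codes)} codes"
            )
        if self.jitter_sigma < 0:
            raise InputError("jitter_sigma must be >= 0")
        for c in self.codes:
            if c not in AMINO_ACIDS:
                raise InputError(f"invalid site code {c!r}")


def default_site_spec(jitter_sigma: float = 0.0, decoy_count: int = 42,
                      codes: str = "DKDKDHPR") -> SiteSpec:
    """Site residues on a ring of radius 5 A centered 18 A off the helix axis."""
    n = len(codes)
    angles = 2 * np.pi * np.arange(n) / n
    geometry = np.column_stack([
        18.0 + 5.0 * np.cos(angles),
        5.0 * np.sin(angles),
        np.linspace(-2.0, 2.0, n),
    ])
    return SiteSpec(codes=codes, geometry=geometry, jitter_sigma=jitter_sigma,
                    decoy_count=decoy_count)


@dataclass
class FamilyTruth:
    structures: list[ProteinStructure]
    rankings: list[ResidueRanking]
    planted_positions: PositionMap
    seed: int
    site: SiteSpec = field(repr=False, default=None)  # type: ignore[assignment]

    def write(self, directory: str | os.PathLike) -> dict[str, dict[str, str]]:
        """Write PDB + rankings files; returns {structure_id: {pdb, rankings}} paths."""
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, dict[str, str]] = {}
        for structure, ranking in zip(self.structures, self.rankings):
            pdb_path = out / f"{structure.structure_id}.pdb"
            rank_path = out / f"{structure.structure_id}.rankings.tsv"
            write_pdb(structure, pdb_path)
            write_rankings(ranking, rank_path)
            paths[structure.structure_id] = {"pdb": str(pdb_path), "rankings": str(rank_path)}
        return paths

    @property
    def site_fraction(self) -> float:
        """Top fraction that selects exactly the planted residues."""
        n = len(self.structures[0])
        return len(self.site.codes) / n


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_toy_family(
    n_structures: int,
    n_residues: int,
    site: SiteSpec,
    mutation_rate: float = 0.0,
    seed: int = 0,
    rank_noise: float = 0.0,
) -> FamilyTruth:
    """Generate a seeded family sharing the planted site.

    Each structure is a helical CA trace; site residues are relocated to the
    site geometry (plus Gaussian jitter), the whole structure is subjected
    to a random rigid motion, and a ranking file puts the site residues at
    ranks 1..k (decoys follow, ordered by distance to the site center plus
    ``rank_noise`` Gaussian noise).  With probability ``mutation_rate`` a
    site residue's identity is substituted.  Deterministic per seed.
    """
    k = len(site.codes)
    if n_structures < 1:
        raise InputError("n_structures must be >= 1")
    if n_residues < k + site.decoy_count:
        raise InputError(
            f"n_residues={n_residues} < site size {k} + decoy_count {site.decoy_count}"
        )
    if not (0.0 <= mutation_rate < 1.0):
        raise InputError("mutation_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    # shared decoy sequence so sequence alignment pairs residues correctly
    decoy_codes = rng.choice(list(AMINO_ACIDS), size=n_residues)
    site_indices = np.unique(np.round(np.linspace(0, n_residues - 1, k)).astype(int))
    if len(site_indices) != k:
        raise InputError("n_residues too small to spread the site residues out")

    structures: list[ProteinStructure] = []
    rankings: list[ResidueRanking] = []
    positions: list[dict[str, ResidueKey]] = [dict() for _ in range(k)]
    site_center = site.geometry.mean(axis=0)

    for s in range(n_structures):
        sid = f"toy{s:02d}"
        codes = [str(c) for c in decoy_codes]
        for slot, idx in enumerate(site_indices):
            code = site.codes[slot]
            if mutation_rate > 0 and rng.random() < mutation_rate:
                others = [c for c in AMINO_ACIDS if c != code]
                code = others[int(rng.integers(len(others)))]
            codes[idx] = code

        t = np.arange(n_residues, dtype=float)
        coords = np.column_stack([
            _HELIX_RADIUS * np.cos(_HELIX_TURN * t),
            _HELIX_RADIUS * np.sin(_HELIX_TURN * t),
            _HELIX_RISE * t,
        ])
        coords[:, 2] -= coords[:, 2].mean()
        jitter = rng.normal(scale=site.jitter_sigma, size=(k, 3)) if site.jitter_sigma > 0 else 0.0
        coords[site_indices] = site.geometry + jitter
        # side-chain proxy: 1.2 A outward from the local origin
        norms = np.linalg.norm(coords, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        cb = coords + 1.2 * coords / norms

        rotation = _random_rotation(rng)
        translation = rng.uniform(-10.0, 10.0, size=3)
        coords = coords @ rotation.T + translation
        cb = cb @ rotation.T + translation
        coords = np.round(coords, 3)  # match PDB precision so reads are exact
        cb = np.round(cb, 3)
        for i, code in enumerate(codes):  # glycine has no side chain
            if code == "G":
                cb[i] = coords[i]

        records = [
            ResidueRecord(
                chain_id="A",
                res_seq=i + 1,
                icode="",
                name3=one_to_three(codes[i]),
                code1=codes[i],
                ca_coord=coords[i],
                sidechain_centroid=cb[i],
            )
            for i in range(n_residues)
        ]
        structure = ProteinStructure(structure_id=sid, residues=records)
        structures.append(structure)

        for slot, idx in enumerate(site_indices):
            positions[slot][sid] = records[idx].key

        # ranks: site residues 1..k (shuffled), decoys by distance to site center
        site_order = rng.permutation(k)
        rank_of: dict[int, int] = {}
        for r, slot in enumerate(site_order, start=1):
            rank_of[int(site_indices[slot])] = r
        decoy_idx = [i for i in range(n_residues) if i not in rank_of]
        site_center_here = rotation @ site_center + translation
        dists = np.linalg.norm(coords[decoy_idx] - site_center_here, axis=1)
        if rank_noise > 0:
            dists = dists + rng.normal(scale=rank_noise, size=len(dists))
        for r, pos in enumerate(np.argsort(dists, kind="stable"), start=k + 1):
            rank_of[decoy_idx[int(pos)]] = r
        entries = [
            RankingEntry(
                key=records[i].key,
                code1=records[i].code1,
                rank=rank_of[i],
                score=round(1.0 - (rank_of[i] - 1) / n_residues, 6),
            )
            for i in range(n_residues)
        ]
        rankings.append(ResidueRanking(structure_id=sid, entries=entries))

    planted = PositionMap(
        reference_id=structures[0].structure_id,
        structure_order=[s.structure_id for s in structures],
        positions=positions,
        threshold=float("nan"),
    )
    return FamilyTruth(structures=structures, rankings=rankings,
                       planted_positions=planted, seed=seed, site=site)


def load_paper_fixture(name: str) -> SalsaTable:
    """Load one of the packaged worked-example site tables by name."""
    if name not in FIXTURE_NAMES:
        raise InputError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    text = resources.files("salsa").joinpath("data").joinpath(f"{name}.tsv").read_text()
    return SalsaTable.from_tsv(text)
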