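"""Ligand/receptor contact fingerprints (LRCFs) from scored docking poses.

For each ligand and each scoring channel (LD = docking score, CD =
interaction energy) the top-scoring pose is selected and every receptor
atom with at least one ligand atom within the distance threshold
(default 2.5 A, inclusive) gets a contact bit of 1.  Columns are named
``RES_<resnum>_<atomname>^<channel>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ReceptorAtom",
    "ReceptorStructure",
    "ScoredPose",
    "ContactSettings",
    "CHANNELS",
    "read_receptor_pdb",
    "write_receptor_pdb",
    "binding_site_atoms",
    "select_top_pose",
    "contact_bits",
    "build_lrcf_matrix",
    "read_score_table",
]

CHANNELS = ("LD", "CD")


@dataclass(frozen=True)
class ReceptorAtom:
    chain: str
    res_name: str
    res_number: int
    atom_name: str
    element: str
    position: tuple
    insertion_code: str = ""

    @property
    def key(self) -> str:
        """``RES_<num>_<atomname>`` (insertion code appended verbatim)."""
        return f"{self.res_name}_{self.res_number}{self.insertion_code}_{self.atom_name}"


@dataclass
class ReceptorStructure:
    """All receptor atoms, explicit waters included."""

    atoms: Sequence[ReceptorAtom]

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            ident = (a.chain, a.res_number, a.insertion_code, a.atom_name)
            if ident in seen:
                raise ValueError(f"duplicate receptor atom {ident}")
            seen.add(ident)
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite coordinates on atom {ident}")

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def keys(self) -> List[str]:
        return [a.key for a in self.atoms]


@dataclass
class ScoredPose:
    ligand_id: str
    pose_id: str
    coordinates: np.ndarray
    scores: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not self.scores:
            raise ValueError(
                f"pose {self.pose_id!r} of ligand {self.ligand_id!r} has no score"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"pose {self.pose_id!r} has non-finite coordinates")


@dataclass(frozen=True)
class ContactSettings:
    threshold: float = 2.5
    #: per-channel flag: True means larger score wins top-pose selection
    higher_is_better: Mapping[str, bool] = field(
        default_factory=lambda: {"LD": True, "CD": True}
    )
    restrict_to_site: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("contact threshold must be positive")


# ---------------------------------------------------------------------------
# PDB I/O (biotite boundary)


def read_receptor_pdb(path) -> ReceptorStructure:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1)
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            ReceptorAtom(
                chain=str(arr.chain_id[i]),
                res_name=str(arr.res_name[i]),
                res_number=int(arr.res_id[i]),
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                position=tuple(float(v) for v in arr.coord[i]),
                insertion_code=str(arr.ins_code[i]).strip(),
            )
        )
    return ReceptorStructure(atoms)


def write_receptor_pdb(receptor: ReceptorStructure, path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(receptor.atoms)
    arr = struc.AtomArray(n)
    for i, a in enumerate(receptor.atoms):
        arr.chain_id[i] = a.chain
        arr.res_name[i] = a.res_name
        arr.res_id[i] = a.res_number
        arr.atom_name[i] = a.atom_name
        arr.element[i] = a.element
        arr.coord[i] = a.position
        arr.ins_code[i] = a.insertion_code
        arr.hetero[i] = a.res_name in ("HOH", "WAT")
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# operations


def binding_site_atoms(
    receptor: ReceptorStructure, center: Sequence[float], radius: float
) -> set:
    """Keys of receptor atoms within ``radius`` of ``center``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = receptor.coordinates()
    dists = np.linalg.norm(coords - np.asarray(center, dtype=float), axis=1)
    return {a.key for a, d in zip(receptor.atoms, dists) if d <= radius}


def site_residues(receptor: ReceptorStructure, center, radius: float) -> set:
    """Residues with any atom within radius (name, number) — convenience."""
    keys = binding_site_atoms(receptor, center, radius)
    residues = set()
    for a in receptor.atoms:
        if a.key in keys:
            residues.add((a.res_name, a.res_number))
    return residues


def select_top_pose(
    poses: Sequence[ScoredPose],
    channel: str,
    settings: ContactSettings = ContactSettings(),
) -> ScoredPose:
    """Argmax (argmin for lower-is-better channels) of the channel score;
    ties broken by lexicographic pose_id."""
    scored = [p for p in poses if channel in p.scores]
    if not scored:
        ligand = poses[0].ligand_id if poses else "<none>"
        raise ValueError(f"ligand {ligand!r}: no pose scored on channel {channel}")
    sign = 1.0 if settings.higher_is_better.get(channel, True) else -1.0
    return min(scored, key=lambda p: (-sign * p.scores[channel], p.pose_id))


def contact_bits(
    receptor: ReceptorStructure,
    pose: ScoredPose,
    settings: ContactSettings = ContactSettings(),
) -> set:
    """Keys of receptor atoms with >= 1 ligand atom at distance <= threshold.

    All-atom and inclusive at the boundary.  KD-tree accelerated; tests
    hold this equal to the naive all-pairs double loop.
    """
    rec_coords = receptor.coordinates()
    atoms = receptor.atoms
    if settings.restrict_to_site is not None:
        idx = [i for i, a in enumerate(atoms) if a.key in settings.restrict_to_site]
        rec_coords = rec_coords[idx]
        atoms = [atoms[i] for i in idx]
    if len(atoms) == 0 or pose.coordinates.shape[0] == 0:
        return set()
    tree = cKDTree(pose.coordinates)
    dists, _ = tree.query(rec_coords, k=1)
    return {a.key for a, d in zip(atoms, dists) if d <= settings.threshold + 1e-12}


def build_lrcf_matrix(
    receptor: ReceptorStructure,
    pose_sets: Mapping[str, Sequence[ScoredPose]],
    settings: ContactSettings = ContactSettings(),
    channels: Sequence[str] = CHANNELS,
) -> pd.DataFrame:
    """Binary ligand x contact matrix over all channels.

    Columns are the union of contacted receptor atoms, named
    ``RES_<num>_<atomname>^<channel>`` and ordered by channel, residue
    number, then atom name.  When both channels pick the same pose its
    contact set is computed once and reused.
    """
    res_number_of = {a.key: (a.res_number, a.atom_name) for a in receptor.atoms}
    per_ligand: Dict[str, Dict[str, set]] = {}
    for ligand_id, poses in pose_sets.items():
        chosen: Dict[str, ScoredPose] = {}
        available = [c for c in channels if any(c in p.scores for p in poses)]
        if not available:
            raise ValueError(f"ligand {ligand_id!r}: no pose scored on any channel")
        bits_cache: Dict[str, set] = {}
        row: Dict[str, set] = {}
        for channel in channels:
            if channel not in available:
                row[channel] = set()
                continue
            pose = select_top_pose(poses, channel, settings)
            if pose.pose_id not in bits_cache:
                bits_cache[pose.pose_id] = contact_bits(receptor, pose, settings)
            row[channel] = bits_cache[pose.pose_id]
            chosen[channel] = pose
        per_ligand[ligand_id] = row

    columns: List[str] = []
    for channel in channels:
        contacted = set()
        for row in per_ligand.values():
            contacted |= row[channel]
        ordered = sorted(contacted, key=lambda k: res_number_of.get(k, (1 << 30, k)))
        columns.extend(f"{k}^{channel}" for k in ordered)

    data = {}
    ligand_ids = list(pose_sets.keys())
    for col in columns:
        key, channel = col.rsplit("^", 1)
        data[col] = [int(key in per_ligand[lid][channel]) for lid in ligand_ids]
    frame = pd.DataFrame(data, index=pd.Index(ligand_ids, name="compound_id"))
    return frame


def read_score_table(path) -> Dict[Tuple[str, str], Dict[str, float]]:
    """TSV ``ligand_id pose_id LD CD`` -> {(ligand, pose): {channel: score}}.

    Empty cells mean the pose was not scored on that channel.
    """
    table = pd.read_csv(path, sep="\t", dtype={"ligand_id": str, "pose_id": str})
    out: Dict[Tuple[str, str], Dict[str, float]] = {}
    for _, row in table.iterrows():
        scores = {
            ch: float(row[ch])
            for ch in CHANNELS
            if ch in table.columns and pd.notna(row[ch])
        }
        out[(row["ligand_id"], row["pose_id"])] = scores
    return out
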