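"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of (config, seed): same seed, same
bytes.  Ligands with planted pharmacophore matches are built by placing
feature-bearing groups (ether oxygen, amine N-H, lone carbons, benzene
rings) directly on the model's feature points, chained through sulfur
linkers so the graph stays connected without perturbing feature
perception.  Receptor pockets are spherical-shell lattices with a
minimum inter-atom spacing of 5 A, which makes planted contact patterns
exact: a ligand atom within 2.4 A of its target receptor atom is
geometrically guaranteed to be > 2.5 A from every other receptor atom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contacts import ReceptorAtom, ReceptorStructure, ScoredPose
from .descriptors import Atom, Bond, Conformer, MoleculeRecord
from .pharmacophore import PharmacophoreModel

__all__ = [
    "SimConfig",
    "gen_pocket",
    "gen_ligands",
    "gen_poses",
    "gen_activities",
    "gen_roc_set",
]

_RESIDUE_NAMES = ["LEU", "PHE", "LYS", "GLY", "VAL", "ASP", "SER", "ALA", "GLU", "ASN"]
_ATOM_NAMES = ["N", "CA", "CB", "HN", "HA", "HB"]

_CC_AROM = 1.39  # aromatic C-C bond length
_ANCHOR_OFFSET = 1.4  # HBA oxygen to its carbon neighbor


@dataclass
class SimConfig:
    seed: int = 0
    n_compounds: int = 40
    noise_sd: float = 0.1
    true_support: Dict[str, float] = field(default_factory=dict)
    contact_distance_range: Tuple[float, float] = (2.0, 2.4)
    activity_range: float = 2.0
    activity_center: float = 6.5
    pocket_atoms: int = 120
    pocket_waters: int = 8


# ---------------------------------------------------------------------------
# receptor pocket


def _fibonacci_shell(n: int, radius: float) -> np.ndarray:
    """Deterministic near-uniform points on a sphere of given radius."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return radius * pts


def gen_pocket(config: SimConfig, n_atoms: Optional[int] = None) -> ReceptorStructure:
    """Labeled shell 'pocket' with unique atom keys and water records.

    Exactly ``n_atoms`` atoms total (waters included).  Minimum pairwise
    spacing >= 5 A by construction (asserted), so planted contacts are
    unambiguous.
    """
    n = n_atoms if n_atoms is not None else config.pocket_atoms
    if not 2 <= n <= 2000:
        raise ValueError("pocket size out of range")
    n_waters = min(config.pocket_waters, max(0, n - 4))
    radius = max(14.0, 2.2 * math.sqrt(n))
    coords = _fibonacci_shell(n, radius)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(coords).query(coords, k=2)
    if n > 1 and d[:, 1].min() < 5.0:  # enlarge until spacing guarantee holds
        radius *= 5.0 / d[:, 1].min() * 1.01
        coords = _fibonacci_shell(n, radius)

    atoms: List[ReceptorAtom] = []
    n_protein = n - n_waters
    for i in range(n_protein):
        res_number = i // len(_ATOM_NAMES) + 1
        res_name = _RESIDUE_NAMES[res_number % len(_RESIDUE_NAMES)]
        atom_name = _ATOM_NAMES[i % len(_ATOM_NAMES)]
        element = "H" if atom_name.startswith("H") else atom_name[0]
        atoms.append(
            ReceptorAtom(
                chain="A",
                res_name=res_name,
                res_number=res_number,
                atom_name=atom_name,
                element=element,
                position=tuple(float(v) for v in coords[i]),
            )
        )
    for w in range(n_waters):
        atoms.append(
            ReceptorAtom(
                chain="W",
                res_name="HOH",
                res_number=1000 + w,
                atom_name="O",
                element="O",
                position=tuple(float(v) for v in coords[n_protein + w]),
            )
        )
    return ReceptorStructure(atoms)


# ---------------------------------------------------------------------------
# ligands with plantable pharmacophore matches


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        return np.array([0.0, 0.0, 1.0])
    return v / n


def _orthobasis(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """u, v with u x v = direction (right-handed)."""
    w = _unit(direction)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, w)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(probe, w))
    v = np.cross(w, u)
    return u, v


class _MolBuilder:
    def __init__(self) -> None:
        self.atoms: List[Atom] = []
        self.bonds: List[Bond] = []
        self.coords: List[np.ndarray] = []

    def add(self, element: str, pos, charge: int = 0, aromatic: bool = False) -> int:
        self.atoms.append(Atom(element, charge, aromatic))
        self.coords.append(np.asarray(pos, dtype=float))
        return len(self.atoms) - 1

    def bond(self, i: int, j: int, order: float = 1.0, aromatic: bool = False) -> None:
        self.bonds.append(Bond(i, j, order, aromatic))

    def build(self, mol_id: str) -> MoleculeRecord:
        return MoleculeRecord(
            mol_id,
            self.atoms,
            self.bonds,
            [Conformer(np.array(self.coords))],
        )


def _planted_matcher(model: PharmacophoreModel, mol_id: str) -> MoleculeRecord:
    """Molecule whose perceived features sit exactly on the model's feature
    origins (projections along the model's own projection directions)."""
    b = _MolBuilder()
    anchors: List[int] = []
    for spec in model.features:
        origin = np.asarray(spec.origin)
        if spec.kind == "HBA":
            direction = (
                _unit(np.asarray(spec.projection) - origin)
                if spec.projection is not None
                else np.array([0.0, 0.0, 1.0])
            )
            o = b.add("O", origin)
            c = b.add("C", origin - _ANCHOR_OFFSET * direction)
            b.bond(o, c)
            anchors.append(c)
        elif spec.kind == "HBD":
            n_idx = b.add("N", origin)
            h_pos = (
                np.asarray(spec.projection)
                if spec.projection is not None
                else origin + np.array([0.0, 0.0, 1.0])
            )
            h = b.add("H", h_pos)
            b.bond(n_idx, h)
            anchors.append(n_idx)
        elif spec.kind == "Hbic":
            anchors.append(b.add("C", origin))
        elif spec.kind == "RingArom":
            direction = (
                _unit(np.asarray(spec.projection) - origin)
                if spec.projection is not None
                else np.array([0.0, 0.0, 1.0])
            )
            u, v = _orthobasis(direction)
            ring = []
            for k in range(6):
                theta = 2.0 * math.pi * k / 6.0
                pos = origin + _CC_AROM * (math.cos(theta) * u + math.sin(theta) * v)
                ring.append(b.add("C", pos, aromatic=True))
            for k in range(6):
                b.bond(ring[k], ring[(k + 1) % 6], order=1.5, aromatic=True)
            anchors.append(ring[0])
        else:  # pragma: no cover
            raise ValueError(f"unknown feature kind {spec.kind}")

    exclusions = [(np.asarray(c), r) for c, r in model.exclusion_spheres]

    def clear_of_exclusions(pos: np.ndarray) -> np.ndarray:
        for _ in range(50):
            if all(np.linalg.norm(pos - c) > r + 0.2 for c, r in exclusions):
                return pos
            pos = pos + np.array([0.0, 0.0, 0.9])
        raise RuntimeError("could not place linker clear of exclusion spheres")

    for a, b_idx in zip(anchors, anchors[1:]):
        mid = (np.asarray(b.coords[a]) + np.asarray(b.coords[b_idx])) / 2.0
        s = b.add("S", clear_of_exclusions(mid))
        b.bond(a, s)
        b.bond(s, b_idx)

    for c, r in exclusions:  # fixed feature atoms must not clash either
        for pos in b.coords:
            if np.linalg.norm(np.asarray(pos) - c) <= r:
                raise RuntimeError(
                    f"model {model.name}: planted atom inside exclusion sphere"
                )
    return b.build(mol_id)


def _decoy(model: PharmacophoreModel, mol_id: str, rng: np.random.Generator) -> MoleculeRecord:
    """Guaranteed non-hit: lacks every polar/aromatic feature kind.

    Carbon/sulfur chain only, so no HBA, HBD or RingArom can be perceived.
    """
    kinds = {f.kind for f in model.features}
    if kinds <= {"Hbic"}:
        raise ValueError("cannot build a guaranteed decoy for an all-Hbic model")
    b = _MolBuilder()
    n_carbons = int(rng.integers(3, 6))
    prev = None
    pos = rng.normal(size=3) * 2.0
    for k in range(n_carbons):
        c = b.add("C", pos)
        if prev is not None:
            s = b.add("S", (pos + prev_pos) / 2.0)
            b.bond(prev, s)
            b.bond(s, c)
        prev, prev_pos = c, pos
        pos = pos + _unit(rng.normal(size=3)) * 3.0
    return b.build(mol_id)


def _random_rigid(rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.normal(scale=5.0, size=3)
    return rot, trans


def gen_ligands(
    config: SimConfig,
    model: PharmacophoreModel,
    match_fraction: float,
) -> List[MoleculeRecord]:
    """``n_compounds`` ligands; the first round(match_fraction * n) are
    planted full matches of ``model`` (each under its own random rigid
    motion), the rest are guaranteed to lack a required feature kind."""
    if not 0.0 <= match_fraction <= 1.0:
        raise ValueError("match_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    n_match = int(round(match_fraction * n))
    ligands: List[MoleculeRecord] = []
    template = _planted_matcher(model, "template") if n_match else None
    for i in range(n):
        mol_id = f"lig{i:03d}"
        if i < n_match:
            rot, trans = _random_rigid(rng)
            coords = template.conformers[0].coordinates @ rot.T + trans
            ligands.append(
                MoleculeRecord(
                    mol_id,
                    template.atoms,
                    template.bonds,
                    [Conformer(coords)],
                )
            )
        else:
            ligands.append(_decoy(model, mol_id, rng))
    return ligands


# ---------------------------------------------------------------------------
# scored poses with plantable contacts


def gen_poses(
    config: SimConfig,
    pocket: ReceptorStructure,
    ligands: Sequence[MoleculeRecord],
    planted_contacts: Optional[Mapping[str, Sequence[str]]] = None,
) -> Dict[str, List[ScoredPose]]:
    """3-10 scored poses per ligand.

    The top pose on both channels realizes the planted contact set at
    distances inside ``contact_distance_range``; decoy poses sit near the
    shell center, > 3 A from every receptor atom.  When
    ``planted_contacts`` is omitted each ligand contacts 1-4 atoms drawn
    from a small seeded pool, so the resulting fingerprint columns carry
    several bits each (dense enough for downstream regression).
    """
    rng = np.random.default_rng(config.seed + 1)
    coords_by_key = {a.key: np.asarray(a.position) for a in pocket.atoms}
    protein_keys = [a.key for a in pocket.atoms if a.res_name != "HOH"]
    pool = [
        protein_keys[i]
        for i in sorted(
            rng.choice(len(protein_keys), size=min(10, len(protein_keys)), replace=False)
        )
    ]
    lo, hi = config.contact_distance_range
    out: Dict[str, List[ScoredPose]] = {}
    for lig in ligands:
        if planted_contacts is not None:
            targets = list(planted_contacts.get(lig.id, ()))
        else:
            k = int(rng.integers(1, 5))
            targets = [
                pool[i] for i in sorted(rng.choice(len(pool), size=k, replace=False))
            ]
        n_atoms = max(len(targets) + 2, 4)
        n_poses = int(rng.integers(3, 11))
        poses: List[ScoredPose] = []
        for p in range(n_poses):
            if p == 0:
                pts = []
                for key in targets:
                    center = coords_by_key[key]
                    direction = _unit(rng.normal(size=3))
                    d = rng.uniform(lo, hi)
                    pts.append(center + d * direction)
                while len(pts) < n_atoms:
                    # shell center; clipped so > 3 A from every shell atom
                    pts.append(np.clip(rng.normal(scale=0.8, size=3), -3.0, 3.0))
                coords = np.array(pts)
                scores = {
                    "LD": 150.0 + float(rng.uniform(0, 5)),
                    "CD": 60.0 + float(rng.uniform(0, 5)),
                }
            else:
                coords = np.clip(rng.normal(scale=0.8, size=(n_atoms, 3)), -3.0, 3.0)
                scores = {
                    "LD": 100.0 + float(rng.uniform(0, 20)),
                    "CD": 30.0 + float(rng.uniform(0, 10)),
                }
            poses.append(ScoredPose(lig.id, f"p{p:02d}", coords, scores))
        out[lig.id] = poses
    return out


# ---------------------------------------------------------------------------
# activities and ROC sets


def gen_activities(
    descriptor_matrix: pd.DataFrame,
    config: SimConfig,
) -> pd.Series:
    """log(1/IC50) from a known sparse linear model plus seeded noise.

    y0 = sum(coef * zscore(column)); rescaled so the noise-free span is at
    least ``activity_range`` log units, centered on ``activity_center``.
    """
    values = (
        descriptor_matrix.set_index("compound_id")
        if "compound_id" in descriptor_matrix.columns
        else descriptor_matrix
    )
    missing = [c for c in config.true_support if c not in values.columns]
    if missing:
        raise ValueError(f"true_support columns not in matrix: {missing}")
    rng = np.random.default_rng(config.seed + 2)
    y0 = np.zeros(len(values))
    for col, coef in config.true_support.items():
        x = values[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        y0 = y0 + coef * z
    span = float(np.ptp(y0))
    if span > 0 and span < config.activity_range:
        y0 = y0 * (config.activity_range / span)
    y = y0 - y0.mean() + config.activity_center
    y = y + rng.normal(scale=config.noise_sd, size=len(y))
    return pd.Series(y, index=values.index, name="log_inv_ic50")


def gen_roc_set(
    config: SimConfig,
    separation: float,
    n_active: int = 383,
    n_inactive: int = 270,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """ROC benchmark: actives' latent scores ~ N(separation, 1), inactives
    ~ N(0, 1); IC50s fill the active (<= 400 nM) and inactive (> 3000 nM)
    ranges by latent rank."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    scores: Dict[str, float] = {}
    lat_a = rng.normal(loc=separation, size=n_active)
    lat_i = rng.normal(loc=0.0, size=n_inactive)
    # higher latent -> more potent -> lower IC50
    for group, latents, lo_nm, hi_nm, prefix in (
        ("active", lat_a, 1.0, 400.0, "act"),
        ("inactive", lat_i, 3000.0 + 1e-6, 100000.0, "inact"),
    ):
        ranks = np.argsort(np.argsort(-latents))  # 0 = highest latent
        denom = max(len(latents) - 1, 1)
        for i, latent in enumerate(latents):
            frac = ranks[i] / denom
            ic50_nm = lo_nm * (hi_nm / lo_nm) ** frac
            cid = f"{prefix}{i:04d}"
            rows.append({"compound_id": cid, "ic50_nM": ic50_nm, "label": group})
            scores[cid] = float(latent)
    table = pd.DataFrame(rows, columns=["compound_id", "ic50_nM", "label"])
    return table, scores
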