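"""Molecular data model, chemical feature perception and descriptors.

The molecule representation is toolkit-independent: an explicit atom/bond
graph plus one or more 3D conformers.  RDKit is used only at the I/O
boundary (SDF/SMILES parsing, Gasteiger charges, van der Waals radii).

Descriptors implemented here are the ones that appear in the bundled
reference QSAR models: second-order connectivity index, third-order kappa
shape index, ring counts, dipole components, principal moments of inertia
and the XY shadow area fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "Conformer",
    "ActivityRecord",
    "ChemicalFeature",
    "MoleculeRecord",
    "FeatureRules",
    "perceive_features",
    "chi2_index",
    "kappa3_index",
    "ring_count",
    "dipole_component",
    "principal_moment",
    "shadow_xy_fraction",
    "log_inverse_ic50",
    "read_sdf",
    "write_sdf",
    "from_smiles",
    "descriptor_table",
    "DESCRIPTOR_COLUMNS",
]

HALOGENS = frozenset({"F", "Cl", "Br", "I"})
#: elements counted as heteroatoms for hydrophobe eligibility rules
HETEROATOMS_EXCLUDED = frozenset({"C", "H"})

# Conversion factor: e*Angstrom -> debye
_EA_TO_DEBYE = 4.80321


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float = 1.0
    aromatic: bool = False


@dataclass
class Conformer:
    """3D coordinates (Angstrom) for one conformation; optional relative energy."""

    coordinates: np.ndarray
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("conformer coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("conformer coordinates must be finite")


@dataclass
class ActivityRecord:
    """IC50 in molar together with the modeled response log10(1/IC50)."""

    ic50: float
    log_inv_ic50: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50}")
        expected = -math.log10(self.ic50)
        if self.log_inv_ic50 is None:
            self.log_inv_ic50 = expected
        elif not math.isclose(self.log_inv_ic50, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"log_inv_ic50={self.log_inv_ic50} inconsistent with ic50={self.ic50}"
            )


@dataclass(frozen=True)
class ChemicalFeature:
    """A perceived pharmacophoric point on a conformer.

    kind is one of HBA, HBD, Hbic, RingArom.  HBA/HBD/RingArom carry a
    projection point (H position, lone-pair direction or ring normal);
    hydrophobes are single centroids.
    """

    kind: str
    origin: tuple
    projection: Optional[tuple]
    source_atoms: frozenset

    def __post_init__(self) -> None:
        if self.kind not in ("HBA", "HBD", "Hbic", "RingArom"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "Hbic" and self.projection is not None:
            raise ValueError("Hbic features carry no projection point")
        if self.kind != "Hbic" and self.projection is None:
            raise ValueError(f"{self.kind} features require a projection point")


@dataclass
class MoleculeRecord:
    """Molecular graph with 0+ conformers and an optional activity."""

    id: str
    atoms: Sequence[Atom]
    bonds: Sequence[Bond]
    conformers: list = field(default_factory=list)
    activity: Optional[ActivityRecord] = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"{self.id}: bond ({b.i},{b.j}) references missing atom")
        if n > 1:
            g = self.graph()
            if not nx.is_connected(g):
                raise ValueError(f"{self.id}: molecular graph is not connected")
        for conf in self.conformers:
            if conf.coordinates.shape[0] != n:
                raise ValueError(
                    f"{self.id}: conformer has {conf.coordinates.shape[0]} atoms, "
                    f"graph has {n}"
                )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def heavy_indices(self) -> list:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def neighbors(self) -> list:
        nbrs: list = [[] for _ in self.atoms]
        for b in self.bonds:
            nbrs[b.i].append(b.j)
            nbrs[b.j].append(b.i)
        return [sorted(v) for v in nbrs]

    def filter_conformers(self, max_energy: float = 20.0, cap: int = 250) -> "MoleculeRecord":
        """Optional ensemble filter: energy window (kcal/mol) plus size cap."""
        kept = [
            c
            for c in self.conformers
            if c.energy is None or c.energy <= max_energy
        ][:cap]
        return MoleculeRecord(self.id, self.atoms, self.bonds, kept, self.activity)


# ---------------------------------------------------------------------------
# feature perception


@dataclass(frozen=True)
class FeatureRules:
    """Configurable perception rules (documented defaults).

    - acceptor: N/O, formal charge <= 0, with an available lone pair
      (for N: at most 3 connections); projection 1.9 A along the
      lone-pair bisector (opposite the mean bond vector).
    - donor: O-H / N-H, one feature per polar hydrogen; projection is the
      H position.
    - aromatic ring: every SSSR ring whose atoms and bonds are all
      aromatic; origin at the centroid, projection 2.0 A along the ring
      normal (Newell construction, covariant under rotation).
    - hydrophobe: centroid of each connected group of non-aromatic
      carbon/halogen atoms, skipping atoms adjacent to a charged atom or
      to an atom bonded to >= 2 heteroatoms; plus every aromatic ring
      centroid.
    """

    acceptor_projection_length: float = 1.9
    ring_projection_length: float = 2.0


DEFAULT_RULES = FeatureRules()


def _sssr(mol: MoleculeRecord) -> list:
    """Smallest set of smallest rings as ordered atom-index tuples.

    Ties broken smallest-ring-first, then by the sorted atom tuple, so the
    output is canonical for a fixed atom labeling.
    """
    g = mol.graph()
    basis = nx.minimum_cycle_basis(g)
    rings = []
    for nodes in basis:
        rings.append(_order_cycle(sorted(nodes), g))
    rings.sort(key=lambda r: (len(r), tuple(sorted(r))))
    return rings


def _order_cycle(nodes: Sequence[int], g: nx.Graph) -> tuple:
    """Walk the induced cycle to recover a cyclic vertex order."""
    node_set = set(nodes)
    start = min(nodes)
    order = [start]
    prev = None
    cur = start
    while len(order) < len(nodes):
        nxt = sorted(n for n in g.neighbors(cur) if n in node_set and n != prev)
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        order.append(cur)
    return tuple(order)


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    """Newell normal of an ordered ring; rotates covariantly with coords."""
    c = coords.mean(axis=0)
    n = np.zeros(3)
    for i in range(len(coords)):
        a = coords[i] - c
        b = coords[(i + 1) % len(coords)] - c
        n += np.cross(a, b)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return np.array([0.0, 0.0, 1.0])
    return n / norm


def perceive_features(
    molecule: MoleculeRecord,
    conformer_index: int = 0,
    rules: FeatureRules = DEFAULT_RULES,
) -> list:
    """Perceive HBA/HBD/Hbic/RingArom features on one conformer.

    Deterministic: feature order is HBA, HBD, Hbic, RingArom, each block
    sorted by source atom indices.
    """
    try:
        conf = molecule.conformers[conformer_index]
    except IndexError:
        raise ValueError(
            f"molecule {molecule.id!r} has no conformer {conformer_index}"
        ) from None
    xyz = conf.coordinates
    atoms = molecule.atoms
    nbrs = molecule.neighbors()
    feats: list = []

    # --- acceptors
    for i, a in enumerate(atoms):
        if a.element not in ("N", "O") or a.formal_charge > 0:
            continue
        heavy_and_h = nbrs[i]
        if a.element == "N" and len(heavy_and_h) > 3:
            continue  # quaternary-like N: no lone pair
        direction = np.zeros(3)
        for j in heavy_and_h:
            v = xyz[j] - xyz[i]
            norm = np.linalg.norm(v)
            if norm > 1e-9:
                direction -= v / norm
        if np.linalg.norm(direction) < 1e-9:
            direction = np.array([0.0, 0.0, 1.0])
        direction /= np.linalg.norm(direction)
        proj = xyz[i] + rules.acceptor_projection_length * direction
        feats.append(
            ChemicalFeature("HBA", tuple(xyz[i]), tuple(proj), frozenset({i}))
        )

    # --- donors: one feature per polar hydrogen
    for i, a in enumerate(atoms):
        if a.element not in ("N", "O"):
            continue
        for j in nbrs[i]:
            if atoms[j].element == "H":
                feats.append(
                    ChemicalFeature(
                        "HBD", tuple(xyz[i]), tuple(xyz[j]), frozenset({i, j})
                    )
                )

    # --- hydrophobes: non-aromatic C/halogen groups
    eligible = set()
    for i, a in enumerate(atoms):
        if a.element not in HALOGENS and a.element != "C":
            continue
        if a.aromatic:
            continue  # aromatic carbons contribute via ring centroids
        blocked = False
        for j in nbrs[i]:
            if atoms[j].formal_charge != 0:
                blocked = True
                break
            hetero_nbrs = sum(
                1
                for k in nbrs[j]
                if atoms[k].element not in HETEROATOMS_EXCLUDED
            )
            if hetero_nbrs >= 2:
                blocked = True
                break
        if not blocked:
            eligible.add(i)
    sub = mol_subgraph(molecule, eligible)
    for comp in sorted(nx.connected_components(sub), key=lambda s: min(s)):
        members = sorted(comp)
        centroid = xyz[members].mean(axis=0)
        feats.append(
            ChemicalFeature("Hbic", tuple(centroid), None, frozenset(members))
        )

    # --- aromatic rings: RingArom + centroid hydrophobe
    for ring in _sssr(molecule):
        if not all(atoms[i].aromatic for i in ring):
            continue
        ring_bonds = {
            frozenset((b.i, b.j)): b for b in molecule.bonds
        }
        ok = True
        for i in range(len(ring)):
            key = frozenset((ring[i], ring[(i + 1) % len(ring)]))
            if key not in ring_bonds or not ring_bonds[key].aromatic:
                ok = False
                break
        if not ok:
            continue
        coords = xyz[list(ring)]
        centroid = coords.mean(axis=0)
        normal = _ring_normal(coords)
        proj = centroid + rules.ring_projection_length * normal
        feats.append(
            ChemicalFeature("Hbic", tuple(centroid), None, frozenset(ring))
        )
        feats.append(
            ChemicalFeature("RingArom", tuple(centroid), tuple(proj), frozenset(ring))
        )

    kind_rank = {"HBA": 0, "HBD": 1, "Hbic": 2, "RingArom": 3}
    feats.sort(key=lambda f: (kind_rank[f.kind], tuple(sorted(f.source_atoms))))
    return feats


def mol_subgraph(molecule: MoleculeRecord, nodes: Iterable[int]) -> nx.Graph:
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(node_set)
    g.add_edges_from(
        (b.i, b.j) for b in molecule.bonds if b.i in node_set and b.j in node_set
    )
    return g


# ---------------------------------------------------------------------------
# graph descriptors (hydrogen-suppressed)


def _heavy_graph(molecule: MoleculeRecord) -> nx.Graph:
    heavy = set(molecule.heavy_indices())
    if not heavy:
        raise ValueError(f"{molecule.id}: no heavy atoms")
    return mol_subgraph(molecule, heavy)


def chi2_index(molecule: MoleculeRecord) -> float:
    """Second-order connectivity index on the hydrogen-suppressed graph.

    Sum over simple 3-atom paths of (di*dj*dk)^(-1/2) with d the heavy-atom
    degree.  Paths are enumerated through their middle atom.
    """
    g = _heavy_graph(molecule)
    deg = dict(g.degree())
    total = 0.0
    for j in g.nodes:
        nb = sorted(g.neighbors(j))
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                i, k = nb[x], nb[y]
                total += 1.0 / math.sqrt(deg[i] * deg[j] * deg[k])
    return total


def _count_paths3(g: nx.Graph) -> int:
    """Simple paths of 4 distinct vertices (3 bonds)."""
    count = 0
    for a in g.nodes:
        for b in g.neighbors(a):
            for c in g.neighbors(b):
                if c == a:
                    continue
                for d in g.neighbors(c):
                    if d in (a, b):
                        continue
                    count += 1
    return count // 2  # each path seen from both ends


def kappa3_index(molecule: MoleculeRecord) -> float:
    """Third-order kappa shape index (plain, non-alpha variant)."""
    g = _heavy_graph(molecule)
    a = g.number_of_nodes()
    p3 = _count_paths3(g)
    if p3 == 0:
        return 0.0
    if a % 2 == 1:
        return (a - 1) * (a - 3) ** 2 / p3**2
    return (a - 3) * (a - 2) ** 2 / p3**2


def ring_count(molecule: MoleculeRecord, size: int) -> int:
    """Number of rings of exactly ``size`` atoms in the SSSR."""
    if size < 3:
        raise ValueError("ring size must be >= 3")
    return sum(1 for r in _sssr(molecule) if len(r) == size)


# ---------------------------------------------------------------------------
# 3D descriptors


def dipole_component(
    conformer: Conformer, partial_charges: Sequence[float], axis: str
) -> float:
    """Dipole-moment component in debye from point charges (e) at coords (A)."""
    charges = np.asarray(partial_charges, dtype=float)
    if charges.shape[0] != conformer.coordinates.shape[0]:
        raise ValueError(
            f"{charges.shape[0]} charges for {conformer.coordinates.shape[0]} atoms"
        )
    ax = {"x": 0, "y": 1, "z": 2}[axis.lower()]
    return _EA_TO_DEBYE * float(np.dot(charges, conformer.coordinates[:, ax]))


def _inertia_eigenvalues(coords: np.ndarray, masses: np.ndarray):
    com = np.average(coords, axis=0, weights=masses)
    r = coords - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    m = masses
    tensor = np.array(
        [
            [np.sum(m * (y**2 + z**2)), -np.sum(m * x * y), -np.sum(m * x * z)],
            [-np.sum(m * x * y), np.sum(m * (x**2 + z**2)), -np.sum(m * y * z)],
            [-np.sum(m * x * z), -np.sum(m * y * z), np.sum(m * (x**2 + y**2))],
        ]
    )
    vals, vecs = np.linalg.eigh(tensor)
    return vals, vecs


def principal_moment(
    conformer: Conformer, masses: Sequence[float], axis_rank: int
) -> float:
    """Principal moment of inertia (amu*A^2); axis_rank 1..3, ascending."""
    if axis_rank not in (1, 2, 3):
        raise ValueError("axis_rank must be 1, 2 or 3")
    masses = np.asarray(masses, dtype=float)
    vals, _ = _inertia_eigenvalues(conformer.coordinates, masses)
    vals = np.clip(vals, 0.0, None)
    return float(vals[axis_rank - 1])


def _principal_axis_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate unit-mass coords so the largest-moment axis is Z (deterministic)."""
    if coords.shape[0] == 1:
        return coords.copy()
    vals, vecs = _inertia_eigenvalues(coords, np.ones(coords.shape[0]))
    # eigh returns ascending -> columns already smallest..largest moment
    for k in range(3):
        col = vecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, k] = -col
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    com = coords.mean(axis=0)
    return (coords - com) @ vecs


def shadow_xy_fraction(
    conformer: Conformer, vdw_radii: Sequence[float], grid_step: float = 0.05
) -> float:
    """Fraction of the tight XY bounding rectangle covered by the projected
    union of atom disks, after rotation into the principal-axis frame."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    radii = np.asarray(vdw_radii, dtype=float)
    coords = _principal_axis_frame(conformer.coordinates)
    cx, cy = coords[:, 0], coords[:, 1]
    xmin, xmax = np.min(cx - radii), np.max(cx + radii)
    ymin, ymax = np.min(cy - radii), np.max(cy + radii)
    box = (xmax - xmin) * (ymax - ymin)
    if box <= 0:
        return 1.0
    xs = np.arange(xmin + grid_step / 2, xmax, grid_step)
    ys = np.arange(ymin + grid_step / 2, ymax, grid_step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    covered = np.zeros(gx.shape, dtype=bool)
    for x, y, r in zip(cx, cy, radii):
        covered |= (gx - x) ** 2 + (gy - y) ** 2 <= r**2
    area = covered.sum() * grid_step**2
    return min(float(area / box), 1.0)


def log_inverse_ic50(ic50: float) -> float:
    """log10(1/IC50) with IC50 in molar (the standard pIC50)."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50)


# ---------------------------------------------------------------------------
# I/O (RDKit boundary)

DESCRIPTOR_COLUMNS = [
    "CHI_2",
    "Kappa_3",
    "Num_Rings5",
    "Num_Rings6",
    "Dipole_Y",
    "PMI_x",
    "Shadow_XYfrac",
]


def _require_rdkit():
    from rdkit import Chem  # noqa: F401

    return Chem


def from_rdkit(mol, mol_id: Optional[str] = None) -> MoleculeRecord:
    """Convert an RDKit mol (with 0+ conformers) into a MoleculeRecord."""
    atoms = [
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            b.GetBondTypeAsDouble(),
            b.GetIsAromatic(),
        )
        for b in mol.GetBonds()
    ]
    conformers = [
        Conformer(np.array(c.GetPositions(), dtype=float))
        for c in mol.GetConformers()
    ]
    name = mol_id
    if name is None:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    activity = None
    if mol.HasProp("ic50"):
        activity = ActivityRecord(float(mol.GetProp("ic50")))
    return MoleculeRecord(name, atoms, bonds, conformers, activity)


def to_rdkit(record: MoleculeRecord):
    """Build an RDKit mol carrying all conformers of the record."""
    Chem = _require_rdkit()
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in record.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        atom.SetIsAromatic(a.aromatic)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for b in record.bonds:
        rw.AddBond(b.i, b.j, order_map.get(b.order, Chem.BondType.SINGLE))
        rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(b.aromatic)
    mol = rw.GetMol()
    mol.SetProp("_Name", record.id)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    for conf in record.conformers:
        c = Chem.Conformer(len(record.atoms))
        for i, (x, y, z) in enumerate(conf.coordinates):
            c.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        mol.AddConformer(c, assignId=True)
    if record.activity is not None:
        mol.SetProp("ic50", repr(record.activity.ic50))
    return mol


def read_sdf(path) -> list:
    """Read an SDF; consecutive records sharing a title merge into one
    multi-conformer MoleculeRecord."""
    Chem = _require_rdkit()
    records: list = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for mol in supplier:
        if mol is None:
            continue
        rec = from_rdkit(mol)
        if mol.HasProp("energy"):
            rec.conformers[0].energy = float(mol.GetProp("energy"))
        if records and records[-1].id == rec.id:
            prev = records[-1]
            if len(prev.atoms) != len(rec.atoms):
                raise ValueError(
                    f"SDF records titled {rec.id!r} have differing atom counts"
                )
            prev.conformers.extend(rec.conformers)
        else:
            records.append(rec)
    return records


def write_sdf(records: Iterable[MoleculeRecord], path) -> None:
    Chem = _require_rdkit()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for rec in records:
        mol = to_rdkit(rec)
        if not rec.conformers:
            writer.write(mol)
            continue
        for conf_id in range(len(rec.conformers)):
            if rec.conformers[conf_id].energy is not None:
                mol.SetProp("energy", repr(rec.conformers[conf_id].energy))
            writer.write(mol, confId=conf_id)
    writer.close()


def from_smiles(smiles: str, mol_id: str = "") -> MoleculeRecord:
    """Graph-only record from SMILES (explicit hydrogens, no conformer)."""
    Chem = _require_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    return from_rdkit(mol, mol_id=mol_id)


def default_vdw_radii(record: MoleculeRecord) -> np.ndarray:
    Chem = _require_rdkit()
    table = Chem.GetPeriodicTable()
    return np.array([table.GetRvdw(a.element) for a in record.atoms])


def default_masses(record: MoleculeRecord) -> np.ndarray:
    Chem = _require_rdkit()
    table = Chem.GetPeriodicTable()
    return np.array([table.GetAtomicWeight(a.element) for a in record.atoms])


def gasteiger_charges(record: MoleculeRecord) -> np.ndarray:
    """Gasteiger partial charges via RDKit (charge model is replaceable)."""
    from rdkit.Chem import AllChem

    mol = to_rdkit(record)
    from rdkit import Chem

    Chem.SanitizeMol(mol)
    AllChem.ComputeGasteigerCharges(mol)
    return np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    )


def descriptor_table(
    records: Sequence[MoleculeRecord],
    charges: Optional[Mapping[str, Sequence[float]]] = None,
    grid_step: float = 0.05,
):
    """Physicochemical descriptor table, one row per molecule.

    Columns follow :data:`DESCRIPTOR_COLUMNS`.  3D descriptors use the
    first conformer; charges default to Gasteiger when not supplied.
    """
    import pandas as pd

    rows = []
    for rec in records:
        if not rec.conformers:
            raise ValueError(f"{rec.id}: 3D descriptors require a conformer")
        conf = rec.conformers[0]
        q = (
            np.asarray(charges[rec.id], dtype=float)
            if charges is not None and rec.id in charges
            else gasteiger_charges(rec)
        )
        rows.append(
            {
                "compound_id": rec.id,
                "CHI_2": chi2_index(rec),
                "Kappa_3": kappa3_index(rec),
                "Num_Rings5": ring_count(rec, 5),
                "Num_Rings6": ring_count(rec, 6),
                "Dipole_Y": dipole_component(conf, q, "y"),
                "PMI_x": principal_moment(conf, default_masses(rec), 1),
                "Shadow_XYfrac": shadow_xy_fraction(
                    conf, default_vdw_radii(rec), grid_step=grid_step
                ),
            }
        )
    return pd.DataFrame(rows, columns=["compound_id"] + DESCRIPTOR_COLUMNS)
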