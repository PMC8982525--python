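"""Pharmacophore models: PHORE file I/O, mapping, alignment, fit values,
3D screening and F-value ranking.

A model is a set of typed feature spheres (origin + optional projection
point, each with its own tolerance radius), a global feature weight W and
optional exclusion spheres.  The fit value of a mapped ligand is

    fit = n_mapped * W * (1 - sum((disp/tol)^2))

where the sum runs over every mapped feature point (origin and, for
vectored features, projection).  A per-feature-sum alternative is provided
because the literal product form can go negative for many poorly mapped
features.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .descriptors import ChemicalFeature, MoleculeRecord, perceive_features

__all__ = [
    "PharmacophoreFeatureSpec",
    "PharmacophoreModel",
    "FeatureMapping",
    "RigidTransform",
    "read_pharmacophore",
    "write_pharmacophore",
    "parse_pharmacophore",
    "format_pharmacophore",
    "enumerate_mappings",
    "superpose",
    "fit_value",
    "best_fit",
    "screen_molecule",
    "f_score",
    "bundled_model_path",
    "bundled_models",
]

_KIND_TOKEN = {"HBA": "HBA", "HBD": "HBD", "Hbic": "HBIC", "RingArom": "RAROM"}
_TOKEN_KIND = {v: k for k, v in _KIND_TOKEN.items()}

F_SCORE_CAP = 1e12


@dataclass(frozen=True)
class PharmacophoreFeatureSpec:
    kind: str
    origin: tuple
    origin_tol: float
    projection: Optional[tuple] = None
    projection_tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.origin_tol <= 0:
            raise ValueError("origin tolerance must be positive")
        if (self.projection is None) != (self.projection_tol is None):
            raise ValueError("projection point and tolerance must come together")
        if self.kind == "Hbic" and self.projection is not None:
            raise ValueError("Hbic feature specs carry no projection")


@dataclass
class PharmacophoreModel:
    name: str
    weight: float
    features: Sequence[PharmacophoreFeatureSpec]
    exclusion_spheres: Sequence[Tuple[tuple, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError(f"model {self.name!r} has no features")
        if self.weight <= 0:
            raise ValueError("model weight must be positive")
        for _, radius in self.exclusion_spheres:
            if radius <= 0:
                raise ValueError("exclusion radii must be positive")


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t (proper rotation only)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class FeatureMapping:
    pairs: list  # (model feature index, ligand feature index)
    transform: RigidTransform
    disps: list  # per mapped feature point, model-frame distances (A)
    fit: float


# ---------------------------------------------------------------------------
# PHORE v1 format


def parse_pharmacophore(text: str, source: str = "<string>") -> PharmacophoreModel:
    name = None
    weight = 1.0
    features: list = []
    exclusions: list = []
    ended = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            keyword = tokens[0].upper()
            if keyword == "MODEL":
                name = " ".join(tokens[1:])
            elif keyword == "WEIGHT":
                weight = float(tokens[1])
            elif keyword == "FEATURE":
                kind = _TOKEN_KIND[tokens[1].upper()]
                origin = tuple(float(v) for v in tokens[2:5])
                tol = float(tokens[5])
                projection = None
                proj_tol = None
                rest = tokens[6:]
                if rest:
                    if rest[0].upper() != "PROJ" or len(rest) != 5:
                        raise ValueError("malformed PROJ clause")
                    projection = tuple(float(v) for v in rest[1:4])
                    proj_tol = float(rest[4])
                features.append(
                    PharmacophoreFeatureSpec(kind, origin, tol, projection, proj_tol)
                )
            elif keyword == "EXCLUDE":
                center = tuple(float(v) for v in tokens[1:4])
                radius = float(tokens[4])
                exclusions.append((center, radius))
            elif keyword == "END":
                ended = True
                break
            else:
                raise ValueError(f"unknown keyword {tokens[0]!r}")
        except (KeyError, IndexError, ValueError) as exc:
            raise ValueError(f"{source}:{lineno}: {exc}") from None
    if name is None:
        raise ValueError(f"{source}: missing MODEL line")
    if not features:
        raise ValueError(f"{source}: model {name!r} has an empty FEATURE block")
    if not ended:
        raise ValueError(f"{source}: missing END line")
    return PharmacophoreModel(name, weight, features, exclusions)


def format_pharmacophore(model: PharmacophoreModel) -> str:
    lines = [f"MODEL {model.name}", f"WEIGHT {model.weight:.6f}"]
    for f in model.features:
        parts = [
            "FEATURE",
            _KIND_TOKEN[f.kind],
            *(f"{v:.6f}" for v in f.origin),
            f"{f.origin_tol:.6f}",
        ]
        if f.projection is not None:
            parts += ["PROJ", *(f"{v:.6f}" for v in f.projection), f"{f.projection_tol:.6f}"]
        lines.append(" ".join(parts))
    for center, radius in model.exclusion_spheres:
        lines.append(
            "EXCLUDE " + " ".join(f"{v:.6f}" for v in center) + f" {radius:.6f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pharmacophore(path) -> PharmacophoreModel:
    with open(path) as fh:
        return parse_pharmacophore(fh.read(), source=str(path))


def write_pharmacophore(model: PharmacophoreModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_pharmacophore(model))


def bundled_model_path(name: str):
    """Path of a shipped .phore fixture (by model name or file stem)."""
    from importlib.resources import files

    stem = name.replace("(", "_").replace(")", "").replace("-", "_")
    candidate = files("phoreqsar.data") / f"{stem}.phore"
    if not candidate.is_file():
        raise FileNotFoundError(f"no bundled pharmacophore named {name!r}")
    return candidate


def bundled_models() -> list:
    from importlib.resources import files

    out = []
    for entry in sorted(files("phoreqsar.data").iterdir(), key=lambda p: p.name):
        if entry.name.endswith(".phore"):
            out.append(parse_pharmacophore(entry.read_text(), source=entry.name))
    return out


# ---------------------------------------------------------------------------
# mapping and alignment


def enumerate_mappings(
    ligand_features: Sequence[ChemicalFeature],
    model: PharmacophoreModel,
    require_all: bool = True,
) -> list:
    """All injective, type-respecting assignments of model features to ligand
    features, as lists of (model index, ligand index) pairs.

    With ``require_all`` every model feature must be covered; otherwise every
    non-empty subset of model features is considered.  Deterministic order.
    """
    candidates = [
        [j for j, lf in enumerate(ligand_features) if lf.kind == mf.kind]
        for mf in model.features
    ]
    n_model = len(model.features)
    if require_all:
        subsets = [tuple(range(n_model))]
    else:
        subsets = [
            combo
            for size in range(n_model, 0, -1)
            for combo in itertools.combinations(range(n_model), size)
        ]
    results: list = []
    for subset in subsets:
        def backtrack(pos: int, used: set, acc: list) -> None:
            if pos == len(subset):
                results.append(list(acc))
                return
            mi = subset[pos]
            for lj in candidates[mi]:
                if lj in used:
                    continue
                used.add(lj)
                acc.append((mi, lj))
                backtrack(pos + 1, used, acc)
                acc.pop()
                used.remove(lj)

        backtrack(0, set(), [])
    return results


def superpose(
    moving_points: np.ndarray, reference_points: np.ndarray
) -> Tuple[RigidTransform, float]:
    """Kabsch least-squares superposition (proper rotation only).

    Degenerate inputs (< 3 points, collinear sets) still return the
    optimal proper rotation/translation; the rotation is then simply not
    unique.
    """
    p = np.asarray(moving_points, dtype=float)
    q = np.asarray(reference_points, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"point sets differ in shape: {p.shape} vs {q.shape}")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = qc - rot @ pc
    transform = RigidTransform(rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(p) - q) ** 2, axis=1))))
    return transform, rmsd


def _mapping_points(
    pairs: Sequence[Tuple[int, int]],
    ligand_features: Sequence[ChemicalFeature],
    model: PharmacophoreModel,
):
    """Ligand/model point arrays and matching tolerances for one assignment."""
    lig_pts, mod_pts, tols = [], [], []
    for mi, lj in pairs:
        mf = model.features[mi]
        lf = ligand_features[lj]
        lig_pts.append(lf.origin)
        mod_pts.append(mf.origin)
        tols.append(mf.origin_tol)
        if mf.projection is not None:
            if lf.projection is None:
                return None
            lig_pts.append(lf.projection)
            mod_pts.append(mf.projection)
            tols.append(mf.projection_tol)
    return np.array(lig_pts), np.array(mod_pts), np.array(tols)


def fit_value(mapped: FeatureMapping, model: PharmacophoreModel) -> float:
    """Re-evaluate the fit score of a mapping from its stored displacements."""
    return _fit_from_disps(
        mapped.pairs, np.asarray(mapped.disps), model, formula="product"
    )


def _fit_from_disps(
    pairs, disps: np.ndarray, model: PharmacophoreModel, formula: str = "product"
) -> float:
    tols = []
    per_feature_slices = []
    start = 0
    for mi, _ in pairs:
        mf = model.features[mi]
        n_pts = 1 + (mf.projection is not None)
        tols.extend(
            [mf.origin_tol] + ([mf.projection_tol] if mf.projection is not None else [])
        )
        per_feature_slices.append(slice(start, start + n_pts))
        start += n_pts
    tols = np.asarray(tols, dtype=float)
    terms = (disps / tols) ** 2
    if formula == "product":
        return len(pairs) * model.weight * (1.0 - float(terms.sum()))
    if formula == "per_feature_sum":
        return float(
            sum(model.weight * (1.0 - terms[sl].sum()) for sl in per_feature_slices)
        )
    raise ValueError(f"unknown fit formula {formula!r}")


def _evaluate_mapping(
    pairs,
    ligand_features,
    model: PharmacophoreModel,
    formula: str,
) -> Optional[FeatureMapping]:
    pts = _mapping_points(pairs, ligand_features, model)
    if pts is None:
        return None
    lig_pts, mod_pts, tols = pts
    transform, _ = superpose(lig_pts, mod_pts)
    disps = np.linalg.norm(transform.apply(lig_pts) - mod_pts, axis=1)
    if np.any(disps > tols + 1e-9):
        return None
    fit = _fit_from_disps(pairs, disps, model, formula=formula)
    return FeatureMapping(list(pairs), transform, list(disps), fit)


def best_fit(
    molecule: MoleculeRecord,
    model: PharmacophoreModel,
    require_all: bool = False,
    formula: str = "product",
    max_assignments: int = 10000,
) -> Optional[Tuple[int, FeatureMapping]]:
    """Best fit over conformers x assignments x superpositions.

    Returns (conformer index, mapping) or None when no assignment keeps all
    mapped points within their tolerances.  Unmappable molecules are scored
    0 downstream.
    """
    best: Optional[Tuple[int, FeatureMapping]] = None
    for ci in range(len(molecule.conformers)):
        feats = perceive_features(molecule, ci)
        assignments = enumerate_mappings(feats, model, require_all=require_all)
        for pairs in assignments[:max_assignments]:
            mapping = _evaluate_mapping(pairs, feats, model, formula)
            if mapping is None:
                continue
            if best is None or mapping.fit > best[1].fit + 1e-12:
                best = (ci, mapping)
    return best


def screen_molecule(
    molecule: MoleculeRecord,
    model: PharmacophoreModel,
    formula: str = "product",
) -> Tuple[bool, Optional[Tuple[int, FeatureMapping]]]:
    """Hit iff all model features map AND no heavy atom of the aligned pose
    sits inside an exclusion sphere."""
    result = best_fit(molecule, model, require_all=True, formula=formula)
    if result is None:
        return False, None
    ci, mapping = result
    heavy = molecule.heavy_indices()
    coords = mapping.transform.apply(molecule.conformers[ci].coordinates[heavy])
    for center, radius in model.exclusion_spheres:
        if np.any(np.linalg.norm(coords - np.asarray(center), axis=1) < radius):
            return False, None
    return True, result


def f_score(fit_values: Sequence[float], activities: Sequence[float]) -> float:
    """F statistic of the simple regression of activity on fit value.

    F = r^2 (n-2) / (1 - r^2); perfectly collinear data returns the 1e12 cap.
    """
    x = np.asarray(fit_values, dtype=float)
    y = np.asarray(activities, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in fit values or activities")
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = r * r
    if 1.0 - r2 < 1e-15:
        return F_SCORE_CAP
    return min(r2 * (n - 2) / (1.0 - r2), F_SCORE_CAP)
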