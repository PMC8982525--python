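import itertools
import math

import numpy as np
import pytest

from phoreqsar import pharmacophore as P
from phoreqsar.descriptors import Atom, Bond, ChemicalFeature, Conformer, MoleculeRecord
from phoreqsar.synthetic import SimConfig, gen_ligands

from conftest import random_rotation


def feat(kind, origin, projection=None):
    return ChemicalFeature(
        kind, tuple(origin), tuple(projection) if projection is not None else None,
        frozenset({0}),
    )


def simple_model(kinds, points, tol=1.6, weight=1.0):
    feats = [
        P.PharmacophoreFeatureSpec(k, tuple(p), tol) for k, p in zip(kinds, points)
    ]
    return P.PharmacophoreModel("toy", weight, feats)


# ---------------------------------------------------------------------------
# PHORE format


def test_bundled_fixture_fidelity(models):
    h5 = models["Hypo(5-R2-08)"]
    assert [f.kind for f in h5.features] == ["HBA", "Hbic", "Hbic", "RingArom"]
    assert h5.weight == pytest.approx(2.26)
    assert len(h5.exclusion_spheres) == 3
    hba = h5.features[0]
    assert hba.origin == pytest.approx((5.60, -0.30, -0.002))
    assert hba.origin_tol == pytest.approx(1.60)
    assert hba.projection == pytest.approx((7.80, 1.78, -0.04))
    assert hba.projection_tol == pytest.approx(2.20)
    assert h5.exclusion_spheres[0][0] == pytest.approx((-1.73, -0.05, 9.32))
    assert h5.exclusion_spheres[0][1] == pytest.approx(0.6)  # 1.2 A diameter

    h6 = models["Hypo(6-R2-07)"]
    assert [f.kind for f in h6.features] == ["HBA", "HBD", "Hbic", "RingArom"]
    assert h6.weight == pytest.approx(1.97)
    assert len(h6.exclusion_spheres) == 4

    h8 = models["Hypo(8-R3-08)"]
    assert h8.weight == pytest.approx(2.18)
    assert [f.kind for f in h8.features] == ["HBA", "HBD", "Hbic", "RingArom"]
    assert h8.features[3].origin == pytest.approx((-1.42, 0.01, -0.01))


def test_phore_roundtrip_identity(models, tmp_path):
    for name, model in models.items():
        path = tmp_path / "m.phore"
        P.write_pharmacophore(model, path)
        back = P.read_pharmacophore(path)
        assert back.name == model.name
        assert back.weight == pytest.approx(model.weight, abs=1e-6)
        for a, b in zip(back.features, model.features):
            assert a.kind == b.kind
            assert np.allclose(a.origin, b.origin, atol=1e-6)
            if b.projection is not None:
                assert np.allclose(a.projection, b.projection, atol=1e-6)
        assert len(back.exclusion_spheres) == len(model.exclusion_spheres)
        # second roundtrip is bit-stable
        path2 = tmp_path / "m2.phore"
        P.write_pharmacophore(back, path2)
        assert path.read_text() == path2.read_text()


def test_empty_feature_block_rejected():
    text = "MODEL empty\nWEIGHT 1.0\nEND\n"
    with pytest.raises(ValueError, match="empty FEATURE block"):
        P.parse_pharmacophore(text)


def test_malformed_line_reports_lineno():
    text = "MODEL x\nFEATURE HBA nope 0 0 1.6\nEND\n"
    with pytest.raises(ValueError, match=":2:"):
        P.parse_pharmacophore(text)


# ---------------------------------------------------------------------------
# mapping enumeration


def test_require_all_unsatisfiable():
    model = simple_model(["HBA", "HBD"], [(0, 0, 0), (1, 0, 0)])
    ligand = [feat("HBA", (0, 0, 0), (1, 0, 0))]
    assert P.enumerate_mappings(ligand, model, require_all=True) == []


def test_two_by_two_permutations():
    model = simple_model(["HBA", "HBA"], [(0, 0, 0), (1, 0, 0)])
    ligand = [feat("HBA", (0, 0, 0), (0, 0, 1)), feat("HBA", (2, 0, 0), (2, 0, 1))]
    found = P.enumerate_mappings(ligand, model, require_all=True)
    assert len(found) == 2


def test_type_mismatch_no_mapping():
    model = simple_model(["Hbic"], [(0, 0, 0)])
    ligand = [feat("HBA", (0, 0, 0), (1, 0, 0))]
    assert P.enumerate_mappings(ligand, model, require_all=True) == []


def test_partial_mappings_enumerated():
    model = simple_model(["HBA", "Hbic"], [(0, 0, 0), (3, 0, 0)])
    ligand = [feat("HBA", (0, 0, 0), (1, 0, 0))]
    partial = P.enumerate_mappings(ligand, model, require_all=False)
    assert [(0, 0)] in partial
    assert len(partial) == 1


# ---------------------------------------------------------------------------
# superposition


def test_superpose_identity():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    transform, rmsd = P.superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-10)


def test_superpose_rotated_set_exact():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(5, 3))
    rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about Z
    transform, rmsd = P.superpose(pts, pts @ rot.T + 2.0)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.linalg.det(transform.rotation) == pytest.approx(1.0)


def test_superpose_rejects_reflection():
    # mirror-image tetrahedron cannot be matched by a proper rotation
    tetra = np.array(
        [[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
    )
    mirrored = tetra * np.array([1.0, 1.0, -1.0])
    transform, rmsd = P.superpose(tetra, mirrored)
    assert rmsd > 0.5
    assert np.linalg.det(transform.rotation) == pytest.approx(1.0)


def test_superpose_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        P.superpose(np.zeros((3, 3)), np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# fit values


def _mapping(pairs, disps, fit=0.0):
    return P.FeatureMapping(pairs, P.RigidTransform.identity(), list(disps), fit)


def test_fit_perfect_overlap():
    model = simple_model(["Hbic"] * 4, [(i, 0, 0) for i in range(4)], weight=1.0)
    mapping = _mapping([(i, i) for i in range(4)], [0.0] * 4)
    assert P.fit_value(mapping, model) == pytest.approx(4.0)


def test_fit_boundary_zero():
    model = simple_model(["Hbic"], [(0, 0, 0)], tol=1.6)
    mapping = _mapping([(0, 0)], [1.6])
    assert P.fit_value(mapping, model) == pytest.approx(0.0)


def test_fit_hand_example():
    model = simple_model(["Hbic"] * 3, [(i, 0, 0) for i in range(3)], tol=1.0)
    mapping = _mapping([(0, 0), (1, 1), (2, 2)], [0.8, 0.5, 0.0])
    assert P.fit_value(mapping, model) == pytest.approx(0.33)


def test_fit_weight_scales(models):
    model = models["Hypo(8-R3-08)"]
    pairs = [(i, i) for i in range(4)]
    n_points = sum(1 + (f.projection is not None) for f in model.features)
    mapping = _mapping(pairs, [0.0] * n_points)
    assert P.fit_value(mapping, model) == pytest.approx(4 * 2.18)


# ---------------------------------------------------------------------------
# best_fit


def planted(model, mol_id="planted"):
    cfg = SimConfig(seed=0, n_compounds=1)
    return gen_ligands(cfg, model, 1.0)[0]


def test_best_fit_planted_match(models):
    for model in models.values():
        lig = planted(model)
        result = P.best_fit(lig, model, require_all=True)
        assert result is not None
        _, mapping = result
        assert len(mapping.pairs) == len(model.features)
        assert mapping.fit <= len(model.features) * model.weight + 1e-9
        assert mapping.fit > 0


def test_best_fit_absent_when_feature_missing(models):
    model = models["Hypo(6-R2-07)"]  # requires an HBD
    # ligand with no N-H: a lone hydrophobe chain
    rec = MoleculeRecord(
        "nohbd",
        [Atom("C"), Atom("S"), Atom("C")],
        [Bond(0, 1), Bond(1, 2)],
        [Conformer(np.array([[0.0, 0, 0], [3, 0, 0], [6, 0, 0]]))],
    )
    assert P.best_fit(rec, model, require_all=True) is None


def test_single_feature_model_always_maps(models):
    """Alignment can always zero a single point: fit == N * W exactly."""
    model = P.PharmacophoreModel(
        "one", 2.5, [P.PharmacophoreFeatureSpec("Hbic", (4.0, 4.0, 4.0), 1.0)]
    )
    rec = MoleculeRecord(
        "c1", [Atom("C")], [], [Conformer(np.array([[100.0, -50.0, 3.0]]))]
    )
    result = P.best_fit(rec, model, require_all=True)
    assert result is not None
    assert result[1].fit == pytest.approx(1 * 2.5, abs=1e-9)


def test_best_fit_rigid_motion_invariant(models):
    model = models["Hypo(5-R2-08)"]
    lig = planted(model)
    base = P.best_fit(lig, model, require_all=True)[1].fit
    rng = np.random.default_rng(11)
    rot = random_rotation(rng)
    moved = MoleculeRecord(
        lig.id,
        lig.atoms,
        lig.bonds,
        [Conformer(lig.conformers[0].coordinates @ rot.T + np.array([5.0, -3.0, 9.0]))],
    )
    assert P.best_fit(moved, model, require_all=True)[1].fit == pytest.approx(
        base, abs=1e-6
    )


def test_best_fit_per_feature_sum_formula():
    model = simple_model(["Hbic", "Hbic"], [(0.0, 0, 0), (4.0, 0, 0)], tol=2.0)
    rec = MoleculeRecord(
        "two",
        [Atom("C"), Atom("S"), Atom("C")],
        [Bond(0, 1), Bond(1, 2)],
        [Conformer(np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]]))],
    )
    prod = P.best_fit(rec, model, require_all=True, formula="product")
    sumf = P.best_fit(rec, model, require_all=True, formula="per_feature_sum")
    assert prod is not None and sumf is not None
    assert prod[1].fit == pytest.approx(sumf[1].fit, abs=1e-9)  # disps all ~0 here


# ---------------------------------------------------------------------------
# brute-force oracle for best_fit


def brute_best_fit(ligand_feats, model):
    """Exhaustive enumeration with an independent SVD alignment."""
    best = None
    n = len(model.features)
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            lig_idx = range(len(ligand_feats))
            for assign in itertools.permutations(lig_idx, size):
                if any(
                    ligand_feats[l].kind != model.features[m].kind
                    for m, l in zip(subset, assign)
                ):
                    continue
                lig_pts, mod_pts, tols = [], [], []
                ok = True
                for m, l in zip(subset, assign):
                    mf, lf = model.features[m], ligand_feats[l]
                    lig_pts.append(lf.origin)
                    mod_pts.append(mf.origin)
                    tols.append(mf.origin_tol)
                    if mf.projection is not None:
                        if lf.projection is None:
                            ok = False
                            break
                        lig_pts.append(lf.projection)
                        mod_pts.append(mf.projection)
                        tols.append(mf.projection_tol)
                if not ok:
                    continue
                p = np.array(lig_pts)
                q = np.array(mod_pts)
                pc, qc = p.mean(0), q.mean(0)
                u, _, vt = np.linalg.svd((p - pc).T @ (q - qc))
                d = np.sign(np.linalg.det(vt.T @ u.T))
                rot = vt.T @ np.diag([1, 1, d]) @ u.T
                aligned = (p - pc) @ rot.T + qc
                disps = np.linalg.norm(aligned - q, axis=1)
                if np.any(disps > np.array(tols) + 1e-9):
                    continue
                fit = size * model.weight * (1 - float(((disps / tols) ** 2).sum()))
                if best is None or fit > best:
                    best = fit
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_best_fit_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    kinds = ["Hbic", "Hbic", "HBA", "HBD"]
    model_feats = []
    for k in kinds[: 3 + seed % 2]:
        origin = tuple(rng.normal(scale=3, size=3))
        if k == "Hbic":
            model_feats.append(P.PharmacophoreFeatureSpec(k, origin, 1.6))
        else:
            proj = tuple(np.asarray(origin) + rng.normal(scale=1, size=3))
            model_feats.append(
                P.PharmacophoreFeatureSpec(k, origin, 1.6, proj, 2.2)
            )
    model = P.PharmacophoreModel("rand", 1.3, model_feats)
    lig_feats = []
    for k in ["Hbic", "HBA", "HBD", "Hbic"]:
        o = rng.normal(scale=3, size=3)
        proj = o + rng.normal(scale=1, size=3) if k != "Hbic" else None
        lig_feats.append(feat(k, o, proj))

    oracle = brute_best_fit(lig_feats, model)

    # engine path: evaluate the same feature list directly
    best_engine = None
    for pairs in P.enumerate_mappings(lig_feats, model, require_all=False):
        m = P._evaluate_mapping(pairs, lig_feats, model, "product")
        if m is not None and (best_engine is None or m.fit > best_engine):
            best_engine = m.fit
    if oracle is None:
        assert best_engine is None
    else:
        assert best_engine == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# screening


def test_screen_planted_hit(models):
    model = models["Hypo(5-R2-08)"]
    lig = planted(model)
    is_hit, result = P.screen_molecule(lig, model)
    assert is_hit and result is not None


def test_screen_exclusion_sphere_flips_hit(models):
    model = models["Hypo(8-R3-08)"]  # no exclusion spheres in the fixture
    lig = planted(model)
    is_hit, result = P.screen_molecule(lig, model)
    assert is_hit
    ci, mapping = result
    # place an exclusion sphere exactly on an aligned heavy atom
    heavy = lig.heavy_indices()
    aligned = mapping.transform.apply(lig.conformers[ci].coordinates[heavy])
    spiked = P.PharmacophoreModel(
        model.name,
        model.weight,
        model.features,
        [(tuple(aligned[0]), 0.6)],
    )
    assert P.screen_molecule(lig, spiked)[0] is False


def test_screen_partial_mapping_not_hit(models):
    model = models["Hypo(6-R2-07)"]
    rec = MoleculeRecord(
        "partial",
        [Atom("C")],
        [],
        [Conformer(np.array([[0.0, 0.0, 0.0]]))],
    )
    assert P.screen_molecule(rec, model)[0] is False


# ---------------------------------------------------------------------------
# F-score


def test_f_score_formula():
    # construct data with exactly r^2 = 0.5 at n = 12: F = 10
    rng = np.random.default_rng(4)
    x = rng.normal(size=12)
    noise = rng.normal(size=12)
    noise -= noise.mean()
    x_c = x - x.mean()
    # orthogonalize noise against x then mix 50/50 in variance
    noise -= (noise @ x_c) / (x_c @ x_c) * x_c
    y = x_c / np.std(x_c) + noise / np.std(noise)
    assert P.f_score(x, y) == pytest.approx(10.0, abs=1e-6)


def test_f_score_collinear_capped():
    x = np.arange(10.0)
    assert P.f_score(x, 2 * x + 1) == P.F_SCORE_CAP


def test_f_score_constant_errors():
    with pytest.raises(ValueError, match="variance"):
        P.f_score([1.0] * 5, [1, 2, 3, 4, 5])
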