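"""Feature perception, model induction, fit scoring and ROC validation."""

import itertools

import numpy as np
import pytest
from scipy.linalg import svd

from foodvs.confgen import Conformer, ConformerSet
from foodvs.fixtures import (FixtureSpec, make_decoys,
                             make_feature_triad_ligands, triad_template)
from foodvs.pharmacophore import (HitEntry, HitList, PharmacophoreFeature,
                                  PharmacophoreModel, fit_from_displacements,
                                  fit_value, generate_common_feature_models,
                                  merge_hitlists, model_from_json,
                                  model_to_json, perceive_features,
                                  search_database, validate_model)


def brute_force_fit(model, conformer):
    """Independent oracle: enumerate every injective kind-compatible mapping
    with plain itertools; superpose with an SVD written out longhand."""
    feats = perceive_features(conformer)
    kinds = [f.kind for f in feats]
    pts = np.array([f.center for f in feats])
    centers = model.centers
    tol = np.array([f.tolerance for f in model.features])
    best = 0.0
    k = model.n_features
    for perm in itertools.permutations(range(len(feats)), k):
        if any(kinds[p] != model.kinds[i] for i, p in enumerate(perm)):
            continue
        lig = pts[list(perm)]
        a = lig - lig.mean(axis=0)
        b = centers - centers.mean(axis=0)
        u, s, vt = svd(a.T @ b)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        placed = a @ rot.T + centers.mean(axis=0)
        disp = np.linalg.norm(placed - centers, axis=1)
        if np.any(disp > tol):
            continue
        best = max(best, float(np.sum(np.maximum(0, 1 - (disp / tol) ** 2))))
    return best


def point_model(kinds, centers, tolerance=1.6, name="toy"):
    feats = [PharmacophoreFeature(k, np.asarray(c, float), tolerance)
             for k, c in zip(kinds, centers)]
    return PharmacophoreModel(name, feats)


class TestPerception:
    def test_protonated_hordenine_triad(self):
        feats = perceive_features(triad_template())
        kinds = sorted(f.kind for f in feats)
        assert kinds.count("AR") == 1
        assert kinds.count("PI") == 1
        assert kinds.count("HBD") >= 1

    def test_flavylium_cation_is_positive_ionisable(self):
        from foodvs.confgen import generate_conformers

        cs = generate_conformers("Oc1cc(O)c2cc(O)c(-c3cc(O)c(O)c(O)c3)[o+]c2c1",
                                 max_n=1, minimize=False, seed=2)
        kinds = {f.kind for f in perceive_features(cs.conformers[0])}
        assert "PI" in kinds

    def test_methane_has_no_features(self):
        from foodvs.confgen import generate_conformers

        cs = generate_conformers("C", max_n=1, minimize=False, seed=2)
        assert perceive_features(cs.conformers[0]) == []

    def test_aromatic_ring_direction_is_unit_normal(self, template):
        ar = [f for f in perceive_features(template) if f.kind == "AR"][0]
        assert np.linalg.norm(ar.direction) == pytest.approx(1.0, abs=1e-9)


class TestFitValue:
    def test_exact_match_attains_maximum(self, triad_model, actives):
        res = fit_value(triad_model, actives[0])
        assert res.fit == pytest.approx(3.0, abs=1e-9)
        assert res.mapping is not None

    def test_no_compatible_mapping_scores_zero(self, triad_model, decoys):
        res = fit_value(triad_model, decoys[0])
        assert res.fit == 0.0 and res.mapping is None

    def test_closed_form_displacement_formula(self):
        # one feature at half tolerance, others exact
        assert fit_from_displacements([0.0, 0.0, 0.8],
                                      [1.6, 1.6, 1.6]) == pytest.approx(2.75)
        assert fit_from_displacements([0, 0, 0], [1.6] * 3) == 3.0
        assert fit_from_displacements([2.0], [1.6]) == 0.0

    def test_displaced_ligand_scores_strictly_less(self, triad_model, template):
        mol = template.mol.__copy__()
        conf = mol.GetConformer()
        coords = template.coords
        n_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N")
        coords[n_idx] += np.array([0.0, 0.0, 0.8])
        for i, p in enumerate(coords):
            conf.SetAtomPosition(i, p.tolist())
        res = fit_value(triad_model, Conformer("displaced", mol))
        assert 2.75 <= res.fit < 3.0

    @pytest.mark.parametrize("noise", [0.0, 0.3, 0.8])
    def test_matches_brute_force_oracle(self, triad_model, noise, rng):
        base = triad_template()
        coords = base.coords + rng.normal(scale=noise, size=base.coords.shape)
        mol = base.mol.__copy__()
        for i, p in enumerate(coords):
            mol.GetConformer().SetAtomPosition(i, p.tolist())
        probe = Conformer("probe", mol)
        assert fit_value(triad_model, probe).fit == pytest.approx(
            brute_force_fit(triad_model, probe), abs=1e-9)

    def test_fit_invariant_to_rigid_motion(self, triad_model, actives, rng):
        from scipy.spatial.transform import Rotation

        cs = actives[1]
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = ConformerSet(cs.variant_ref,
                             [c.transformed(rot, np.array([5.0, 5.0, -3.0]))
                              for c in cs])
        assert fit_value(triad_model, moved).fit == pytest.approx(
            fit_value(triad_model, cs).fit, abs=1e-6)

    def test_fit_bounded_by_n_features(self, triad_model, actives, decoys):
        for cs in list(actives[:4]) + list(decoys[:4]):
            assert 0.0 <= fit_value(triad_model, cs).fit <= triad_model.n_features


class TestModelInduction:
    def test_shared_triad_recovered(self, triad_model):
        assert set(triad_model.kinds) == {"HBD", "AR", "PI"}

    def test_no_shared_kinds_gives_empty(self):
        # three ligands with disjoint feature kinds at the same spot
        from foodvs.confgen import generate_conformers

        mols = ["CCCCCC", "OCCO", "c1ccccc1"]  # HY only / HBD-HBA / AR only
        confs = [generate_conformers(s, max_n=1, minimize=False, seed=3).conformers[0]
                 for s in mols]
        assert generate_common_feature_models(confs, k_features=3) == []

    def test_max_models_truncation(self, small_spec):
        from foodvs.fixtures import make_training_ligands

        train = make_training_ligands(small_spec, n=4)
        models = generate_common_feature_models(train, k_features=3, max_models=1)
        assert len(models) <= 1

    def test_model_centers_average_training_features(self, small_spec):
        from foodvs.fixtures import make_training_ligands

        train = make_training_ligands(small_spec, n=4)
        model = generate_common_feature_models(train, k_features=3)[0]
        # at zero noise all training ligands coincide: centers must match
        feats = {f.kind: f.center for f in perceive_features(train[0])}
        for f in model.features:
            assert np.allclose(f.center, feats[f.kind], atol=1e-9)

    def test_distance_matrix_consistent_with_centers(self, triad_model):
        mat = triad_model.inter_feature_distances
        assert mat.shape == (3, 3)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        c = triad_model.centers
        assert mat[0, 1] == pytest.approx(np.linalg.norm(c[0] - c[1]))

    def test_json_round_trip(self, triad_model):
        back = model_from_json(model_to_json(triad_model))
        assert back.kinds == triad_model.kinds
        assert np.allclose(back.centers, triad_model.centers)


class TestSearchAndMerge:
    def test_search_counts_and_order(self, triad_model, actives, decoys):
        db = list(actives[:4]) + list(decoys[:6])
        hits = search_database(triad_model, db, fit_cutoff=2.2)
        assert len(hits) == 4
        fits = [e.best_fit for e in hits]
        assert fits == sorted(fits, reverse=True)

    def test_cutoff_zero_keeps_every_mapped_variant(self, triad_model, actives,
                                                    decoys):
        db = list(actives[:3]) + list(decoys[:3])
        hits = search_database(triad_model, db, fit_cutoff=0.0)
        assert len(hits) == 3  # decoys never map (no PI feature)

    def test_cutoff_above_n_features_rejected(self, triad_model):
        with pytest.raises(ValueError):
            search_database(triad_model, [], fit_cutoff=3.1)

    def test_raising_cutoff_never_adds_hits(self, triad_model, small_spec):
        noisy = make_feature_triad_ligands(
            FixtureSpec(seed=11, n_actives=10, noise=0.6))
        sizes = [len(search_database(triad_model, noisy, c))
                 for c in (0.0, 1.0, 2.0, 2.5, 2.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_merge_disjoint_and_idempotent(self):
        a = HitList([HitEntry("a1", "p1", "CCO", {"A": 2.3}),
                     HitEntry("a2", "p2", "CCN", {"A": 2.1}),
                     HitEntry("a3", "p3", "CCC", {"A": 2.0})], ("A",))
        b = HitList([HitEntry("b1", "p4", "CCCl", {"B": 2.6}),
                     HitEntry("b2", "p5", "CCBr", {"B": 2.4})], ("B",))
        assert len(merge_hitlists(a, b)) == 5
        assert len(merge_hitlists(a, a)) == len(a)

    def test_merge_keeps_both_fits_side_by_side(self):
        a = HitList([HitEntry("x", "p", "CCO", {"A": 2.3})], ("A",))
        b = HitList([HitEntry("x", "p", "OCC", {"B": 2.6})], ("B",))
        merged = merge_hitlists(a, b)
        assert len(merged) == 1
        assert merged.entries[0].fits == {"A": 2.3, "B": 2.6}


def mann_whitney_auc(active_scores, decoy_scores):
    """Rank-statistic oracle for the ROC area (ties count half)."""
    wins = ties = 0
    for a in active_scores:
        for d in decoy_scores:
            wins += a > d
            ties += a == d
    return (wins + 0.5 * ties) / (len(active_scores) * len(decoy_scores))


class TestValidation:
    def test_separable_sets_give_perfect_auc(self, triad_model, actives, decoys):
        roc = validate_model(triad_model, list(actives), list(decoys))
        assert roc.auc == 1.0
        assert roc.min_mapped_active_fit == pytest.approx(3.0)

    def test_constant_scores_give_half(self, triad_model, decoys):
        # identical (zero) score for every compound: tie convention
        roc = validate_model(triad_model, list(decoys[:3]), list(decoys[3:6]))
        assert roc.auc == pytest.approx(0.5)

    def test_auc_matches_rank_statistic_oracle(self, triad_model):
        noisy_actives = make_feature_triad_ligands(
            FixtureSpec(seed=13, n_actives=15, noise=0.7))
        noisy_decoys = make_decoys(
            FixtureSpec(seed=13, n_actives=5, n_decoys_per_active=3, noise=0.7),
            mode="scrambled")
        roc = validate_model(triad_model, noisy_actives, noisy_decoys)
        assert roc.auc == pytest.approx(
            mann_whitney_auc(roc.active_fits, roc.decoy_fits), abs=1e-9)

    def test_rank_statistic_oracle_on_printed_example(self):
        assert mann_whitney_auc([2.9, 2.5, 1.0], [2.0, 0.5, 0.0]) \
            == pytest.approx(8 / 9)

    def test_empty_side_rejected(self, triad_model, actives):
        with pytest.raises(ValueError):
            validate_model(triad_model, list(actives), [])
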