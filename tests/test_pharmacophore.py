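"""Featurization rules, Gaussian overlap volumes, Tanimoto and alignment."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from fibrilscreen.chemotypes import Chemotype
from fibrilscreen.pharmacophore import (
    DegenerateVolumeError,
    FeaturelessMoleculeError,
    PharmacophoreFeature,
    PharmacophoreModel,
    align,
    ensure_conformer,
    featurize_molecule,
    gaussian_overlap,
    tanimoto,
)

from conftest import rigid_motion


def feature(kind, x, y, z, alpha=1.0, height=1.0):
    return PharmacophoreFeature(kind, np.array([x, y, z], dtype=float), alpha, height)


def model(mid, *feats):
    return PharmacophoreModel(id=mid, features=list(feats))


def mol3d(smiles):
    return ensure_conformer(Chem.MolFromSmiles(smiles))


def kinds_count(m):
    out = {}
    for f in m.features:
        out[f.kind] = out.get(f.kind, 0) + 1
    return out


class TestFeaturize:
    def test_methanol(self):
        m = featurize_molecule(mol3d("CO"), "methanol")
        counts = kinds_count(m)
        assert counts.get(Chemotype.DONOR) == 1
        assert counts.get(Chemotype.ACCEPTOR) == 1
        assert Chemotype.HYDROPHOBIC not in counts
        donor = next(f for f in m.features if f.kind is Chemotype.DONOR)
        acceptor = next(f for f in m.features if f.kind is Chemotype.ACCEPTOR)
        np.testing.assert_allclose(donor.center, acceptor.center)  # both at the O

    def test_benzene(self):
        m = featurize_molecule(mol3d("c1ccccc1"), "benzene")
        assert kinds_count(m) == {Chemotype.HYDROPHOBIC: 1}
        conf = mol3d("c1ccccc1").GetConformer().GetPositions()
        np.testing.assert_allclose(m.features[0].center, conf.mean(axis=0), atol=1e-6)

    def test_isoxazole_amide_scaffold(self):
        # aryl–isoxazole–glycolic amide–aryl scaffold class
        m = featurize_molecule(mol3d("c1ccc(cc1)-c1cc(NC(=O)COc2ccccc2)on1"))
        counts = kinds_count(m)
        assert counts.get(Chemotype.HYDROPHOBIC, 0) >= 2  # two aryl rings
        assert counts.get(Chemotype.DONOR, 0) >= 1  # amide N–H
        assert counts.get(Chemotype.ACCEPTOR, 0) >= 2  # isoxazole N/O, carbonyl O

    def test_amide_nitrogen_not_acceptor(self):
        m = featurize_molecule(mol3d("CC(=O)NC"), "nma")
        acceptors = [f for f in m.features if f.kind is Chemotype.ACCEPTOR]
        # only the carbonyl O accepts; the amide N is excluded
        assert len(acceptors) == 1

    def test_featureless_molecule_raises(self):
        with pytest.raises(FeaturelessMoleculeError):
            featurize_molecule(mol3d("CC"), "ethane")  # 2-carbon cluster: no feature

    def test_propane_cluster_is_hydrophobic(self):
        m = featurize_molecule(mol3d("CCC"), "propane")
        assert kinds_count(m) == {Chemotype.HYDROPHOBIC: 1}


class TestGaussianOverlap:
    def test_identical_unit_features_closed_form(self):
        a = model("a", feature(Chemotype.DONOR, 0, 0, 0))
        b = model("b", feature(Chemotype.DONOR, 0, 0, 0))
        assert gaussian_overlap(a, b) == pytest.approx((np.pi / 2.0) ** 1.5, rel=1e-12)

    def test_kind_mismatch_is_zero(self):
        a = model("a", feature(Chemotype.DONOR, 0, 0, 0))
        b = model("b", feature(Chemotype.ACCEPTOR, 0, 0, 0))
        assert gaussian_overlap(a, b) == 0.0

    @pytest.mark.parametrize("d,alpha", [(2.0, 0.7), (0.5, 0.7), (1.3, 1.1)])
    def test_matches_numerical_integration(self, d, alpha):
        a = model("a", feature(Chemotype.HYDROPHOBIC, 0, 0, 0, alpha=alpha))
        b = model("b", feature(Chemotype.HYDROPHOBIC, d, 0, 0, alpha=alpha))
        # independent oracle: grid integration of the Gaussian product on a
        # 0.05 Å grid; the integrand is separable so each axis integrates 1-D
        axis = np.arange(-8.0, 8.0 + d, 0.05)
        ix = np.trapezoid(np.exp(-alpha * axis**2 - alpha * (axis - d) ** 2), axis)
        iy = np.trapezoid(np.exp(-2 * alpha * axis**2), axis)
        oracle = ix * iy * iy
        assert gaussian_overlap(a, b) == pytest.approx(oracle, rel=1e-3)


class TestTanimoto:
    def test_self_is_one(self, groove_exemplar):
        from fibrilscreen.pharmacophore import model_from_exemplar

        m = model_from_exemplar(groove_exemplar)
        assert tanimoto(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_kinds_zero(self):
        a = model("a", feature(Chemotype.DONOR, 0, 0, 0))
        b = model("b", feature(Chemotype.HYDROPHOBIC, 0, 0, 0))
        assert tanimoto(a, b) == 0.0

    def test_hand_computed_two_feature_value(self):
        # one coincident matching pair + one distant pair of a different kind
        a = model(
            "a",
            feature(Chemotype.DONOR, 0, 0, 0),
            feature(Chemotype.ACCEPTOR, 10, 0, 0),
        )
        b = model(
            "b",
            feature(Chemotype.DONOR, 0, 0, 0),
            feature(Chemotype.ACCEPTOR, 14, 0, 0),
        )
        g = (np.pi / 2.0) ** 1.5
        vab = g * (1.0 + np.exp(-0.5 * 16.0))  # donors coincide, acceptors 4 Å apart
        vaa = 2 * g + 2 * g * 0.0  # cross terms donor/acceptor don't mix
        expected = vab / (vaa + vaa - vab)
        assert tanimoto(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        kinds = [Chemotype.DONOR, Chemotype.ACCEPTOR, Chemotype.HYDROPHOBIC]
        a = model("a", *[feature(kinds[i % 3], *rng.normal(0, 2, 3)) for i in range(4)])
        b = model("b", *[feature(kinds[i % 3], *rng.normal(0, 2, 3)) for i in range(5)])
        assert abs(tanimoto(a, b) - tanimoto(b, a)) < 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        a = model("a", *[feature(Chemotype.DONOR, *rng.normal(0, 2, 3)) for _ in range(3)])
        b = model("b", *[feature(Chemotype.DONOR, *rng.normal(0, 2, 3)) for _ in range(3)])
        t0 = tanimoto(a, b)
        rot, trans = rigid_motion(rng)
        assert tanimoto(a.transformed(rot, trans), b.transformed(rot, trans)) == pytest.approx(
            t0, abs=1e-10
        )


def _grid_search_oracle(mobile, target, step_deg=10.0):
    """SO(3) grid search with centroid translation, then numeric polish."""
    from scipy.optimize import minimize

    cm, ct = mobile.centers().mean(axis=0), target.centers().mean(axis=0)

    def value(rot):
        trans = ct - rot @ cm
        return tanimoto(mobile.transformed(rot, trans), target)

    best_rot, best_val = np.eye(3), value(np.eye(3))
    grid = np.arange(0.0, 360.0, step_deg)
    grid_b = np.arange(0.0, 180.0 + step_deg, step_deg)
    for a in grid:
        for b in grid_b:
            for c in grid:
                rot = Rotation.from_euler("zyz", [a, b, c], degrees=True).as_matrix()
                v = value(rot)
                if v > best_val:
                    best_val, best_rot = v, rot

    def neg(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        return -tanimoto(mobile.transformed(rot, x[3:]), target)

    x0 = np.concatenate(
        [Rotation.from_matrix(best_rot).as_rotvec(), ct - best_rot @ cm]
    )
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    return max(best_val, -res.fun)


class TestAlign:
    def test_recovers_applied_rigid_motion(self):
        rng = np.random.default_rng(5)
        kinds = [Chemotype.DONOR, Chemotype.ACCEPTOR, Chemotype.HYDROPHOBIC,
                 Chemotype.DONOR, Chemotype.HYDROPHOBIC]
        mobile = model("m", *[feature(k, *rng.normal(0, 3, 3)) for k in kinds])
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        trans = np.array([4.0, -2.0, 1.0])
        target = mobile.transformed(rot, trans)
        result = align(mobile, target, n_starts=8, seed=0)
        assert result.tanimoto >= 0.999
        moved = mobile.transformed(result.rotation, result.translation)
        assert np.abs(moved.centers() - target.centers()).max() <= 1e-3

    def test_single_feature_translation_suffices(self):
        a = model("a", feature(Chemotype.DONOR, 1, 2, 3))
        b = model("b", feature(Chemotype.DONOR, -5, 0, 9))
        result = align(a, b, n_starts=1, seed=0)
        assert result.tanimoto == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        kinds = [Chemotype.DONOR, Chemotype.ACCEPTOR, Chemotype.HYDROPHOBIC,
                 Chemotype.ACCEPTOR, Chemotype.DONOR]
        mobile = model("m", *[feature(k, *rng.normal(0, 2.5, 3)) for k in kinds])
        rot, trans = rigid_motion(rng)
        target = model(
            "t",
            *[
                feature(f.kind, *(rot @ f.center + trans + rng.normal(0, 0.2, 3)))
                for f in mobile.features
            ],
        )
        result = align(mobile, target, n_starts=12, seed=1)
        oracle = _grid_search_oracle(mobile, target)
        assert result.tanimoto >= oracle - 1e-3

    def test_never_below_best_start(self):
        # identity start is already optimal for identical models
        a = model("a", feature(Chemotype.DONOR, 0, 0, 0), feature(Chemotype.ACCEPTOR, 3, 0, 0))
        result = align(a, a, n_starts=4, seed=0)
        assert result.tanimoto == pytest.approx(1.0, abs=1e-9)

    def test_more_starts_never_worse(self):
        rng = np.random.default_rng(3)
        kinds = [Chemotype.DONOR, Chemotype.ACCEPTOR, Chemotype.HYDROPHOBIC]
        a = model("a", *[feature(k, *rng.normal(0, 3, 3)) for k in kinds * 2])
        b = model("b", *[feature(k, *rng.normal(0, 3, 3)) for k in kinds * 2])
        previous = -1.0
        for n_starts in (4, 8, 16):
            t = align(a, b, n_starts=n_starts, seed=9).tanimoto
            assert t >= previous - 1e-12
            previous = t

    def test_stored_transform_reproduces_tanimoto(self):
        rng = np.random.default_rng(21)
        a = model("a", *[feature(Chemotype.DONOR, *rng.normal(0, 2, 3)) for _ in range(3)])
        b = model("b", *[feature(Chemotype.DONOR, *rng.normal(0, 2, 3)) for _ in range(3)])
        result = align(a, b, n_starts=6, seed=0)
        recomputed = tanimoto(a.transformed(result.rotation, result.translation), b)
        assert recomputed == pytest.approx(result.tanimoto, abs=1e-9)


class TestDegenerate:
    def test_empty_model_rejected(self):
        with pytest.raises(FeaturelessMoleculeError):
            PharmacophoreModel(id="x", features=[])
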