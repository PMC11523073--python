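"""The five descriptors: hand-computed oracles, closed forms, invariances."""

import numpy as np
import pytest

import ccsfocus as cf
from ccsfocus.descriptors import molecular_surface_area

from conftest import FA_MASK


def conf(*atoms, charge=-1):
    return cf.Conformer("t", [cf.Atom(s, *xyz) for s, *xyz in atoms],
                        formal_charge=charge)


class TestCenterOfMass:
    def test_single_atom_is_identity(self):
        assert np.allclose(cf.center_of_mass(conf(("O", 1, 2, 3))), [1, 2, 3])

    def test_equal_masses_give_midpoint(self):
        c = conf(("O", 0, 0, 0), ("O", 2, 0, 0))
        assert np.allclose(cf.center_of_mass(c), [1, 0, 0])

    def test_mass_weighting_uses_monoisotopic_masses(self):
        c = conf(("H", 0, 0, 0), ("C", 1, 0, 0))
        expected = 12.0 / (12.0 + 1.007825)
        assert cf.center_of_mass(c)[0] == pytest.approx(expected, abs=1e-6)


class TestMaxDistance:
    def test_single_atom_zero(self):
        assert cf.max_distance_from_com(conf(("C", 5, 5, 5))) == 0.0

    def test_no_heteroatoms_returns_zero_by_convention(self):
        c = conf(("C", 0, 0, 0), ("C", 3, 0, 0), ("H", 5, 0, 0))
        assert cf.max_distance_from_com(c, heteroatoms_only=True) == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(scale=4, size=(3, 3))
        c = conf(*[("O", *xyz) for xyz in coords])
        com = cf.center_of_mass(c)
        expected = max(np.linalg.norm(xyz - com) for xyz in coords)
        assert cf.max_distance_from_com(c) == pytest.approx(expected, abs=1e-12)


class TestMzAnion:
    def test_methane(self, methane):
        # neutral CH4 16.03130 Da minus a proton
        assert cf.mz_anion(methane, geometry_is_neutral=True) == pytest.approx(
            15.0240, abs=2e-4
        )

    def test_oleic_acid_formula(self):
        # deprotonated geometry C18H33O2 -> neutral C18H34O2 -> m/z 281.2486
        atoms = (
            [("C", float(i), 0, 0) for i in range(18)]
            + [("H", float(i), 2, 0) for i in range(33)]
            + [("O", 0, -2, 0), ("O", 1, -2, 0)]
        )
        assert cf.mz_anion(conf(*atoms)) == pytest.approx(281.2486, abs=2e-4)

    def test_adding_carbon_adds_exactly_12(self, methane):
        base = cf.mz_anion(methane)
        plus = cf.Conformer(
            "p", list(methane.atoms) + [cf.Atom("C", 9, 9, 9)], formal_charge=0
        )
        assert cf.mz_anion(plus) - base == pytest.approx(12.0, abs=1e-12)


class TestHeteroatomCount:
    @pytest.mark.parametrize(
        "formula, expected",
        [({"C": 18, "H": 34, "O": 2}, 2), ({"C": 6, "H": 14}, 0),
         ({"C": 12, "H": 21, "N": 1, "O": 6}, 7)],
    )
    def test_counts_non_ch_atoms(self, formula, expected):
        atoms, i = [], 0
        for sym, count in formula.items():
            for _ in range(count):
                atoms.append((sym, float(i), 0, 0))
                i += 1
        assert cf.count_heteroatoms(conf(*atoms)) == expected


class TestSurfaceArea:
    def test_single_sphere_matches_analytic_area(self):
        # C with 1.4 A probe: 4 pi (1.70+1.40)^2
        area = molecular_surface_area(conf(("C", 0, 0, 0)))
        assert area == pytest.approx(4 * np.pi * 3.1**2, rel=5e-3)

    def test_disjoint_spheres_add(self):
        area = molecular_surface_area(conf(("C", 0, 0, 0), ("C", 100, 0, 0)))
        assert area == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=5e-3)

    def test_two_intersecting_spheres_match_closed_form(self):
        # equal expanded radii R at distance d: each sphere loses a cap of
        # height h = R - d/2 and area 2 pi R h
        R, d = 1.70 + 1.4, 1.5
        h = R - d / 2
        expected = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
        area = molecular_surface_area(conf(("C", 0, 0, 0), ("C", d, 0, 0)))
        assert area == pytest.approx(expected, rel=1e-2)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(11)
        atoms = [("C", *xyz) for xyz in rng.normal(scale=3, size=(20, 3))]
        a1 = molecular_surface_area(conf(*atoms), points_per_atom=960)
        a2 = molecular_surface_area(conf(*atoms), points_per_atom=1920)
        assert abs(a2 - a1) / a1 < 5e-3


@pytest.fixture(scope="module")
def chain():
    spec = cf.SyntheticSpec(18, (9,), n_conformers=1, seed=3)
    return cf.generate_chain_conformer(spec, 0)


class TestFeaturizeInvariance:

    def test_translation_leaves_vector_unchanged(self, chain):
        f0 = cf.featurize(chain)
        shifted = chain.with_coordinates(chain.coordinates + 5.0)
        f1 = cf.featurize(shifted)
        assert np.allclose(f0.as_array(), f1.as_array(), rtol=1e-9)

    def test_rotation_leaves_vector_within_sampling_tolerance(self, chain):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
        rotated = chain.with_coordinates(chain.coordinates @ R.T)
        f0, f1 = cf.featurize(chain), cf.featurize(rotated)
        assert f0.mz == f1.mz and f0.n_het == f1.n_het
        assert f1.d_atom_max == pytest.approx(f0.d_atom_max, rel=1e-9)
        assert f1.d_het_max == pytest.approx(f0.d_het_max, rel=1e-9)
        # fixed-lattice sphere sampling carries ~1% orientation dependence
        assert f1.msa == pytest.approx(f0.msa, rel=2e-2)

    def test_het_distance_never_exceeds_atom_distance(self):
        for i in range(10):
            c = cf.generate_chain_conformer(
                cf.SyntheticSpec(20, (8, 11, 14), n_conformers=10, seed=8), i
            )
            f = cf.featurize(c)
            assert f.d_het_max <= f.d_atom_max


class TestFeatureShiftSurvey:
    def _fv(self, d_het, d_atom, msa):
        return cf.FeatureVector(mz=280.0, d_het_max=d_het, d_atom_max=d_atom,
                                n_het=2, msa=msa)

    def test_identical_collections_shift_zero(self):
        ref = [self._fv(5, 8, 600), self._fv(6, 9, 620)]
        rep = cf.feature_shift_survey(ref, list(ref))
        assert all(v == pytest.approx(0.0) for v in rep.as_dict().values())

    def test_doubled_query_means_give_plus_100(self):
        ref = [self._fv(5, 8, 600)]
        qry = [self._fv(10, 16, 1200)]
        rep = cf.feature_shift_survey(ref, qry)
        assert all(v == pytest.approx(100.0) for v in rep.as_dict().values())

    def test_hand_computed_percentages(self):
        ref = [self._fv(10, 20, 100)]
        qry = [self._fv(11, 25, 90)]
        rep = cf.feature_shift_survey(ref, qry)
        assert rep.d_het_max == pytest.approx(10.0)
        assert rep.d_atom_max == pytest.approx(25.0)
        assert rep.msa == pytest.approx(-10.0)


def test_feature_vector_mask_selects_columns():
    fv = cf.FeatureVector(mz=281.2, d_het_max=5.0, d_atom_max=9.0, n_het=2, msa=640.0)
    assert np.allclose(fv.as_array(FA_MASK), [281.2, 5.0, 9.0, 640.0])
    with pytest.raises(ValueError):
        cf.FeatureVector(mz=281.2, d_het_max=10.0, d_atom_max=9.0, n_het=2, msa=640.0)
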