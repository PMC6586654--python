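"""Model rasterization, rigid-body docking and model-to-map FSC."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.spatial.transform import Rotation

from ipet import fitting, synthetic as syn
from ipet.io import AtomicModel, Volume3D
from ipet.reconstruct import resolution_at_threshold


def make_model(coords, masses=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    masses = np.ones(n) if masses is None else np.asarray(masses, float)
    return AtomicModel(
        coords=coords, masses=masses,
        elements=np.array(["C"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        backbone=np.ones(n, dtype=bool),
    )


@pytest.fixture(scope="module")
def asymmetric_body():
    """Tri-lobe body with three unequal arms: no rotational symmetry."""
    rng = np.random.default_rng(5)
    pts = []
    for center, radius, count in (((0, 0, 0), 12, 120),
                                  ((26, 0, 0), 9, 60),
                                  ((0, 20, 8), 6, 30)):
        p = rng.normal(size=(count * 3, 3))
        p = p[np.linalg.norm(p, axis=1) <= 1.0][:count] * radius
        pts.append(p + np.asarray(center, float))
    return make_model(np.concatenate(pts))


class TestRasterize:
    def test_single_atom_gives_centered_blob(self):
        model = make_model([[0.0, 0.0, 0.0]], [12.0])
        vol = fitting.rasterize_model(model, 2.0, 15.0, box_size=32,
                                      origin=np.full(3, -32.0))
        com = np.array([(vol.values * g).sum() / vol.values.sum()
                        for g in np.meshgrid(*[np.arange(32)] * 3,
                                             indexing="ij")])
        np.testing.assert_allclose(com, 16.0, atol=0.1)

    def test_map_integral_scales_with_mass(self):
        model = make_model([[0, 0, 0], [10, 0, 0]], [12.0, 16.0])
        heavy = replace(model, masses=2 * model.masses)
        a = fitting.rasterize_model(model, 2.0, 12.0, box_size=32,
                                    origin=np.full(3, -32.0))
        b = fitting.rasterize_model(heavy, 2.0, 12.0, box_size=32,
                                    origin=np.full(3, -32.0))
        assert b.values.sum() == pytest.approx(2 * a.values.sum(), rel=1e-6)

    def test_atoms_20A_apart_resolvable_at_15A(self):
        """Two equal Gaussians of FWHM 15 A at 20 A separation show a dip
        between two local maxima (analytic: separation > 2 sigma)."""
        model = make_model([[-10, 0, 0], [10, 0, 0]])
        vol = fitting.rasterize_model(model, 2.0, 15.0, box_size=40,
                                      origin=np.full(3, -40.0))
        profile = vol.values[:, 20, 20]
        peaks = [i for i in range(1, 39)
                 if profile[i] > profile[i - 1] and profile[i] > profile[i + 1]]
        assert len(peaks) == 2

    def test_resolution_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fitting.rasterize_model(make_model([[0, 0, 0]]), 2.0, 3.0)


class TestRigidFit:
    def test_identity_recovered_from_own_rasterization(self, asymmetric_body):
        target = fitting.rasterize_model(asymmetric_body, 3.0, 15.0,
                                         box_size=48, origin=np.full(3, -72.0))
        transform, corr = fitting.rigid_fit(asymmetric_body, target, 20.0,
                                            15.0, resolution_A=15.0)
        assert corr >= 0.99
        assert transform.rotation_angle_deg() < 5.0
        assert np.linalg.norm(transform.translation) < 3.0

    def test_translated_target_recovered(self, asymmetric_body):
        target = fitting.rasterize_model(asymmetric_body, 3.0, 15.0,
                                         box_size=48, origin=np.full(3, -72.0))
        shifted = target.with_values(np.roll(target.values, 4, axis=0))
        transform, corr = fitting.rigid_fit(asymmetric_body, shifted, 20.0,
                                            20.0, resolution_A=15.0)
        np.testing.assert_allclose(transform.translation, [12.0, 0, 0],
                                   atol=3.0)
        assert corr > 0.95

    def test_rotated_target_recovered_within_5_degrees(self, asymmetric_body):
        rot = Rotation.from_euler("zyz", [0, 25, 0], degrees=True)
        pivot = asymmetric_body.mass_center()
        moved = replace(asymmetric_body,
                        coords=(asymmetric_body.coords - pivot) @ rot.as_matrix().T
                        + pivot)
        target = fitting.rasterize_model(moved, 3.0, 15.0, box_size=48,
                                         origin=np.full(3, -72.0))
        transform, corr = fitting.rigid_fit(asymmetric_body, target, 15.0,
                                            15.0, resolution_A=15.0)
        rel = transform.matrix @ rot.as_matrix().T
        miss = np.degrees(np.linalg.norm(
            Rotation.from_matrix(rel).as_rotvec()))
        assert miss < 5.0
        assert corr > 0.95

    def test_empty_map_rejected(self, asymmetric_body):
        with pytest.raises(ValueError):
            fitting.rigid_fit(asymmetric_body,
                              Volume3D(np.zeros((16, 16, 16)), 3.0), 20, 10)

    def test_coarse_step_bound(self, asymmetric_body):
        with pytest.raises(ValueError):
            fitting.rigid_fit(asymmetric_body,
                              Volume3D(np.ones((16, 16, 16)), 3.0),
                              angular_step_deg=45.0,
                              translation_search_A=10.0)


class TestMultibody:
    def test_intact_model_fits_as_identities(self):
        spec = syn.build_phantom_spec("X")
        model, part = syn.phantom_to_model(spec)
        target = fitting.rasterize_model(model, 4.5, 18.0, box_size=48,
                                         origin=np.full(3, -108.0))
        result = fitting.fit_multibody(
            model, part, target, fitting.default_igg_linkage(),
            angular_step_deg=20.0, translation_search_A=15.0,
            max_rotation_deg=30.0, resolution_A=18.0)
        for label, t in result.transforms.items():
            assert np.linalg.norm(t.translation) < 6.0, label
        assert all(result.connectivity_ok.values())

    def test_internal_geometry_never_deformed(self):
        spec = syn.build_phantom_spec("X")
        model, part = syn.phantom_to_model(spec)
        target = fitting.rasterize_model(model, 4.5, 18.0, box_size=48,
                                         origin=np.full(3, -108.0))
        result = fitting.fit_multibody(model, part, target, [],
                                       angular_step_deg=20.0,
                                       translation_search_A=15.0,
                                       max_rotation_deg=30.0,
                                       resolution_A=18.0)
        mask = part.mask("Fab1")
        before = model.coords[mask]
        after = result.fitted_model.coords[mask]
        d_before = np.linalg.norm(before[0] - before[-1])
        d_after = np.linalg.norm(after[0] - after[-1])
        assert d_after == pytest.approx(d_before, abs=1e-9)

    def test_tight_linkage_limit_flags_disconnection(self):
        spec = syn.build_phantom_spec("X")
        model, part = syn.phantom_to_model(spec)
        target = fitting.rasterize_model(model, 4.5, 18.0, box_size=48,
                                         origin=np.full(3, -108.0))
        rules = [fitting.LinkageRule("Fab1", "HalfFcA_CH2", 1.0)]
        result = fitting.fit_multibody(model, part, target, rules,
                                       angular_step_deg=20.0,
                                       translation_search_A=10.0,
                                       max_rotation_deg=20.0,
                                       resolution_A=18.0)
        assert result.connectivity_ok[("Fab1", "HalfFcA_CH2")] is False


class TestModelMapFSC:
    def test_own_rasterization_gives_unity_fsc(self, asymmetric_body):
        target = fitting.rasterize_model(asymmetric_body, 3.0, 15.0,
                                         box_size=48, origin=np.full(3, -72.0))
        curve, r05, r0143 = fitting.model_map_fsc(asymmetric_body, target,
                                                  15.0)
        assert np.all(curve.correlation > 0.999)
        assert r05 == pytest.approx(2 * 3.0)  # warning path: never crosses

    def test_added_noise_coarsens_the_crossing(self, asymmetric_body, rng):
        target = fitting.rasterize_model(asymmetric_body, 3.0, 15.0,
                                         box_size=48, origin=np.full(3, -72.0))
        noisy = target.with_values(
            target.values + rng.normal(0, 0.5 * target.values.std(),
                                       target.values.shape))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, clean05, _ = fitting.model_map_fsc(asymmetric_body, target, 15.0)
            _, noisy05, _ = fitting.model_map_fsc(asymmetric_body, noisy, 15.0)
        assert noisy05 > clean05

    def test_misplaced_model_scores_worse(self, asymmetric_body, rng):
        """A correctly placed model beats 10 A random kicks in >= 95% of
        trials (here: all of a seeded batch)."""
        target = fitting.rasterize_model(asymmetric_body, 3.0, 15.0,
                                         box_size=48, origin=np.full(3, -72.0))

        def mean_fsc(model):
            curve, _, _ = fitting.model_map_fsc(model, target, 15.0)
            return curve.correlation[1:10].mean()

        base = mean_fsc(asymmetric_body)
        worse = 0
        for seed in range(20):
            kick = np.random.default_rng(seed).normal(size=3)
            kick = 10.0 * kick / np.linalg.norm(kick)
            kicked = replace(asymmetric_body,
                             coords=asymmetric_body.coords + kick)
            worse += mean_fsc(kicked) <= base
        assert worse >= 19
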