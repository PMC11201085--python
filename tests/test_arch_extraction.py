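import numpy as np
import pytest

from archform.arch_extraction import (
    ExtractionError,
    extract_arch_forms,
    fit_arch_polynomial,
    identify_landmarks,
    layer_soft_tissue,
    segment_teeth,
    select_lilo,
    smoothness_score,
)
from archform.geometry import DentalMesh
from archform.synthetic_data import SyntheticCohortConfig, generate_synthetic_cast

from conftest import grid_surface, tube_surface


def match_rate(pred, gt):
    """Fraction of vertices whose label agrees after majority mapping."""
    mapping = {}
    for t in range(pred.max() + 1):
        vals, cnt = np.unique(gt[pred == t], return_counts=True)
        mapping[t] = vals[np.argmax(cnt)]
    mapped = np.array([mapping.get(x, -1) if x >= 0 else -1 for x in pred])
    return (mapped == gt).mean()


class TestSegmentTeeth:
    def test_all_crowns_found_zero_noise(self, zero_noise_cast):
        seg = segment_teeth(zero_noise_cast.mesh)
        assert len(seg.teeth) == 12

    def test_vertex_labels_match_ground_truth(self, noisy_cast):
        seg = segment_teeth(noisy_cast.mesh)
        assert len(seg.teeth) == 12
        assert match_rate(seg.vertex_labels, noisy_cast.true_vertex_labels) >= 0.95

    def test_partition_exhaustive_and_disjoint(self, zero_noise_cast):
        seg = segment_teeth(zero_noise_cast.mesh)
        n_tooth_faces = sum(len(t.faces) for t in seg.teeth)
        assert n_tooth_faces + len(seg.remainder.faces) == len(zero_noise_cast.mesh.faces)

    def test_flat_plane_has_no_teeth(self):
        x = np.linspace(0, 10, 30)
        mesh = grid_surface(x, lambda xx, z: np.full_like(xx, z), np.linspace(0, 10, 30))
        # reinterpret rows as y: build plane z=0 directly
        v = mesh.vertices.copy()
        v[:, 2] = 0.0
        flat = DentalMesh(vertices=v, faces=mesh.faces, jaw="mandible")
        seg = segment_teeth(flat)
        assert len(seg.teeth) == 0
        assert len(seg.remainder.faces) == len(flat.faces)

    def test_caps_without_contour_raise(self):
        # gentle Gaussian bumps on a large sheet: strongly convex caps but no
        # concave crease sharp enough to form a separating contour
        g = np.linspace(-30, 30, 121)
        X, Y = np.meshgrid(g, g)
        Z = np.zeros_like(X)
        for cx in (-20, -10, 0, 10, 20):
            for cy in (-20, -10, 0, 10, 20):
                Z += 4.0 * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 2.5**2))
        v = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        faces = []
        n = len(g)
        for r in range(n - 1):
            a = r * n + np.arange(n - 1)
            faces.append(np.column_stack([a, a + 1, a + 1 + n]))
            faces.append(np.column_stack([a, a + 1 + n, a + n]))
        mesh = DentalMesh(vertices=v, faces=np.vstack(faces), jaw="mandible")
        with pytest.raises(ExtractionError):
            segment_teeth(mesh)


class TestLandmarks:
    def test_zero_noise_landmarks_exact(self, zero_noise_cast):
        seg = segment_teeth(zero_noise_cast.mesh)
        lm = identify_landmarks(seg.teeth)
        got = np.asarray(lm.points)
        true = np.asarray(zero_noise_cast.true_landmarks.points)
        fwd = np.abs(got - true).max()
        rev = np.abs(got[::-1] - true).max()  # walk direction is arbitrary
        assert min(fwd, rev) < 1e-9

    def test_mirrored_cast_mirrors_landmarks(self, zero_noise_cast):
        v = zero_noise_cast.mesh.vertices.copy()
        v[:, 0] *= -1
        mirrored = DentalMesh(vertices=v, faces=zero_noise_cast.mesh.faces, jaw="mandible")
        seg = segment_teeth(mirrored)
        lm = identify_landmarks(seg.teeth)
        true = np.asarray(zero_noise_cast.true_landmarks.points) * np.array([-1.0, 1.0, 1.0])
        got = np.asarray(lm.points)
        d = np.linalg.norm(got[:, None] - true[None, :], axis=2)
        assert d.min(axis=1).max() < 1e-9  # same landmark set, mirrored

    def test_noisy_landmarks_within_twice_noise(self, dental_templates, alveolar_templates):
        sd = 0.02
        for seed in (11, 12):
            cfg = SyntheticCohortConfig(shape_noise_sd=sd)
            cast = generate_synthetic_cast(
                dental_templates[3], alveolar_templates[3], config=cfg, seed=seed
            )
            seg = segment_teeth(cast.mesh)
            lm = identify_landmarks(seg.teeth)
            got = np.asarray(lm.points)
            tpl = dental_templates[3]
            # displacement from the noise-free template positions
            disp = np.abs(got[:, 1] - tpl.evaluate(got[:, 0]))
            assert disp.mean() <= 2 * sd * tpl.width

    def test_empty_input_raises(self):
        with pytest.raises(ExtractionError):
            identify_landmarks([])


class TestLayering:
    def test_cylinder_layers_are_identical_circles(self):
        mesh = tube_surface(lambda z: 10.0, np.linspace(0, 5, 26))
        contours = layer_soft_tissue(mesh, n_layers=5)
        assert contours.valid.all()
        means = []
        for layer in contours.layers:
            r = np.linalg.norm(layer - layer.mean(axis=0), axis=1)
            assert np.allclose(r, 10.0, atol=0.1)  # inscribed-polygon shrinkage
            means.append(r.mean())
        assert np.ptp(means) < 1e-6  # identical circles across heights
        assert np.allclose(contours.smoothness, contours.smoothness[0], atol=1e-6)

    def test_cone_top_layers_invalid(self):
        # cone tapers to its apex at z=1; slices requested up to z=2 are empty
        mesh = tube_surface(lambda z: max(1e-3, 1.0 - z), np.linspace(0, 1, 21))
        contours = layer_soft_tissue(mesh, n_layers=8, top=2.0, bottom=0.0)
        assert (~contours.valid).any() and contours.valid.any()
        assert np.isinf(contours.smoothness[~contours.valid]).all()
        # invalid layers are the ones above the apex
        assert contours.heights[~contours.valid].min() > 1.0

    def test_too_few_layers_raise(self, zero_noise_cast):
        with pytest.raises(ExtractionError):
            layer_soft_tissue(zero_noise_cast.mesh, n_layers=1)


class TestSmoothness:
    def test_straight_segment_scores_zero(self):
        pts = np.column_stack([np.linspace(0, 5, 40), np.linspace(1, 3, 40)])
        assert smoothness_score(pts) < 1e-12

    def test_uniform_circle_scores_zero(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        assert smoothness_score(np.column_stack([np.cos(t), np.sin(t)])) < 1e-9

    def test_corrugation_increases_score(self):
        from archform.arch_extraction import resample_polyline

        x = np.linspace(0, 50, 500)
        smooth = resample_polyline(np.column_stack([x, 20 * np.sin(np.pi * x / 50)]), 200)
        wavy = resample_polyline(
            np.column_stack([x, 20 * np.sin(np.pi * x / 50) + 0.5 * np.sign(np.sin(2 * x))]), 200
        )
        assert smoothness_score(wavy) > smoothness_score(smooth)

    def test_too_few_points_raise(self):
        with pytest.raises(ExtractionError):
            smoothness_score([[0, 0], [1, 1]])


class TestSelectLilo:
    def test_planted_layer_recovered(self, zero_noise_extraction, zero_noise_cast):
        assert zero_noise_extraction.lilo_index == zero_noise_cast.true_lilo_layer

    def test_tie_breaks_toward_apical(self, zero_noise_extraction):
        contours = zero_noise_extraction.contours
        tied = type(contours)(
            heights=contours.heights,
            raw_layers=contours.raw_layers,
            layers=contours.layers,
            smoothness=np.ones(contours.n_layers),
            valid=np.ones(contours.n_layers, dtype=bool),
        )
        assert select_lilo(tied) == contours.n_layers - 1

    def test_single_valid_layer(self, zero_noise_extraction):
        contours = zero_noise_extraction.contours
        valid = np.zeros(contours.n_layers, dtype=bool)
        valid[3] = True
        only = type(contours)(
            heights=contours.heights,
            raw_layers=contours.raw_layers,
            layers=contours.layers,
            smoothness=contours.smoothness,
            valid=valid,
        )
        assert select_lilo(only) == 3

    def test_no_valid_layers_raise(self, zero_noise_extraction):
        contours = zero_noise_extraction.contours
        none_valid = type(contours)(
            heights=contours.heights,
            raw_layers=contours.raw_layers,
            layers=contours.layers,
            smoothness=contours.smoothness,
            valid=np.zeros(contours.n_layers, dtype=bool),
        )
        with pytest.raises(ExtractionError):
            select_lilo(none_valid)


class TestPolynomialFit:
    def test_seven_points_of_parabola_interpolated(self):
        x = np.linspace(-3, 3, 7)
        curve = fit_arch_polynomial(np.column_stack([x, x**2]))
        assert curve.rms_residual < 1e-9

    def test_degree6_round_trip(self):
        rng = np.random.default_rng(0)
        coef = rng.normal(0, 1, 7) / (30.0 ** np.arange(7))
        x = np.linspace(-17, 17, 50)
        y = np.polynomial.polynomial.polyval(x, coef)
        curve = fit_arch_polynomial(np.column_stack([x, y]))
        scale = np.abs(coef) + np.abs(coef).max() * 1e-3
        assert np.max(np.abs(curve.coefficients - coef) / scale) < 1e-6

    def test_too_few_distinct_x_raise(self):
        x = np.linspace(0, 1, 6)
        with pytest.raises(ExtractionError):
            fit_arch_polynomial(np.column_stack([x, x]))


class TestPipelineDeterminism:
    def test_repeated_extraction_identical(self, noisy_cast, noisy_extraction):
        res2 = extract_arch_forms(noisy_cast.mesh)
        assert res2.lilo_index == noisy_extraction.lilo_index
        assert np.array_equal(
            res2.dental_curve.coefficients, noisy_extraction.dental_curve.coefficients
        )
        assert np.array_equal(
            res2.dentoalveolar_curve.coefficients,
            noisy_extraction.dentoalveolar_curve.coefficients,
        )
        assert np.array_equal(
            np.asarray(res2.landmarks.points), np.asarray(noisy_extraction.landmarks.points)
        )
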