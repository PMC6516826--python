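"""Morphometry: SWC parsing, mirroring, PCA axes/extents, shape
classification, orientation, laminar spread, and primary-dendrite counts."""

import io

import numpy as np
import pandas as pd
import pytest

from icvip.errors import ConfigurationError, FormatError
from icvip.morphometry import (
    NeuronMorphology,
    classify_shape,
    count_primary_dendrites,
    laminar_spread,
    mirror_to_left,
    morphometric_profile,
    orientation_angle,
    principal_axes,
    read_swc,
    write_swc,
)
from icvip.stats import proportion
from icvip.synth.morph import ArborConfig, generate_morphology
from icvip.synth.cohort import generate_morph_cohort

from oracles import brute_force_pca

MINIMAL_SWC = """# soma plus two dendrite points
1 1 0 0 0 8 -1
2 3 10 0 0 1 1
3 3 20 0 0 1 2
"""


def cloud_morphology(coords, side="left"):
    rows = [(1, 1, 0.0, 0.0, 0.0, 8.0, -1)]
    for k, p in enumerate(np.atleast_2d(coords), start=2):
        rows.append((k, 3, p[0], p[1], p[2] if len(p) > 2 else 0.0, 1.0, 1))
    nodes = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z",
                                        "radius", "parent"])
    return NeuronMorphology(nodes=nodes, side=side)


class TestSWCIO:
    def test_minimal_file_parses(self):
        m = read_swc(io.StringIO(MINIMAL_SWC))
        assert count_primary_dendrites(m) == 1
        assert m.dendrite_coords().shape == (2, 3)

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        m = generate_morphology(ArborConfig(), seed=0)
        path = tmp_path / "cell.swc"
        write_swc(m, path)
        m2 = read_swc(path)
        np.testing.assert_allclose(m2.dendrite_coords(),
                                   m.dendrite_coords(), atol=1e-5)
        assert count_primary_dendrites(m2) == count_primary_dendrites(m)

    def test_orphan_parent_reports_line_number(self):
        bad = "1 1 0 0 0 8 -1\n2 3 1 0 0 1 99\n"
        with pytest.raises(FormatError, match="line 2"):
            read_swc(io.StringIO(bad))

    def test_cyclic_parents_rejected(self):
        bad = "1 3 0 0 0 1 2\n2 3 1 0 0 1 1\n"
        with pytest.raises(FormatError, match="cyclic"):
            read_swc(io.StringIO(bad))

    def test_non_numeric_field_reports_line(self):
        bad = "1 1 0 0 0 8 -1\n2 3 x 0 0 1 1\n"
        with pytest.raises(FormatError, match="line 2"):
            read_swc(io.StringIO(bad))


class TestMirror:
    def test_left_neuron_unchanged(self):
        m = cloud_morphology([[50.0, 10.0, 0.0]], side="left")
        m2 = mirror_to_left(m)
        np.testing.assert_array_equal(m2.dendrite_coords(),
                                      m.dendrite_coords())

    def test_right_neuron_reflected_about_soma(self):
        m = cloud_morphology([[50.0, 10.0, 0.0]], side="right")
        m2 = mirror_to_left(m)
        np.testing.assert_allclose(m2.dendrite_coords()[0],
                                   [-50.0, 10.0, 0.0])
        assert m2.side == "left"

    def test_flip_twice_is_identity(self):
        m = generate_morphology(ArborConfig(side="right"), seed=1)
        once = mirror_to_left(m)
        twice = mirror_to_left(once)
        np.testing.assert_array_equal(once.dendrite_coords(),
                                      twice.dendrite_coords())

    def test_unknown_side_rejected(self):
        m = cloud_morphology([[1.0, 0.0, 0.0]])
        m.side = None
        with pytest.raises(ConfigurationError):
            mirror_to_left(m)


class TestPrincipalAxes:
    def test_points_on_x_axis(self):
        coords = np.column_stack([np.linspace(-50, 50, 100), np.zeros(100)])
        ax = principal_axes(coords, dims=2)
        np.testing.assert_allclose(np.abs(ax.directions[:, 0]), [1.0, 0.0],
                                   atol=1e-12)
        assert ax.extents[1] == pytest.approx(0.0, abs=1e-9)

    def test_axis_aligned_rectangle_extents(self):
        x = np.linspace(-150, 150, 61)
        y = np.linspace(-50, 50, 21)
        boundary = np.vstack([
            np.column_stack([x, np.full_like(x, -50.0)]),
            np.column_stack([x, np.full_like(x, 50.0)]),
            np.column_stack([np.full_like(y, -150.0), y]),
            np.column_stack([np.full_like(y, 150.0), y])])
        ax = principal_axes(boundary, dims=2)
        assert ax.extents[0] == pytest.approx(300.0, rel=1e-9)
        assert ax.extents[1] == pytest.approx(100.0, rel=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        cov = np.diag([300.0, 100.0, 50.0]) ** 2
        coords = rng.multivariate_normal(np.zeros(3), cov, size=500)
        for dims in (2, 3):
            ax = principal_axes(coords, dims=dims)
            evals, evecs, extents = brute_force_pca(coords[:, :dims])
            np.testing.assert_allclose(ax.eigenvalues, evals, rtol=1e-9)
            np.testing.assert_allclose(ax.extents, extents, rtol=1e-9)
            for k in range(dims):
                dot = abs(ax.directions[:, k] @ evecs[:, k])
                assert dot == pytest.approx(1.0, abs=1e-9)

    def test_generator_ratio_matches_direct_pca(self):
        cfg = ArborConfig(axis_lengths=(300.0, 100.0, 50.0),
                          points_per_dendrite=100, n_primary_dendrites=5)
        m = generate_morphology(cfg, seed=7)
        _, _, extents = brute_force_pca(m.dendrite_coords())
        ax = principal_axes(m, dims=3)
        np.testing.assert_allclose(ax.extents, extents, rtol=1e-9)
        assert ax.extents[0] / ax.extents[1] == pytest.approx(3.0, rel=0.15)


class TestClassifyShape:
    def test_threshold_at_three(self):
        from icvip.morphometry import PrincipalAxes
        mk = lambda r: PrincipalAxes(np.eye(3), np.array([r, 1.0, 0.5]),
                                     np.array([r, 1.0, 0.5]))
        assert classify_shape(mk(2.99))[0] == "stellate"
        assert classify_shape(mk(3.00))[0] == "disc_shaped"

    def test_perfect_line_is_disc_shaped(self):
        coords = np.column_stack([np.linspace(0, 100, 50),
                                  np.zeros(50), np.zeros(50)])
        shape, ratio = classify_shape(principal_axes(coords, dims=3))
        assert shape == "disc_shaped"
        assert np.isinf(ratio)

    def test_high_aspect_generator_is_reliably_disc(self):
        hits = 0
        cfg = ArborConfig(axis_lengths=(120.0, 30.0, 20.0),
                          points_per_dendrite=200, n_primary_dendrites=5)
        for seed in range(100):
            m = generate_morphology(cfg, seed=seed)
            if classify_shape(principal_axes(m, dims=3))[0] == "disc_shaped":
                hits += 1
        assert hits >= 95

    def test_fixture_cohort_reproduces_93_percent_stellate(self):
        # 39 ratios < 3 and 3 ratios >= 3 -> 93% stellate
        from icvip.morphometry import PrincipalAxes
        ratios = list(np.linspace(1.1, 2.8, 39)) + [3.2, 3.6, 4.1]
        classes = [classify_shape(PrincipalAxes(
            np.eye(3), np.array([r, 1.0, 0.5]), np.array([r, 1.0, 0.5])))[0]
            for r in ratios]
        n_stellate = sum(c == "stellate" for c in classes)
        assert proportion(n_stellate, 42, decimals=0).percent == 93.0


class TestOrientation:
    def test_horizontal_segment_is_zero_mod_180(self):
        coords = np.column_stack([np.linspace(-50, 50, 60), np.zeros(60)])
        ang, within = orientation_angle(principal_axes(coords, dims=2))
        assert min(ang, 180.0 - ang) == pytest.approx(0.0, abs=1e-6)
        assert not within

    def test_45_degree_diagonal_is_within_lamina(self):
        # dorsolateral (display up-right) = raw (x, -y) direction
        u = np.linspace(-50, 50, 60)
        coords = np.column_stack([u, -u])
        ang, within = orientation_angle(principal_axes(coords, dims=2))
        assert ang == pytest.approx(45.0, abs=1e-6)
        assert within

    def test_rotated_cloud_recovers_angle(self):
        cfg = ArborConfig(axis_lengths=(200.0, 60.0, 40.0),
                          orientation_deg=30.0, points_per_dendrite=150)
        m = generate_morphology(cfg, seed=5)
        ang, _ = orientation_angle(principal_axes(m, dims=2))
        assert ang == pytest.approx(30.0, abs=2.0)

    def test_rotation_equivariance_and_ratio_invariance(self):
        base = generate_morphology(ArborConfig(
            axis_lengths=(200.0, 60.0, 40.0), orientation_deg=20.0,
            points_per_dendrite=150), seed=9).dendrite_coords()
        ax0 = principal_axes(base, dims=2)
        ang0, _ = orientation_angle(ax0)
        ratio0 = ax0.extents[0] / ax0.extents[1]
        theta = 25.0
        th = np.radians(theta)
        # display-convention rotation: (x, -y) rotated CCW by theta
        x, yd = base[:, 0], -base[:, 1]
        rot = np.column_stack([x * np.cos(th) - yd * np.sin(th),
                               -(x * np.sin(th) + yd * np.cos(th))])
        ax1 = principal_axes(rot, dims=2)
        ang1, _ = orientation_angle(ax1)
        assert (ang1 - ang0) % 180.0 == pytest.approx(theta, abs=1e-6)
        assert ax1.extents[0] / ax1.extents[1] == pytest.approx(ratio0,
                                                                rel=1e-9)

    def test_translation_invariance_of_descriptors(self):
        base = generate_morphology(ArborConfig(), seed=3).dendrite_coords()
        shifted = base + np.array([123.0, -456.0, 78.0])
        ax0, ax1 = (principal_axes(c, dims=3) for c in (base, shifted))
        np.testing.assert_allclose(ax0.extents, ax1.extents, rtol=1e-9)
        np.testing.assert_allclose(
            laminar_spread(base), laminar_spread(shifted), rtol=1e-9)

    def test_mirror_maps_angle_to_180_minus(self):
        cfg = ArborConfig(axis_lengths=(200.0, 60.0, 40.0),
                          orientation_deg=30.0, points_per_dendrite=150,
                          side="right")
        m = generate_morphology(cfg, seed=4)
        ang0, _ = orientation_angle(principal_axes(m, dims=2))
        m2 = mirror_to_left(m)
        ang1, _ = orientation_angle(principal_axes(m2, dims=2))
        assert (ang0 + ang1) % 180.0 == pytest.approx(0.0, abs=1e-6) or \
            ang0 + ang1 == pytest.approx(180.0, abs=1e-6)
        ax0 = principal_axes(m, dims=3)
        ax1 = principal_axes(m2, dims=3)
        assert ax0.extents[0] / ax0.extents[1] == pytest.approx(
            ax1.extents[0] / ax1.extents[1], rel=1e-9)
        assert laminar_spread(m) != laminar_spread(m2) or True  # spread preserved below
        # spread is preserved only up to the lamina reflection; compare the
        # mirrored spread against the spread of the 135-degree lamina
        assert laminar_spread(m2, 45.0) == pytest.approx(
            laminar_spread(m, 135.0), rel=1e-9)

    def test_isotropic_cloud_is_indeterminate(self):
        coords = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        ang, within = orientation_angle(principal_axes(coords, dims=2))
        assert ang is None and within is None


class TestLaminarSpread:
    def test_segment_in_the_lamina_has_zero_spread(self):
        u = np.linspace(-50, 50, 30)
        coords = np.column_stack([u, -u])   # display 45-degree direction
        assert laminar_spread(coords, 45.0) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_segment_spreads_fully(self):
        u = np.linspace(-50, 50, 30) / np.sqrt(2.0)
        coords = np.column_stack([u, u])    # display -45 deg = normal
        assert laminar_spread(coords, 45.0) == pytest.approx(100.0, rel=1e-9)

    def test_matches_per_point_projection_oracle(self, rng):
        coords = rng.normal(size=(200, 3)) * [120.0, 40.0, 30.0]
        th = np.radians(45.0)
        normal = np.array([-np.sin(th), -np.cos(th)])
        proj = coords[:, :2] @ normal
        assert laminar_spread(coords, 45.0) == pytest.approx(
            proj.max() - proj.min(), rel=1e-12)


class TestPrimaryDendrites:
    def test_five_stem_star(self):
        cfg = ArborConfig(n_primary_dendrites=5, points_per_dendrite=10)
        assert count_primary_dendrites(generate_morphology(cfg, seed=0)) == 5

    def test_single_stem_chain_with_branches(self):
        rows = [(1, 1, 0.0, 0.0, 0.0, 8.0, -1)]
        nid = 2
        for k in range(10):          # chain with side branches off node 2
            rows.append((nid, 3, float(k + 1), 0.0, 0.0, 1.0,
                         1 if nid == 2 else nid - 1))
            nid += 1
        nodes = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z",
                                            "radius", "parent"])
        m = NeuronMorphology(nodes=nodes, side="left")
        assert count_primary_dendrites(m) == 1

    def test_no_soma_is_an_error(self):
        coords = cloud_morphology([[1.0, 0.0, 0.0]])
        coords.nodes.loc[coords.nodes["type"] == 1, "type"] = 3
        coords.nodes["parent"] = -1
        with pytest.raises(FormatError):
            count_primary_dendrites(coords)

    def test_cohort_stem_counts_center_on_published_mean(self):
        cohort = generate_morph_cohort(n=60, n_disc=0, seed=2)
        stems = [count_primary_dendrites(m) for m, _ in cohort]
        sem = 1.38 / np.sqrt(len(stems))
        assert abs(np.mean(stems) - 4.77) <= 3.0 * sem + 0.5  # rounding bias


class TestProfile:
    def test_profile_covers_all_descriptors(self):
        m, targets = generate_morph_cohort(n=1, n_disc=0, seed=5)[0]
        prof = morphometric_profile(m)
        assert prof.shape_class == "stellate"
        assert prof.length_width_ratio == pytest.approx(targets["ratio"],
                                                        rel=0.15)
        assert prof.n_primary_dendrites == targets["n_primary_dendrites"]
        assert prof.laminar_spread > 0
        assert 0.0 <= prof.orientation_deg < 180.0
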