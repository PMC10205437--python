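import math

import numpy as np
import pytest

import dais
from dais.errors import DegenerateInputError
from dais.persistent_homology import compute_diagram, diagrams_to_dataframe

from _oracles import bottleneck_leq, full_complex_persistence
from conftest import random_cloud


def finite_multiset(diagram):
    return sorted(
        (f.dimension, f.birth, f.death)
        for f in diagram.features
        if math.isfinite(f.death)
    )


def full_multiset(diagram):
    return sorted(
        (f.dimension, f.birth, f.death) for f in diagram.features
    )


def assert_multisets_close(a, b, tol=1e-9):
    assert len(a) == len(b)
    for (d1, b1, x1), (d2, b2, x2) in zip(a, b):
        assert d1 == d2
        assert b1 == pytest.approx(b2, abs=tol)
        if math.isinf(x1) or math.isinf(x2):
            assert x1 == x2
        else:
            assert x1 == pytest.approx(x2, abs=tol)


class TestSmallExactCases:
    def test_equilateral_triangle_rips(self):
        """Loop of an equilateral triangle (side 2 Å) is born at radius
        1.0 Å — half the edge length under the radius convention."""
        pts = np.array([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]], float)
        d = compute_diagram(pts, filtration="rips")
        loops = d.in_dimension(1)
        assert len(loops) == 1
        assert loops[0].birth == pytest.approx(1.0, abs=1e-12)
        assert loops[0].generators == frozenset({0, 1, 2})

    def test_circle_20_points_rips(self):
        """A 20-point circle has exactly one persistent loop whose
        generator set is all 20 points."""
        phi = 2 * np.pi * np.arange(20) / 20
        pts = np.stack([10 * np.cos(phi), 10 * np.sin(phi), 0 * phi], axis=1)
        d = compute_diagram(pts, max_dimension=1, filtration="rips")
        loops = [f for f in d.in_dimension(1) if f.persistence > 0.05]
        assert len(loops) == 1
        assert loops[0].generators == frozenset(range(20))

    def test_fewer_than_two_points_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_diagram(np.zeros((1, 3)))

    def test_duplicate_points_deduplicated(self):
        pts = np.array(
            [[0, 0, 0], [0, 0, 0], [2, 0, 0], [1, 1.7, 0.2], [1, 0.6, 1.9]],
            float,
        )
        d = compute_diagram(pts, filtration="rips")
        # 4 unique points -> 4 dim-0 classes (3 finite + 1 essential)
        assert len(d.in_dimension(0)) == 4


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_rips_engine_matches_bruteforce(self, seed):
        """Engine diagrams equal an independent full-complex boundary-
        matrix reduction, including zero-persistence pairs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        pts = random_cloud(rng, n)
        got = full_multiset(compute_diagram(pts, filtration="rips"))
        want = full_complex_persistence(pts, max_dim=2, flavor="rips")
        assert_multisets_close(got, want, tol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_alpha_matches_cech_oracle(self, seed):
        """Alpha and Cech complexes are homotopy equivalent at every
        radius, so their persistence diagrams coincide for clouds in
        general position."""
        rng = np.random.default_rng(100 + seed)
        pts = random_cloud(rng, 8)
        got = compute_diagram(pts, filtration="alpha")
        want = full_complex_persistence(pts, max_dim=2, flavor="cech")
        # alpha carries only Delaunay simplices: zero-persistence Cech
        # pairs may differ; compare features with persistence > 1e-9
        g = [x for x in full_multiset(got) if not math.isclose(x[1], x[2] if math.isfinite(x[2]) else x[1] + 1, abs_tol=1e-9)]
        w = [x for x in want if not math.isclose(x[1], x[2] if math.isfinite(x[2]) else x[1] + 1, abs_tol=1e-9)]
        assert_multisets_close(g, w, tol=1e-7)


class TestInvariance:
    @pytest.mark.parametrize("filtration,tol", [("rips", 1e-9), ("alpha", 1e-6)])
    def test_rigid_motion_invariance(self, filtration, tol):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        pts = random_cloud(rng, 12 if filtration == "rips" else 25)
        R = Rotation.random(random_state=8).as_matrix()
        moved = pts @ R.T + np.array([5.0, -3.0, 11.0])
        assert_multisets_close(
            full_multiset(compute_diagram(pts, filtration=filtration)),
            full_multiset(compute_diagram(moved, filtration=filtration)),
            tol=tol,
        )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        pts = random_cloud(rng, 10)
        perm = rng.permutation(10)
        assert_multisets_close(
            full_multiset(compute_diagram(pts, filtration="rips")),
            full_multiset(compute_diagram(pts[perm], filtration="rips")),
            tol=1e-9,
        )

    def test_bottleneck_stability_smoke(self):
        """Perturbing every point by <= eps moves each matched diagram
        point by <= 2*eps in max-norm."""
        eps = 0.01
        rng = np.random.default_rng(7)
        pts = random_cloud(rng, 20)
        noise = rng.uniform(-1, 1, size=pts.shape)
        noise *= eps / np.abs(noise).max()
        d1 = compute_diagram(pts, filtration="alpha")
        d2 = compute_diagram(pts + noise, filtration="alpha")
        for dim in (0, 1, 2):
            a = [
                (f.birth, f.death)
                for f in d1.in_dimension(dim)
                if math.isfinite(f.death)
            ]
            b = [
                (f.birth, f.death)
                for f in d2.in_dimension(dim)
                if math.isfinite(f.death)
            ]
            assert bottleneck_leq(a, b, 2 * eps)
            assert bottleneck_leq(b, a, 2 * eps)


class TestDiagramSeries:
    def test_one_diagram_per_frame(self, ring_ensemble):
        sel = dais.select_cas(ring_ensemble, ring_ensemble)
        dgs = dais.compute_diagram_series(ring_ensemble, sel)
        assert [d.frame_index for d in dgs] == list(range(ring_ensemble.n_frames))

    def test_static_ensemble_identical_diagrams(self):
        ens = dais.make_ring_ensemble(
            dais.FixtureSpec(n_residues=16, n_frames=4, jitter_sd=0.0)
        )
        sel = dais.select_cas(ens, ens)
        dgs = dais.compute_diagram_series(ens, sel)
        ref = sorted(
            (f.dimension, f.birth, f.death) for f in dgs[0].features
        )
        for d in dgs[1:]:
            got = sorted((f.dimension, f.birth, f.death) for f in d.features)
            assert got == ref

    def test_jittered_ring_always_has_a_loop(self, ring_ensemble):
        sel = dais.select_cas(ring_ensemble, ring_ensemble)
        dgs = dais.compute_diagram_series(ring_ensemble, sel)
        for d in dgs:
            loops = [f for f in d.in_dimension(1) if f.persistence > 0.05]
            assert len(loops) >= 1

    def test_generators_are_residue_keys(self, ring_ensemble):
        sel = dais.select_cas(ring_ensemble, ring_ensemble)
        d = dais.compute_diagram_series(ring_ensemble, sel)[0]
        universe = set(sel.residue_keys)
        for f in d.features:
            assert f.generators <= universe
            if f.dimension >= 1:
                assert f.generators

    def test_dataframe_serialization(self, ring_ensemble):
        sel = dais.select_cas(ring_ensemble, ring_ensemble)
        dgs = dais.compute_diagram_series(ring_ensemble, sel)[:2]
        df = diagrams_to_dataframe(dgs)
        assert set(df.columns) == {
            "frame", "feature_id", "dimension", "birth", "death", "generators"
        }
        assert (df.death >= df.birth).all()
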