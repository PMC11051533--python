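"""Landmark catalog, propagation, expert means and extremum refinement."""

import numpy as np
import pytest

from kneemorph.frames import ReferenceFrame
from kneemorph.landmarks import (
    LandmarkDefinition,
    LandmarkSet,
    annotate_subject,
    build_seed_table,
    expert_mean_landmarks,
    load_landmark_catalog,
    optimize_extremum,
    propagate_landmark,
)
from kneemorph.registration import CorrespondedMesh


CANON = ReferenceFrame.canonical()


class TestCatalog:
    def test_full_catalog_shape(self):
        catalog = load_landmark_catalog()
        assert len(catalog) == 23
        assert sum(d.bone == "femur" for d in catalog.values()) == 15
        assert sum(d.bone == "tibia" for d in catalog.values()) == 8
        # constructed landmarks are propagate-only
        propagate_only = {a for a, d in catalog.items() if not d.is_extremum}
        assert propagate_only == {
            "FMCPP", "FLCPP", "FMCIP", "FMCEP", "FLCIP", "FLCEP", "TMCA", "TLCA"}

    def test_inconsistent_definition_rejected(self):
        with pytest.raises(ValueError):
            LandmarkDefinition("X", "femur", "x", "d", refine_axis="y", refine_sense=None)
        with pytest.raises(ValueError):
            LandmarkDefinition("X", "femur", "x", "d", refine_axis="w", refine_sense="max")


class TestPropagation:
    def test_identity_correspondence(self, femur_phantom):
        mesh, truth = femur_phantom
        cm = CorrespondedMesh.from_mesh(mesh)
        lset = LandmarkSet("s", "obs1", dict(truth.landmarks))
        out = propagate_landmark(lset, cm, cm)
        for a in lset.acronyms():
            err = np.linalg.norm(out[a] - lset[a])
            assert err < 0.2  # only the on-surface projection of the truth point

    def test_landmark_at_vertex_maps_to_same_vertex(self, sphere):
        src = CorrespondedMesh.from_mesh(sphere)
        dst_mesh = sphere.vertices * 1.3 + np.array([1.0, 2.0, 3.0])
        dst = CorrespondedMesh(dst_mesh, sphere.faces, "dst", np.zeros(sphere.n_vertices))
        k = 42
        lset = LandmarkSet("s", "obs1", {"P": sphere.vertices[k]})
        out = propagate_landmark(lset, src, dst)
        np.testing.assert_allclose(out["P"], dst.vertices[k], atol=1e-9)

    def test_far_landmark_warns_and_projects(self, sphere):
        cm = CorrespondedMesh.from_mesh(sphere)
        lset = LandmarkSet("s", "obs1", {"P": np.array([30.0, 0.0, 0.0])})
        with pytest.warns(RuntimeWarning):
            out = propagate_landmark(lset, cm, cm)
        assert np.linalg.norm(out["P"]) <= 10.001  # on the sphere surface

    def test_topology_mismatch_rejected(self, sphere):
        from conftest import icosphere

        a = CorrespondedMesh.from_mesh(sphere)
        b = CorrespondedMesh.from_mesh(icosphere(subdivisions=2))
        lset = LandmarkSet("s", "obs1", {"P": sphere.vertices[0]})
        with pytest.raises(ValueError):
            propagate_landmark(lset, a, b)


class TestExpertMean:
    def test_single_observation_identity(self):
        s = LandmarkSet("s", "obs1", {"A": [1.0, 2.0, 3.0]})
        out = expert_mean_landmarks([s])
        np.testing.assert_allclose(out["A"], [1, 2, 3])

    def test_repeats_are_pre_averaged(self):
        """Three repeats at the origin must not outweigh one at (3,0,0)."""
        sets = [LandmarkSet("s", "obs1", {"A": [0.0, 0, 0]}) for _ in range(3)]
        sets.append(LandmarkSet("s", "obs2", {"A": [3.0, 0, 0]}))
        out = expert_mean_landmarks(sets)
        np.testing.assert_allclose(out["A"], [1.5, 0, 0])

    def test_three_observers_give_centroid(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        sets = [LandmarkSet("s", f"obs{i}", {"A": p}) for i, p in enumerate(pts)]
        out = expert_mean_landmarks(sets)
        np.testing.assert_allclose(out["A"], pts.mean(axis=0))

    def test_missing_acronym_reported(self):
        sets = [
            LandmarkSet("s", "obs1", {"A": [0.0, 0, 0], "B": [1.0, 0, 0]}),
            LandmarkSet("s", "obs2", {"A": [0.0, 0, 0]}),
        ]
        with pytest.raises(ValueError, match="obs2"):
            expert_mean_landmarks(sets)

    def test_mixed_subjects_rejected(self):
        sets = [LandmarkSet("s1", "o", {"A": [0.0, 0, 0]}),
                LandmarkSet("s2", "o", {"A": [0.0, 0, 0]})]
        with pytest.raises(ValueError):
            expert_mean_landmarks(sets)


class TestSeedTable:
    def test_landmark_at_vertex(self, sphere):
        lset = LandmarkSet("m", "MEAN", {"A": sphere.vertices[7]})
        seeds = build_seed_table(sphere, lset)
        assert seeds["A"] == 7

    def test_face_centroid_snaps_to_a_face_vertex(self, sphere):
        face = sphere.faces[0]
        centroid = sphere.vertices[face].mean(axis=0)
        seeds = build_seed_table(sphere, LandmarkSet("m", "MEAN", {"A": centroid}))
        assert seeds["A"] in set(face.tolist())

    def test_matches_brute_force_nearest(self, femur_phantom):
        mesh, _ = femur_phantom
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.normal(0, 25, 3)
            seeds = build_seed_table(
                mesh, LandmarkSet("m", "MEAN", {"A": p}))
            brute = int(np.linalg.norm(mesh.vertices - p, axis=1).argmin())
            assert seeds["A"] == brute


def _definition(axis="z", sense="min"):
    return LandmarkDefinition("TEST", "femur", "test", "d",
                              refine_axis=axis, refine_sense=sense)


class TestOptimizeExtremum:
    def test_sphere_lower_cap_finds_south_pole(self, sphere):
        south = int(sphere.vertices[:, 2].argmin())
        lower_cap = np.flatnonzero(sphere.vertices[:, 2] < -8.0)
        seed = int(lower_cap[0])
        got = optimize_extremum(sphere, seed, _definition("z", "min"), CANON,
                                search_radius=np.pi * 10)
        assert got == south

    def test_seed_at_extremum_is_fixpoint(self, sphere):
        south = int(sphere.vertices[:, 2].argmin())
        assert optimize_extremum(sphere, south, _definition("z", "min"), CANON, 5.0) == south

    def test_idempotent_on_phantom(self, femur_phantom):
        mesh, truth = femur_phantom
        catalog = load_landmark_catalog()
        for acr in ("FMCP", "FLCP", "FMCD", "Notch", "FMTA"):
            seed = int(np.linalg.norm(mesh.vertices - truth.landmarks[acr], axis=1).argmin())
            first = optimize_extremum(mesh, seed, catalog[acr], CANON, 10.0)
            second = optimize_extremum(mesh, first, catalog[acr], CANON, 10.0)
            assert first == second, acr

    def test_never_less_extreme_than_seed(self, femur_phantom):
        mesh, _ = femur_phantom
        rng = np.random.default_rng(2)
        d = _definition("y", "min")
        for seed in rng.integers(0, mesh.n_vertices, 20):
            got = optimize_extremum(mesh, int(seed), d, CANON, 8.0)
            assert mesh.vertices[got, 1] <= mesh.vertices[seed, 1]

    def test_monotone_in_radius(self, femur_phantom):
        mesh, truth = femur_phantom
        d = _definition("y", "min")
        seed = int(np.linalg.norm(mesh.vertices - truth.landmarks["FMCP"], axis=1).argmin())
        prev = np.inf
        for radius in (2.0, 5.0, 10.0, 20.0):
            got = optimize_extremum(mesh, seed, d, CANON, radius)
            assert mesh.vertices[got, 1] <= prev + 1e-12
            prev = mesh.vertices[got, 1]

    def test_contract_errors(self, sphere):
        with pytest.raises(ValueError):
            optimize_extremum(sphere, 0, _definition(None, None).__class__(
                "X", "femur", "x", "d"), CANON, 5.0)
        with pytest.raises(IndexError):
            optimize_extremum(sphere, 10 ** 6, _definition(), CANON, 5.0)

    def test_secondary_axis_breaks_exact_ties(self):
        """Flat strip: all vertices share y, ties resolved along secondary x."""
        from kneemorph.mesh import TriangleMesh

        v = np.array([[x, 0.0, 0.0] for x in range(5)] +
                     [[x + 0.5, 1.0, 0.0] for x in range(4)])
        f = np.array([[i, i + 1, i + 5] for i in range(4)] +
                     [[i + 1, i + 6, i + 5] for i in range(3)])
        mesh = TriangleMesh(v, f)
        d = LandmarkDefinition("T", "tibia", "t", "d", refine_axis="y",
                               refine_sense="min", secondary_axis="x",
                               secondary_sense="max")
        got = optimize_extremum(mesh, 0, d, CANON, search_radius=100.0)
        assert got == 4  # y == 0 row, largest x


class TestAnnotateSubject:
    def test_mean_shape_subject_reproduces_refined_seeds(self, femur_phantom):
        mesh, truth = femur_phantom
        catalog = {a: d for a, d in load_landmark_catalog().items() if d.bone == "femur"}
        cm = CorrespondedMesh.from_mesh(mesh, "self")
        seeds = build_seed_table(mesh, truth.landmark_set())
        first = annotate_subject(cm, seeds, catalog, truth.frame)
        seeds2 = build_seed_table(mesh, first)
        second = annotate_subject(cm, seeds2, catalog, truth.frame)
        for a in first.acronyms():
            np.testing.assert_allclose(first[a], second[a], atol=1e-9)

    def test_all_outputs_are_mesh_vertices(self, femur_phantom):
        mesh, truth = femur_phantom
        catalog = {a: d for a, d in load_landmark_catalog().items() if d.bone == "femur"}
        cm = CorrespondedMesh.from_mesh(mesh, "self")
        seeds = build_seed_table(mesh, truth.landmark_set())
        out = annotate_subject(cm, seeds, catalog, truth.frame)
        assert out.observer == "AUTO"
        for a in out.acronyms():
            d = np.linalg.norm(mesh.vertices - out[a], axis=1).min()
            assert d == 0.0

    def test_refinement_recovers_displaced_extremum(self, femur_phantom):
        """Seeding a few vertices away must still land on the condylar apex."""
        mesh, truth = femur_phantom
        catalog = load_landmark_catalog()
        cm = CorrespondedMesh.from_mesh(mesh, "self")
        apex = int(np.linalg.norm(mesh.vertices - truth.landmarks["FMCP"], axis=1).argmin())
        refined_apex = optimize_extremum(mesh, apex, catalog["FMCP"], truth.frame, 10.0)
        # displace the seed ~3 mm along the surface
        from kneemorph.mesh import geodesic_neighborhood

        nb = geodesic_neighborhood(mesh, apex, 3.5)
        displaced = int(nb.members[np.argmax(nb.distances)])
        got = optimize_extremum(mesh, displaced, catalog["FMCP"], truth.frame, 10.0)
        assert got == refined_apex
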