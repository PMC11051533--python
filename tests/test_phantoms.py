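"""Phantom generator: determinism, ground-truth realisation, deformation,
simulated observers."""

import numpy as np
import pytest

from kneemorph.landmarks import load_landmark_catalog
from kneemorph.phantoms import (
    PhantomSpec,
    deform_knee,
    deform_phantom,
    generate_knee,
    generate_phantom,
    simulate_observers,
)


class TestGenerate:
    def test_same_seed_bitwise_identical(self):
        spec = PhantomSpec(bone="femur_like", direction_jitter=0.03, seed=7)
        m1, t1 = generate_phantom(spec)
        m2, t2 = generate_phantom(PhantomSpec(bone="femur_like", direction_jitter=0.03, seed=7))
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        np.testing.assert_array_equal(m1.faces, m2.faces)
        for a in t1.landmarks:
            np.testing.assert_array_equal(t1.landmarks[a], t2.landmarks[a])

    def test_different_seed_differs_under_jitter(self):
        m1, _ = generate_phantom(PhantomSpec(direction_jitter=0.03, seed=1))
        m2, _ = generate_phantom(PhantomSpec(direction_jitter=0.03, seed=2))
        assert not np.allclose(m1.vertices, m2.vertices)

    def test_scaling_doubles_truth_measurements(self):
        _, t1 = generate_phantom(PhantomSpec(bone="femur_like", scale=1.0))
        _, t2 = generate_phantom(PhantomSpec(bone="femur_like", scale=2.0,
                                             mesh_resolution=4.0))
        for k, v in t1.measurements.items():
            assert t2.measurements[k] == pytest.approx(2 * v, rel=1e-4)

    def test_every_truth_landmark_near_mesh(self, femur_phantom, tibia_phantom):
        for mesh, truth in (femur_phantom, tibia_phantom):
            edge = mesh.mean_edge_length()
            for a, p in truth.landmarks.items():
                d = np.linalg.norm(mesh.vertices - p, axis=1).min()
                assert d <= edge, f"{a}: {d:.2f} mm from mesh"

    def test_extremum_landmarks_are_local_extrema_on_mesh(self, femur_phantom):
        """The defining property: each lobe realises its landmark as a local
        extremum of the frame coordinate."""
        from kneemorph.frames import AXIS_INDEX

        mesh, truth = femur_phantom
        catalog = load_landmark_catalog()
        adjacency = mesh.vertex_adjacency
        for a, d in catalog.items():
            if d.bone != "femur" or not d.is_extremum:
                continue
            v = int(np.linalg.norm(mesh.vertices - truth.landmarks[a], axis=1).argmin())
            sign = 1.0 if d.refine_sense == "max" else -1.0
            score = sign * mesh.vertices[:, AXIS_INDEX[d.refine_axis]]
            nbs = adjacency.indices[adjacency.indptr[v]: adjacency.indptr[v + 1]]
            # within one ring of the snapped vertex, nothing is much more extreme
            assert score[nbs].max() <= score[v] + 0.35 * mesh.mean_edge_length(), a

    def test_resolution_guard(self):
        with pytest.raises(ValueError, match="too coarse"):
            generate_phantom(PhantomSpec(bone="tibia_like", mesh_resolution=6.0))

    def test_knee_truth_covers_full_catalog(self, base_knee):
        assert set(base_knee.truth.landmarks) == set(load_landmark_catalog())
        assert len(base_knee.truth.measurements) == 15


class TestDeform:
    def test_zero_magnitude_is_identity(self, femur_phantom):
        mesh, truth = femur_phantom
        out_mesh, out_truth = deform_phantom(mesh, truth, 0.0, 20.0, seed=3)
        np.testing.assert_array_equal(out_mesh.vertices, mesh.vertices)
        for a in truth.landmarks:
            np.testing.assert_array_equal(out_truth.landmarks[a], truth.landmarks[a])

    def test_rigid_only_preserves_measurements(self, femur_phantom):
        mesh, truth = femur_phantom
        _, out_truth = deform_phantom(mesh, truth, 1.0, 20.0, seed=3, rigid_only=True)
        for k, v in truth.measurements.items():
            assert out_truth.measurements[k] == pytest.approx(v, abs=1e-9)

    def test_displacement_rms_matches_request(self, femur_phantom):
        mesh, truth = femur_phantom
        magnitude = 2.0
        disp = []
        for seed in range(5):
            out_mesh, _ = deform_phantom(mesh, truth, magnitude, 20.0, seed=seed)
            d = np.linalg.norm(out_mesh.vertices - mesh.vertices, axis=1)
            disp.append(np.sqrt(np.mean(d ** 2)))
        assert np.mean(disp) == pytest.approx(magnitude, rel=1e-6)

    def test_truth_landmark_displacement_tracks_field(self, femur_phantom):
        mesh, truth = femur_phantom
        rms = []
        for seed in range(5):
            _, out_truth = deform_phantom(mesh, truth, 2.0, 20.0, seed=seed)
            d = [np.linalg.norm(out_truth.landmarks[a] - truth.landmarks[a])
                 for a in truth.landmarks]
            rms.append(np.sqrt(np.mean(np.square(d))))
        assert abs(np.mean(rms) - 2.0) / 2.0 < 0.30

    def test_smoothness_guard(self, femur_phantom):
        mesh, truth = femur_phantom
        with pytest.raises(ValueError, match="smoothness"):
            deform_phantom(mesh, truth, 1.0, 0.5 * mesh.mean_edge_length(), seed=0)

    def test_excessive_magnitude_flags_flips(self, femur_phantom):
        mesh, truth = femur_phantom
        with pytest.raises(ValueError, match="flips"):
            deform_phantom(mesh, truth, 80.0, 10.0, seed=1)

    def test_knee_deformation_shares_one_field(self, base_knee):
        out = deform_knee(base_knee, 2.0, 20.0, seed=5, subject="d")
        assert out.femur.n_vertices == base_knee.femur.n_vertices
        assert out.tibia.n_vertices == base_knee.tibia.n_vertices
        moved_f = np.linalg.norm(out.femur.vertices - base_knee.femur.vertices, axis=1)
        moved_t = np.linalg.norm(out.tibia.vertices - base_knee.tibia.vertices, axis=1)
        assert moved_f.max() > 0 and moved_t.max() > 0
        assert len(out.truth.measurements) == 15


class TestSimulateObservers:
    def test_zero_sigma_reproduces_truth_on_surface(self, femur_phantom):
        mesh, truth = femur_phantom
        sets = simulate_observers(truth, {"femur": mesh}, "s", n_observers=2,
                                  n_repeats=2, sigma_intra=0.0, sigma_inter=0.0, seed=0)
        assert len(sets) == 3  # obs1 x2 + obs2 x1
        for s in sets:
            for a in s.acronyms():
                # only the projection of the analytic truth onto the mesh remains
                assert np.linalg.norm(s[a] - truth.landmarks[a]) < 0.25

    def test_repeat_structure(self, femur_phantom):
        mesh, truth = femur_phantom
        sets = simulate_observers(truth, {"femur": mesh}, "s", n_observers=3,
                                  n_repeats=3, seed=1)
        observers = [s.observer for s in sets]
        assert observers.count("obs1") == 3
        assert observers.count("obs2") == 1 and observers.count("obs3") == 1

    def test_expert_mean_converges_to_truth(self, femur_phantom):
        """Law of large numbers: averaging many observers cancels the bias."""
        from kneemorph.landmarks import expert_mean_landmarks

        mesh, truth = femur_phantom
        n = 50
        sigma = 1.5
        sets = simulate_observers(truth, {"femur": mesh}, "s", n_observers=n,
                                  n_repeats=1, sigma_intra=0.0, sigma_inter=sigma, seed=2)
        mean = expert_mean_landmarks(sets)
        errs = [np.linalg.norm(mean[a] - truth.landmarks[a]) for a in mean.acronyms()]
        # 2-D tangent noise: SD of the mean is sigma*sqrt(2)/sqrt(n) per point,
        # plus a small on-surface projection offset
        assert np.mean(errs) <= 3 * sigma / np.sqrt(n) + 0.25

    def test_intra_errors_smaller_than_inter(self, femur_phantom):
        from kneemorph.agreement import landmark_errors

        mesh, truth = femur_phantom
        sets = []
        for subj in range(4):
            sets.extend(simulate_observers(truth, {"femur": mesh}, f"s{subj}",
                                           sigma_intra=1.0, sigma_inter=1.5,
                                           seed=100 + subj))
        intra_sets = [s for s in sets if s.observer == "obs1"]
        intra = np.mean([e.error for e in landmark_errors(intra_sets, "INTRA")])
        inter = np.mean([e.error for e in landmark_errors(sets, "INTER")])
        assert intra < inter
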