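import math

import numpy as np
import pytest
import scipy.linalg

from cmkn.nystrom_layer import (
    AnchorSet,
    StaleStateError,
    constraint_project,
    forward_sequence,
    gram_inverse_sqrt,
    init_anchors,
    project_window,
    sample_pairs,
    save_anchors_tsv,
    load_anchors_tsv,
)
from cmkn.pam_kernel import NPFM, k0
from cmkn.seq_io import DNA, CirclePosition, map_position

from conftest import random_circle_position, random_encoded, random_npfm


def make_anchors(rng, n, k=3):
    motifs = np.stack([random_npfm(rng, k=k).matrix for _ in range(n)])
    positions = np.stack([random_circle_position(rng).vector for _ in range(n)])
    return AnchorSet(motifs=motifs, positions=positions)


class TestSamplePairs:
    def test_deterministic(self, rng):
        data = [random_encoded(rng, 12, id=f"s{i}") for i in range(2)]
        a = sample_pairs(data, 10, 3, seed=7)
        b = sample_pairs(data, 10, 3, seed=7)
        for (m1, p1), (m2, p2) in zip(a, b):
            np.testing.assert_array_equal(m1.matrix, m2.matrix)
            np.testing.assert_array_equal(p1.vector, p2.vector)

    def test_pairs_are_windows_of_inputs(self, rng):
        data = [random_encoded(rng, 12, id=f"s{i}") for i in range(3)]
        for motif, pos in sample_pairs(data, 50, 3, seed=1):
            angle = math.atan2(pos.vector[1], pos.vector[0])
            found = False
            for x in data:
                p = round(angle * x.length / math.pi)
                if 1 <= p <= x.length - 2 and np.array_equal(
                    motif.matrix, x.matrix[:, p - 1 : p + 2]
                ):
                    found = True
            assert found

    def test_empty_dataset(self):
        with pytest.raises(ValueError, match="empty"):
            sample_pairs([], 5, 3)

    def test_uniform_over_windows(self, rng):
        # 2 sequences of length 12, k=3 -> 20 windows; binomial 3-sigma bound
        data = [random_encoded(rng, 12, id=f"s{i}") for i in range(2)]
        n_draws = 100_000
        pairs = sample_pairs(data, n_draws, 3, seed=0)
        angles = np.array([math.atan2(p.vector[1], p.vector[0]) for _, p in pairs])
        positions = np.round(angles * 12 / math.pi).astype(int)
        counts = np.bincount(positions, minlength=11)[1:]  # positions 1..10, both seqs merged
        expected = n_draws / 10
        sigma = math.sqrt(n_draws * 0.1 * 0.9)
        assert np.all(np.abs(counts - expected) <= 3 * sigma)


class TestInitAnchors:
    def test_recovers_duplicated_points(self, rng):
        base = [(random_npfm(rng, k=3), random_circle_position(rng)) for _ in range(4)]
        pairs = [p for p in base for _ in range(25)]
        anchors = init_anchors(pairs, 4, seed=0)
        got = {tuple(np.round(anchors.motifs[i].ravel(), 9)) for i in range(4)}
        want = {tuple(np.round(m.matrix.ravel(), 9)) for m, _ in base}
        assert got == want

    def test_output_satisfies_invariants(self, rng):
        data = [random_encoded(rng, 20, id=f"s{i}") for i in range(5)]
        anchors = init_anchors(sample_pairs(data, 200, 4, seed=0), 10, seed=0)
        anchors.validate()

    def test_cluster_center_recovery(self, rng):
        # 3 well-separated synthetic clusters of (motif || position) points
        centers = [make_anchors(rng, 1, k=3) for _ in range(3)]
        pairs = []
        for c in centers:
            for _ in range(100):
                m = c.motifs[0] + rng.normal(0, 0.01, c.motifs[0].shape)
                m = np.clip(m, 0, None)
                m /= np.linalg.norm(m, axis=0, keepdims=True)
                ang = math.atan2(c.positions[0, 1], c.positions[0, 0])
                ang = min(max(ang + rng.normal(0, 0.01), 0.0), math.pi)
                pairs.append(
                    (NPFM(m), CirclePosition(np.array([math.cos(ang), math.sin(ang)])))
                )
        anchors = init_anchors(pairs, 3, seed=0)
        for c in centers:
            target = np.concatenate([c.motifs[0].ravel(), c.positions[0]])
            best = min(
                np.linalg.norm(
                    np.concatenate([anchors.motifs[i].ravel(), anchors.positions[i]]) - target
                )
                for i in range(3)
            )
            assert best < 0.1

    def test_too_few_pairs(self, rng):
        pairs = [(random_npfm(rng), random_circle_position(rng))]
        with pytest.raises(ValueError, match="at least"):
            init_anchors(pairs, 2)


class TestConstraintProject:
    def test_rescale_column(self):
        anchors = AnchorSet(
            motifs=np.array([[[3.0], [0.0], [0.0], [0.0]]]),
            positions=np.array([[0.0, 1.0]]),
        )
        out = constraint_project(anchors)
        np.testing.assert_allclose(out.motifs[0][:, 0], [1, 0, 0, 0])

    def test_all_negative_column_becomes_uniform(self):
        anchors = AnchorSet(
            motifs=np.array([[[-1.0], [-2.0], [-3.0], [-4.0]]]),
            positions=np.array([[0.0, 1.0]]),
        )
        out = constraint_project(anchors)
        np.testing.assert_allclose(out.motifs[0][:, 0], [0.5, 0.5, 0.5, 0.5])

    def test_position_clamped_to_upper_half(self):
        anchors = AnchorSet(
            motifs=np.array([[[1.0], [0.0], [0.0], [0.0]]]),
            positions=np.array([[0.6, -0.8]]),
        )
        out = constraint_project(anchors)
        np.testing.assert_allclose(out.positions[0], [1.0, 0.0])

    def test_idempotent(self, rng):
        anchors = AnchorSet(
            motifs=rng.normal(size=(5, 4, 3)), positions=rng.normal(size=(5, 2))
        )
        once = constraint_project(anchors)
        twice = constraint_project(once)
        np.testing.assert_allclose(twice.motifs, once.motifs, atol=1e-12)
        np.testing.assert_allclose(twice.positions, once.positions, atol=1e-12)

    def test_valid_anchors_unchanged(self, rng):
        anchors = make_anchors(rng, 4)
        out = constraint_project(anchors)
        np.testing.assert_allclose(out.motifs, anchors.motifs, atol=1e-12)
        np.testing.assert_allclose(out.positions, anchors.positions, atol=1e-12)


class TestGramInverseSqrt:
    def test_single_anchor(self, rng, small_params):
        anchors = make_anchors(rng, 1)
        state = gram_inverse_sqrt(anchors, small_params)
        np.testing.assert_allclose(state.K_ZZ, [[1.0]], atol=1e-12)
        np.testing.assert_allclose(state.K_ZZ_inv_sqrt, [[1.0]], atol=1e-6)

    def test_inverse_property(self, rng, small_params):
        anchors = make_anchors(rng, 8)
        state = gram_inverse_sqrt(anchors, small_params, epsilon=1e-6)
        ident = state.K_ZZ_inv_sqrt @ state.K_ZZ @ state.K_ZZ_inv_sqrt
        assert np.abs(ident - np.eye(8)).max() <= 1e-5

    def test_unit_diagonal(self, rng, small_params):
        state = gram_inverse_sqrt(make_anchors(rng, 6), small_params)
        np.testing.assert_allclose(np.diag(state.K_ZZ), 1.0, atol=1e-9)

    def test_rank_deficient_is_finite(self, rng, small_params):
        a = make_anchors(rng, 3)
        a.motifs[1] = a.motifs[0]
        a.positions[1] = a.positions[0]
        state = gram_inverse_sqrt(a, small_params)
        assert np.all(np.isfinite(state.K_ZZ_inv_sqrt))


class TestProjectWindow:
    def test_single_anchor_closed_form(self, rng, small_params):
        anchors = make_anchors(rng, 1)
        state = gram_inverse_sqrt(anchors, small_params)
        w = (random_npfm(rng, k=3), random_circle_position(rng))
        psi = project_window(w, state, anchors, small_params)
        expected = k0((anchors.motif(0), anchors.position(0)), w, small_params)
        assert psi.shape == (1,)
        assert math.isclose(psi[0], expected, rel_tol=1e-9)

    def test_nystrom_exactness_on_anchors(self, rng, small_params):
        anchors = make_anchors(rng, 6)
        state = gram_inverse_sqrt(anchors, small_params, epsilon=1e-6)
        psis = np.array(
            [
                project_window((anchors.motif(i), anchors.position(i)), state, anchors, small_params)
                for i in range(6)
            ]
        )
        np.testing.assert_allclose(psis @ psis.T, state.K_ZZ, atol=1e-6)

    def test_against_dense_oracle(self, rng, small_params):
        # independent path: scipy sqrtm + pinv, scalar k0 evaluations
        anchors = make_anchors(rng, 5)
        state = gram_inverse_sqrt(anchors, small_params, epsilon=1e-12)
        w = (random_npfm(rng, k=3), random_circle_position(rng))
        kz = np.array(
            [k0((anchors.motif(i), anchors.position(i)), w, small_params) for i in range(5)]
        )
        oracle = np.linalg.pinv(scipy.linalg.sqrtm(state.K_ZZ).real) @ kz
        np.testing.assert_allclose(
            project_window(w, state, anchors, small_params), oracle, atol=1e-9
        )

    def test_stale_state_detected(self, rng, small_params):
        anchors = make_anchors(rng, 3)
        state = gram_inverse_sqrt(anchors, small_params)
        anchors.motifs[0, 0, 0] += 0.1
        with pytest.raises(StaleStateError):
            project_window((random_npfm(rng, k=3), random_circle_position(rng)), state, anchors, small_params)


class TestForwardSequence:
    def test_matches_per_window_reference(self, rng, small_params):
        data = [random_encoded(rng, 30, id="x")]
        anchors = init_anchors(sample_pairs(data, 100, 3, seed=0), 10, seed=0)
        state = gram_inverse_sqrt(anchors, small_params)
        x = data[0]
        fm = forward_sequence(x, state, anchors, small_params)
        assert fm.shape == (28, 10)
        from cmkn.seq_io import map_position as mp

        for p in (1, 5, 28):
            w = (NPFM(x.matrix[:, p - 1 : p + 2]), mp(p, 30))
            np.testing.assert_allclose(
                fm[p - 1], project_window(w, state, anchors, small_params), atol=1e-9
            )

    def test_shapes_for_different_lengths(self, rng, small_params):
        anchors = make_anchors(rng, 4)
        state = gram_inverse_sqrt(anchors, small_params)
        f1 = forward_sequence(random_encoded(rng, 20), state, anchors, small_params)
        f2 = forward_sequence(random_encoded(rng, 25), state, anchors, small_params)
        assert f1.shape == (18, 4) and f2.shape == (23, 4)

    def test_too_short(self, rng, small_params):
        anchors = make_anchors(rng, 4)
        state = gram_inverse_sqrt(anchors, small_params)
        with pytest.raises(ValueError, match="length"):
            forward_sequence(random_encoded(rng, 2), state, anchors, small_params)

    def test_finite_and_kernel_bounds(self, rng, small_params):
        anchors = make_anchors(rng, 4)
        state = gram_inverse_sqrt(anchors, small_params)
        x = random_encoded(rng, 20)
        from cmkn.nystrom_layer import kernel_responses
        from cmkn.pam_kernel import sequence_windows
        from cmkn.seq_io import circle_positions

        win = sequence_windows(x, 3)
        k0r = kernel_responses(win, circle_positions(20, count=18), anchors, small_params)
        assert np.all(k0r > 0) and np.all(k0r <= 1 + 1e-12)
        assert np.all(np.isfinite(forward_sequence(x, state, anchors, small_params)))

    def test_projection_norm_bounded(self, rng, small_params):
        anchors = make_anchors(rng, 6)
        state = gram_inverse_sqrt(anchors, small_params, epsilon=1e-6)
        for _ in range(20):
            w = (random_npfm(rng, k=3), random_circle_position(rng))
            psi = project_window(w, state, anchors, small_params)
            assert np.isfinite(psi).all()
            # responses bounded by 1, so ||psi|| <= ||K_ZZ^-1/2||_2 * sqrt(n)
            bound = np.linalg.eigvalsh(state.K_ZZ_inv_sqrt).max() * math.sqrt(6)
            assert np.linalg.norm(psi) <= bound + 1e-9


class TestAnchorArchive:
    def test_roundtrip(self, rng, small_params, tmp_path):
        anchors = make_anchors(rng, 4)
        path = tmp_path / "anchors.tsv"
        save_anchors_tsv(path, anchors, small_params, DNA)
        loaded, params, alphabet = load_anchors_tsv(path)
        np.testing.assert_allclose(loaded.motifs, anchors.motifs, atol=1e-15)
        np.testing.assert_allclose(loaded.positions, anchors.positions, atol=1e-12)
        assert params == small_params
        assert alphabet.kind == "dna"
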