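"""Local frames and the geometry-complete convolution: orthonormality,
SE(3) equivariance, permutation equivariance, chirality sensitivity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chiraldiff.autodiff import Tensor
from chiraldiff.gcpnet import GCPNetwork, build_frames, rbf_features


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def centered_points(n, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    x = scale * rng.standard_normal((n, 3))
    return x - x.mean(axis=0)


def make_net(seed=0, n_layers=2, n_in=6, n_out=6, **kw):
    return GCPNetwork(n_in, n_out, n_layers, np.random.default_rng(seed), **kw)


class TestFrames:
    def test_hand_example(self):
        # a centered 4-point set whose first two atoms sit at (1,0,0) and
        # (0,1,0); the frame of the ordered pair (0,1) follows by hand:
        # a = (x0-x1)/|x0-x1|, b = (x0 x x1)/|x0 x x1|, c = a x b
        s = 1 / np.sqrt(2)
        frames = build_frames(np.array([[1.0, 0, 0], [0, 1.0, 0],
                                        [-0.5, -0.5, 0], [-0.5, -0.5, 0]]))
        f = frames.frames.data[0, 1]
        assert np.allclose(f[0], [s, -s, 0], atol=1e-12)          # a_01
        assert np.allclose(f[1], [0, 0, 1], atol=1e-12)           # b_01
        assert np.allclose(f[2], [-s, -s, 0], atol=1e-12)         # c_01

    def test_orthonormal_right_handed(self):
        x = centered_points(6, seed=1)
        frames = build_frames(x)
        f = frames.frames.data
        for i in range(6):
            for j in range(6):
                if frames.degenerate[i, j]:
                    continue
                gram = f[i, j] @ f[i, j].T
                assert np.allclose(gram, np.eye(3), atol=1e-6)
                assert np.isclose(np.linalg.det(f[i, j]), 1.0, atol=1e-6)

    def test_rotation_equivariance_exact(self):
        x = centered_points(5, seed=2)
        R = random_rotation(3)
        f0 = build_frames(x).frames.data
        f1 = build_frames(x @ R.T).frames.data
        assert np.abs(f1 - f0 @ R.T).max() < 1e-10

    def test_mirror_does_not_mirror_b(self):
        """b_ij is a pseudovector: reflecting the points does not simply
        reflect it, which is what makes the frames chirality-aware."""
        x = centered_points(5, seed=4)
        M = np.diag([1.0, 1.0, -1.0])
        f0 = build_frames(x).frames.data
        f1 = build_frames(x @ M).frames.data
        b_mirrored = f0[..., 1, :] @ M
        assert np.abs(f1[..., 1, :] - b_mirrored).max() > 0.1

    def test_degenerate_pairs_flagged_and_zero(self):
        # coincident atoms and a linear molecule (all cross products vanish)
        x = np.array([[1.0, 0, 0], [1.0, 0, 0], [-2.0, 0, 0]])
        x -= x.mean(axis=0)
        frames = build_frames(x)
        assert frames.degenerate[0, 1]
        assert np.allclose(frames.frames.data[0, 1], 0.0)
        assert np.all(np.isfinite(frames.frames.data))
        assert frames.degenerate.diagonal().all()

    def test_non_centered_input_rejected(self):
        with pytest.raises(ValueError, match="centered"):
            build_frames(np.array([[1.0, 0, 0], [2.0, 0, 0]]))


class TestRBF:
    def test_invariant_under_rigid_motion(self):
        x = centered_points(5, seed=5)
        R = random_rotation(6)
        d0 = np.linalg.norm(x[:, None] - x[None], axis=-1)
        xr = x @ R.T + np.array([1.0, -2.0, 3.0])
        d1 = np.linalg.norm(xr[:, None] - xr[None], axis=-1)
        assert np.allclose(rbf_features(d0), rbf_features(d1), atol=1e-12)


class TestGCPNetwork:
    def test_se3_equivariance(self):
        net = make_net()
        x = centered_points(6, seed=7)
        s = np.random.default_rng(8).standard_normal((6, 6))
        x_out, s_out = net(x, s)
        for k in range(20):
            R = random_rotation(100 + k)
            x2, s2 = net(x @ R.T, s)
            assert np.abs(x2.data - x_out.data @ R.T).max() < 1e-4
            assert np.abs(s2.data - s_out.data).max() < 1e-4

    def test_translation_via_centering_convention(self):
        """Translations act on the quotient space: centering the translated
        molecule recovers the same network output."""
        net = make_net()
        x = centered_points(5, seed=9)
        s = np.random.default_rng(10).standard_normal((5, 6))
        x_out, s_out = net(x, s)
        tau = np.array([0.5, -1.0, 2.0])
        x_shifted = (x + tau) - (x + tau).mean(axis=0)
        x2, s2 = net(x_shifted, s)
        assert np.abs(x2.data - x_out.data).max() < 1e-12
        assert np.abs(s2.data - s_out.data).max() < 1e-12

    def test_permutation_equivariance(self):
        net = make_net()
        x = centered_points(7, seed=11)
        s = np.random.default_rng(12).standard_normal((7, 6))
        x_out, s_out = net(x, s)
        perm = np.random.default_rng(13).permutation(7)
        x2, s2 = net(x[perm], s[perm])
        assert np.abs(x2.data - x_out.data[perm]).max() < 1e-10
        assert np.abs(s2.data - s_out.data[perm]).max() < 1e-10

    def test_chirality_discrimination(self):
        """Mirror-image 4-point chiral configurations produce different
        invariant outputs (SE(3), not E(3), behavior)."""
        net = make_net(seed=21)
        x = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0, 0, 0.9]])
        x -= x.mean(axis=0)
        mirror = x @ np.diag([1.0, 1.0, -1.0])
        s = np.eye(4, 6)
        _, s_a = net(x, s)
        _, s_b = net(mirror, s)
        assert np.abs(s_a.data - s_b.data).max() > 1e-6

    def test_continuous_at_collinear_configurations(self):
        """Outputs for an exactly-linear molecule are the limit of its
        perturbed neighbors: the frame information is smoothly gated, not
        hard-switched, near the degenerate set."""
        net = make_net(seed=50)
        x0 = np.array([[-1.1, 0, 0], [-0.03, 0, 0], [1.13, 0, 0]])
        x0 -= x0.mean(axis=0)
        s = np.eye(3, 6)
        _, out0 = net(x0, s)
        rng = np.random.default_rng(51)
        direction = rng.standard_normal((3, 3))
        direction -= direction.mean(axis=0)
        prev_gap = None
        for scale in (1e-2, 1e-3, 1e-4):
            xp = x0 + scale * direction
            xp -= xp.mean(axis=0)
            _, outp = net(xp, s)
            gap = np.abs(outp.data - out0.data).max()
            if prev_gap is not None:
                assert gap < prev_gap  # converges to the linear limit
            prev_gap = gap
        assert prev_gap < 1e-2

    def test_single_atom_molecule(self):
        net = make_net()
        x = np.zeros((1, 3))
        s = np.ones((1, 6))
        x_out, s_out = net(x, s)
        assert x_out.shape == (1, 3) and s_out.shape == (1, 6)
        assert np.all(np.isfinite(s_out.data))

    def test_coordinates_stay_zero_com(self):
        net = make_net(seed=30, n_layers=3)
        x = centered_points(6, seed=31)
        s = np.random.default_rng(32).standard_normal((6, 6))
        x_out, _ = net(x, s)
        assert np.abs(x_out.data.mean(axis=0)).max() < 1e-10

    def test_large_magnitude_inputs_stay_finite(self):
        net = make_net()
        x = centered_points(5, seed=33, scale=1e3)
        s = 1e3 * np.random.default_rng(34).standard_normal((5, 6))
        x_out, s_out = net(x, s)
        assert np.all(np.isfinite(x_out.data))
        assert np.all(np.isfinite(s_out.data))

    def test_gradients_finite_on_toy_batch(self):
        net = make_net()
        x = centered_points(6, seed=35)
        s = np.random.default_rng(36).standard_normal((6, 6))
        x_out, s_out = net(Tensor(x), Tensor(s))
        loss = (x_out * x_out).sum() + (s_out * s_out).sum()
        loss.backward()
        for name, p in net.named_parameters().items():
            assert p.grad is None or np.all(np.isfinite(p.grad)), name

    def test_aggregation_sum_vs_mean_differ(self):
        x = centered_points(5, seed=37)
        s = np.random.default_rng(38).standard_normal((5, 6))
        out_mean = make_net(seed=40, aggregation="mean")(x, s)
        out_sum = make_net(seed=40, aggregation="sum")(x, s)
        assert np.abs(out_mean[1].data - out_sum[1].data).max() > 1e-8
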