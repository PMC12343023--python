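"""Geometry-complete perceptron convolution (GCPConv).

Message passing over the fully connected molecular graph in which every
ordered atom pair (i, j) carries a local orthonormal frame

    a_ij = (x_i - x_j) / ||x_i - x_j||
    b_ij = (x_i x x_j) / ||x_i x x_j||      (cross product)
    c_ij = a_ij x b_ij

built from *centered* coordinates. Vector features are scalarized by
projection onto the frame rows before entering the message MLP, and vector
outputs are formed as scalar-gated combinations of the input vectors and
the frame axes. Because b_ij is a pseudovector, the scalarized features
change under reflection: the network is SE(3)-equivariant but *not*
E(3)-equivariant, i.e. it can tell mirror images (chirality) apart.

Coordinates are updated residually from the equivariant channel and
re-projected to the zero-center-of-mass subspace after every layer, which
is what makes translations a quotiented-out symmetry.

Shapes (a leading batch axis is optional throughout):
    x: (..., N, 3)   h: (..., N, d_h)   chi: (..., N, m, 3)
    frames: (..., N, N, 3, 3)   edge RBF: (..., N, N, n_rbf)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import MLP, Linear, Module

DEGENERATE_EPS = 1e-6
_NORM_EPS = 1e-24


@dataclass
class LocalFrameSet:
    """Per-ordered-pair frames; rows of ``frames[..., i, j, :, :]`` are
    (a_ij, b_ij, c_ij). Degenerate pairs (coincident atoms, or atoms
    collinear with the centroid, where a cross product vanishes) carry the
    zero frame and are flagged in ``degenerate``.

    ``cross_gate`` is a smooth weight in [0, 1) that vanishes as a pair
    approaches collinearity-with-the-centroid. The b/c frame rows are
    well-defined but directionally unstable near that set; downstream
    layers scale their contributions by this gate so the network is
    *continuous* across the degenerate configurations (a hard cutoff
    would make exactly-linear molecules behave discontinuously relative
    to their own infinitesimally perturbed neighbors)."""

    frames: Tensor           # (..., N, N, 3, 3)
    degenerate: np.ndarray   # (..., N, N) bool; True also on the diagonal
    cross_gate: Tensor | None = None   # (..., N, N)


def _check_centered(positions_data: np.ndarray, tol: float = 1e-8):
    com = positions_data.mean(axis=-2)
    if np.abs(com).max() > tol:
        raise ValueError(
            "positions must be centered (zero column means): local frames "
            "use absolute positions, so translation invariance only holds "
            "on the zero-center-of-mass subspace")


CROSS_GATE_SCALE = 0.1


def build_frames(positions: Tensor | np.ndarray,
                 eps: float = DEGENERATE_EPS,
                 gate_scale: float = CROSS_GATE_SCALE) -> LocalFrameSet:
    """Construct the local frame for every ordered atom pair.

    Requires centered positions. Pairs where ||x_i - x_j|| or
    ||x_i x x_j|| falls below ``eps`` are degenerate: they get the zero
    frame (and, downstream, scalar-only messages). The returned
    ``cross_gate`` = ||x_i x x_j||^2 / (||x_i x x_j||^2 + gate_scale^2)
    fades the chirality-bearing b/c rows out smoothly near collinear
    configurations.
    """
    x = Tensor.as_tensor(positions)
    _check_centered(x.data)
    xi = x[..., :, None, :]                       # (..., N, 1, 3)
    xj = x[..., None, :, :]                       # (..., 1, N, 3)
    diff = xi - xj                                # (..., N, N, 3)
    cr = ad.cross(xi + ad.Tensor(np.zeros_like(diff.data)),
                  xj + ad.Tensor(np.zeros_like(diff.data)))
    diff_norm = ad.norm(diff, keepdims=True, eps=_NORM_EPS)
    cr_norm = ad.norm(cr, keepdims=True, eps=_NORM_EPS)
    degenerate = ((diff_norm.data[..., 0] < eps) |
                  (cr_norm.data[..., 0] < eps))
    # eps-regularized norms make the rows vanish *naturally* at the
    # degenerate set (a at coincidence, b and c at collinearity); no hard
    # zeroing, so the frames are continuous functions of the positions
    a = diff / diff_norm
    b = cr / cr_norm
    c = ad.cross(a, b)
    frames = ad.stack([a, b, c], axis=-2)         # (..., N, N, 3, 3)
    cr_sq = (cr * cr).sum(axis=-1)
    gate = cr_sq / (cr_sq + gate_scale ** 2)      # (..., N, N)
    return LocalFrameSet(frames=frames, degenerate=degenerate,
                         cross_gate=gate)


def rbf_features(distances: np.ndarray, n_rbf: int = 16,
                 cutoff: float = 8.0) -> np.ndarray:
    """Gaussian radial basis embedding of pairwise distances over
    [0, cutoff] angstroms; rotation/translation invariant by construction."""
    centers = np.linspace(0.0, cutoff, n_rbf)
    width = cutoff / (n_rbf - 1)
    return np.exp(-((distances[..., None] - centers) ** 2) / (2 * width ** 2))


def scalarize(vectors: Tensor, frames: Tensor) -> Tensor:
    """Project vector channels onto the frame rows.

    vectors: (..., N, N, k, 3), frames: (..., N, N, 3, 3) with basis rows
    -> invariant coefficients (..., N, N, k, 3).
    """
    return vectors @ ad.swapaxes(frames, -1, -2)


def _broadcast_to(t: Tensor, shape) -> Tensor:
    return t + Tensor(np.zeros(shape))


class GCPConvLayer(Module):
    """One geometry-complete convolution: message -> aggregate ->
    node/vector update -> GCP module -> residual coordinate update."""

    def __init__(self, d_h: int, m: int, n_rbf: int,
                 rng: np.random.Generator, d_hidden: int = 96,
                 aggregation: str = "mean"):
        if aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")
        self.d_h, self.m, self.aggregation = d_h, m, aggregation
        n_scalarized = 3 * m + 3 * m + 3          # chi_i, chi_j, xi_ij
        d_msg_in = 2 * d_h + n_rbf + n_scalarized + 1
        # message head: d_h scalar channels + 6 gate groups of m vector gates
        self.msg_mlp = MLP([d_msg_in, d_hidden, d_h + 6 * m], rng)
        self.mix_i = Linear(m, m, rng, bias=False)
        self.mix_j = Linear(m, m, rng, bias=False)
        # node update phi: residual scalar update + per-channel vector gates
        self.node_mlp = MLP([2 * d_h, d_hidden, d_h + m], rng)
        # GCP module: invariant update + equivariant per-channel gates
        self.gcp_mlp = MLP([d_h + m, d_hidden, d_h + m], rng)
        # reduction of the m equivariant channels to one coordinate update;
        # zero init => the layer starts as the identity on coordinates
        self.coord_head = Linear(m, 1, rng, bias=False, scale=0.0)

    def __call__(self, x: Tensor, h: Tensor, chi: Tensor, e_rbf: np.ndarray,
                 ) -> tuple[Tensor, Tensor, Tensor]:
        n = x.shape[-2]
        m, d_h = self.m, self.d_h
        lead = x.shape[:-2]
        frames = build_frames(x)

        xi_vec = x[..., :, None, :] - x[..., None, :, :]       # (...,N,N,3)
        dist = ad.norm(xi_vec, keepdims=True, eps=_NORM_EPS)

        # gate the b/c frame rows once: scalarizations and basis
        # contributions built from `fr` then fade out smoothly near
        # collinear (degenerate-frame) configurations, keeping the layer
        # continuous there; chirality still enters via the gated b row
        one = Tensor(np.ones_like(frames.cross_gate.data))
        fr = frames.frames * ad.stack(
            [one, frames.cross_gate, frames.cross_gate], axis=-1)[..., None]
        chi_i = chi[..., :, None, :, :]                        # (...,N,1,m,3)
        chi_j = chi[..., None, :, :, :]                        # (...,1,N,m,3)
        proj_i = scalarize(chi_i, fr).reshape(lead + (n, n, 3 * m))
        proj_j = scalarize(chi_j, fr).reshape(lead + (n, n, 3 * m))
        proj_xi = scalarize(xi_vec[..., None, :], fr
                            ).reshape(lead + (n, n, 3))

        h_i = _broadcast_to(h[..., :, None, :], lead + (n, n, d_h))
        h_j = _broadcast_to(h[..., None, :, :], lead + (n, n, d_h))
        msg_in = ad.concatenate(
            [h_i, h_j, Tensor(e_rbf), proj_i, proj_j, proj_xi, dist], axis=-1)
        out = self.msg_mlp(msg_in)
        msg_s = out[..., :d_h]                                  # (...,N,N,d_h)
        gates = ad.sigmoid(out[..., d_h:]) - 0.5                # (...,N,N,6m)

        # vector message: gated combination of mixed inputs and frame axes.
        # The (xi, a, b, c) part is one batched matmul: gates (...,m,4)
        # against the stacked basis (...,4,3).
        gi = gates[..., 0 * m:1 * m, None]
        gj = gates[..., 1 * m:2 * m, None]
        mix_i = ad.swapaxes(self.mix_i(ad.swapaxes(chi_i, -1, -2)), -1, -2)
        mix_j = ad.swapaxes(self.mix_j(ad.swapaxes(chi_j, -1, -2)), -1, -2)
        basis = ad.concatenate([xi_vec[..., None, :], fr],
                               axis=-2)                         # (...,N,N,4,3)
        g_basis = ad.swapaxes(
            gates[..., 2 * m:].reshape(lead + (n, n, 4, m)), -1, -2)
        msg_v = gi * mix_i + gj * mix_j + g_basis @ basis       # (...,N,N,m,3)

        # no self-edges; degenerate pairs lose their unstable frame
        # contributions through the cross gate / vanishing rows, so no
        # hard vector-message cutoff is needed
        self_mask = np.eye(n, dtype=bool)
        msg_s = ad.where(self_mask[..., None], Tensor(0.0), msg_s)
        msg_v = ad.where(self_mask[..., None, None], Tensor(0.0), msg_v)

        # aggregation over neighbors j
        denom = float(max(n - 1, 1)) if self.aggregation == "mean" else 1.0
        agg_s = msg_s.sum(axis=-2) * (1.0 / denom)              # (...,N,d_h)
        agg_v = msg_v.sum(axis=-3) * (1.0 / denom)              # (...,N,m,3)

        # node update phi (residual)
        node_out = self.node_mlp(ad.concatenate([h, agg_s], axis=-1))
        h_new = h + node_out[..., :d_h]
        vgate = ad.tanh(node_out[..., d_h:])
        chi_new = chi + vgate[..., None] * agg_v

        # GCP module: invariant scalar update + gated equivariant channel
        chi_norm = ad.norm(chi_new, axis=-1, eps=_NORM_EPS)
        gcp_out = self.gcp_mlp(ad.concatenate([h_new, chi_norm], axis=-1))
        h_p = gcp_out[..., :d_h]
        chi_p = ad.tanh(gcp_out[..., d_h:])[..., None] * chi_new
        h_new = h_new + h_p

        # coordinate update from the equivariant channel, re-centered
        dx = self.coord_head(ad.swapaxes(chi_p, -1, -2))[..., 0]  # (...,N,3)
        x_new = x + dx
        x_new = x_new - x_new.mean(axis=-2, keepdims=True)
        return x_new, h_new, chi_p


class GCPNetwork(Module):
    """A stack of GCPConv layers with scalar input/output projections.

    ``forward(x, s)`` takes centered coordinates (..., N, 3) and scalar
    node features (..., N, n_in), and returns updated coordinates plus
    (..., N, n_out) scalars. The equivariant channel chi is initialized
    from the centered coordinates (per-channel learned scaling); the edge
    RBF features are computed once from the input geometry and reused by
    every layer.
    """

    def __init__(self, n_in: int, n_out: int, n_layers: int,
                 rng: np.random.Generator, d_h: int = 64, m: int = 8,
                 n_rbf: int = 16, rbf_cutoff: float = 8.0,
                 d_hidden: int = 96, aggregation: str = "mean"):
        self.config = dict(n_in=n_in, n_out=n_out, n_layers=n_layers,
                           d_h=d_h, m=m, n_rbf=n_rbf, rbf_cutoff=rbf_cutoff,
                           d_hidden=d_hidden, aggregation=aggregation)
        # +1: radial distance to the centroid, an invariant scalar that
        # keeps atoms distinguishable even when every pair frame is
        # degenerate (e.g. linear molecules)
        self.embed = Linear(n_in + 1, d_h, rng)
        self.chi_init = Tensor(0.1 * rng.standard_normal(m), requires_grad=True)
        self.layers = [GCPConvLayer(d_h, m, n_rbf, rng, d_hidden, aggregation)
                       for _ in range(n_layers)]
        # two-layer readout: a single linear map from d_h to a narrow
        # output (e.g. the latent bottleneck) separates feature clusters
        # poorly; one hidden layer removes that failure mode
        self.readout = MLP([d_h, d_h // 2, n_out], rng)
        self.n_rbf, self.rbf_cutoff = n_rbf, rbf_cutoff

    def __call__(self, x: Tensor | np.ndarray, s: Tensor | np.ndarray
                 ) -> tuple[Tensor, Tensor]:
        x = Tensor.as_tensor(x)
        s = Tensor.as_tensor(s)
        _check_centered(x.data)
        diff = x.data[..., :, None, :] - x.data[..., None, :, :]
        e_rbf = rbf_features(np.linalg.norm(diff, axis=-1),
                             self.n_rbf, self.rbf_cutoff)
        radial = ad.norm(x, axis=-1, keepdims=True, eps=_NORM_EPS)
        h = self.embed(ad.concatenate([s, radial], axis=-1))
        chi = self.chi_init[:, None] * x[..., None, :]       # (...,N,m,3)
        for idx, layer in enumerate(self.layers):
            x, h, chi = layer(x, h, chi, e_rbf)
            if not np.all(np.isfinite(x.data)) or not np.all(np.isfinite(h.data)):
                raise FloatingPointError(
                    f"non-finite activation in GCPConv layer {idx}")
        return x, self.readout(h)
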