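"""Geometry-complete autoencoder between atom space and latent space.

The encoder is a single GCPConv stack mapping a centered molecule
``(x, h)`` to a latent pair ``z = (z_x, z_h)``: equivariant latent
coordinates (N x 3, zero center of mass) and invariant latent scalars
(N x k_latent). A small Gaussian perturbation ``sigma * delta`` (delta
close to zero) is added to both blocks during training, which keeps the
discrete atom features continuous in latent space. The decoder applies
three GCPConv stacks and emits reconstructed coordinates plus scalar
feature logits; the training objective is the squared L2 reconstruction
error, averaged over atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .gcpnet import GCPNetwork
from .molgraph import (DEFAULT_ALPHABET, MoleculeGraph, center_molecule,
                       defeaturize, featurize)
from .nn import Module


@dataclass
class LatentState:
    """Equivariant latent coordinates ``z_x`` (zero CoM) and invariant
    latent scalars ``z_h``."""

    z_x: np.ndarray
    z_h: np.ndarray

    def __post_init__(self):
        self.z_x = np.asarray(self.z_x, dtype=np.float64)
        self.z_h = np.asarray(self.z_h, dtype=np.float64)
        if not (np.all(np.isfinite(self.z_x)) and np.all(np.isfinite(self.z_h))):
            raise ValueError("non-finite latent state")
        com = np.abs(self.z_x.mean(axis=-2)).max()
        if com > 1e-10:
            raise ValueError(f"z_x must have zero center of mass (|mean|={com:g})")


def project_zero_com(v: Tensor) -> Tensor:
    """Project the coordinate block onto the zero-center-of-mass subspace."""
    return v - v.mean(axis=-2, keepdims=True)


class GeometricAutoencoder(Module):
    """Encoder (1 GCPConv stack) + decoder (3 stacks) with latent width
    ``k_latent`` and encoder noise scale ``delta``."""

    def __init__(self, rng: np.random.Generator, nf: int = 6,
                 k_latent: int = 3, delta: float = 0.03,
                 d_h: int = 64, m: int = 8, d_hidden: int = 96,
                 encoder_layers: int = 1, decoder_layers: int = 3,
                 alphabet: tuple[str, ...] = DEFAULT_ALPHABET):
        if k_latent < 1:
            raise ValueError("k_latent must be >= 1")
        if delta < 0:
            raise ValueError("delta must be >= 0")
        self.config = dict(nf=nf, k_latent=k_latent, delta=delta, d_h=d_h,
                           m=m, d_hidden=d_hidden,
                           encoder_layers=encoder_layers,
                           decoder_layers=decoder_layers)
        self.k_latent, self.delta, self.nf = k_latent, delta, nf
        self.alphabet = tuple(alphabet)
        self.encoder = GCPNetwork(nf, k_latent, encoder_layers, rng,
                                  d_h=d_h, m=m, d_hidden=d_hidden)
        self.decoder = GCPNetwork(k_latent, nf, decoder_layers, rng,
                                  d_h=d_h, m=m, d_hidden=d_hidden)

    # -- array-level API (used in training; a leading batch axis is fine) --

    def encode_arrays(self, x, h, rng: np.random.Generator | None = None,
                      ) -> tuple[Tensor, Tensor]:
        """Encode centered coordinates + scalar features; when ``rng`` is
        given, standard-normal noise scaled by ``delta`` is added to both
        latent blocks (training-time regularization) and z_x is
        re-projected to zero CoM."""
        z_x, z_h = self.encoder(x, h)
        if rng is not None and self.delta > 0:
            z_x = z_x + Tensor(rng.standard_normal(z_x.shape) * self.delta)
            z_h = z_h + Tensor(rng.standard_normal(z_h.shape) * self.delta)
            z_x = project_zero_com(z_x)
        return z_x, z_h

    def decode_arrays(self, z_x, z_h) -> tuple[Tensor, Tensor]:
        return self.decoder(z_x, z_h)

    # -- molecule-level API -----------------------------------------------

    def encode(self, mol: MoleculeGraph,
               rng: np.random.Generator | None = None) -> LatentState:
        mol = center_molecule(mol)
        with no_grad():
            z_x, z_h = self.encode_arrays(mol.positions, featurize(mol), rng)
        return LatentState(z_x.data - z_x.data.mean(axis=-2, keepdims=True),
                           z_h.data)

    def decode(self, z: LatentState) -> tuple[np.ndarray, np.ndarray]:
        with no_grad():
            x_bar, h_bar = self.decode_arrays(z.z_x, z.z_h)
        return x_bar.data, h_bar.data

    def decode_discrete(self, h_bar: np.ndarray
                        ) -> tuple[tuple[str, ...], np.ndarray]:
        """Map scalar-feature logits to element symbols and integer
        charges (argmax over the one-hot block, nearest-integer charge)."""
        return defeaturize(h_bar, self.alphabet)

    def reconstruct(self, mol: MoleculeGraph) -> MoleculeGraph:
        z = self.encode(mol)
        x_bar, h_bar = self.decode(z)
        types, charges = self.decode_discrete(h_bar)
        return MoleculeGraph(x_bar, types, np.clip(charges, -2, 2),
                             alphabet=self.alphabet)


def reconstruction_loss(x, h, x_bar: Tensor, h_bar: Tensor) -> Tensor:
    """Squared L2 reconstruction error over coordinates and scalar
    features, summed per atom and averaged over atoms."""
    x, h = Tensor.as_tensor(x), Tensor.as_tensor(h)
    if x.shape != x_bar.shape or h.shape != h_bar.shape:
        raise ValueError("reconstruction shapes do not match input")
    n_atoms = float(np.prod(x.shape[:-1]))
    err = ((x - x_bar) * (x - x_bar)).sum() + ((h - h_bar) * (h - h_bar)).sum()
    return err * (1.0 / n_atoms)
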