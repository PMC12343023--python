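"""Latent-space denoising diffusion: schedule, losses, ancestral sampling.

The forward chain perturbs a latent pair z_0 = (z_x, z_h) with Gaussian
noise, q(z_t | z_{t-1}) = N(sqrt(1-beta_t) z_{t-1}, beta_t I), whose
marginal is q(z_t | z_0) = N(sqrt(abar_t) z_0, (1-abar_t) I) with
abar_t = prod_{i<=t} (1-beta_i). The reverse chain is parameterized by a
noise-prediction network eps_theta realized as a geometry-complete
convolution stack, so transitions are SE(3)-equivariant; combined with a
rotation-invariant prior on the zero-center-of-mass subspace this makes
the model's sample distribution rotation-invariant and well-defined up to
translation.

All Gaussian draws touching the coordinate block are mean-projected onto
the zero-CoM subspace. The final reverse step is deterministic
(sigma_1 = 0, with the boundary convention abar_0 = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .autoencoder import GeometricAutoencoder, reconstruction_loss
from .gcpnet import GCPNetwork
from .molgraph import (AtomCountDistribution, MoleculeGraph,
                       sample_num_atoms)
from .nn import Module, load_params, save_params

# ---------------------------------------------------------------------------
# Noise schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSchedule:
    """Arrays indexed by time step t = 1..T (index 0 holds the boundary
    conventions beta_0 = 0, abar_0 = 1, sigma_1 = 0)."""

    T: int
    beta: np.ndarray        # (T+1,)
    alpha: np.ndarray       # 1 - beta
    alpha_bar: np.ndarray   # cumulative product of alpha
    sigma: np.ndarray       # posterior std

    def __post_init__(self):
        b = self.beta[1:]
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("beta_t must lie in (0, 1)")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")
        if self.alpha_bar[-1] >= 0.01:
            raise ValueError("terminal alpha_bar must be < 0.01 "
                             "(z_T must approach the standard-normal prior)")
        if abs(self.sigma[1]) > 0:
            raise ValueError("sigma_1 must be 0 (deterministic final step)")


def make_schedule(T: int, kind: str = "polynomial") -> NoiseSchedule:
    """Build a noise schedule.

    ``polynomial`` (default): abar_t proportional to (1 - (t/T)^2)^2, the
    convention of equivariant-diffusion models, with the implied beta_t
    clipped to [1e-5, 0.999] for numerical safety. ``linear``: beta_t
    linear in t, scaled with 1000/T so the total injected noise (and hence
    the terminal abar_T) is roughly T-independent.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t = np.arange(T + 1)
    if kind == "polynomial":
        raw = (1.0 - (t / T) ** 2) ** 2
        # precision scaling keeps abar_T slightly above zero
        raw = 1e-4 + (1.0 - 2e-4) * raw
        beta = 1.0 - raw[1:] / raw[:-1]
    elif kind == "linear":
        scale = 1000.0 / T
        beta = np.linspace(1e-4, 0.02, T) * scale
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    beta = np.concatenate([[0.0], np.clip(beta, 1e-5, 0.999)])
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    sigma = np.zeros(T + 1)
    sigma[1:] = np.sqrt(beta[1:] * (1.0 - alpha_bar[:-1])
                        / (1.0 - alpha_bar[1:]))
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar,
                         sigma=sigma)


# ---------------------------------------------------------------------------
# Forward process, posterior, reverse step (array level)
# ---------------------------------------------------------------------------

def q_sample(z0, t, schedule: NoiseSchedule, eps):
    """Draw z_t ~ q(z_t | z_0) = N(sqrt(abar_t) z_0, (1-abar_t) I) by
    reparameterization with the provided standard-normal draw ``eps``.
    ``t`` may be an int or an integer array broadcasting against z0's
    leading axes."""
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError(f"t must lie in 1..{schedule.T}")
    ab = schedule.alpha_bar[t]
    z0_arr = z0.data if isinstance(z0, Tensor) else np.asarray(z0)
    extra = z0_arr.ndim - ab.ndim
    ab = ab.reshape(ab.shape + (1,) * extra)
    if isinstance(z0, Tensor) or isinstance(eps, Tensor):
        return Tensor.as_tensor(z0) * np.sqrt(ab) \
            + Tensor.as_tensor(eps) * np.sqrt(1.0 - ab)
    return np.sqrt(ab) * z0_arr + np.sqrt(1.0 - ab) * np.asarray(eps)


def posterior_params(z_t, eps, t: int, schedule: NoiseSchedule
                     ) -> tuple[np.ndarray, float]:
    """Mean and variance of the true posterior q(z_{t-1} | z_t, z_0),
    written in terms of the forward noise eps = (z_t - sqrt(abar_t) z_0)
    / sqrt(1 - abar_t)."""
    if t < 1 or t > schedule.T:
        raise ValueError(f"t must lie in 1..{schedule.T}")
    a_t = schedule.alpha[t]
    ab_t = schedule.alpha_bar[t]
    mean = (np.asarray(z_t) - (1.0 - a_t) / np.sqrt(1.0 - ab_t)
            * np.asarray(eps)) / np.sqrt(a_t)
    var = float(schedule.sigma[t] ** 2)
    return mean, var


def reverse_step(z_t: np.ndarray, eps_hat: np.ndarray, t: int,
                 schedule: NoiseSchedule, noise: np.ndarray | float = 0.0
                 ) -> np.ndarray:
    """One ancestral sampling step: the posterior mean evaluated at the
    predicted noise, plus sigma_t times a fresh standard-normal draw
    (sigma_1 = 0 makes the last step deterministic)."""
    mean, _ = posterior_params(z_t, eps_hat, t, schedule)
    return mean + schedule.sigma[t] * noise


# ---------------------------------------------------------------------------
# Denoiser network
# ---------------------------------------------------------------------------


_TIME_FREQS = np.array([1.0, 2.0, 4.0, 8.0])


def time_features(t_frac) -> np.ndarray:
    """Sinusoidal embedding of the diffusion time t/T.

    A raw scalar is too coarse for the network to modulate its behavior
    sharply across noise regimes; Fourier features at a few frequencies
    are the standard remedy. Returns shape ``np.shape(t_frac) + (9,)``.
    """
    t = np.asarray(t_frac, dtype=np.float64)[..., None]
    ang = 2.0 * np.pi * t * _TIME_FREQS
    return np.concatenate([t, np.sin(ang), np.cos(ang)], axis=-1)


class Denoiser(Module):
    """Noise-prediction network over the latent pair.

    The time step (as sinusoidal features of t/T) — and, for conditional
    models, the normalized property value — is appended to every atom's
    invariant features. The equivariant noise estimate is read off
    residually from the coordinate channel, so it inherits zero CoM and
    SE(3) equivariance.
    """

    N_TIME = 9  # raw t/T + 4 sin/cos pairs

    def __init__(self, rng: np.random.Generator, k_latent: int = 3,
                 n_layers: int = 4, d_h: int = 64, m: int = 8,
                 d_hidden: int = 96, conditional: bool = False):
        self.config = dict(k_latent=k_latent, n_layers=n_layers, d_h=d_h,
                           m=m, d_hidden=d_hidden, conditional=conditional)
        self.k_latent = k_latent
        self.conditional = conditional
        n_in = k_latent + self.N_TIME + (1 if conditional else 0)
        self.net = GCPNetwork(n_in, k_latent, n_layers, rng,
                              d_h=d_h, m=m, d_hidden=d_hidden)

    def __call__(self, z_x, z_h, t_frac, condition=None
                 ) -> tuple[Tensor, Tensor]:
        z_x = Tensor.as_tensor(z_x)
        z_h = Tensor.as_tensor(z_h)
        lead = z_h.shape[:-1]
        tf = time_features(t_frac)
        if tf.ndim > 1:  # per-sample t: insert the atom axis
            tf = tf[..., None, :]
        cols = [z_h, Tensor(np.broadcast_to(tf, lead + (self.N_TIME,)).copy())]
        if self.conditional:
            if condition is None:
                raise ValueError("conditional denoiser requires a condition")
            cols.append(Tensor(np.broadcast_to(
                np.reshape(condition, np.shape(condition) + (1, 1))
                if np.ndim(condition) else condition, lead + (1,)).copy()))
        elif condition is not None:
            raise ValueError("condition passed to an unconditional denoiser")
        from . import autodiff as ad
        x_out, eps_h = self.net(z_x, ad.concatenate(cols, axis=-1))
        eps_x = x_out - z_x
        return eps_x, eps_h


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def diffusion_loss(z0_x, z0_h, t, eps_x, eps_h, denoiser: Denoiser,
                   schedule: NoiseSchedule, condition=None) -> Tensor:
    """Noise-matching loss ||eps - eps_theta(z_t, t)||^2, summed per atom
    over the coordinate and scalar latent blocks and averaged over atoms."""
    zt_x = q_sample(z0_x, t, schedule, eps_x)
    zt_h = q_sample(z0_h, t, schedule, eps_h)
    pred_x, pred_h = denoiser(zt_x, zt_h, np.asarray(t) / schedule.T,
                              condition)
    ex = Tensor.as_tensor(eps_x)
    eh = Tensor.as_tensor(eps_h)
    n_atoms = float(np.prod(ex.shape[:-1]))
    err = ((ex - pred_x) * (ex - pred_x)).sum() \
        + ((eh - pred_h) * (eh - pred_h)).sum()
    return err * (1.0 / n_atoms)


def joint_loss(x, h, autoencoder: GeometricAutoencoder, denoiser: Denoiser,
               schedule: NoiseSchedule, rng: np.random.Generator,
               condition=None) -> tuple[Tensor, float, float]:
    """One draw of the joint objective L = L_AE + L_LD on a (batched)
    molecule array. Returns (total loss tensor, L_AE value, L_LD value)."""
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    z_x, z_h = autoencoder.encode_arrays(x, h, rng)
    x_bar, h_bar = autoencoder.decode_arrays(z_x, z_h)
    l_ae = reconstruction_loss(x, h, x_bar, h_bar)

    batch_shape = x.shape[:-2]
    t = rng.integers(1, schedule.T + 1, size=batch_shape)
    eps_x = rng.standard_normal(z_x.shape)
    eps_x -= eps_x.mean(axis=-2, keepdims=True)
    eps_h = rng.standard_normal(z_h.shape)
    # the denoising term treats the latent as data (stop-gradient): the
    # encoder is shaped by reconstruction alone, so the latent
    # distribution the denoiser chases stays stationary
    l_ld = diffusion_loss(z_x.detach(), z_h.detach(), t, eps_x, eps_h,
                          denoiser, schedule, condition)
    total = l_ae + l_ld
    return total, float(l_ae.data), float(l_ld.data)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def denoise_step(z_x: np.ndarray, z_h: np.ndarray, t: int,
                 denoiser: Denoiser, schedule: NoiseSchedule,
                 rng: np.random.Generator, condition=None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One reverse transition z_t -> z_{t-1} for the latent pair. Fresh
    noise for the coordinate block is projected to zero CoM, and so is the
    output (numerical hygiene; the dynamics already preserve the
    subspace)."""
    with no_grad():
        eps_x, eps_h = denoiser(z_x, z_h, t / schedule.T, condition)
    noise_x = rng.standard_normal(z_x.shape)
    noise_x -= noise_x.mean(axis=-2, keepdims=True)
    noise_h = rng.standard_normal(z_h.shape)
    z_x_new = reverse_step(z_x, eps_x.data, t, schedule, noise_x)
    z_h_new = reverse_step(z_h, eps_h.data, t, schedule, noise_h)
    z_x_new -= z_x_new.mean(axis=-2, keepdims=True)
    return z_x_new, z_h_new


@dataclass
class ConditionNormalizer:
    mean: float
    sd: float

    def normalize(self, c: float) -> float:
        return (c - self.mean) / self.sd


@dataclass
class ModelBundle:
    """Everything needed to sample: autoencoder, denoiser, schedule,
    molecule-size distribution p(N), and (for conditional models) the
    property normalizer."""

    autoencoder: GeometricAutoencoder
    denoiser: Denoiser
    schedule: NoiseSchedule
    size_dist: AtomCountDistribution
    normalizer: ConditionNormalizer | None = None
    # latent whitening: the diffusion chain runs on z / scale so the
    # standard-normal prior matches the data variance; samples are
    # rescaled before decoding
    latent_scale: tuple[float, float] = (1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def sample(self, n_molecules: int, rng: np.random.Generator,
               condition: float | None = None) -> list[MoleculeGraph]:
        """Generate molecules: draw N ~ p(N), draw z_T from the standard
        normal prior (coordinate block zero-CoM), run T reverse steps,
        decode and discretize. Deterministic given the rng state."""
        if condition is not None and not self.denoiser.conditional:
            raise ValueError("condition passed to an unconditional model")
        if condition is None and self.denoiser.conditional:
            raise ValueError("conditional model requires a condition value")
        c_norm = (self.normalizer.normalize(condition)
                  if condition is not None else None)
        sizes = [sample_num_atoms(self.size_dist, rng)
                 for _ in range(n_molecules)]
        k = self.autoencoder.k_latent
        out: list[MoleculeGraph | None] = [None] * n_molecules
        for size in sorted(set(sizes)):
            idx = [i for i, s in enumerate(sizes) if s == size]
            b = len(idx)
            z_x = rng.standard_normal((b, size, 3))
            z_x -= z_x.mean(axis=-2, keepdims=True)
            z_h = rng.standard_normal((b, size, k))
            for t in range(self.schedule.T, 0, -1):
                z_x, z_h = denoise_step(z_x, z_h, t, self.denoiser,
                                        self.schedule, rng, c_norm)
            sx, sh = self.latent_scale
            with no_grad():
                x_bar, h_bar = self.autoencoder.decode_arrays(z_x * sx,
                                                              z_h * sh)
            for row, i in enumerate(idx):
                types, charges = self.autoencoder.decode_discrete(
                    h_bar.data[row])
                out[i] = MoleculeGraph(
                    x_bar.data[row], types, np.clip(charges, -2, 2),
                    condition=condition,
                    alphabet=self.autoencoder.alphabet)
        return out  # type: ignore[return-value]

    # -- checkpoint serialization (single binary file, config header) ------

    def save(self, path) -> None:
        config = dict(
            version=1,
            autoencoder=self.autoencoder.config,
            denoiser=self.denoiser.config,
            schedule_T=self.schedule.T,
            alphabet=list(self.autoencoder.alphabet),
            size_support=list(self.size_dist.support),
            size_probs=list(self.size_dist.probabilities),
            normalizer=(None if self.normalizer is None
                        else [self.normalizer.mean, self.normalizer.sd]),
            latent_scale=list(self.latent_scale),
            meta=self.meta,
        )
        arrays = {"__config__": np.frombuffer(
            json.dumps(config).encode(), dtype=np.uint8)}
        arrays["schedule_beta"] = self.schedule.beta
        for k, v in save_params(self.autoencoder).items():
            arrays[f"ae::{k}"] = v
        for k, v in save_params(self.denoiser).items():
            arrays[f"dn::{k}"] = v
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            beta = data["schedule_beta"]
            ae_state = {k[4:]: data[k] for k in data.files if k.startswith("ae::")}
            dn_state = {k[4:]: data[k] for k in data.files if k.startswith("dn::")}
        rng = np.random.default_rng(0)  # shapes only; weights overwritten
        ae = GeometricAutoencoder(rng, alphabet=tuple(config["alphabet"]),
                                  **config["autoencoder"])
        dn = Denoiser(rng, **config["denoiser"])
        load_params(ae, ae_state)
        load_params(dn, dn_state)
        alpha = 1.0 - beta
        alpha_bar = np.cumprod(alpha)
        T = int(config["schedule_T"])
        sigma = np.zeros(T + 1)
        sigma[1:] = np.sqrt(beta[1:] * (1 - alpha_bar[:-1])
                            / (1 - alpha_bar[1:]))
        schedule = NoiseSchedule(T, beta, alpha, alpha_bar, sigma)
        dist = AtomCountDistribution(tuple(config["size_support"]),
                                     tuple(config["size_probs"]))
        norm = (None if config["normalizer"] is None
                else ConditionNormalizer(*config["normalizer"]))
        scale = tuple(config.get("latent_scale", (1.0, 1.0)))
        return cls(ae, dn, schedule, dist, norm, latent_scale=scale,
                   meta=config.get("meta", {}))
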