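"""Quantitative validation experiments for the whole pipeline.

Each function runs one self-contained experiment — symmetry checks on the
networks, Monte-Carlo checks of the diffusion math, desk-scale trainings
with sample-quality metrics — and returns a flat dict of measured numbers
together with the problem size used. The test suite asserts on these
numbers; the reproduction script reports them.

All experiments are deterministic given their seed.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np
from scipy.spatial.transform import Rotation

from .autoencoder import GeometricAutoencoder, LatentState
from .diffusion import (Denoiser, make_schedule, posterior_params,
                        reverse_step)
from .evaluation import evaluate_samples, load_bond_table
from .gcpnet import GCPNetwork
from .molgraph import (center_molecule, featurize, generate_toy_dataset,
                       sample_num_atoms)
from .train import (reconstruction_metrics, train_autoencoder,
                    train_denoiser, train_joint)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def equivariance_suite(seed: int = 0, n_molecules: int = 10,
                       n_transforms: int = 20) -> dict:
    """Max deviation from exact SE(3) equivariance / invariance across the
    convolution stack, the encoder, the decoder and one reverse-diffusion
    step, over random rigid motions of random toy molecules.

    Translations act through the centering convention: inputs live on the
    zero-center-of-mass subspace, so a translated molecule is centered
    before encoding, which is the quotient-space reading of translation
    equivariance.
    """
    rng_net, rng_mol, rng_rot = _spawn(seed, 3)
    net = GCPNetwork(6, 6, 2, rng_net)
    ae = GeometricAutoencoder(rng_net, delta=0.0)
    dn = Denoiser(rng_net, k_latent=ae.k_latent, n_layers=1)
    sched = make_schedule(50)
    mols = generate_toy_dataset(n_molecules, seed=rng_mol, jitter_sd=0.1)
    max_coord = max_scalar = 0.0
    for mol in mols:
        mol = center_molecule(mol)
        x, h = mol.positions, featurize(mol)
        x_out, s_out = net(x, h)
        z = ae.encode(mol)
        dx, dh = ae.decode(z)
        zs_x = z.z_x
        zs_h = z.z_h
        eps1, _ = dn(zs_x, zs_h, 0.5)
        for k in range(n_transforms):
            R = Rotation.random(rng=rng_rot).as_matrix()
            tau = rng_rot.normal(scale=2.0, size=3)
            xt = (x @ R.T + tau)
            xt = xt - xt.mean(axis=0)
            # convolution stack
            x2, s2 = net(xt, h)
            max_coord = max(max_coord, np.abs(x2.data - x_out.data @ R.T).max())
            max_scalar = max(max_scalar, np.abs(s2.data - s_out.data).max())
            # encoder
            z2 = ae.encode(replace(mol, positions=xt))
            max_coord = max(max_coord, np.abs(z2.z_x - zs_x @ R.T).max())
            max_scalar = max(max_scalar, np.abs(z2.z_h - zs_h).max())
            # decoder
            dx2, dh2 = ae.decode(LatentState(zs_x @ R.T, zs_h))
            max_coord = max(max_coord, np.abs(dx2 - dx @ R.T).max())
            max_scalar = max(max_scalar, np.abs(dh2 - dh).max())
            # one reverse-diffusion step (deterministic part)
            eps2, _ = dn(zs_x @ R.T, zs_h, 0.5)
            m1, _ = posterior_params(zs_x, eps1.data, 10, sched)
            m2, _ = posterior_params(zs_x @ R.T, eps2.data, 10, sched)
            max_coord = max(max_coord, np.abs(m2 - m1 @ R.T).max())
    return {"max_coord_error": float(max_coord),
            "max_scalar_error": float(max_scalar),
            "n": n_molecules * n_transforms}


def chirality_gap(seed: int = 0, n_inits: int = 5) -> dict:
    """Smallest invariant-output gap between mirror-image chiral 4-point
    configurations across several random network initializations. An
    E(3)-invariant model would show a gap of exactly zero."""
    x = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0, 0, 0.9]])
    x -= x.mean(axis=0)
    mirror = x @ np.diag([1.0, 1.0, -1.0])
    s = np.eye(4, 6)
    gaps = []
    for rng in _spawn(seed, n_inits):
        net = GCPNetwork(6, 6, 2, rng)
        _, sa = net(x, s)
        _, sb = net(mirror, s)
        gaps.append(float(np.abs(sa.data - sb.data).max()))
    return {"min_gap": min(gaps), "max_gap": max(gaps), "n": n_inits}


def marginal_consistency(seed: int = 0, n_draws: int = 10_000,
                         t_target: int = 40, T: int = 100) -> dict:
    """Compose the one-step forward kernels and compare the empirical
    moments of z_t with the closed-form marginal, in units of the
    Monte-Carlo standard error."""
    s = make_schedule(T)
    rng = np.random.default_rng(seed)
    z0 = 1.7
    z = np.full(n_draws, z0)
    for t in range(1, t_target + 1):
        z = np.sqrt(1 - s.beta[t]) * z \
            + np.sqrt(s.beta[t]) * rng.standard_normal(n_draws)
    exp_mean = np.sqrt(s.alpha_bar[t_target]) * z0
    exp_var = 1 - s.alpha_bar[t_target]
    z_mean = (z.mean() - exp_mean) / np.sqrt(exp_var / n_draws)
    z_var = (z.var() - exp_var) / (exp_var * np.sqrt(2 / (n_draws - 1)))
    return {"mean_zscore": float(abs(z_mean)),
            "var_zscore": float(abs(z_var)), "n": n_draws}


def posterior_vs_numerical_bayes(seed: int = 0, T: int = 100,
                                 n_grid: int = 200_001) -> dict:
    """Compare the closed-form posterior q(z_{t-1} | z_t, z0) with direct
    numerical Bayes integration on a fine grid of scalar Gaussians."""
    s = make_schedule(T)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for t in (2, 20, 60):
        z0 = rng.normal()
        eps = rng.normal()
        z_t = np.sqrt(s.alpha_bar[t]) * z0 + np.sqrt(1 - s.alpha_bar[t]) * eps
        grid = np.linspace(-10, 10, n_grid)
        lik = np.exp(-(z_t - np.sqrt(1 - s.beta[t]) * grid) ** 2
                     / (2 * s.beta[t]))
        prior = np.exp(-(grid - np.sqrt(s.alpha_bar[t - 1]) * z0) ** 2
                       / (2 * (1 - s.alpha_bar[t - 1])))
        post = lik * prior
        post /= np.trapezoid(post, grid)
        num_mean = np.trapezoid(grid * post, grid)
        num_var = np.trapezoid((grid - num_mean) ** 2 * post, grid)
        mean, var = posterior_params(z_t, eps, t, s)
        worst = max(worst, abs(num_mean - float(mean)), abs(num_var - var))
    return {"max_abs_error": float(worst), "n": n_grid}


def gaussian_sampler_limit(seed: int = 0, n_chains: int = 5_000,
                           T: int = 100) -> dict:
    """Ancestral sampling with the analytically optimal denoiser for
    standard-normal scalar data: E[eps | z_t] = sqrt(1-abar_t) z_t.

    The closed-form limit of this chain is computable exactly: each step
    contracts by alpha_t and adds sigma_t^2, so the terminal variance is
    the recursion v_{t-1} = alpha_t v_t + sigma_t^2 from v_T = 1. With
    the reduced-variance posterior choice sigma_t^2 = beta-tilde the
    limit sits a few percent *below* the data variance 1 (it would be
    exactly 1 with sigma_t^2 = beta_t); the sampled population must
    recover the closed-form mean and variance within Monte-Carlo error.
    """
    s = make_schedule(T)
    expected_var = 1.0
    for t in range(T, 0, -1):
        expected_var = s.alpha[t] * expected_var + s.sigma[t] ** 2
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_chains)
    for t in range(T, 0, -1):
        eps_hat = np.sqrt(1 - s.alpha_bar[t]) * z
        noise = rng.standard_normal(n_chains) if t > 1 else 0.0
        z = reverse_step(z, eps_hat, t, s, noise)
    return {"mean": float(z.mean()), "variance": float(z.var()),
            "expected_variance": float(expected_var),
            "mean_se": float(np.sqrt(expected_var / n_chains)),
            "var_se": float(expected_var * np.sqrt(2 / (n_chains - 1))),
            "n": n_chains}


def autoencoder_recovery(seed: int = 0, n_train: int = 500,
                         n_test: int = 100, steps: int = 700,
                         fine_tune_steps: int = 300) -> dict:
    """Train the autoencoder alone on ideal toy molecules and measure
    atom-type accuracy and coordinate RMSD on held-out molecules."""
    rng_init, rng_data, rng_test = _spawn(seed, 3)
    ae = GeometricAutoencoder(rng_init)
    train = generate_toy_dataset(n_train, seed=rng_data, jitter_sd=0.0)
    test = generate_toy_dataset(n_test, seed=rng_test, jitter_sd=0.0)
    t0 = time.time()
    train_autoencoder(ae, train, steps=steps, batch_size=32, lr=2e-3,
                      seed=seed)
    train_autoencoder(ae, train, steps=fine_tune_steps, batch_size=32,
                      lr=4e-4, seed=seed + 1)
    metrics = reconstruction_metrics(ae, test)
    metrics.update({"train_seconds": time.time() - t0, "n": n_test})
    return metrics


def end_to_end_generation(seed: int = 0, n_train: int = 500,
                          joint_steps: int = 500,
                          denoiser_steps: int = 4600, T: int = 100,
                          n_samples: int = 200) -> dict:
    """Train the full latent diffusion model on the ideal toy set, then
    generate and evaluate samples with the valence-based metrics.

    Training runs in two phases: the joint objective until the
    reconstruction term converges, then denoiser-only refinement on the
    frozen autoencoder's latents (see train_denoiser)."""
    rng_init, rng_data, rng_sample = _spawn(seed, 3)
    ae = GeometricAutoencoder(rng_init)
    dn = Denoiser(rng_init, k_latent=ae.k_latent, n_layers=4)
    sched = make_schedule(T)
    train = generate_toy_dataset(n_train, seed=rng_data, jitter_sd=0.0)
    t0 = time.time()
    _, history = train_joint(ae, dn, sched, train, steps=joint_steps,
                             batch_size=32, lr=2e-3, seed=seed)
    bundle, hist2 = train_denoiser(ae, dn, sched, train,
                                   steps=denoiser_steps, batch_size=32,
                                   lr=2e-3, lr_final=5e-5, seed=seed + 1)
    history += hist2
    train_s = time.time() - t0
    samples = bundle.sample(n_samples, rng_sample)
    rep = evaluate_samples(samples, load_bond_table())
    return {"atom_stability": rep.atom_stability,
            "molecule_stability": rep.molecule_stability,
            "validity": rep.validity,
            "valid_and_unique": rep.valid_and_unique,
            "final_loss": history[-1].get("loss", history[-1].get("loss_ld")),
            "train_seconds": train_s, "n": n_samples}


def metric_correctness(seed: int = 0, n_per_level: int = 500) -> dict:
    """Ideal template molecules must score perfectly, and atom stability
    must degrade monotonically along a coordinate-jitter grid."""
    table = load_bond_table()
    rngs = _spawn(seed, 5)
    ideal = evaluate_samples(
        generate_toy_dataset(n_per_level, seed=rngs[0], jitter_sd=0.0), table)
    grid = (0.0, 0.1, 0.3, 1.0)
    curve = [evaluate_samples(
        generate_toy_dataset(n_per_level, seed=rng, jitter_sd=j),
        table).atom_stability for j, rng in zip(grid, rngs[1:])]
    return {"ideal_atom_stability": ideal.atom_stability,
            "ideal_molecule_stability": ideal.molecule_stability,
            "ideal_validity": ideal.validity,
            "jitter_grid_atom_stability": curve,
            "monotone": all(a >= b for a, b in zip(curve, curve[1:])),
            "n": n_per_level}


def size_distribution_fidelity(seed: int = 0, n_draws: int = 10_000,
                               n_train: int = 500) -> dict:
    """Molecule sizes drawn at sampling time must match the training
    histogram p(N) within multinomial error (max z-score over sizes)."""
    from .molgraph import atom_count_distribution
    rng_data, rng_draw = _spawn(seed, 2)
    train = generate_toy_dataset(n_train, seed=rng_data, jitter_sd=0.0)
    dist = atom_count_distribution(train)
    draws = np.array([sample_num_atoms(dist, rng_draw)
                      for _ in range(n_draws)])
    worst = 0.0
    for size, p in zip(dist.support, dist.probabilities):
        freq = np.mean(draws == size)
        se = np.sqrt(p * (1 - p) / n_draws)
        worst = max(worst, abs(freq - p) / se)
    return {"max_zscore": float(worst), "n": n_draws}
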