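"""Training loops for the autoencoder and the joint latent-diffusion model.

Molecules are grouped by atom count so each minibatch is a dense
(batch, N, ...) array; every step draws one size group (probability
proportional to its population) and a with-replacement minibatch from it.
All randomness flows from a single integer seed through named
`numpy.random.Generator` streams, so runs are exactly reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .autoencoder import GeometricAutoencoder, reconstruction_loss
from .diffusion import (ConditionNormalizer, Denoiser, ModelBundle,
                        NoiseSchedule, joint_loss)
from .molgraph import (MoleculeGraph, atom_count_distribution,
                       center_molecule, featurize)
from .nn import Adam


@dataclass
class SizeGroup:
    x: np.ndarray          # (B, N, 3), centered
    h: np.ndarray          # (B, N, nf)
    condition: np.ndarray | None  # (B,)


def group_by_size(mols: list[MoleculeGraph]) -> dict[int, SizeGroup]:
    groups: dict[int, list[MoleculeGraph]] = {}
    for m in mols:
        groups.setdefault(m.num_atoms, []).append(m)
    out = {}
    for n, ms in sorted(groups.items()):
        x = np.stack([center_molecule(m).positions for m in ms])
        h = np.stack([featurize(m) for m in ms])
        conds = [m.condition for m in ms]
        cond = (np.array(conds, dtype=np.float64)
                if all(c is not None for c in conds) else None)
        out[n] = SizeGroup(x, h, cond)
    return out


def _draw_batch(groups: dict[int, SizeGroup], batch_size: int,
                rng: np.random.Generator) -> SizeGroup:
    sizes = list(groups)
    weights = np.array([groups[s].x.shape[0] for s in sizes], dtype=float)
    size = sizes[rng.choice(len(sizes), p=weights / weights.sum())]
    g = groups[size]
    idx = rng.integers(g.x.shape[0], size=batch_size)
    return SizeGroup(g.x[idx], g.h[idx],
                     None if g.condition is None else g.condition[idx])


def train_autoencoder(ae: GeometricAutoencoder, mols: list[MoleculeGraph],
                      steps: int, batch_size: int = 32, lr: float = 1e-3,
                      seed: int = 0, log_every: int = 50) -> list[dict]:
    """Optimize the reconstruction loss alone; returns the step history."""
    groups = group_by_size(mols)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    opt = Adam(ae.parameters(), lr=lr)
    history = []
    t0 = time.time()
    for step in range(steps):
        batch = _draw_batch(groups, batch_size, rng)
        ae.zero_grad()
        z_x, z_h = ae.encode_arrays(batch.x, batch.h, rng)
        x_bar, h_bar = ae.decode_arrays(z_x, z_h)
        loss = reconstruction_loss(batch.x, batch.h, x_bar, h_bar)
        loss.backward()
        opt.step()
        if step % log_every == 0 or step == steps - 1:
            history.append({"step": step, "loss_ae": float(loss.data),
                            "elapsed_s": time.time() - t0})
    return history


def train_joint(ae: GeometricAutoencoder, denoiser: Denoiser,
                schedule: NoiseSchedule, mols: list[MoleculeGraph],
                steps: int, batch_size: int = 32, lr: float = 1e-3,
                seed: int = 0, log_every: int = 50,
                conditional: bool = False) -> tuple[ModelBundle, list[dict]]:
    """Jointly optimize L_AE + L_LD; returns the sampling-ready bundle
    (including p(N) traversed from the training set) and the history."""
    groups = group_by_size(mols)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    params = ae.parameters() + denoiser.parameters()
    opt = Adam(params, lr=lr)
    normalizer = None
    if conditional:
        conds = np.array([m.condition for m in mols], dtype=np.float64)
        if np.any(np.isnan(conds)):
            raise ValueError("conditional training requires a condition "
                             "value on every molecule")
        normalizer = ConditionNormalizer(float(conds.mean()),
                                         float(conds.std() or 1.0))
    history = []
    t0 = time.time()
    for step in range(steps):
        batch = _draw_batch(groups, batch_size, rng)
        cond = None
        if conditional:
            cond = (batch.condition - normalizer.mean) / normalizer.sd
        for p in params:
            p.grad = None
        loss, l_ae, l_ld = joint_loss(batch.x, batch.h, ae, denoiser,
                                      schedule, rng, cond)
        loss.backward()
        opt.step()
        if step % log_every == 0 or step == steps - 1:
            history.append({"step": step, "loss": float(loss.data),
                            "loss_ae": l_ae, "loss_ld": l_ld,
                            "elapsed_s": time.time() - t0})
    bundle = ModelBundle(ae, denoiser, schedule,
                         atom_count_distribution(mols), normalizer)
    return bundle, history


def train_denoiser(ae: GeometricAutoencoder, denoiser: Denoiser,
                   schedule: NoiseSchedule, mols: list[MoleculeGraph],
                   steps: int, batch_size: int = 32, lr: float = 1e-3,
                   lr_final: float | None = None, ema_decay: float = 0.999,
                   seed: int = 0, log_every: int = 50,
                   conditional: bool = False,
                   normalizer: ConditionNormalizer | None = None,
                   ) -> tuple[ModelBundle, list[dict]]:
    """Optimize the denoising loss alone, with the autoencoder frozen.

    Once the reconstruction term has converged its gradient is near zero,
    so continuing the joint objective reduces to this phase; skipping the
    frozen autoencoder's forward/backward roughly doubles the steps per
    second. Encoder outputs are cached per size group; the delta-noise of
    the encoder is drawn fresh every step so the denoiser sees the same
    latent distribution as under joint training.

    The learning rate decays linearly to ``lr_final`` (default lr/10),
    and an exponential moving average of the denoiser weights
    (``ema_decay``) is written back at the end — the EMA weights are what
    the returned bundle samples with.
    """
    from .autodiff import no_grad
    from .diffusion import diffusion_loss

    groups = group_by_size(mols)
    latents = {}
    for n, g in groups.items():
        with no_grad():
            z_x, z_h = ae.encode_arrays(g.x, g.h)
        latents[n] = (z_x.data, z_h.data, g.condition)
    # whiten: run the chain on z / scale so the unit-variance prior
    # matches the latent data variance (samples are rescaled on decode)
    scale_x = float(np.concatenate(
        [v[0].ravel() for v in latents.values()]).std() or 1.0)
    scale_h = float(np.concatenate(
        [v[1].ravel() for v in latents.values()]).std() or 1.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    params = denoiser.parameters()
    opt = Adam(params, lr=lr)
    lr_final = lr / 10.0 if lr_final is None else lr_final
    ema = [p.data.copy() for p in params]
    sizes = list(groups)
    # atom-weighted group sampling: the quality metrics are per-atom, so
    # larger molecules get proportionally more optimization attention
    weights = np.array([groups[s].x.shape[0] * s for s in sizes],
                       dtype=float)
    weights /= weights.sum()
    if conditional and normalizer is None:
        conds = np.array([m.condition for m in mols], dtype=np.float64)
        normalizer = ConditionNormalizer(float(conds.mean()),
                                         float(conds.std() or 1.0))
    history = []
    t0 = time.time()
    for step in range(steps):
        size = sizes[rng.choice(len(sizes), p=weights)]
        z_x_all, z_h_all, cond_all = latents[size]
        idx = rng.integers(z_x_all.shape[0], size=batch_size)
        z_x = z_x_all[idx] + rng.standard_normal(
            (batch_size,) + z_x_all.shape[1:]) * ae.delta
        z_x -= z_x.mean(axis=-2, keepdims=True)
        z_x /= scale_x
        z_h = z_h_all[idx] + rng.standard_normal(
            (batch_size,) + z_h_all.shape[1:]) * ae.delta
        z_h /= scale_h
        cond = None
        if conditional:
            cond = (cond_all[idx] - normalizer.mean) / normalizer.sd
        t = rng.integers(1, schedule.T + 1, size=batch_size)
        eps_x = rng.standard_normal(z_x.shape)
        eps_x -= eps_x.mean(axis=-2, keepdims=True)
        eps_h = rng.standard_normal(z_h.shape)
        denoiser.zero_grad()
        loss = diffusion_loss(z_x, z_h, t, eps_x, eps_h, denoiser, schedule,
                              cond)
        loss.backward()
        opt.lr = lr + (lr_final - lr) * step / max(steps - 1, 1)
        opt.step()
        for e, p in zip(ema, params):
            e *= ema_decay
            e += (1.0 - ema_decay) * p.data
        if step % log_every == 0 or step == steps - 1:
            history.append({"step": step, "loss_ld": float(loss.data),
                            "elapsed_s": time.time() - t0})
    for e, p in zip(ema, params):
        p.data = e.copy()
    bundle = ModelBundle(ae, denoiser, schedule,
                         atom_count_distribution(mols), normalizer,
                         latent_scale=(scale_x, scale_h))
    return bundle, history


def reconstruction_metrics(ae: GeometricAutoencoder,
                           mols: list[MoleculeGraph]) -> dict[str, float]:
    """Atom-type accuracy and coordinate RMSD of encode-decode on held-out
    molecules (both measured in the centered frame)."""
    n_correct = n_atoms = 0
    sq = 0.0
    for m in mols:
        m = center_molecule(m)
        rec = ae.reconstruct(m)
        n_correct += sum(a == b for a, b in zip(rec.atom_types, m.atom_types))
        n_atoms += m.num_atoms
        sq += float(((rec.positions - m.positions) ** 2).sum())
    return {"type_accuracy": n_correct / n_atoms,
            "coord_rmsd": float(np.sqrt(sq / n_atoms))}
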