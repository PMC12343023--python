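# Methods

## Overview

`chiraldiff` generates 3D molecules — atom coordinates `x ∈ R^{N×3}` (Å),
element types and formal charges — with a latent diffusion model whose
every network component is an SE(3)-equivariant, chirality-aware graph
convolution. The pipeline has three parts:

1. a **geometry-complete autoencoder** mapping molecules `(x, h)` to a
   continuous latent pair `z = (z_x, z_h)` and back,
2. a **denoising diffusion model** over that latent space, and
3. **valence-based evaluation** of generated samples (atom/molecule
   stability, RDKit validity, uniqueness).

## Geometry-complete convolution (GCPConv)

Molecules are treated as fully connected graphs. Every ordered atom pair
`(i, j)` carries a local orthonormal frame built from *centered*
coordinates:

    a_ij = (x_i − x_j) / ‖x_i − x_j‖
    b_ij = (x_i × x_j) / ‖x_i × x_j‖
    c_ij = a_ij × b_ij

Under a proper rotation `R` each frame row maps to `R·row`, so projecting
vector features (the node channel `χ ∈ R^{N×m×3}` and the edge
displacement `ξ_ij = x_i − x_j`) onto the frame rows yields rotation- and
translation-invariant scalars ("scalarization"). Because `b_ij` is a
pseudovector, these scalars are *not* invariant under reflection: the
network distinguishes mirror images, i.e. it is SE(3)- but not
E(3)-equivariant. This is the property that lets it resolve chirality,
and it is asserted quantitatively in the test suite (mirror-image chiral
four-point configurations must produce different invariant outputs).

One layer performs: message MLP over `[h_i, h_j, e_ij, scalarized
(χ_i, χ_j, ξ_ij), ‖x_i − x_j‖]` → mean aggregation over neighbors →
residual node update (invariant channel) and gated vector update
(equivariant channel) → a perceptual module producing an invariant update
`h_p` and an equivariant update `χ_p` → a residual coordinate update from
a learned combination of the `χ_p` channels, re-projected to zero center
of mass. Vector outputs are always scalar-gated combinations of
equivariant inputs (`χ_i`, `χ_j`, `ξ_ij`, frame rows), which is what makes
equivariance exact rather than approximate.

Key conventions:

- **Zero center of mass everywhere.** `b_ij` uses absolute positions, so
  it is only well-defined relative to a fixed origin; all coordinates are
  required to be centered (the constructor raises otherwise). Translations
  then act on the quotient space: equivariance under translation means
  `center(x + τ)` gives the same output. This is the standard resolution
  in equivariant diffusion models, and without it the translation part of
  the symmetry contract is false as written.
- **Degenerate frames and the cross gate.** For atoms collinear with the
  centroid (all pairs of a linear molecule) the cross product vanishes
  and the b/c rows are undefined; for coincident atoms the whole frame
  is. The norms are ε-regularized so the affected rows go to zero
  *naturally* at the degenerate set, and because b/c are directionally
  unstable *near* it, their projections and basis contributions are
  scaled by a smooth gate `w = ‖x_i × x_j‖² / (‖x_i × x_j‖² + s²)` with
  `s = 0.1`. The stable a-row is never suppressed. The network is
  therefore a continuous function of the coordinates across collinear
  configurations (asserted by a convergence test). This matters in
  practice: training sees noise-perturbed (hence non-collinear) geometry,
  so a hard degeneracy cutoff would process an exactly-linear molecule in
  a regime the network never trained on — which showed up as a
  reproducible atom-type misclassification on hydrogen cyanide before
  the gate was introduced. Pairs below ε = 1e−6 are still *flagged*
  degenerate for inspection.
- **Radial input feature.** Each network receives `‖x_i‖` (distance to
  the centroid) as one extra invariant input scalar. For linear molecules
  every frame is degenerate and all scalarized vector features vanish;
  the radial scalar keeps atoms geometrically distinguishable there.
- **Edge features.** Edge scalars are 16 Gaussian radial basis functions
  of the pairwise distance over [0, 8] Å, computed once from the input
  geometry of a stack and shared by its layers; edge vectors `ξ` and the
  frames are recomputed from the current coordinates in every layer.
- **Aggregation** defaults to the mean over neighbors (size-robust across
  variable N); sum is available by configuration.

Default widths: invariant channel `d_h = 64`, hidden width 96, `m = 8`
vector channels. The message/update networks are two-layer MLPs with SiLU
activations. Coordinate-update heads start at zero, so every stack is the
identity on coordinates at initialization.

## Autoencoder

The encoder is one GCPConv stack emitting `z_x ∈ R^{N×3}` (equivariant,
zero CoM) and `z_h ∈ R^{N×k}` (invariant); during training,
standard-normal noise scaled by `δ = 0.1` is added to both blocks (and
`z_x` re-projected). This keeps the discrete atom features continuous in
latent space, and — just as importantly — trains the *decoder* to project
noisy latents back onto clean geometry. At sampling time the reverse
diffusion chain lands near, not on, the latent data manifold; a decoder
trained against `δ`-scale perturbations absorbs that residual error
instead of passing it through to the atom coordinates. `δ` is small
against the ~1–2 Å coordinate scale; with `δ = 0.01` the correction
effect is negligible and desk-scale sample stability drops markedly. The decoder applies three GCPConv stacks and emits
reconstructed coordinates and scalar-feature logits; types are recovered
by argmax over the one-hot block (ties broken in alphabet order) and
charges by nearest integer.

The reconstruction objective is the squared L2 error over coordinates and
scalar features, summed per atom and averaged over atoms so molecules of
different sizes weight equally in a batch. Squared error is used for the
one-hot block as well (cross-entropy would also be natural; squared error
is the stated objective and trains to 100% type accuracy on the toy
distribution).

**Latent width.** `k = 3` invariant channels by default. With `k = 2`
the encoder reproducibly collapses two element/environment clusters (the
nitrogen of hydrogen cyanide onto fluorine), capping held-out type
accuracy at ~98%; three channels separate all clusters on the H/C/N/O/F
alphabet while still compressing the 6 scalar features. The noise `σ·δ`
is applied during training only; encoding at inference is deterministic.

## Diffusion model

Standard DDPM algebra on the latent pair, with every Gaussian draw that
touches the coordinate block mean-projected onto the zero-CoM subspace —
this makes the prior rotation-invariant *and* translation-well-defined,
which together with equivariant reverse transitions makes the sample
distribution rotation-invariant.

- Forward: `q(z_t | z_{t−1}) = N(√(1−β_t) z_{t−1}, β_t I)` with marginal
  `q(z_t | z_0) = N(√ᾱ_t z_0, (1−ᾱ_t) I)`, `ᾱ_t = Π α_i`. Both are
  cross-checked in tests by Monte-Carlo composition and, for the
  posterior `q(z_{t−1} | z_t, z_0)`, by numerical Bayes integration.
- Schedule: the functional form is a free choice; the default is the
  polynomial `ᾱ_t ∝ (1 − (t/T)²)²` used across the equivariant-diffusion
  lineage, with the implied `β_t` clipped to `[1e−5, 0.999]`; a linear-β
  schedule (scaled by 1000/T so the terminal `ᾱ_T` is T-independent) is
  available for ablation. Invariants enforced: `ᾱ` strictly decreasing,
  `ᾱ_T < 0.01`. Boundary conventions `ᾱ_0 = 1`, `σ_1 = 0` (deterministic
  final step).
- The denoiser is a GCPConv stack (default 4 layers) predicting the noise
  pair `(ε_x, ε_h)`; the time step enters as sinusoidal features of `t/T`
  (the raw value plus four sin/cos pairs) appended to every atom's
  invariant features — a bare scalar proved too coarse for the network to
  modulate its behavior across noise regimes. For conditional models the
  property value — normalized to zero mean and unit variance over the
  training set — is appended the same way.
  The equivariant block `ε_x` is read off residually (output coordinates
  minus input coordinates), so it inherits zero CoM and exact
  equivariance. The network output is used directly as predicted noise;
  the posterior mean is then the usual
  `(z_t − (1−α_t)/√(1−ᾱ_t)·ε̂)/√α_t`.
- Loss: `‖ε − ε̂‖²` summed per atom over both blocks, averaged over
  atoms, with `t` uniform on `1..T`.

**Joint objective.** Training minimizes `L = L_AE + L_LD` in one
optimizer. The denoising term is evaluated on *stop-gradient* latents:
the encoder is shaped by reconstruction alone, so the latent distribution
the denoiser chases stays stationary. (Backpropagating `L_LD` into the
encoder destroys reconstruction in practice — held-out RMSD degraded from
~0.003 Å to ~0.3 Å in our experiments — because the denoising term
dominates and drags the latent map.)

**Sampling.** Draw the molecule size `N ~ p(N)` from the empirical
training histogram, draw `z_T` from the standard-normal prior (coordinate
block projected), run `T` reverse steps, decode, discretize. All
randomness flows from one `numpy` generator, so sampling is reproducible
given a seed.

## Evaluation metrics

Generated molecules carry no bonds; bonds are inferred from interatomic
distances against a table of reference covalent bond lengths for
H/C/N/O/F (single/double/triple), shipped as an editable TSV resource.
A pair at distance `d` receives the *highest* order whose window
`[length − margin, length + margin]` contains `d`; margins are
order-dependent (0.10 / 0.05 / 0.03 Å), the lookup convention of
distance-based bond inference in equivariant molecule generation. Element
pairs absent from the table never bond (logged once).

- *Atom stability*: the summed inferred bond orders equal an allowed
  valence for the element adjusted by formal charge (N and O gain/lose a
  bond with charge, e.g. N⁺ binds 4 and O⁻ binds 1; for other elements a
  charge removes a bond).
- *Molecule stability*: every atom stable.
- *Validity*: the inferred connection table sanitizes under RDKit.
- *Valid-and-unique*: first occurrences of the canonical SMILES among the
  valid samples, over the full sample count.

Metrics can be reported as mean ± sd over equal sample batches (the
convention for repeated sampling runs).

## Toy dataset

The bundled generator emulates an idealized micro-version of a small
organic molecule set: nine templates (water, ammonia, methane, methanol,
ethane, ethene, formaldehyde, hydrogen fluoride, hydrogen cyanide) with
textbook bond lengths and angles, each drawn under a uniform random
rotation, a Gaussian translation (sd 2 Å) and optional i.i.d. coordinate
jitter. At zero jitter the set scores exactly 100% on all stability
metrics, which ties the generator to the evaluation module; increasing
jitter degrades stability monotonically, giving the metrics a non-trivial
operating range.

What it does *not* emulate: conformational flexibility, size diversity
beyond 2–8 atoms, aromatic systems, charge diversity, or the property
labels of quantum-chemistry datasets. Training and passing tests on this
distribution demonstrates that the machinery is correct and trainable at
desk scale, not that it reproduces benchmark numbers on real datasets —
those require GPU-scale training and are out of scope. Hydrogens are
explicit throughout.

## Problem sizes and numerical choices

Desk-scale experiment sizes (chosen so the whole validation suite runs
comfortably on one CPU): autoencoder recovery trains on 500 ideal
molecules for 1,000 Adam steps (batch 32, lr 2e−3 then 4e−4). The full
model trains in two phases: 500 steps of the joint objective (lr 2e−3)
— enough for the reconstruction term to converge — then 4,600
denoiser-only refinement steps on the frozen autoencoder's latents
(lr decaying 2e−3 → 5e−5 linearly, EMA decay 0.999, size groups drawn
proportional to their atom counts), with `T = 100`; quality is measured
on 200 generated samples. Monte-Carlo oracles use 10,000 draws and the
closed-form sampler check 5,000 chains. `T = 1000` and longer training
remain the intended settings for full-scale runs; at desk scale the
generated-sample atom stability lands around 0.75–0.85 depending on the
training seed (the estimate over 200 molecules itself carries a
standard error of roughly 3 points).

One closed-form subtlety worth recording: with the reduced-variance
posterior `σ_t² = β̃_t` the ancestral chain slightly under-disperses
broad data distributions — for standard-normal scalar data and `T = 100`
its exact terminal variance is 0.957, not 1 (it equals 1 only for the
`σ_t² = β_t` convention). The sampler tests therefore compare against
the exact variance recursion, not against the data variance.

Everything is float64. Equivariance is asserted at 1e−4 (absolute, on
unit-scale data) to absorb accumulation-order effects; frame algebra
itself is exact to ~1e−10. Gradient-norm clipping at 10 stabilizes early
joint training. Optimizer state is not serialized: resuming a checkpoint
restarts Adam moments (the step counter continues).

## Known limitations

- The cross-product frame construction ties translation handling to the
  centering convention; inputs must be centered by the caller (enforced).
- Linear molecules exercise only the scalar message path (all frames
  degenerate); they train slower than bent geometries.
- The latent prior is the projected standard normal, not learned; no
  likelihood evaluation, classifier-free guidance or accelerated
  samplers.
- Uniqueness is meaningful only for large sample counts; on the
  nine-template toy distribution it saturates at 9 / n_samples.
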