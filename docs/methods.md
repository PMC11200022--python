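# Methods

## The estimation problem

A diffusion-weighted acquisition measures, per voxel, signals
S = [S_1 … S_n] along encoding directions v_i with b-values b_i.  A
biophysical or signal model maps per-voxel parameters P to predicted
signals Ŝ_i = f(P, v_i, b_i).  Classical fitting inverts f voxel by
voxel (linearized least squares, or nonlinear search).  dwifit instead
trains a small convolutional network G that maps the measured volumes to
parameter maps, P̂ = G(S), and optimizes the network weights by gradient
descent on the discrepancy between the measured signals and the signals
the forward model re-synthesizes from P̂ — a self-supervised,
physics-informed formulation that needs no reference parameter maps.
Because one network serves all voxels, the mapping is regularized by
shared structure across voxels, which suppresses noise relative to
independent per-voxel fits.

## Forward models

**Diffusion tensor** (7 parameters: six unique D_jk in mm²/s, plus S0):

    S_i = S0 · exp(−b_i Σ_jk v_ij v_ik D_jk)

No positive-definiteness constraint is imposed, matching the behaviour
of log-linear least-squares fits.

**Diffusion kurtosis** (22 parameters: D, the 15 unique elements of the
fully symmetric rank-4 kurtosis tensor K_jklm, and S0):

    S_i = S0 · exp(−b_i Σ v v D + (1/6) b_i² MD² K_app(v_i)),
    K_app(v) = Σ_jklm v_j v_k v_l v_m K_jklm,   MD = tr(D)/3.

K is stored as the 15 sorted-index elements; the quartic form applies
the multiset permutation multiplicities 4!/∏(counts!) ∈ {1, 4, 6, 12}.

**Watson-NODDI** (5 parameters: f_iso, f_ic, mean orientation µ given by
azimuth/elevation angles, Watson concentration κ):

    S_i = S0 [(1−f_iso)(f_ic A_ic + (1−f_ic) A_ec) + f_iso A_iso]

* A_iso = exp(−b d_iso), the CSF ball.
* A_ic: a stick (axial diffusivity d∥, zero radial) dispersed by the
  Watson distribution W(n|µ,κ) ∝ exp(κ(µ·n)²).  The orientation
  integral is evaluated by a fixed product quadrature on the sphere
  (Gauss–Legendre in cos θ × uniform azimuth, default order 28 → 1568
  nodes, ≤1e-4 relative error up to κ ≈ 64).  Because the integrand
  factorizes as exp(κ(µ·n)²)·exp(−b d∥ (v·n)²), the acquisition factor
  is precomputed once per scheme and the per-voxel cost reduces to one
  elementwise exponential and a matrix product.
* A_ec: the tortuosity zeppelin (radial diffusivity d∥(1−f_ic)) averaged
  over the Watson distribution.  The average uses
  τ₁(κ) = E[(µ·n)²] = ₁F₁(3/2,5/2,κ) / (3·₁F₁(1/2,3/2,κ)).  A config
  switch `ec_dispersion=False` disables the κ-average (zeppelin rigidly
  aligned with µ) for comparison, since published formulations differ on
  whether the extra-cellular tensor sees the dispersion.
* Constants: d∥ = 1.7e-3 mm²/s, d_iso = 3.0e-3 mm²/s — the canonical
  in-vivo NODDI values.
* S0 is an input (the mean of the b=0 volumes), not a fitted parameter.

Gradients with respect to κ flow through the confluent hypergeometric
normalization via the exact identity
d₁F₁(1/2,3/2,κ)/dκ = (1/3)·₁F₁(3/2,5/2,κ), wired into the autodiff
graph as a custom primitive (scipy evaluates the forward values).

## Network and output scaling

The mapping network is deliberately plain: M layers of 3×3×3
convolution (stride 1, zero padding, size-preserving; receptive field
2M+1 voxels per axis) followed by N layers of 1×1×1 convolution, with
M+N = 7.  Channel widths follow n_in → c1 → c2 → c2 → c2 → c2 → c3 → c4
with c2 = 256 and c3 = 64 by default; c4 equals the parameter count of
the model (7/22/5).  ReLU follows every layer except the last.  Every
layer whose output width is c2 is paired with a dropout layer
(p = 0.05).  Weights use seeded fan-in uniform initialization.

Output scaling: tensor and kurtosis channels receive no squashing — the
diffusivity channels are read in µm²/ms and converted linearly (×1e-3)
to mm²/s.  This unit convention keeps the network outputs at O(1),
which is where O(1)-scaled initializations and Adam steps operate;
training directly at the 1e-3 mm²/s scale stalls.  For NODDI, the
fraction channels pass through a sigmoid; the concentration channel x
maps to sigmoid(x) for x < 0 and 0.5 + x for x ≥ 0 (continuous at 0,
unbounded above); the two orientation angles pass through unchanged
(the Watson distribution is antipodally symmetric, so the sign of µ is
irrelevant).

**MC dropout.**  Dropout stays active at inference; the trained network
is applied l = 20 times (seeded), outputs are scaled to parameters, and
their per-voxel mean is the estimate while the per-voxel standard
deviation is the uncertainty map.  l = 1 is the single stochastic pass.

## Objectives

**Masked MSE.**  L = (1/n) Σ_i MSE over masked voxels of (S_i, Ŝ_i).
The mask is the brain-tissue mask (excluding CSF) for tensor/kurtosis
and the whole-brain mask for NODDI.

**CWLS** (kurtosis).  A log-linear OLS pre-fit P̂_ols = (XᵀX)⁻¹Xᵀ ln S
supplies per-voxel weights ω = softmax(Ŝ_ols) over the n volumes,
computed once from the input data and frozen (no gradient flows through
them).  The content term is Σ_i MSE(ω_i S_i, ω_i Ŝ_i), evaluated on raw
signals by default; a `cwls_log` switch evaluates the residual on log
signals instead, since the weighted-least-squares literature works in
the log domain while the normalized-weights formulation above is stated
on raw signals — both are provided, raw is the default.  The bound term
penalizes negative apparent kurtosis along a fixed 60-direction
repulsion set: L_bound = mean over masked voxels of Σ_d ReLU(−K_app(d)),
and L_cwls = L_content + λ·L_bound with λ = 1000.

## Training

Volumes are normalized by the median of the mean-b0 image within brain
tissue (the scale is returned so S0 maps back to scanner units), then
tiled into blocks over the brain-mask bounding box: per axis,
ceil(extent/block_size) origins evenly spaced with the last block flush
to the boundary (minimal overlap); volumes smaller than the block are
zero-padded, and the pad never enters the loss because it lies outside
every mask.  Each block is one Adam step (batch size one block).
Left-right flipping doubles the block set; the gradient table is not
mirrored — a mirrored signal block is a valid signal pattern whose
implied orientations are mirrored, so the self-supervised objective
remains consistent.

The learning rate is staged: 1e-3 for the first 10 000 block-steps,
1e-4 for the following 6000 (defaults; both counts configurable).  With
Monte-Carlo validation enabled, the (augmented) block set is re-split
80/20 at every epoch, the validation loss is evaluated after each epoch
with dropout off, and the weights at the minimum validation loss are
kept.  Validation checkpointing is disabled by default for NODDI, where
it tends to lock in early local minima of the dispersion/orientation
channels.  Transfer learning: `pretrain` pools blocks across subjects at
the stage-1 rate; `fine_tune` continues at 1e-4.
`synthesize_training_targets` generates noise-free volumes from
reference parameters on an arbitrary gradient table, enabling
cross-scheme pre-training.

Determinism: every stochastic element (init, shuffling, dropout,
validation splits, noise draws) derives from one seed; two runs with
the same TrainSpec produce bitwise-identical checkpoints
single-threaded.  A non-finite block loss is skipped with a warning;
two in a row abort.

## Numerical choices

* Signal exponents are clamped to ±15 (pass-through gradient inside the
  window).  Physical exponents for in-vivo diffusivities at b ≤ 3000
  s/mm² stay within roughly [−10, 3]; the clamp only protects the first
  optimization steps from overflow of the exponential.
* Signals are floored at 1e-6 (of the normalized b0 level) before
  logarithms; the W = MD²·K → K conversion guards MD² ≥ 1e-12.
* b-values ≤ 50 s/mm² count as non-diffusion-weighted.
* The 60-direction bound set, the 256-direction metric set, the
  phantom's 90- and 128-direction shells and every other orientation set
  come from the same incremental electrostatic-repulsion construction
  with fixed documented seeds, so any prefix of a scheme is itself
  near-uniform (this mirrors how staged acquisition tables are designed,
  and keeps sub-sampled schemes well conditioned).
* Radial kurtosis averages set directions within 1° of the plane
  perpendicular to V1; if the 256-point set has none for a given V1 (the
  band covers ~1.7% of the sphere, so small sets can miss it), an exact
  16-point perpendicular ring is used instead.  Axial kurtosis uses the
  exact V1 direction.
* SSIM standardizes each image by its tissue mean/std, maps x→(x+3)/6
  without clamping the |z|>3 tails, and uses Gaussian weighting
  (σ = 1.5) with the standard constants; values are averaged over the
  tissue mask.

## The phantom generator

`make_phantom` reproduces a multi-tensor protocol: every voxel holds
1–3 tensors (equal volume fractions 1/T) with eigenvalues
[1.5e-3, 3e-4, 3e-4] mm²/s and principal axes drawn rectangle-uniformly
in azimuth θ ∈ [0°, 360°] and elevation Φ ∈ [−90°, 90°] — deliberately
*not* area-uniform on the sphere, replicating the stated protocol.  The
default scheme is 18 b=0 plus 90 + 128 b=1000 s/mm² directions (236
samples); Rician noise uses σ = s0/SNR on both quadrature channels
(S̃ = √((S+ε₁)² + ε₂²)), with noise-free data kept as ground truth.
Ground-truth scalar maps are obtained by the OLS tensor fit of the
noise-free signal, so "truth" means the same thing for every method
compared.  Kurtosis phantoms draw K = a·K_iso + c·(u⊗u⊗u⊗u) with
a ∈ [0.3, 1.5], c ∈ [0, 1.5], keeping directional apparent kurtosis in
[0, 3]; NODDI phantoms draw fractions uniformly in [0.05, 0.95] and κ
log-uniformly in [0.5, 16].  What the phantoms do **not** emulate:
anatomy and spatial correlation (parameters are independent across
voxels, so convolutional context cannot help and results understate the
spatial-regularization benefit on real brains), spatially varying SNR,
gradient nonlinearity, motion, eddy currents, and susceptibility
distortion.  Passing tests therefore validate the estimators and
optimization machinery, not in-vivo performance.

## Evaluation statistics

Masked MAE with the protocol's exclusion rules: kurtosis metric errors
above the 97th percentile are dropped (outlier convention for MK/RK);
NODDI f_ic and ODI errors exclude voxels whose reference f_iso exceeds
0.8 (there the remaining parameters are arbitrary).  Orientation error
is arccos|a·b| in degrees.  ODI = (2/π)·arctan(1/κ).  Directional
kurtosis for the metric maps is MD²·K_app(v)/D_app(v)²; directions with
non-positive D_app are excluded.

## Test and script problem sizes

The shipped test-suite and acceptance-script runs use reduced problem
sizes chosen as the package's own desk-scale design: 8³–16³ voxel
phantoms, 30–63 volume schemes, networks at width c2 = 64 (128 for the
NODDI input layer), and 1500–2000 block-steps, which reproduce the
qualitative comparisons (denoising vs OLS across ten seeds, MC-20 vs
MC-1, constrained vs unconstrained kurtosis, transfer between phantoms)
in minutes on one CPU.

## Known limitations

* The NODDI recovery experiment shows that with spatially independent
  voxels drawn uniformly over the full parameter box, the per-voxel
  information limit dominates: at SNR 20 even an exhaustive refined grid
  search attains f_ic MAE ≈ 0.2 (errors concentrate at high f_iso,
  where f_ic is weakly identified), and the network fit tracks rather
  than beats that floor.  On real tissue — spatially smooth maps, f_iso
  near zero outside CSF — both the absolute errors and the network's
  relative advantage are substantially better.
* The numpy autodiff/NN stack is single-threaded and trades speed for
  having no heavyweight framework dependency; problem sizes beyond
  ~10⁵ voxels per step become slow.
* Rician bias is not modelled in any objective (MSE on magnitude data);
  all compared methods share this bias.
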