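# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Reconstruction model

Undersampled Cartesian 2D multicoil k-space `S(0) ∈ ℂ^{nx×ny×nc}` (phase
encoding on axis 0, every R-th line acquired outside a fully sampled
central ACS block, DC at index `n//2`) is interpolated by a scan-specific
complex-valued CNN:

    S'(k) = S(k-1) ⊛ W(k)          (complex conv, dilated by R along PE)
    S(k)  = ℂLReLU(S'(k))          = LReLU(Re) + i·LReLU(Im), slope a ∈ [0,1]
    S(int) = S(nhid) ⊛ W(int)      (linear, R·nc output channels)

There are no bias terms. Output channel `r·nc + c` (offset-major), read at
a sampled grid line `p`, estimates coil `c` at line `p + r`. Acquired grid
lines are kept from the measured data by default; off-grid ACS lines are
*not* re-inserted at inference, so reconstruction quality can be judged on
them too. With `a = 1` the model is globally linear; one linearly activated
layer calibrated by least squares is exactly GRAPPA, and the whole analysis
machinery below applies to it unchanged.

Defaults: two hidden layers of 128/64 channels, kernels [2,5], [1,1],
[1,5], slope a = 0.5. The real-parameter count is
`2·Σ bx·by·ch_in·ch_out`; the eight totals for 16/20 coils at R = 4–6 and
for the wide-first-kernel ([4,7]) variant are asserted exactly in the
acceptance suite.

### Tap-offset convention

Kernel taps sit at signed k-space offsets `(i − (bx−1)//2)·R` along PE and
`j − (by−1)//2` along RO, so a `[2,·]` kernel reads the sampled line at the
target's own grid position and the one above — the bracketing geometry of
standard GRAPPA. Convolutions are cross-correlation-oriented and circular
(periodic) by default; a zero-padded mode exists for fidelity studies, and
its deviation from the circular mode is confined to boundary k-space lines
(asserted in the tests).

## Training

All layers are calibrated jointly on the ACS by Adam (lr 5e-4, full ACS as
one batch per iteration, complex Glorot initialization, seeded). Gradients
are hand-derived Wirtinger/real-pair gradients for this specific
architecture, implemented in NumPy with im2col + BLAS matmuls. The source
is the ACS with only every R-th line retained; targets are the true ACS
values in the inference channel layout; the loss (mean squared complex
error) is evaluated only where the dilated receptive field is fully
supported inside the ACS. The ACS is normalized by its maximum modulus
before training — the network is positively homogeneous (leaky ReLU
included), so trained weights apply unchanged at any data scale. Training
offsets include `r = 0` (identity reproduction), consistent with the
`R·nc` output-channel layout. Default 2000 epochs with early stopping on a
200-epoch loss plateau; the returned weights are the best-loss iterate.
Epoch counts in tests and the acceptance script are smaller (600–1500,
stated per experiment) — these small scan-specific networks converge in
hundreds of iterations at the 64×64 problem sizes used.

## Image-space formalism

All transforms are unitary and centered. Three exact building blocks:

- **Kernel transfer.** A dilated k-space convolution is an elementwise
  multiplication in image space by the transfer function obtained by
  embedding the taps at their signed offsets and evaluating the
  (unnormalized) centered DFT; a central unit tap maps to the constant 1.
- **Activation masks.** ℂLReLU in k-space equals elementwise
  multiplication by the mask `A = ℂLReLU(S')/S'` (set to 1 where `S' = 0`;
  any finite value preserves the identity there since ℂLReLU(0) = 0, and 1
  keeps the linear limit exact with zero spurious mask energy). Since
  `f_a = a·id + (1−a)·relu`, masks obey `A(a) − 1 = (1−a)(A(0) − 1)`: mask
  deviation — and hence off-center mask-image energy — scales exactly as
  `(1−a)²`, which is the monotonicity the mask-structure tests assert. The
  image-domain mask `Â = IFFT(A)/√N` is scaled so that the centered
  circular convolution `x ⊛ Â` (zero lag at `n//2`) equals the k-space
  product exactly; `A ≡ 1` maps to a one-pixel delta.
- **Offset recombination.** Placing offset-channel estimates on their PE
  lines is done by summing phase-ramp-modulated offset images (shift
  theorem). No comb projection is needed: because the input is zero off the
  sampling grid and all PE taps are R-spaced, the offset-r interpolant
  vanishes identically on lines that are not grid-shifted by r, so the
  ramp-modulated sum reproduces the k-space line placement exactly. This
  requires `nx % R == 0` at inference, which the sampling scheme enforces.

Together these make image-space inference *exactly* (to rounding) equal to
the k-space path under the circular convention — the domain-equivalence
test measures ~1e-16 relative deviation on a trained 64×64 model.

## Noise propagation and the g-factor

With masks and coil-combination weights frozen at the operating point, the
whole inference chain is complex-linear; the Jacobian `J` of every
combined-image voxel with respect to every aliased coil-image voxel is the
explicit composition of diagonal (kernel-transfer) and circulant
(mask-convolution) operators, offset ramps, and the SOS combination weights
`P_lh = conj(Ŝ_lh)/sos_l`. This is the package's `analytic_jacobian`,
cross-validated against a central-finite-difference Jacobian of the same
frozen map (max |Δ| < 1e-6 on 16×16 instances for a ∈ {0, 0.5, 1}).

The g-factor is

    g_l = sqrt( Σ_{m,t} |(J Π)_{l;mt}|² Σ²_tt ) /
          sqrt( Σ_h |P_lh|² Σ²_hh ) / sqrt(R)

where `Π` restricts the input coordinates to the noise-carrying subspace:
aliased images whose k-space lives on the acquired grid lines — precisely
the directions the pseudo-replica experiment perturbs. The restriction
matters: activation masks necessarily carry a comb structure along PE
(pre-activations vanish off the sampling grid, where the mask takes its
convention value), so the free-input Jacobian holds correlated mass at
aliasing lags, and an independent-voxel row sum over all of image space
systematically overestimates the variance (by ~25% in g for trained a=0.5
models in our studies). With the restriction the expression is the exact
first-order noise propagation; for a one-linear-layer model the Jacobian is
voxel-diagonal, the restriction reduces to a factor 1/R, and the formula
collapses to the classical image-space GRAPPA g-factor — asserted to 1e-6
against an independently coded closed form, and implementable without the
Jacobian by streaming unit k-space impulses on the grid lines through the
frozen map (`analytic_gfactor_map`, memory bounded by the chunk size; the
materialized-Jacobian route carries an explicit memory guard and the
recommendation to crop to a centered 32×32 region, which preserves trained
kernels by translation invariance).

### Monte Carlo convention

Pseudo-replica maps add iid circular complex Gaussian noise to the sampled
k-space entries of the *prewhitened* data (default per-component std
1/√2, i.e. unit complex variance), reconstruct with fixed weights, and take
the voxelwise variance of the *magnitude* stack. At high SNR the magnitude
variance measures the along-signal noise component — half the complex
variance — and the identical halving applies to the fully sampled
reference, so the analytic reference variance enters per component and the
ratio is consistent (validated: median analytic/MC ratio 1.001 for GRAPPA
at nrep = 1000). The MC denominator reuses the analytic reference variance
rather than a second replica stack. Because replicas are magnitudes, MC
maps are meaningful only where voxel SNR is well above 1; comparisons are
therefore restricted to a support mask at 10% of the peak phantom
magnitude. First-order (frozen-mask) and fully nonlinear replica
reconstructions agree closely at the SNR of these studies; the residual
median analytic-vs-MC deviation (~1.5%) is dominated by replica sampling
noise.

Voxelwise Kolmogorov–Smirnov normality of the replica magnitudes is
evaluated against a normal fitted from the same sample; fitting the
parameters from the sample makes the test conservative (it under-rejects),
which the calibration test on exactly normal synthetic stacks makes
explicit, alongside a power check against exponential samples.

## Synthetic data

The generator emulates a 2D complex object imaged by a ring of smooth coil
profiles with additive correlated complex Gaussian coil noise:

- **Phantom**: Shepp–Logan (resized) or seeded smooth blobs, max modulus 1,
  2-pixel zero border, with a seeded smooth low-order phase so the
  real/imaginary sign structure of k-space is nontrivial (a purely real
  object would make the imaginary-part masks degenerate).
- **Coils**: broad Gaussian lobes on a ring with seeded linear+random
  phases, hard-bandlimited to the central quarter of k-space, scaled to
  root-sum-of-squares ≈ 1 on the central disc (asserted within [0.5, 1.5]).
- **Noise**: circular complex Gaussian with Hermitian PD covariance Σ²
  (each real component carries Σ²/2), drawn independently per k-space
  sample; prewhitening multiplies the coil dimension by the inverse
  Cholesky factor. Retrospectively added noise levels (`base_snr_sweep`)
  are parameterized by the per-component standard deviation.
- **Sampling**: every R-th PE line anchored so the DC line is acquired,
  plus a centered ACS block.

Baseline study conditions (chosen once): base coil-noise std 1e-3 relative
to peak signal for validation experiments that require the first-order
regime (image SNR ~10³ after whitening, so linearization error is
negligible and replica statistics are Gaussian); problem sizes 16×16 to
64×64 with 2–8 coils, R = 2–4, 8–24 ACS lines, scaled down from clinical
matrix sizes to keep every experiment repeatable in minutes on one CPU.

What the generator does *not* emulate: anatomical texture and contrast,
physiological noise or flow, gradient imperfections, and the ~10× larger
in-vivo matrix/coil dimensions. Passing tests demonstrate the algebraic
identities, the internal consistency of the noise model, and the
qualitative regularization phenomenology — not clinical image quality.

## The negative-slope sweep: two study families

The slope a trades residual artifacts against noise resilience. In these
synthetic studies the two facets of that claim do not appear in a single
noise regime, so the sweep is evaluated on two documented families (64×64,
R = 4, 18 ACS lines, hidden channels 32/16):

- **High-SNR family** (8 coils, noise std 1/30): trained models retain the
  noise-suppression ordering — mean analytic g increases with a
  (≈0.68 ≤ 0.75 ≤ 0.85 at seed 0).
- **Noisy scarce-ACS family** (6 coils, noise std 0.1, 1500 epochs without
  early stopping): the reconstruction NMSE attains its minimum strictly
  inside (0, 1) (at a = 0.5 for seed 0), the regularization trade-off.
  In this regime training-data noise shrinks the *linear* model's weights —
  an implicit Tikhonov effect that lowers its g-factor — so the mean-g
  ordering inverts; this is the same phenomenon as the "noisy calibration
  regularizes GRAPPA" paradox and is reported as such rather than hidden.

Both families are fixed instruments (phantom and coil seeds pinned); the
acceptance seed drives noise realizations, initialization and replicas.

## Degenerate inputs and tie-breaks

- `S' = 0` in a mask: value 1 (see above). LReLU subgradient at 0: slope 1.
- Voxels with zero combined signal: P rows zero, g undefined and masked.
- Zero-variance voxels in the KS map: excluded and flagged.
- Underdetermined GRAPPA calibration: rejected unless Tikhonov > 0.
- `nx % R ≠ 0`: rejected at offset placement (the circular shift-theorem
  recombination needs a uniform grid under wrap).

## Known limitations

- First-order treatment: masks and P are data-dependent; their derivative
  contributions are neglected. The frozen-mask versus fully nonlinear
  replica comparison quantifies this at the studied SNR (small); at low SNR
  sign flips in the activations would grow the neglected terms.
- The dense Jacobian is O(n²·nc·ch) memory; use the streaming g-factor map
  or centered crops for larger matrices.
- Magnitude-based MC statistics bias toward Rayleigh behaviour at low SNR.
- Only leaky-ReLU-family activations are implemented; the mask-by-division
  construction generalizes but is untested beyond it.
- Non-Cartesian and 3D sampling are out of scope.
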