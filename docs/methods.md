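# Methods

## Signal model and its assumptions

A voxel is modeled as a static ensemble of non-exchanging microscopic
environments, each with a Gaussian diffusion propagator described by an
axisymmetric, positive-semidefinite rank-2 tensor.  The measured signal is
then a weighted sum of exponentials,

    S_i = sum_n w_n exp(-B_i : D_n),

where B_i is the encoding tensor of acquisition i and the weights w_n carry
absolute signal units, so S0 = Σ w_n is fitted rather than assumed.
Axisymmetry reduces each component to four free parameters
(D_par, D_perp, θ, φ), equivalently (D_iso, D_Δ, θ, φ) with
D_iso = (D_par + 2 D_perp)/3 and D_Δ = (D_par − D_perp)/(3 D_iso).
Assumptions worth keeping in mind: no water exchange between environments,
no time/frequency dependence of the diffusivities (restriction appears only
through effective tensor values), Gaussian phase dispersion within each
environment, and magnitude-image (Rician) noise.

For two axisymmetric tensors the contraction reduces to the closed form
`b·D_iso·(1 + 2 b_Δ D_Δ P2(cos β))`, with β the angle between the symmetry
axes; the vectorized kernel uses this, and the test suite checks it against
the explicit Σ_ij b_ij D_ij double sum at 1e-12 relative.

## Acquisition protocol

The default scheme has 4 + 6×4×15 = 364 entries: one b = 0 image per shape
followed, shape-major, by six shells (0.042, 0.173, 0.388, 1.080, 2.116,
3.499 ×10⁹ s/m²) × four shapes (b_Δ = −0.5, 0, 0.5, 1) × 15 directions.
The direction set is repulsion-optimized on the half-sphere under antipodal
symmetry, starting from a Fibonacci layout and running a fixed number of
deterministic gradient steps; the 15-point set is frozen as a package
constant so schemes are bit-reproducible.  The same directions are shared
by every shell and shape — rotational invariants are insensitive to this
choice, and it keeps the design matrix structure simple.  b = 0 entries are
stored as exactly zero with their shape label retained.

Scheme files are whitespace text with a `#dialect:` header, either
`bdelta` (b, b_Δ, Θ, Φ) or `voigt` (b_xx, b_yy, b_zz, b_xy, b_xz, b_yz),
units s/m²; values are written with 17 significant digits so round trips
preserve every element.

## Gradient waveforms

The optional synthesis stage produces one self-refocused waveform per
target shape: the dephasing vector q(t) sits on a cone at angle
ζ = arccos√((2 b_Δ + 1)/3) about z, with amplitude envelope
sin²(πt/T) and an azimuth that advances proportionally to the
envelope-squared time measure.  That reparametrization makes the
transverse second moments average exactly over each full turn, so the
continuous-time b-tensor is axisymmetric with b_Δ = P2(cos ζ) by
construction; discretization leaves ~1e-4 residual shape error at the
default 2000 samples.  This is one admissible realization of
variable-angle-spinning encoding — only the resulting b-tensor matters
downstream, not the waveform's exact shape.  γ is fixed to the proton value
2.6752218744e8 rad s⁻¹ T⁻¹.

## Denoising

Marchenko–Pastur PCA operates on each sliding 3×3 in-plane window (clipped
at borders, not padded): the M×N window matrix (M ≤ 9 kernel voxels, N
series points) is eigen-decomposed through its M×M covariance; scanning the
number of retained components p upward, the first p whose residual
eigenvalues fit inside an MP bulk (spread ≤ 4σ̂²√((M−p)/N), σ̂² their mean)
is accepted.  Components below the bulk edge are nulled and the window
reconstructed.  Each voxel's output is the **average over all windows
containing it**; a single centered window leaves a residual noise floor of
~σ√(p/M), which for p = 3 signal components out of M = 9 is only a 1.7×
RMSE reduction, whereas overlap averaging empirically reaches ≥2× on the
rank-3 calibration stack.  The σ map is likewise the over-window average;
the rank map reports the centered window.  No Rician-bias correction is
applied after denoising.

## Monte Carlo inversion

Per voxel (and per bootstrap replicate) the discrete DTD is found by a
proliferation–mutation–extinction search:

1. draw `n_candidates` = 200 components with log10 D_par, log10 D_perp
   uniform in [−11.3, −8.3] (0.005–5 ×10⁻⁹ m²/s, covering the descriptor
   bin space with margin) and orientations uniform on the sphere;
2. solve nonnegative least squares for the weights against
   A_in = exp(−B_i : D_n);
3. keep the `n_survivors` = 10 heaviest components (stable sort);
4. generate `n_mutants` = 3 mutated copies of each survivor — diffusivities
   multiplied by 10^ε with ε uniform in ±0.2·decay^it decades, axes rotated
   by a random angle uniform in ±45°·decay^it about a random perpendicular
   direction, decay = 0.8;
5. pool the *unmutated* survivors (elitism), their mutants and fresh random
   candidates, and repeat for `n_iterations` = 30; the final NNLS defines
   the weights, S0 = Σw and the residual sum of squares.

The annealed mutation schedule matters: with a fixed mutation scale the
search cannot refine components below ~1% parameter error (noiseless
single-component RSS stalls around 1e-3), and with a small initial angular
scale it cannot rotate survivors to the true axis of anisotropic voxels.
The chosen schedule reaches RSS ≤ 1e-10 on noiseless single-component
voxels while converging anisotropic phantom voxels to machine-level bin
purity.  Elitism guarantees monotone improvement of the retained pool.

Uncertainty: `n_bootstrap` = 96 replicates resample the acquisitions
(rows) with replacement — replicate k uses a generator seeded
`seed + k`, so ensembles are exactly reproducible — and each replicate is
refit from scratch.  Image fits derive per-voxel base seeds from the
configured seed and the voxel's linear index.  All-zero signals yield an
empty DTD with S0 = 0.  No noise-floor term enters the likelihood (plain
least squares on magnitude data).

## Descriptors and bins

Per DTD, weight-normalized means, variances and the covariance of
(D_iso, D_Δ²) are computed; per bin, the signal fraction, conditional
moments and a mean-orientation tensor (the weighted dyadic Σ w_n u_n u_nᵀ,
whose principal eigenvector respects the axial u ≡ −u symmetry).  The three
default bins are

| bin   | D_iso (10⁻⁹ m²/s) | D_Δ²        | captures |
|-------|-------------------|-------------|----------|
| thin  | [0.005, 2)        | [0.25, 1]   | WM-like anisotropic |
| thick | [0.005, 2)        | [0, 0.25)   | GM-like slow isotropic |
| big   | [2, 5]            | [0, 1]      | CSF-like fast isotropic |

Intervals are lower-inclusive; upper bounds coinciding with the global
limits of the space are closed.  The half-open convention ensures an
exactly isotropic component (D_Δ² = 0) belongs to thick/big and an exact
stick (D_Δ² = 1) to thin.  D_Δ² folds prolate and oblate shapes together;
oblate components with D_Δ = −0.5 land at D_Δ² = 0.25, i.e. on the thin
bin's lower edge.  Ensemble condensation takes the median of every scalar
over the 96 replicates (per-bin brightness is the median of fractions, not
the fraction of a median DTD); undefined (empty-bin) values are excluded
from medians.  Quality maps: median S0 / √(median RSS), and the per-voxel
mean/SD of the spherical-encoding entries at the highest shell.

## Synthetic data

Preset voxels place their components strictly inside the intended bins:

| preset | composition | D_iso (10⁻⁹) | D_Δ² |
|--------|-------------|--------------|------|
| CSF | 1 isotropic | 3.1 | 0 |
| GM | 1 prolate | 0.7 | 0.2 |
| WM | 1 prolate (D_par 2.0, D_perp 0.2) | 0.8 | 0.56 |
| HEX | 1 prolate (1.5 / 0.1) | 0.57 | 0.68 |
| DODECANE | 1 isotropic | 0.8 | 0 |
| WATER | 1 isotropic | 2.3 | 0 |
| MIX | ½ CSF + ½ GM | E = 1.9, Var = 1.44e-18 | E = 0.1, Cov = −0.12e-9 |

CSF and GM reproduce in vivo descriptor values; the GM anisotropy sign is
taken prolate (only D_Δ² is constrained by the target moments).  WM and the
phantom diffusivities are configuration choices respecting the slow-
anisotropic / slow-isotropic / fast-isotropic ordering of the materials
they emulate, not measured values.  The default phantom is a 16×16
single-slice grid of concentric regions (background frame, WM, GM, a
one-voxel CSF+GM partial-volume rim, CSF core).  Noise is Rician —
|S + ε₁ + iε₂|, ε ~ N(0, σ²) — with σ = (mean GM b0 signal)/SNR and
SNR = 26 by default; a Gaussian switch exists for calibration work.  The
generator emulates the statistical structure the inversion assumes
(multi-exponential decay, magnitude noise, partial volume).  It does **not**
emulate scanner physics — spatially varying echo time and diffusion
weighting along the readout, susceptibility artifacts, motion, spatially
correlated noise — so passing recovery tests demonstrates correctness of
the estimation chain under its own noise model, not robustness to every
property of real acquisitions.

## Numerical choices and degenerate inputs

NNLS uses the Lawson–Hanson active-set solver; design matrices are built
with the closed-form axisymmetric contraction.  Survivor ties break by
stable sort on weight then index.  Returned DTDs keep at most
`max_components` = 50 nonzero-weight components (typical solutions carry
5–15).  Empty DTDs and empty bins propagate as NaN flagged `defined=False`
rather than raising.  b-matrix → shape conversion averages the nearly
degenerate eigenvalue pair and rejects matrices whose pair splits by more
than 5% of b as non-axisymmetric.  Denoising of exactly-rank-deficient
noiseless data is exact (a relative tolerance absorbs numerically zero
eigenvalue spread).

## Known limitations

- The positive anisotropy bias of unconstrained inversion at low SNR:
  fits of a single raw voxel at SNR 26 overestimate E[D_Δ²] by roughly
  +0.1 (spurious high-anisotropy components absorb directional noise).
  MP-PCA denoising of a full image before fitting is the intended
  mitigation; no regularization is applied inside the inversion.
- Bootstrap medians quantify solution spread given the model; they do not
  correct model misspecification (exchange, non-Gaussian compartments).
- Fast-diffusing components near the big-bin lower edge (e.g. D_iso just
  above 2e-9 m²/s) can leak weight into thick under noise; bin fractions
  near boundaries should be read with the replicate spread in hand.
- Processing is single-slice 2-D; the slice axis is carried with length 1
  and the denoiser kernel is in-plane only.
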