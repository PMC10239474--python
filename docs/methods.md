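# Methods

## Problem and approach

Experimental cryo-EM reconstructions lose contrast at high spatial
frequency and vary in quality across the volume.  `cryopolish` treats
map enhancement as supervised volumetric restoration: a 3D
Swin-Conv-UNet is trained to map slices of an experimental density map
to the corresponding slices of a *simulated* target map computed from
the deposited atomic model, and a full map is enhanced by tiled
inference with overlap averaging.

## Forward model

The target density at grid point **x** for a structure of heavy atoms
with atomic numbers `Z_i` at positions **r**_i is

    rho(x) = sum_i theta * Z_i * exp(-k |x - r_i|^2),

with `k = (pi / (1.2 + 0.6 R))^2` (R the nominal resolution in Å) and
`theta = (k / pi)^1.5`, which normalises each atomic Gaussian to
integrate to `Z_i`.  Hydrogens are excluded; waters and hetero atoms are
included by default (an `drop_waters` switch exists) since the model
places no restriction on heavy-atom type.  Gaussians are truncated at
`5 / sqrt(k)` where the tail is below `e^-25`; a brute-force
atoms-by-voxels oracle in the test suite bounds the truncation error.
Per-atom B-factors and electron scattering-factor tables are out of
scope: the model deliberately uses one isotropic width per map.

## Preprocessing

Experimental maps are regridded to the working spacing (1.0 Å default,
0.5 Å variant for sub-Å voxel maps) by cubic B-spline interpolation
(mirror boundary for the spline coefficients; the physical extent and
origin are preserved), clipped at zero, and divided by their
99.999-percentile density value.  The percentile is the standard
linear-interpolation percentile over all voxels — deterministic and
scale-covariant.  Simulated target maps are used as produced by the
forward model, with no percentile division: normalisation is a property
of experimental amplitudes, and keeping targets in forward-model units
gives enhanced maps a physically interpretable scale.  Half-map pairs
are averaged voxel-wise before enhancement; a single half-map can also
be processed alone for half-map cross-validation experiments.

Axis conventions: `DensityGrid.values` is indexed `[z, y, x]`; voxel
`(i, j, k)` is centred at `origin + (i, j, k) * spacing` (grid-point
convention).  MRC files with permuted axis-order headers are
canonicalised on read; non-orthogonal cells are rejected; when both the
ORIGIN record and NXSTART offsets are present, ORIGIN wins (the modern
single-particle convention).  Output maps are written as float32
(mode 2).

## Chunking and augmentation

Training cuts matched volumes into 60^3 boxes with stride 30 (desk-scale
studies use 32^3 boxes with stride 32 on 64^3 fixtures); pairs in which
either member has no positive density are dropped — an all-zero
experimental or target box carries no training signal.  Each raw pair
is augmented per epoch by one rigid transform applied jointly to both
members: a rotation drawn uniformly from the 24 proper cube rotations
(reflections excluded) plus a random crop to the network box size.
Inference cuts the map into network-sized boxes with stride 12; per
axis the starts are `0, stride, 2*stride, ...` with a flush-end start
appended so the final box touches the boundary, and axes shorter than
the box are zero-padded (solvent).  Overlapping outputs are averaged,
which makes chunk–identity–reassemble exactly the identity map.

## Network

The network is a UNet of swin-conv (SC) blocks: three encoder levels,
one bottleneck and three decoder levels; downsampling by stride-2
convolutions, upsampling by stride-2 transposed convolutions, additive
encoder-to-decoder skip connections.  An SC block projects with a 1x1x1
convolution, splits channels in half, runs in parallel a swin
transformer pair (window attention + MLP with pre-norm, window size 3,
the second sub-block with cyclically shifted partitioning at half the
window) and a residual convolution branch (two 3x3x3 convolutions,
ReLU), concatenates, projects back and adds the block input.  The box
side must be divisible by 8x the window size — three downsamplings
shrink the side by 8 and the deepest level must still tile into
windows (hence window 4 for a 32 box).  Attention heads are
`branch_channels / 32` (minimum 1); the MLP ratio is 2; GELU in the
transformer MLP, ReLU in the convolution branch.

Simplifications relative to canonical shifted-window attention: the
shifted sub-block uses a cyclic roll without a boundary attention mask
(solvent-padded density makes wrap-around mixing benign at these window
sizes) and no relative-position bias table.  The exact channel widths of
any published model are not reproduced; the defaults are a reduced
reference configuration, not a weight-compatible clone.

Initialisation: truncated normal with std `gain / sqrt(fan_in)`; unit
gain on linear paths, `sqrt(2)` before ReLU, and a small gain (0.25 on
SC output projections, 0.5 on the tail) so the untrained network is
near identity scale.  Without the damped residual projections the
activation magnitude grows roughly 3.5x per block and the untrained
output sits orders of magnitude above the targets, which wastes the
early epochs undoing the initialisation.

The network, its gradients and the Adam optimizer run on a small
reverse-mode automatic-differentiation engine written on numpy
(`cryopolish.autodiff`): broadcasted arithmetic, batched matmul, fused
layer-norm/softmax primitives, and im2col-based 3D convolutions.
Convolution column buffers are recomputed during the backward pass and
interior gradients are freed as soon as they are consumed, which keeps a
batch-8 training step of the reduced model within ~2 GB.  Gradients of
every primitive are checked against central finite differences in the
test suite.

## Loss

The objective is the sum of a local and a non-local term, each averaged
over the batch:

* smooth L1: mean over voxels of `0.5 d^2` if `|d| < 1` else `|d| - 0.5`;
* SSIM loss: `1 - (2 sigma_XY + eps) / (sigma_X^2 + sigma_Y^2 + eps)`
  with `eps = 1e-6`, computed from *global* per-slice statistics (no
  sliding windows) — the contrast-times-structure part of SSIM, without
  the luminance term.

Variances use the `1/(N^3-1)` normalisation; the ratio is
normalisation-independent, so the choice is cosmetic.  `eps` sits inside
the combined ratio, so two constant slices give loss 0 rather than 0/0.
The SSIM term is invariant to adding constants to either slice and to
joint positive rescaling, and lies in `[0, 2]` up to `O(eps)`.

## Training schedule

Adam, initial learning rate 5e-4, batch 108 at full scale (configurable
down; desk-scale studies use 8).  The rate is halved when the best mean
training loss of the last 4 epochs is no better than the best seen
earlier, with the comparison window restarting after each halving
("no decrease for 4 continuous epochs", plateau reading; any decrease
resets).  Training stops at 300 epochs or when the rate reaches 1e-5.
Validation pairs are centre-cropped and never augmented, so model
selection is not corrupted by augmentation noise; the checkpoint with
the least validation loss is returned.  A non-finite loss aborts with a
diagnostic rather than being clipped.  Data order is shuffled per epoch
under the run seed; with fixed seeds, fixture builds, loss curves and
enhanced maps are bit-for-bit reproducible in single-threaded mode.

## Synthetic fixtures

The fixture generator emulates the statistical structure of the training
conditions at desk scale: heavy-atom pseudo-structures (helix-like
spiral traces with 1.5 Å rise and 100° turn per atom — folded into
antiparallel segments when longer than the box — plus random-coil and
blob-cluster styles) of C/N/O atoms inside 64^3 maps at 1.0 Å spacing;
per-item resolutions drawn uniformly from 3.0–6.0 Å; clean targets
computed exactly by the forward model; degraded inputs produced by
normalising the clean map to 0–1, Gaussian-blurring with a
resolution-scaled width (`sigma = R/6` Å, so 6 Å fixtures look blurrier
than 3 Å ones) and adding i.i.d. Gaussian noise with SD 1/6.  A
pure-noise grid (SD-1/6 noise on an empty volume) supports the
noise-suppression study.  Degraded inputs then pass through the same
clip + percentile normalisation as real maps.  What the fixtures do
*not* emulate: image-formation physics (CTF, projection, reconstruction
correlations in the noise), B-factor heterogeneity, lipid/ligand
density, and masking applied to deposited primary maps — so passing
desk-scale tests demonstrates the pipeline's correctness and the
method's qualitative behaviour, not performance on deposited maps.

## Evaluation metrics

All metrics are self-contained proxies for the usual phenix tooling and
are labelled as such; parity with phenix is not claimed.  The unmasked
FSC uses shells one Fourier voxel wide (frequencies in cycles/Å from
the voxel spacing; DC shell excluded from threshold search); FSC-0.5 is
the lowest-frequency crossing located by linear interpolation, with the
Nyquist resolution and a flag returned when the curve never crosses.
The map-model FSC compares against the forward-model map of the
structure.  Real-space correlations: CC_box over the whole volume,
CC_mask over voxels within 3 Å of any heavy atom, CC_peaks over the
union of each map's top-V voxels with V the mask count (ties at the
V-th value all included, for determinism).  The local correlation map
computes the Pearson correlation of 7^3 neighbourhoods centred at every
voxel with positive density in the first map, with a validity mask for
borders and non-positive voxels.

One analytic caveat found while testing: because the FSC is normalised
per shell, any isotropic linear filter (Gaussian blur, shell-wise
Wiener weighting) leaves every shell correlation — and hence FSC-0.5 —
exactly unchanged.  Degradation moves the FSC only through added noise,
and denoising improves it only through non-shell-uniform (real-space,
nonlinear) operations such as solvent suppression, which is precisely
the mechanism the network learns.  The property tests use
(blur + fixed noise) for monotone degradation and a support-mask
denoiser as the improvement oracle.

## Desk-scale study sizes

The acceptance study trains the reduced configuration (box 24, base 16
channels, one SC block per level, ~0.7 M parameters) on 20 fixtures
(17 train / 3 held out), six 32^3 pairs per training map, batch 8, for
12 epochs — about 10 minutes on one CPU.  Held-out quality is measured
on whole enhanced maps against their clean targets; many individual
24^3 crops of these sparse fixtures are nearly empty, where the global
SSIM term is pinned near 1 by construction and cannot discriminate
models.  The trained model reduces the whole-map held-out loss by well
over half and improves the proxy map-model FSC-0.5 on the held-out
fixtures.  Applied to a pure-noise grid, the trained model suppresses
the noise to low density values relative to the enhanced signal maps
(the acceptance script reports the 99th-percentile noise/signal output
ratio); the suppression sharpens with continued training, and output
near the zero-padded map borders is systematically less suppressed
than in the interior, where the network sees full context.

## Known limitations

* CPU-bound: a full-scale 48-box, batch-108 training run is far outside
  this engine's envelope; the package targets desk-scale studies and
  method experimentation.
* The SC block internals follow the cited SCUNet pattern but channel
  widths, head counts and the absence of attention masks/position
  biases mean published weights cannot be loaded.
* Fixture realism is limited as described above; conclusions about real
  deposited maps require real data.
* `cc_mask`/`cc_peaks` region definitions differ in detail from
  phenix's; values are comparable within this package only.
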