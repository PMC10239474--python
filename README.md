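# cryopolish

Deep-learning enhancement of cryo-EM density maps with a 3D
Swin-Conv-UNet.

Raw cryo-EM reconstructions lose contrast at high spatial frequency and
vary in quality across the volume, which complicates model building.
`cryopolish` enhances a map by learning the mapping from experimental
density to *simulated* density: a volumetric Swin-Conv-UNet — residual
convolutions for local modelling and shifted-window attention for
non-local modelling, arranged in a multiscale UNet — is trained on
paired slices of experimental maps and Gaussian forward-model maps of
their atomic structures, then applied to full maps by sliding-window
inference with overlap averaging.  The package is aimed at method
experimentation at desk scale on a CPU: every stage (forward model,
chunking, network, loss, training schedule, metrics) is exercisable and
tested on synthetic fixtures without any external data.

## The model in brief

Target maps come from the Gaussian forward model

```
rho(x) = sum_i  theta · Z_i · exp(-k |x - r_i|^2),
k = (pi / (1.2 + 0.6 R))^2,   theta = (k / pi)^1.5,
```

summing over heavy atoms with atomic number `Z_i` at `r_i`, with `R` the
nominal map resolution in Å.  Training minimises the sum of a local and
a non-local term between a processed slice `X` and its target `Y`
(side `N`):

```
SmoothL1(X, Y) = mean_ijk  { 0.5 d²   if |d| < 1;   |d| - 0.5 otherwise }
SSIMLoss(X, Y) = 1 - (2 σ_XY + ε) / (σ_X² + σ_Y² + ε),   ε = 1e-6
```

with slice-global statistics — the second term is the contrast ×
structure part of SSIM and rewards correlated density patterns rather
than pointwise agreement.  Adam starts at lr 5e-4; the rate is halved
after 4 epochs without training-loss improvement and training stops at
300 epochs or lr 1e-5, keeping the best-validation checkpoint.
Enhancement of a full map applies clip-at-zero, division by the
99.999-percentile density, 48³ tiling with stride 12 (box 24 in the
reduced desk-scale configuration), network inference, and overlap
averaging; quality is assessed with unmasked FSC curves, the FSC-0.5
threshold resolution, proxy CC_box / CC_mask / CC_peaks correlations
and 7³-neighbourhood local correlation maps.

## Worked example

`examples/train_and_enhance.py` builds eight synthetic fixtures
(forward-model targets degraded by resolution-dependent blur plus
Gaussian noise of SD 1/6), trains the reduced network for eight epochs
and enhances the held-out map:

```
21 training pairs, 2 validation pairs
epoch 0: train 1.007 val 0.929
epoch 1: train 0.908 val 0.825
...
epoch 7: train 0.591 val 0.491
held-out fixture at nominal 4.86 A:
  degraded input FSC-0.5 : 4.97 A
  enhanced map FSC-0.5   : 4.09 A
```

The falling loss shows the network learning the degraded-to-simulated
mapping; the held-out FSC-0.5 dropping from 4.97 Å to 4.09 Å means the
enhanced map correlates with its atomic model out to substantially finer
resolution than the degraded input — the map got sharper, not just
smoother.  The other examples (`simulate_and_score.py`,
`local_correlation.py`) demonstrate the forward model, the metric suite
and local correlation maps; each prints what its numbers mean.

A command-line interface mirrors the library for shell use:

```
cryopolish fixtures --spec spec.yaml --seed 7 --out fx/
cryopolish train --data fx/ --out model.npz
cryopolish enhance --map in.mrc --model model.npz --out out.mrc
cryopolish fsc --map-a out.mrc --model model.pdb --resolution 3.5 --out curve.tsv
```

## Scope and caveats

The metrics are self-contained proxies (the model map is the Gaussian
forward model, not an electron-scattering-factor map); numerical parity
with phenix tools is not claimed.  Published full-scale weights are not
reproducible here — channel widths of the original networks are not
public and training at full scale is a GPU-cluster task.  See
`docs/methods.md` for assumptions, parameter defaults, what the
synthetic fixtures do and do not emulate, and known limitations.
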