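# Methods

## The problem and the model

Single-axis cryo-electron tomography tilts the specimen about the Y axis over
a limited range, nominally ±60°. By the projection theorem each tilt image
measures one central plane of the 3D Fourier transform, so the union of
measured planes is a fan in the (kx, kz) plane and the complement — two
opposing wedges where the angle from the kx axis exceeds the maximal tilt —
is never measured. In real space this "missing wedge" smears every feature
along Z and deletes horizontally oriented structures (membranes, flat
interfaces).

`isotomo` restores the wedge with a self-supervised scheme that needs no
clean reference:

1. **Extract** cubic subtomograms from the tomogram (contrast-inverted and
   percentile-normalized so 90 % of voxels land in (0, 1)).
2. **Rotate** each cube by elements of the proper cubic rotation group. Of
   the 24 group elements, the 4 that map the wedge region onto itself
   (identity and the 180° rotations about X, Y, Z) are useless as
   augmentations; the remaining 20 move the cube's missing wedge to a new
   orientation.
3. **Re-impose** the standard wedge on each rotated copy in Fourier space.
   The pair (re-filtered copy → rotated copy) is a supervised example whose
   mapping is exactly "undo one wedge's worth of information loss". Both
   members are centre-cropped *after* filtering so edge voxels carry complete
   Fourier information.
4. **Train** a volumetric U-Net on these pairs (mean absolute error, Adam at
   learning rate 4·10⁻⁴, a fixed number of epochs per refinement iteration).
5. **Predict and merge**: the network runs on the *original* cubes; only the
   wedge region of its output is kept (inverse-wedge filter) and added to the
   original in Fourier space. Measured Fourier amplitudes are therefore
   carried through unchanged at every iteration — the scheme cannot
   accumulate error in the data it actually measured. The corrected cubes
   become the rotation targets of the next iteration, so target quality —
   and with it wedge recovery — improves over iterations.

An optional noisier-input denoising mode adds reconstruction-consistent noise
(2D Gaussian images backprojected over the tilt range, optionally ramp- or
Hamming-ramp-filtered) to the *inputs* only, at a level defined as
std(noise)/std(cube). The default schedule is ten warmup iterations at level
0, then +0.05 every five iterations, capped at 0.2.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| tilt range | −60…+60 | degrees | wedge geometry; asymmetric ranges supported |
| cube size | 96 | voxels | extraction box; memory-bound in practice |
| crop size | 64 | voxels | training pairs are centre-crops of rotated cubes |
| subtomograms | 300 | — | across 1–5 tomograms |
| U-Net depth | 3 | blocks | stride-2 encoder; width doubles per depth |
| base channels | 32 | — | first-block width (not fixed by the method; configurable) |
| convs per block | 3 | — | 3×3×3 kernels, ReLU |
| dropout | 0.5 | — | one layer per block, training only |
| learning rate | 4·10⁻⁴ | — | Adam, optimizer state reset per iteration |
| epochs/iteration | 10 | — | one pass over all cube × rotation pairs each |
| batch size | 8 | — | 8 or 16 are both sensible |
| iterations | 10–30 | — | 10–15 suffice without denoising |
| snrfalloff F | 1.0 | — | SSNR decay; higher = stronger low-pass |
| deconv strength S | 1.0 | — | SSNR scale 10^S |
| high-pass corner | 0.02 | cycles/pixel | cosine ramp, zero at DC |
| denoise level cap | 0.2 | std ratio | staircase schedule above |

## CTF deconvolution

Tomograms recorded at underfocus without a phase plate are filtered by the
oscillatory CTF. We apply a rotationally symmetric 3D Wiener filter
W(f) = CTF(f)/(CTF(f)² + 1/SSNR(f)) with the empirical model
SSNR(f) = e^(−f·100F) · 10^S · H(f). H is a cosine-ramp high-pass (zero at
DC, one beyond its corner frequency): it prevents the huge SSNR at very low
frequency from turning the filter into a raw inverse there. The DC
coefficient is passed through unchanged, since H(0) = 0 would otherwise
delete the volume mean. A single defocus per tomogram is assumed — the
volume is already reconstructed, and depth-dependent defocus is out of
scope. The CTF uses the standard weak-phase form with relativistic electron
wavelength; underfocus is positive and gives negative low-frequency
contrast.

## Masks

Empty regions (vacuum, pure ice, carbon) are excluded by the intersection of
two statistical masks computed on the (deconvolved, if available) tomogram:
a density mask (Gaussian smooth σ = 2 the contrast-inverted volume, sliding
5³ maximum filter, keep the top percentage by value) and a local
standard-deviation mask (5³ window, keep the top percentage). Ties at the
percentile threshold are broken by keeping strictly-above values, so a
constant volume yields an empty std mask (with a warning) rather than an
arbitrary one. A `z_crop` fraction of slices is removed from each of the top
and bottom of the stack.

## Numerical choices

- **Wedge filter**: binary, evaluated per Fourier voxel from the signed
  angle of the (kx, kz) direction reduced to its Hermitian representative;
  boundary voxels exactly on the fan edge count as sampled; DC is sampled
  (inverse filter: DC = 0). The filter edge is not smoothed.
- **Rotations for training** are exact axis permutations/flips — lossless
  and bit-reversible; the only interpolating rotation (trilinear) lives in
  the synthetic benchmark generator.
- **Percentile normalization** uses the symmetric (5, 95) pair; the affine
  transform is recorded so predictions can be mapped back to the original
  intensity frame.
- **Wedge-preservation test** for selecting training rotations is run
  voxelwise on a small centred odd grid, which every signed permutation maps
  onto itself exactly.
- **Overlap-tile prediction** pads the volume symmetrically, predicts
  overlapping chunks, and writes back only each chunk's core; cores tile the
  output exactly (margin default = crop/4). One tomogram-level
  normalization transform is shared by all tiles to avoid contrast steps.
- **FSC**: shells one Fourier-voxel wide; conical FSC uses a 20° half-angle
  double cone; resolution is the first downward crossing of the cutoff,
  linearly interpolated, with Nyquist (2·pixel size) reported when the curve
  never crosses.
- **Degenerate inputs**: constant volumes are rejected by normalization;
  SSNR identically zero raises instead of silently zeroing a tomogram;
  non-finite voxels are refused at I/O boundaries.

## The network engine

The U-Net is implemented directly in NumPy with explicit reverse-mode
gradients (im2col + GEMM convolutions in channels-last layout, transposed
convolutions for upsampling, inverted dropout, Adam). This keeps the
dependency footprint to the scientific Python stack and makes training runs
bit-reproducible given the master seed; the per-layer gradients are verified
against central differences in the test suite. The cost is speed: the
engine is practical for the cube sizes used in the tests and for small
production runs, not for GPU-scale workloads.

## The synthetic benchmark

`isotomo.synthetic` reproduces the shape of the standard simulation study:
a band-limited ground-truth volume is rotated into ten random orientations
(trilinear interpolation) and the missing wedge is deleted in Fourier space;
the corrupted copies are refined and compared with the matched rotated
truths. Procedural phantoms (spherical shells with carved caps, tube
bundles, Gaussian assemblies, lattices) stand in for molecular density maps
so the repository needs no downloads; any user-supplied MRC volume can be
used as ground truth instead. Recovery is scored as real-space Pearson
correlation plus spectral correlations restricted to the wedge region and to
the passband.

What the phantoms do *not* emulate: CTF corruption, dose-dependent noise,
molecular crowding, or the intensity statistics of real reconstructions.
Passing the synthetic suite demonstrates that the machinery (pair
generation, conservation merge, training, tiling, scoring) is correct and
that wedge information is genuinely recovered for structured volumes; it
does not certify resolution claims on real specimens.

## Scaled test conditions

The automated suite exercises the full refinement loop at a reduced size
chosen so a complete run stays comfortable on an ordinary CPU: 32³ cubes in
ten random orientations, 16³ training crops, a depth-2 U-Net with 8 base
channels and 2 convolutions per block, batch 8, 2 epochs per iteration,
5 iterations, three fixed seeds. Under these conditions the wedge-region
spectral correlation with ground truth rises from ≈0 (corrupted input) to
≈0.6–0.75 by the fifth iteration. The per-iteration real-space trace climbs
steeply in the first iteration and then fluctuates by a few 10⁻³ around a
slowly rising plateau; with only two epochs per iteration strict
per-iteration monotonicity is not always observed at this scale, which the
acceptance test accounts for by majority over seeds.

## Known limitations

- Single-axis geometry only (no dual-axis missing pyramid), one defocus per
  tomogram, no per-tilt dose weighting.
- The NumPy engine is CPU-bound; production-size refinements (96³ cubes,
  hundreds of subtomograms, 30 iterations) are out of reach without a GPU
  framework behind the same interfaces.
- The 3D FSC cone aggregation uses per-cone shell averages over a
  hemisphere grid; other implementations differ in smoothing details.
- Noise simulation assumes additive Gaussian noise per tilt image; detector
  MTF and Poisson statistics are not modelled.
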