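# Methods note

This note records the numerical conventions and design choices behind
`cryphase`, a package for studying iterative projection algorithms (IPAs)
applied to crystallographic phase retrieval with solvent-flatness and
histogram constraints.

## Problem formulation

Phasing is posed as a feasibility problem between two constraint sets
acting on a real electron-density map sampled on an even-dimensioned grid
over a P1 unit cell:

* **Constraint A (real space).** The solvent region is flat, and the
  protein-region density values follow a reference histogram. The
  projection flattens the solvent to its mean and applies an
  order-preserving quantile transport of the protein values onto the
  reference (ranks `k/(n-1)`, linear interpolation between order
  statistics). For a fixed envelope and reference this is idempotent and
  distance-minimizing.
* **Constraint B (Fourier space).** Measured amplitudes are imposed while
  phases are retained (a zero-amplitude coefficient is assigned phase 0);
  unmeasured amplitudes are capped at a multiple (default 2.0) of the shell
  mean of the measured amplitudes (a Wilson-statistics restraint); terms
  outside the reflection set are zeroed (band limiting); F(000) is held
  fixed.

Fourier conventions: `F(h) = sum_x rho(x) exp(+2 pi i h.x)` over fractional
voxel coordinates, computed as `N * ifftn(rho)`. Exactly one member of each
Friedel pair is stored (`h > 0`, or `h = 0, k > 0`, or `h = k = 0, l > 0`);
grid Nyquist frequencies are excluded; F(000) is carried separately. In P1
all reflections are acentric with degeneracy factor epsilon = 1; the
agreement statistics nevertheless accept epsilon weights so imported
higher-symmetry data can be scored correctly.

## Algorithms

Five update rules share the two projections P_A and P_B: ER (`P_A P_B`),
the one-parameter difference map DM (four projection applications per
iteration; the relaxation parameters tied to 1/beta; beta in (-1,1),
beta != 0; flipping the sign of beta exchanges the roles of the two
constraints), RRR (`x + beta [P_A(2 P_B x - x) - P_B x]`, beta in (0,2);
beta = 1 is Douglas-Rachford), revRRR (the same with the projections
interchanged), and RAAR (`beta [x + P_B(2 P_A x - x)] + (1-2 beta) P_A x`,
beta in (0,1]; at beta = 1 identical to revRRR). For the non-ER rules the
iterate is a surrogate; each iteration yields two solution estimates, one
satisfying each constraint exactly, which coincide at a fixed point. The
RAAR estimate uses the revRRR estimate formula at every beta as a pragmatic
choice, since the beta != 1 iterate admits no exact estimate.

Runs are fixed-length with no early stopping. The envelope used by P_A is
re-estimated once per iteration from the monitored solution estimate by
thresholding the local density variance in a spherical window (periodic
FFT convolution) so that exactly `ceil(f * N)` voxels are solvent.

## Origin anchoring in P1 (package design choice)

In P1 both constraint sets are invariant under lattice translations, so a
reconstruction's origin is a free continuous gauge: with per-iteration
envelope refresh, iterate fluctuations random-walk the whole solution
through the cell while the envelope follows it. The solution remains
correct up to translation, but fixed-origin scores decay. Higher-symmetry
space groups pin the origin to a discrete set, so the effect is specific
to the P1 scope of this package. To fix the gauge, each re-estimated
envelope is registered against the run's initial envelope by the
integer-voxel shift maximizing periodic mask overlap (FFT
cross-correlation) before it is used (`AlgorithmConfig.anchor_origin`,
default on). This uses only the run's own iteration-0 state — never
reference phases — and leaves the projection mathematics untouched.

## Circular phase-error model

Corruption at circular variance V applies von Mises noise (concentration
kappa solving `1 - I1(kappa)/I0(kappa) = V`) to acentric phases and a
wrapped-Bernoulli pi-flip (retention probability `p = 1 - V/2`) to centric
phases. Sampling uses the Best–Fisher rejection scheme, vectorized over
blocks of candidate uniforms, with randomness drawn from per-reflection
substreams keyed by `(seed, h, k, l)` so corruption commutes with
reflection reordering and subsetting.

## Agreement statistics and trajectory analysis

The mean absolute phase difference places each difference in [0, 180]
degrees via the four-quadrant construction. The map correlation is the
amplitude/phase-difference form
`sum eps F1 F2 cos(dphi) / sqrt(sum eps F1^2 sum eps F2^2)`, equal to the
voxel-space Pearson correlation of the synthesized maps (F(000) excluded).
The Fisher–Lee circular correlation uses the O(n) expansion through the
auxiliary trigonometric sums.

After convergence, per-reflection circular mean directions and mean
lengths over a trailing window (default 30 iterations) feed a Fourier
synthesis (amplitudes either measured or mean-length-weighted); the PRTF
is `|mean reconstructed coefficient| / measured amplitude` per reflection,
epsilon-weighted in equal-count resolution shells of 1/d^3. For the
constraint-B estimate the PRTF equals the mean resultant length exactly.
A stationarity diagnostic splits the window in half and reports the
amplitude- and reliability-weighted mean circular distance between
half-window mean directions (weights `F * min(R1, R2)`; threshold 0.1 rad).
The weighting is a package choice: an unweighted mean is dominated by weak
reflections whose phases fluctuate freely even at stationarity, whereas the
weighted form tracks what the synthesized map is sensitive to. The
diagnostic never stops a run.

## Synthetic crystal

The toy crystal is a cluster of positive Gaussian blobs confined to a
central sub-box of a cubic P1 cell, rank-thresholded so the solvent region
(default fraction 0.74) is exactly flat at zero; diffraction data are the
exact grid-DFT amplitudes of this truth, optionally noisified or thinned,
and the reference histogram for constraint A is the truth's protein-region
value distribution. A geometry-free generator draws Wilson (Rayleigh)
amplitudes normalized to `<F^2> = 1` with uniform phases (plus an optional
centric subset with two-point phases) for error-model and metric
calibration at any sample size.

Because a sharp-solvent map cannot be exactly band-limited, the two
constraint sets intersect only approximately on the toy crystal (relative
iterate residual about 1% at the truth); exact fixed-point behavior is
verified on convex toys where the intersection is exact.

## Scaled-down study conditions (package choices for desk-scale budgets)

The statistical claims are validated at reduced size so the whole test
suite fits a desk-scale time budget, without changing any claim:

* toy crystal for algorithm experiments: 30 A cubic cell, 32^3 grid,
  d_min 3.0 A, 40 blobs of width 1.8 A, solvent fraction 0.74
  (~2,100 reflections), envelope window radius 2.5 A;
* trajectory-averaging and beta-breadth experiments: 8 replicates per
  beta in {0.3, 0.5, 0.8, 1.1}, 150 iterations from V = 0.75 corruption;
* convergence-regime experiments: 10 replicates (V = 0.5 recovery) and 8
  replicates (V = 0.8 algorithm comparison);
* error-model calibration: 10,000 reflections (5% centric), 10 seeded
  replicates — full scale, since it is cheap.

`scripts/acceptance.py` recomputes the calibration targets from scratch:

```
python scripts/acceptance.py --seed 1 --out targets.json
```
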