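# Methods

`lung4dxv` measures regional lung function from a respiratory-gated 4D
CT series: it reconstructs one volume per breath time bin, segments the
airway tree at end-expiration, tracks parenchymal speckle motion between
successive phases by 3D cross-correlation (X-ray velocimetry, XV), maps
regional expansion as the divergence of the displacement field, and
links expansion to the airway tree (Airway Tree Link, ATL) to obtain
per-branch airflow and expiratory time constants. Because no suitable
public 4D dataset exists, the package ships a synthetic breathing-lung
phantom with closed-form ground truth; every stage is validated against
that truth.

## Coordinate and unit conventions

Volumes are numpy arrays indexed `(z, y, x)`, 0-based; positions are
float voxel coordinates in the same order; world lengths are
`voxels x voxel_size`. Times are milliseconds within one breath, with
phase 0 = end-expiration (functional residual capacity), the zero
reference of every volume series.

## The breathing-lung phantom

**Airway tree.** A full binary tree of `g` generations
(`2^(g+1)-1` segments, `2^g` terminals; default g = 6, the deepest
generation resolved in small-animal work) grows inside an ellipsoidal
lung envelope by space-filling bifurcation: a seeded point cloud fills
the envelope, each bifurcation splits its point set across the set's
principal axis, and children aim at the centroids of the two halves.
This spreads terminals evenly (pairwise separations of ~7-16 voxels on
a 128^3 grid), which keeps both skeleton recovery and region assignment
well-posed. Radii decay by 2^(-1/3) per generation (Murray's law);
branch lengths are floored at a multiple of the radius so that no branch
is shorter than the junction blob a skeletonization would merge it into.

**Rendering.** Parenchyma receives a band-limited random texture
("speckle", the trackable pattern that phase-contrast imaging produces
from alveolar clusters): Gaussian-filtered white noise with kernel
chosen so the autocorrelation FWHM equals `speckle_grain` (default 5
voxels). Airway lumens are rendered dark (air) on the brighter
parenchyma; the non-lung background is flat. Speckle is a *texture*,
not a wave-optics simulation: propagation physics contributes nothing to
velocimetry beyond trackable contrast, so it is out of scope.

**Motion model.** The displacement field is

    u(x, t) = a * phi(t; tau(x)) * g(x) * (x - c)

a uniform dilation about the lung centre `c` with `a =
tidal_fraction/3`, so the healthy peak volumetric strain (divergence) is
exactly `tidal_fraction` (default 0.12). `g(x)` is the defect factor:
1 outside, `expansion_scale` inside spherical defects, blended over a
2-voxel cosine shell. The temporal profile `phi` rises as a raised
cosine over the inspiratory time and decays as `exp(-(t - t_insp)/tau)`
over expiration, so the expiratory time constant is a direct phantom
parameter (default 80 ms; defects scale it by `tau_scale`, by default
applied per terminal region so each region has a single tau). The
divergence is available in closed form,
`div u = a * phi * (3 g + (x - c) . grad g)`, and regional air-volume
ground truth integrates it over each terminal's supply region — hence
the sum over regions equals the total lung volume change exactly.

A uniform base dilation was chosen deliberately: any field pinned to
zero at the lung boundary has zero net flux and cannot inflate the lung,
and a spatially graded alternative makes the divergence oracle depend on
the taper rather than on the estimator under test. The cost is that the
phantom does not reproduce the centre-weighted expansion seen in real
lobes; defects provide the spatial heterogeneity instead.

Phase volumes warp the reference by pulling through the negated forward
field (trilinear interpolation) — exact to first order, with errors
second order in the strain (<~2% at the default tidal fraction).

**Ventilation protocol defaults** follow a small-animal pressure
protocol: PIP 12 / PEEP 2 cm H2O (metadata only — no mechanics), 250/250
ms inspiration/expiration, hence 120 breaths/min, imaged at 30 frames/s,
giving 15 gated time bins of 33.3 ms. Peak inspiration falls at bin 7
(233 ms).

## Gated reconstruction

`GatingSchedule` enforces that `frame_rate * 60 / respiratory_rate` is
an integer (otherwise bins drift between breaths) and that binning is a
partition: 6000 ventilator-triggered frames at 15 bins give exactly 400
projections per bin spread over 360 degrees. The effective pixel at the
isocenter is `detector_pitch * r1 / r2`; for the 194 um / 0.36 m / 3.0 m
bench this evaluates to 23.3 um (bench descriptions sometimes quote a
rounder 20 um; the formula value is used).

Reconstruction is Feldkamp-type filtered backprojection: cosine
pre-weighting on the virtual detector at the isocenter, row-wise ramp
filter in the frequency domain (zero-padded to the next power of two,
Hann apodization by default), and distance-weighted backprojection.
Each projection is weighted by its angular gap, so the interleaved,
non-uniform per-bin angle sets of a gated acquisition reconstruct
without bias. The reconstruction grid is a cube at the isocenter with
voxel = effective pixel. No scatter, beam hardening, phase retrieval or
iterative methods; geometric calibration is assumed known (phantom
geometry is exact by construction).

## Airway segmentation

Multiscale Hessian vesselness (Frangi-type, via scikit-image, one call
per scale so the winning scale is retained) with dark-ridge polarity —
airways are air-filled tubes on brighter tissue. Default weights alpha =
beta = 0.5 and contrast weight gamma = half the maximal Hessian norm per
scale (the original conventions); scales default to 10 geometric steps
over 1-30 voxels (tests use narrower ranges matched to their phantoms —
the kernel support must fit the volume). The filter response is
invariant to additive offsets and monotone in contrast.

Flood fill takes the 26-connected component of `{response >= threshold}`
containing the trachea seed; the default threshold is Otsu's on the
response histogram. Skeletonization thins the mask, builds a
26-connected centerline graph, roots it at the seed (BFS resolves
junction-cluster cycles), compresses chains into segments, prunes
terminal spurs shorter than `prune_factor x` the local radius (from the
Euclidean distance transform, which also supplies per-point radii), and
numbers generations by bifurcation count from the root.

On clean phantom lumen masks the generation-4 tree is recovered exactly
(15 bifurcations). On rendered volumes with speckle, the flood fill
reaches >=90% of proximal lumen voxels but also picks up speckle troughs
adjacent to the tree, so the skeletonized tree over-segments (extra
short terminals); the true tree is contained within it. This is a known
limitation of threshold-based flood fill on textured data and is why
interactive thresholding is common practice.

## Velocimetry (XV)

Volumes are Gaussian-smoothed (sigma 1 voxel) and bandpass filtered
(radial passband 0.02-0.25 cycles/voxel) to enhance speckle and remove
both the DC/anatomy pedestal and voxel noise. Interrogation windows of
32^3 voxels with 50% overlap tile the volume (grid spacing = window x
(1 - overlap)); a 128^3 volume gives a 7^3 node grid.

Each window pair is correlated by FFT (windows zero-mean, normalized).
Inside `displacement_field` the correlation map is divided by the
per-lag overlap fraction (floored at 0.3): at lag `l` only `(1 - |l|/W)`
of the window content can match, and without this *unbiased*
normalization the 3-point fit is biased toward zero by up to ~0.25
voxel. The integer peak is refined per axis by a 3-point Gaussian fit
(parabolic available); quality is the ratio of the primary peak to the
highest peak outside its 3-voxel neighbourhood. Vectors with quality
below 1.2, zero-variance windows, or centers outside the lung mask are
invalid; invalid interior nodes are median-filled from valid
26-neighbours (flagged), boundary nodes stay sparse — mirroring how
low-quality regions (e.g. around the heart) are left sparse in practice.

Accuracy, measured on speckle phantoms (grain 3, the optimal few-voxels
feature size for a 32^3 window): integer circular shifts are recovered
exactly for periodic window content and to <=0.15 voxel (exact after
rounding) through the full windowed path; half-voxel Fourier shifts to
<=0.2 voxel. Windows that straddle the lung boundary measure the
displacement of their *textured* content, whose centroid sits inside the
lung; such vectors are biased toward interior values. With the lung
mask supplied, expansion is therefore flagged valid only where a full
central-difference stencil of in-mask nodes exists, and the regional
integration extrapolates boundary values from the nearest valid node.

Expansion is the divergence of the incremental displacement by central
differences on the node grid (small-strain approximation — "gradients of
the vectors" — rather than det(F) - 1). Tracking runs over successive
phase pairs (t -> t+1); cumulative displacement resamples each increment
at the advected node position, cumulative expansion sums increments at
fixed nodes.

## Airway Tree Link (ATL)

Every lung voxel is assigned to the nearest terminal-segment endpoint
(Euclidean; ties to the lowest segment id). Regional volumes integrate
the node-grid expansion — linearly upsampled to the voxel grid — over
each region and accumulate over phase intervals, starting at 0 at
end-expiration. Voxel-level integration was chosen over whole
interrogation-cell volumes because cubic cells mis-count the curved lung
boundary by more than the few-percent accuracy the volume recovery
otherwise achieves. Flow summation is a post-order traversal: leaf
series are the terminal series, every parent's series is the sum of its
daughters' (airway compression neglected under tidal ventilation), so
conservation at every bifurcation holds to floating-point exactness and
the trachea series is the total lung volume change. On the default
phantom the XV-measured total tidal volume lands within ~4% of ground
truth (typically <1%); per-pair expansion RMS error is ~9-13% of the
field amplitude.

The expiratory time constant per branch is the time after the start of
expiration (taken from the ventilation protocol, since acquisition is
ventilator-triggered; a measured-peak option exists) at which the
branch's expired volume first reaches `1 - 1/e` (~63%) of its tidal
volume (= the peak of its series, measured from its own end-expiration
zero), linearly interpolated between phase samples. This operational,
fit-free definition matches how the quantity is used clinically; an
exponential-fit estimator is available as an option. Branches that
never reach the threshold, or with non-positive tidal volume, are
flagged invalid rather than extrapolated. With 15 samples over a 500 ms
breath, a 100 ms exponential deflation is recovered to ~2.5%; regions
with tau in {80, 160} ms classify without error at a 120 ms cut.

The aeration map assigns every centerline location its segment's
cumulative volume per phase (zero everywhere at t = 0), exported as VTK
polylines coloured per phase; time-constant maps are exported the same
way. Colour scales are linear and configurable.

## Problem sizes and numerical choices

Default experiments run on 128^3 grids with 15 phases, generation-6
trees, 32^3/50% XV windows — sizes at which every stage's validation
completes in seconds to a couple of minutes on one CPU. The cone-beam
checks use a 64^3 sphere with 200 projections on an 80^2 detector
(Pearson correlation with truth ~0.985). Tolerances used in validation:
conservation residuals < 1e-9 (exact by construction), divergence of
analytic linear fields to machine precision, XV shift recovery as
above, tidal volume within 5%, tau within 5%.

Degenerate inputs are defined rather than accidental: zero-variance
correlation windows flag invalid (no exception), flat expiratory series
flag invalid, empty gating bins / masks / projection sets raise with the
offending indices named, and a tree that cannot fit its grid names the
first offending segment.

## Known limitations

- The lung envelope is a generic ellipsoid; no lobes, no anatomy, no
  cardiac motion (real data leaves sparse XV coverage near the heart;
  the phantom emulates the *mechanism* — decorrelated regions are
  flagged invalid — not the heart itself).
- Speckle is texture, not propagation physics; image noise is additive
  Gaussian.
- Boundary-window content bias (above) limits expansion accuracy within
  half a window of the lung surface.
- Frangi response dips at bifurcations can disconnect thin distal
  branches at high thresholds; on textured renderings the segmented tree
  over-branches at low ones.
- Per-region tau makes the expiratory displacement field discontinuous
  at region boundaries; XV validation of expansion therefore uses
  inspiration-phase pairs.
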