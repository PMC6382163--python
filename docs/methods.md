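# Methods

## The spike-based grid score

`spikesym` quantifies the local hexagonal order of a 2-D spike pattern by
assigning a score and an orientation to every spike. The construction is
borrowed from the bond-orientational order parameter used to describe
local order in crystals, adapted in two ways to neuronal data: the
relevant "neighbors" of a spike are spikes in *neighboring grid fields*
(roughly one grid spacing away), not the nearest spikes; and competing
symmetries must be rejected explicitly, because firing patterns contain
few fields and can look deceptively ordered.

For spike k with neighbors l = 1..N at angles φ_l (measured
counter-clockwise from the positive x axis),

    ψ_k^(M) = (1/N) Σ_l exp(i M φ_l),        M ∈ {2, …, 7}

The per-spike grid score is

    ψ̂_k = |ψ_k^(6)|   if |ψ_k^(6)| > |ψ_k^(M)| for all M ∈ {2,3,4,5,7}
    ψ̂_k = 0           otherwise,

and the per-spike orientation is θ_k = arg(ψ_k^(6))/6, reported in
degrees in (−30, 30]. The arena-wide score Ψ is the arithmetic mean of
ψ̂_k over *all* spikes (zeros included); the arena-wide orientation Θ is
the circular mean (period 60°) of θ_k over the spikes with ψ̂_k > 0.

### Neighborhood shell

Neighbors are the spikes inside an annulus of radii (5/6)ℓ to (7/6)ℓ
centered on the spike, where ℓ is the grid spacing. ℓ is estimated from
the histogram of all pairwise spike distances, binned at 0.5% of the
maximal distance and smoothed with a Gaussian kernel of σ = 1% of the
maximal distance: the first peak reflects the field size, the second the
spacing. Two remedies for noisy patterns are provided: take the first
peak beyond a cutoff of 15% of the arena side (`cutoff` mode), or pool
the median spacing over other cells of the same module; a manual spacing
can also be supplied. Detection failure does not abort a pipeline run:
the map receives all-zero scores with an explicit failure flag, because
that is how such cells behave downstream (they cannot beat a shuffled
threshold).

For other target symmetries the shell moves inward: the annulus is
centered at (2/3)ℓ for 4-fold patterns and at ℓ/2 for band-like (2-fold)
patterns, keeping the hexagonal relative half-width of ℓ/6.

### Numerical choices

* **Tie breaking.** The dominance comparison is strict; an exact tie
  (e.g. two diametrically opposite neighbors, where |ψ^(2)| = |ψ^(6)| = 1)
  scores 0. Because such ties are not bit-exact in floating point, the
  comparison requires |ψ^(6)| to exceed every competitor by more than
  1e−12.
* **Shell boundary.** Spikes exactly on the annulus boundary count as
  neighbors (closed interval); the choice has measure zero.
* **Angle conventions.** arg maps to (−π, π]; orientations therefore lie
  in (−30, 30]. Circular means are computed by summing unit vectors at
  6θ and taking arg/6, which is exact at the ±30° wrap.
* **Zero-neighbor spikes** score 0 and carry a distinct flag
  (`n_neighbors == 0`), so "no neighbors" is distinguishable from
  "failed the symmetry comparison" and Ψ stays well defined.
* **Θ averaging** is unweighted over the contributing spikes
  (`include_zero_score_spikes` switches to all spikes with a defined
  orientation); weighting by ψ̂ is deliberately not applied.

## The correlogram reference score ρ

For comparison, the conventional rotation-correlation grid score is
implemented: spikes are binned into a rate map (2-cm bins, 4-cm Gaussian
smoothing for a 1-m arena, both scaling with arena size; no occupancy
normalization, since no trajectory is modeled), the spatial
autocorrelogram is computed as a Pearson correlation at every integer
lag (lags with an overlap below 20 bins are masked), and an annulus is
cropped around the six fields nearest the center. Fields are located the
standard way: connected regions of the correlogram above a correlation
of 0.1, represented by value-weighted centroids — far more robust than
raw local maxima on noisy maps. The annulus' inner radius is where the
central peak falls below 0.1 or the first radial local minimum
(whichever is smaller); the outer radius is 1.25× the mean distance of
the six fields. Then

    ρ = min(r_60, r_120) − max(r_30, r_90, r_150)

where r_a is the Pearson correlation between the annulus and its copy
rotated by a degrees (bilinear interpolation, partially-valid pixels
excluded pairwise). Perfect hexagonal patterns give ρ ≈ 1.5; patterns
without hexagonal structure give ρ ≲ 0. ρ is reported as failed when
fewer than six fields are found; the classification treats a failed
actual score as "not a grid cell" and a failed shuffle score as the
score floor (−2), so failures never inflate a null threshold.

The annulus constants (0.1 threshold, 1.25 factor, 20-bin overlap) are
package defaults exposed in the configuration; they are a reconstruction
of the conventional procedure, not a published parameter set.

## Classification

A cell is called a grid cell when its score (Ψ or ρ) strictly exceeds
the 95th percentile (linear interpolation between order statistics) of
the scores of 100 shuffled versions of its spike map. Shuffling redraws
every spike position uniformly over the arena, preserving the spike
count and the spike times; shell or annulus detection is re-run per
shuffled map. The per-cell null keeps the threshold fair for cells with
many background spikes. The shuffling strategy is replaceable; whether
the original procedure preserves any structure (e.g. shifts along the
trajectory) is unknown, and uniform relocation is the variant that
destroys all spatial structure.

On structureless (uniform) spike maps this construction admits ~5%
false positives by design; the test suite verifies the calibration over
200 maps of 200 spikes — a size at which spacing detection on uniform
maps still returns (meaningless) spacings, so the null scores vary
continuously. On much denser uniform maps detection itself usually
fails, and the classification is then negative by the failure rule.

## Local analyses

Because every spike carries its own score, local analyses are averages:

* **Partitions.** Mean ψ̂ and circular-mean θ per named region
  (rectangles are half-open, [min, max), except at the arena's maximum
  edges, so abutting strips assign each spike exactly once; first match
  wins for overlapping regions). Summaries pool across cells by
  spike-count weighting; circular means pool by summing the per-spike
  unit vectors, which makes pooling exact.
* **Temporal filtering.** A centered boxcar in *time* (not spike index):
  the smoothed value at spike k averages ψ̂ over spikes within
  ±window/2 seconds; edge windows truncate. Smoothing operates at spike
  times rather than on a regular time grid.
* **Reference scoring.** Each query spike is scored with neighbors drawn
  only from a reference map (e.g. all spikes fired under light). The
  query contributes no neighbors to itself; since the shell's inner
  radius is positive, scoring a map against itself reproduces the
  ordinary pipeline exactly.
* **Block averages.** Spikes binned by (trial label, ⌊(t mod
  trial_len)/block_len⌋), e.g. 2-minute trials into 12 × 10-s blocks.
* **Covariate correlation.** Pearson correlation between the smoothed
  score series and a covariate evaluated at spike times.

## Synthetic spike maps

The generator emulates a grid cell's spike map as draws from isotropic
Gaussian firing fields on a triangular lattice (spacing ℓ, optional
rotation and phase) that covers the arena plus a one-spacing margin;
each spike picks a field uniformly and is rejected-and-resampled until
it lands in the arena. Defaults: ℓ = 0.5 m in a 1 m × 1 m arena,
2000 spikes, field width σ = 0.15 ℓ. The field width is the one
genuinely open parameter: σ = 0.15 ℓ gives a field diameter (~4σ) of
0.6 ℓ, consistent with the experimentally constant ratio of field size
to grid spacing, and yields the characteristic Ψ ≈ 0.35 for unperturbed
grids — appreciably narrower fields leave too few field-edge spikes
(Ψ drifts toward 0.6), appreciably wider fields merge.

Perturbation families: Gaussian jitter of field centers (optionally
restricted to a region), horizontal shear about the arena midline
(area-preserving), replacement of a fraction of spikes by uniform
background, abrupt or strip-wise drifting lattice orientation, and a
temporal switch from uniform to grid firing at a constant spike rate
(1 Hz), which attaches spike times.

What the generator does **not** emulate: running trajectories and
occupancy inhomogeneity, temporal spike statistics (bursting,
refractoriness), firing-rate differences between fields, and elliptic
field shapes. Passing tests therefore demonstrate the estimator's
behavior under controlled geometric distortions, not its robustness to
every property of experimental recordings.

## Problem sizes and reproducibility

All generators and the shuffle are deterministic given a seed. The
acceptance script and the heavy tests use 8 jitter levels × 25 maps of
2000 spikes (Ψ–ρ correlation; level 0 doubles as the unperturbed
ensemble and the last level, jitter = ℓ/2, as the randomized-field
ensemble), 8 × 20 maps for the shear and background sweeps, and
200 × (1 + 100) score evaluations for the null calibration — sizes at
which the reported means are stable to well within the tolerances
asserted.

## Known limitations

* The detected spacing sits ~4% below the true lattice constant (the
  raw pair-distance histogram weights distances geometrically); the
  ℓ/3-wide shell absorbs this.
* For randomized field locations the reconstructed ρ procedure yields a
  mean near −0.3 (per-map spread ±0.4); values around −0.5 depend on
  annulus details that are not published.
* Per-spike adaptive shells for spatially varying grid spacing are out
  of scope; the shell is global per map.
* Spikes in boundary fields are scored against an incomplete neighbor
  ring; their scores are anisotropic (high-score stripes tangential to
  the arena boundary), which is inherent to the estimator.
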