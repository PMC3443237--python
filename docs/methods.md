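# Methods

## The statistic

MEG beamformer contrast images are inhomogeneously smooth: information-rich
near strong sources and very smooth elsewhere, with broad maxima and
side-lobes whose overlap across participants can create apparently
disconnected group-level effects. `peakclust` sidesteps voxelwise group
statistics by compressing each participant's volumetric image to the list
of its local maxima (the only locations where individual beamformer
estimates are reliable) and testing whether the top-ranked peaks cluster
across participants more tightly than randomly ranked peaks would.

**Peaks.** A peak is a voxel whose value strictly exceeds all of its
18-connected in-mask neighbours (6 faces + 12 edges; the 8 corners are
excluded), so two maxima can sit a single non-maximal voxel apart.
Neighbours outside the array or mask are ignored, making boundary maxima
reportable. Plateaus (exact ties) have no strict maximum and are not
reported. Peaks are rank-ordered by value within each participant for a
chosen sign of interest; "wrong-sign" values are kept by default because
only rank order enters the statistic (a `require_sign_consistent` flag
drops them).

**Clustering.** For N participants' top-M peaks (N·M pooled points), a
k-means procedure with k = M assigns points to centroids; each cluster is
then *trimmed* so no participant contributes more than one point, keeping
the point nearest the centroid (ties go to the better rank); centroids are
recomputed from the trimmed members and the loop repeats (30 iterations by
default) over several k-means++ restarts (default 10; the recorded minimum
can only improve with more restarts). For every achieved participant count
N' ∈ [n_min, N] the smallest trimmed cluster is kept. Cluster size is the
major radius of the 95% confidence ellipsoid: eigen-decompose the 3×3
sample covariance (ddof = 1) of the member locations; axis half-lengths
are 1.959964 × √eigenvalue (two-sided Gaussian 95% half-width). Clusters
trimmed below 2 points are discarded for that round; with fewer than 3
distinct points the missing eigen-directions get radius 0. Volume
(4/3 π r₁r₂r₃) is reported but never used for ranking.

The trim-to-nearest rule means the procedure is not an exact global
search: on adversarial point sets a one-point-per-participant subset can
exist whose centroid is closer to another of some member's peaks, making
it unreachable. On data with a genuine tight cluster the procedure
reliably attains the enumeration optimum (verified against brute force in
the tests), and it can never do better than that optimum.

**Null and p-value.** Under the null, peak rank carries no spatial
information, so ranks are shuffled uniformly *within* each participant's
full peak list (locations never move) and the clustering is re-run; K
permutations (default 500) give, per N', the chance distribution of
smallest major radii. The null uses identical engine settings to the
observed analysis so the comparison is like-for-like; p = (1 + #{null
radii ≤ observed}) / (K + 1) (add-one estimator, never exactly 0).
Permutations that never achieve a subgroup size count as "larger".

**Choosing M.** Testing M over a range re-tests one hypothesis on
overlapping data; an effectively independent peak set enters only when M
doubles, so the family size is 1 + log₂(M_end/M_start) and the test-wise
threshold is α divided by that (0.05 over M = 2..40 → 0.0094). The
heuristic J(M, N') = √(M² + R(M, N')²) scores the distance from the knee
of the R-vs-M curve, where R is by default the 95th percentile of the
null major-radius distribution (the 5th percentile — the significance
threshold itself — is the alternative reading; both fall with M, and the
percentile is a parameter). J is a heuristic in mixed units (peak count
vs mm); axis scalings are exposed. When one region recurs across M, the
reported representative has the largest N', then the smallest major
radius (centres within 15 mm are considered the same region by default).

## The simulation study

The simulator emulates the conditions of the published validation
protocol. Per participant: one equivalent current dipole at
N((52, −29, 13) mm, isotropic SD 5 mm), driven by a 40 Hz sinusoid in
200 ms epochs at 200 Hz sampling, active in 30 of 60 epochs, plus i.i.d.
Gaussian sensor noise of density 10 fT/√Hz over an 80 Hz bandwidth
(per-sample SD 10·√80 ≈ 89.4 fT). All participants share one sensor
array and head model; only source location/orientation and noise differ.

Design choices where the published description could not be reproduced
exactly:

- **Sensor geometry.** 275 radial magnetometers on a Fibonacci-lattice
  spherical cap (12 cm radius, extending ~20° below the equator) around a
  9 cm conducting sphere — a stand-in for a whole-head axial-gradiometer
  array, whose exact coordinates are not public. Gradiometers are
  approximated as radial magnetometers; results depend only weakly on the
  layout.
- **Forward model.** Sarvas closed-form solution for a dipole in a
  homogeneous conducting sphere. Radial moments are externally silent, so
  the source basis is tangential; the independent test oracle exploits the
  fact that radial sensors see only the primary-current field's radial
  component.
- **Orientation.** The original protocol snapped each seed to a cortical
  mesh and used its surface normal. Without a mesh, a fixed reference
  direction is tilted by (location jitter)/25 mm and projected onto the
  tangential plane, so orientation co-varies with the 5 mm location
  jitter across participants.
- **Coordinate frames.** MNI-style mm map to the head frame by a fixed
  translation (0, −20, 20) mm; all distances (including the 20 mm
  hit/miss rule) are computed in mm, so the choice cancels.

**Beamformer.** Scalar LCMV: W = C⁻¹Hη / (ηᵀHᵀC⁻¹Hη) with a single
covariance window spanning active and passive epochs; the orientation η
maximises output SNR — the generalised eigenvector of (HᵀC⁻¹H, HᵀC⁻²H)
at the largest eigenvalue. Images are pseudo-t values
T = (WᵀC_active W − WᵀC_control W)/(σ²WᵀW) with identity noise covariance
scaled by the known simulated noise variance (estimated from passive
epochs when unknown); a variant that also divides by 2 exists in the
literature — rank order of peaks, which is all the clustering consumes,
is invariant to that constant. No regularisation by default (`mu = 0`,
maximum spatial resolution, noisiest images, most peaks); matrix
inversion is a pseudo-inverse with relative cutoff 1e-12. The image grid
is 10 mm, masked to voxels ≥ 1 cm inside the sphere; the (silent) sphere
centre and any voxel with a singular leadfield Gram matrix are marked
invalid.

**Comparator.** A faithful-in-spirit SnPM-style one-sample test, not a
port: voxelwise pseudo-t with variance smoothed by a normalised masked
Gaussian (FWHM 25 mm in the simulation; 6/12/24 mm mirror typical
experimental choices), a sign-flipping null (full enumeration when
2ⁿ ≤ n_perms, else random flips including identity), and FWE control by
the (1−α) quantile of the permutation max statistic. Significant local
maxima of the t image are the comparator's findings.

**Hit/miss protocol.** Per source magnitude: a 10-participant pool of
pseudo-t images, 20 random groups of 8, both methods per group, and every
significant finding centre classified as a hit (< 20 mm from the fixed
seed centre (52, −29, 13) — per-participant realised locations differ, so
the distribution centre is used; a per-group alternative is a flag) or a
miss. The clustering test runs at M = 5 with subgroup size N' = the full
group (n_min = 8), so it yields at most one finding per group; when
subgroup statistics are enabled, findings within 20 mm of a larger-N'
finding are deduplicated. At 50 nAm this reproduces the 20-hits/0-misses
endpoint; at moderate magnitudes (10–20 nAm) the comparator's smooth
side-lobe overlap produces many off-source findings while the clustering
method stays clean. In this simulation the comparator is *more* sensitive
at moderate SNR than the clustering test (which here has few peaks per
image, so rank shuffling has little room); relative sensitivity depends
on geometry and regularisation, whereas the artefactual miss excess is
robust.

## The fixture generator

`make_fixture` emulates only the statistical structure the clustering
layer assumes: per participant, one optional "true" peak jittered around
a common centre (participation fraction configurable) among uniform decoy
peaks in a brain-sized box, with values giving the true peak rank 1 by
default (a Beta value model can demote it). It does not emulate spatial
smoothness, inter-peak correlations, or realistic peak-count
distributions — passing calibration/power tests on fixtures shows the
statistic behaves correctly for exchangeable ranks, not that real
beamformer images meet those assumptions.

## Problem sizes and numerical choices

Defaults follow the study conditions (K = 500 permutations, 30 k-means
iterations). The test suite scales stochastic checks down to keep runs
short: K = 200 for the simulated endpoint and artefact-immunity checks,
250 replicates at K = 200 (restarts = 1, 15 iterations) for type-I
calibration — calibration only requires identical settings for observed
and null, not strong search. The acceptance script runs the full K = 500
protocol. All randomness flows from a single seed through
`numpy.random.Generator`; reports record it.

## Known limitations

- Single-sphere head model, white uncorrelated noise, single-source
  scenes; no BEM, correlated brain noise, or multi-source interactions.
- No condition-label shuffling alternative (future work); rank shuffling
  only.
- The exact-minimum ellipsoid search is exponential and used only as a
  tiny-scale test oracle.
- The tool never converts between template spaces; world coordinates are
  whatever the input affines declare.
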