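# Methods

`marrowniche` quantifies how megakaryocytes (MKs) are arranged around the
bone-marrow vasculature and how much they move.  It consists of five parts:
a synthetic-geometry generator (stand-in for unavailable light-sheet
volumes), distance-transform morphometry, two Monte-Carlo placement null
models, anomalous-diffusion trajectory analysis, and pipeline plumbing.
This note records the models, the defaults, and the choices that were
genuinely open.

## Coordinate and label conventions

Volumes are anisotropic voxel grids indexed `(i, j, k) ↔ (x, y, z)` with a
default spacing of 0.5 × 0.5 × 2 µm.  Voxel `(i, j, k)` has its center at
`(i·sx, j·sy, k·sz)`; all distances are Euclidean distances in µm between
voxel centers, computed with an anisotropic Euclidean distance transform
(scipy's exact EDT).  Labels are 0 marrow / 1 vessel / 2 bone in one array;
MK ids live in a second integer array.  MK ids may overlap the vessel label
(intravascular cells) but never bone.

"Edge-to-edge" distances are operationalized as the vessel (or bone)
distance map evaluated on an MK's voxels and minimized.  Whether the
original surface-mesh measurements used voxel centers or mesh faces is not
knowable from the data we emulate; the center-to-center convention is
declared, not inferred, and is exact at the voxel scale.

## Association thresholds

* **Vessel-associated (VA)**: edge distance ≤ 2.0 µm (configurable).  2 µm
  is the largest voxel extent, which makes the 3D "within one voxel" rule
  and the 2D cryo-section "< 2 µm contact" rule the same number.
* **Bone-associated (BA)**: edge distance to the bone cortex strictly
  < 100 µm.
* **Intravascular**: more than 50% of the MK's voxels carry the vessel
  label.  Only the existence of intravascular MKs is documented
  experimentally, not a cutoff; 0.5 is this package's decision and is
  configurable.

## Vessel-to-vessel spacing

The intervascular spacing statistic is *twice* the value of the vessel
distance map at its local maxima restricted to marrow — the distance through
the point midway between two adjacent vessels, i.e. the diameter of the
largest sphere that fits between them.  Local maxima use a 26-neighborhood
maximum filter (plateau-aware: every voxel of a flat plateau qualifies);
maxima closer than one voxel diagonal (≈ 2.06 µm at default spacing) are
single-linkage merged, keeping the largest value.  Maxima whose *every*
voxel lies on the grid border are discarded: there the map may still be
rising toward structures outside the imaged volume, so no spacing can be
certified.  Clusters that merely touch the border while extending into the
interior (e.g. the midplane between two sheets spanning the whole volume)
are kept.

## Virtual sectioning

`virtual_slice_metrics` cuts the volume into slabs of configurable thickness
(default 10 µm, the usual cryo-section) and recomputes, per slab, in-plane
2D distances between MK voxels and vessel voxels *within the same voxel
plane*, taking the minimum over the slab's planes.  Because every
(MK voxel, vessel voxel) pair considered in 2D is also available to the 3D
minimum, the per-MK 2D distance is never below the 3D distance — sections
can only miss vessels, never invent them.  This makes the known
section-vs-volume bias (sections underestimate vessel association) a
construction-level guarantee, which the acceptance checks confirm on
realistic scaffolds.  Cross-section diameters are equivalent-circle
diameters of the slab-projected MK area.

## Synthetic scaffold generator

The generator replaces the unavailable imaging data and defines the study
conditions; its defaults are the experimentally reported summary values.

* **Vessel network.** The real sinusoid topology is unknown to us, and only
  the realized spacing statistic matters downstream.  We therefore use a
  random geometric graph: Poisson-disk (dart-throwing) node sampling, edges
  to the 3 nearest neighbors, components bridged at their closest node
  pairs so the network is connected.  Edge radii are lognormal (median 6 µm,
  σ = 0.25); the sinusoid radius distribution is not experimentally
  constrained, so this is an exposed parameter, not a claim.  The node
  spacing is an internal calibration: realized median spacing tracks
  `0.72 · target + 2 · median radius`, fixed once on reference scaffolds so
  that a 43 µm target yields a realized median within the contract's ±25%.
* **Rasterization.** Edges become capsules (segment + radius, hemispherical
  caps); a voxel is vessel when its center falls inside.  The bone cortex is
  a simple hollow rectangular shell of configurable thickness on all faces;
  bone wins over vessel at conflicts.  Trabecular/epiphyseal bone is out of
  scope.
* **MK population.** Diameters are normal 20.36 ± 8.19 µm truncated below
  at 5 µm — the printed SD admits non-physical negative diameters, so a
  floor is mandatory; 5 µm is roughly the smallest plausible MK precursor.
  MKs are spheres rasterized on the anisotropic grid (the shape provider is
  a function boundary, so ellipsoids could be added); their "measured"
  diameter downstream is the equivalent-volume sphere diameter of the voxel
  set.  A `vessel_bias` fraction (default 0.7, matching the observed ~70%
  VA) is forced into vessel contact by sampling centers from the distance
  band `(r, r + threshold]`; the rest are uniform over marrow.  Placement is
  rejection sampling, largest-first (this eases packing and changes nothing
  in the sparse regimes used here), with no overlap of vessel, bone, other
  MKs, or the grid exterior.
* **Default domain** 240 × 240 × 180 µm with 80 MKs: large enough for the
  4× spacing precondition and an MK volume fraction of a few percent, small
  enough that a full analysis runs in seconds to minutes on one CPU.  These
  sizes are the package's chosen desk-scale study conditions; the original
  volumes (whole bones) are orders of magnitude larger.

What the generator does *not* emulate: image formation (PSF, noise,
attenuation), segmentation errors, non-spherical MK morphology, curved
vessels, trabecular bone, and spatial heterogeneity of vessel density.
Passing tests therefore validate the *analysis logic* (distances,
classification, null-model inference), not robustness to imaging artifacts.

## Placement null models

* **SimR** draws MK centers uniformly over marrow voxels and rejects
  candidates whose rasterized sphere overlaps vessel, bone, a placed MK, or
  leaves the grid.  Contact (edge distance ≤ threshold) with vessels is
  allowed — MKs are extraluminal but may touch; without contact SimR could
  never produce a vessel-associated cell, contradicting the reported SimR
  VA fractions.  Bone contact is likewise allowed, overlap is not; the
  original overlap tolerances are unstated, these are declared decisions.
* **SimNVA** freezes the observed VA cells and re-places only the NVA
  subpopulation "without vessel or cell contact", mapped to: measured edge
  distance strictly greater than the association threshold from vessels and
  frozen cells (guaranteed via center clearance > r + threshold and the
  triangle inequality on the distance map), and center-to-center distance
  > r_i + r_j + threshold between new cells.  Every placed object is hence
  NVA by construction, which the code asserts.  The number of re-placed
  cells is the length of the supplied diameter list; the pipeline passes
  the observed NVA cells' own diameters (matching number and size
  distribution), rather than a fixed 30% quota, since the NVA fraction is a
  measured quantity.
* **Comparison.** Per scenario over replicates (default 6): mean ± SD of
  the VA fraction and of the replicate-mean NVA distance; a two-sided
  Mann–Whitney U test (normal approximation, tie-corrected) of the observed
  all-MK vessel-distance distribution against the scenario's pooled one
  (this is the verdict test), and the same test on the NVA subsets.  The
  all-MK distribution is the discriminating statistic: conditional on
  non-association, SimR's NVA cells are uniform just like genuinely
  unbiased NVA cells, so an NVA-only test cannot reject SimR — the VA
  deficit can.  "Rejected"/"compatible" is decided at a configurable
  significance level (default 0.05).  Note the compatibility check is a
  true-null p-value: by construction it fails for ~5% of seeds.

## Trajectory model and MSD analysis

Tracks follow `MSD(τ) = 2 d K_α τ^α` (for 2D centroid tracks the familiar
`4 K_α τ^α`).  The generator synthesizes: Brownian increments (per-axis
variance `2 K Δt`); fractional Gaussian increments with Hurst `H = α/2`,
built from the Cholesky factor of the fGn covariance
`K Δt^α (|k+1|^α − 2|k|^α + |k−1|^α)` — exact for the track lengths used
here (hundreds of frames), no spectral approximation; ballistic lines with
speed `√(2 d K)`; and stationary points.  `α = 2` under the fBm model
degenerates to perfectly correlated increments and is generated as a random
constant-velocity line with a warning.  Optional localization noise is
i.i.d. Gaussian on every position.

Analysis: the time-averaged MSD over all start frames, for lags up to
`max_lag_fraction` of the track (default 0.25 — long lags average few pairs
and are noise-dominated; the original fit range is unpublished, so this is
a package default, configurable).  `α` is the slope and `2 d K_α` the
intercept of an unweighted least-squares line on log τ vs log MSD
(`n_pairs`-weighting available).  Zero-MSD lags are dropped with a warning;
an all-zero curve has no defined exponent and errors.  Motion classes use a
±0.1 Brownian band — strict equality is meaningless for finite data.
Cohort summaries report median ± SD of α, K_α, and MSD at a caller-chosen
reference lag (the lag behind published cohort MSD values is unstated, so
it is a required argument), plus instantaneous speeds pooled across steps
(the alternative — per-track medians first — is available by summarizing
per track).  Proplatelet-forming cells are excluded by an input flag,
mirroring the manual exclusion upstream of tracking.

## Numerical choices and degenerate inputs

* Distance maps on empty masks are errors (distance undefined); absent
  structures (e.g. no bone) yield infinite distances and false flags.
* Spheres smaller than one voxel rasterize to the center voxel, so objects
  are never empty; MK objects must be 26-connected, and fragmented ids are
  split into suffixed ids with a warning.
* The chi-square uniformity and shell checks compare Monte-Carlo placement
  against exhaustive enumeration over the admissible center grid, which
  removes voxelization bias from the comparison.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; every generator and simulation is bit-reproducible per seed.

## Known limitations

* Spheres only; real MKs are irregular and the equivalent-diameter summary
  hides shape variance.
* The vessel network is statistically, not anatomically, realistic; its
  radius distribution is a guess exposed as a parameter.
* The spacing statistic depends on local maxima of a sampled field; on
  coarse grids plateau detection can merge or split maxima near the merge
  tolerance.
* SimNVA's "no contact" clearance is enforced through center-based bounds
  that are sufficient but mildly conservative: a sliver of admissible
  centers at exactly threshold clearance is excluded.
* Desk-scale domains carry boundary effects (border maxima are discarded,
  spheres must fit inside the grid) that whole-bone volumes would not.
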