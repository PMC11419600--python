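# Methods

## Scope and model

`voxmap` quantifies in situ hybridization signal per reconstructed
neuron without segmenting the image. The unit of evidence is the voxel:
an image pixel with physical extent `px_x × px_y × dz` µm. A voxel at
or above an intensity floor carries an *expression volume*; a voxel
whose center falls inside a neuron's closed surface donates that volume
to the neuron; a neuron's *total expression percent* is its donated
volume over its enclosed mesh volume, ×100; a positive call means that
percent reaches a threshold θ. Everything else in the package exists to
make those four sentences reproducible: deterministic voxelization,
automated landmark registration, an exact point-in-mesh primitive, and
a calibration procedure that justifies θ against known expression.

The approach assumes: (i) meshes are watertight and expressed in the
same physical units (µm) as the stack; (ii) a rigid (optionally
uniformly scaled) motion suffices to align specimen and reconstruction
— biological variability beyond a rigid pose is not modeled; (iii) the
voxel scale is fine relative to the cell scale, so center-point
containment approximates volumetric overlap.

## Expression volume: binary vs weighted

The per-voxel expression volume is ambiguous in principle: a bright
voxel could count its full geometric volume or be discounted by
intensity. Both conventions are implemented (`mode="binary"`, the
default, and `mode="weighted"`, intensity/255-scaled). Binary is the
default because the downstream percent-of-cell-volume arithmetic reads
most naturally as volumetric occupancy, and because the calibration
stage absorbs the difference between the two conventions into θ. Binary
totals always dominate weighted totals at the same floor (tested).

The intensity floor defaults to 10 of 255 to suppress detector noise;
the total retained expression volume is monotone non-increasing in the
floor (tested). Thresholding calls uses *total* expression percent;
relative expression (percent ÷ per-probe maximum) is reported as a
column but never thresholded, since a per-probe normalization would
make θ depend on the brightest neuron of each in situ.

## Registration

Manual overlay of expression objects on cell shapes is irreproducible
in a library, so alignment is automated as landmark correspondence. A
landmark group names (a) a set of mesh neurons, reduced to one
volume-weighted centroid, and (b) a stack-side selector: the connected
component (26-connectivity) with the greatest expression volume inside
a user-supplied search box (default), or the union of all above-floor
voxels in the box (`region_union` — used when one anatomical "patch" is
rendered as several disjoint blobs, as with the ellipsoid stand-ins).
Groups carry a per-group reference channel; the classical choice is
VGAT (eminens dorsal cap; right-side anterior/posterior photoreceptor
patches; dorsal AMG patch), but any channel with an identifiable blob
works, which the hindbrain-only fixture exploits by also anchoring on
VAChT blobs.

Given ≥ 3 non-collinear correspondences the stack→mesh transform is the
closed-form least-squares similarity fit (SVD of the cross-covariance;
reflection corrected to a proper rotation; scale fixed to 1 unless
`allow_scale` is set, since both frames are metric but different
specimens differ in size). The residual RMSD is always reported. The
fit is exact (RMSD < 1e-9) on noiseless rigid motions and its
translation error stays below 0.2 µm for 0.1 µm isotropic landmark
noise in ≥ 95% of trials (both exercised in the acceptance suite).
Channels within one stack share the reference channel's transform;
cross-specimen co-registration of stacks lacking landmarks is out of
scope and must be supplied as a `manual_transform`.

## Point-in-mesh and assignment

Containment is ray-casting parity: a ray from the query point along a
fixed direction is intersected with every triangle (Möller–Trumbore,
vectorized over point×face blocks); an odd crossing count means inside.
Hits within 1e-9 (barycentric) of a triangle boundary, rays nearly
parallel to a candidate facet, and intersections at parameter t ≈ 0
mark the point *unstable*; unstable points are re-cast along random
directions from a fixed-seed generator (≤ 12 attempts), so grazing a
vertex or edge cannot corrupt the parity and results stay
deterministic. Tests require exact agreement with an independently
implemented generalized-winding-number oracle and ≥ 99.9% agreement
with the analytic ellipsoid inequality (disagreements confined to the
facet-chord shell, i.e. representation error of the mesh, not parity
error).

Assignment prunes candidate voxels per mesh by axis-aligned bounding
box before testing centers. The contract is that pruning changes
nothing: on seeded random scenes the accelerated path must equal the
exhaustive all-pairs loop bit for bit (acceptance suite). Voxels
contained in several meshes (possible with touching reconstructions)
are credited to every container by default (`overlap_policy="all"`;
per-neuron percent-of-own-volume makes double credit harmless, though
percents may then exceed 100), or to the nearest-centroid container
(`"nearest"`). With disjoint meshes the policies coincide (tested).
An exact polyhedron–voxel intersection volume is deliberately out of
scope; at the fixture scales the center-point rule biases any neuron's
recovered volume by at most a one-voxel surface shell (tested).

## Threshold calibration

"A threshold that aligns with ground truth" is operationalized as:
sweep θ over 0.5–20% in 0.1% steps; at each θ compute per-gene balanced
accuracy (mean of sensitivity and specificity) of the calls against the
labels, averaged over genes, where the truth's negative set is the
declared neuron universe minus its positives; report the full *feasible
interval* of thresholds attaining the maximum and choose its midpoint
(rounded to sweep resolution). Reporting the interval rather than a
single endpoint shows exactly where any conventional value — such as
5.5% — sits relative to the data. Calls are monotone in θ (tested), so
the feasible set of a perfectly separable calibration is always an
interval. The comparison is inclusive (≥ θ).

## Synthetic scenes

The generator emulates the structure of the real inputs, not their
optics. Neurons are axis-aligned ellipsoids (icosphere meshes,
subdivision 3, volume within 1% of (4/3)π·abc) at class-stereotyped
centroids; expression is planted per (gene, neuron); in-cell and
background intensities are Gaussian (defaults 180 ± 25 and 5 ± 3 of
255, chosen once as confocal-realistic); blur is an isotropic Gaussian
(σ = 0.4 µm); the whole stack frame is offset from the mesh frame by a
known rigid pose. Clipping to 0–255 happens after blur, before a
round-half-up integer cast. Rendering is a pure function of
(spec, seed) with a documented draw order (channels in spec order;
background field first, then positive neurons in centroid order), so
fixtures are bit-stable. Membership during rendering uses the analytic
ellipsoid inequality, keeping the generator independent of the
collision code it tests.

Two packaged scenes define the test conditions:

- **hindbrain** (19 neurons, 3 channels, 0.5 × 0.5 × 1.0 µm spacing,
  128 × 64 × 32 stack): planted truth is the known motor-ganglion
  expression — VAChT in AMG5, the six MGINs and the MNs; VGAT in
  AMG1–4, 6, 7; AMPAR in left MNs only. Planted positives express
  through the whole cell (true percent ≫ 8%), negatives receive only
  background (≤ 2%), so calibration must find a wide feasible interval
  containing 5.5%.
- **connectome** (166 neurons, 5 channels, 0.8 × 0.8 × 1.2 µm spacing,
  130 × 44 × 27 stack): neuron ids, classes and planted truth come from
  the packaged published call table; members of each class are placed
  greedily on a 5 µm lattice around anatomically ordered class anchors
  (photoreceptor patches right-lateral, eminens dorsal, AMG row dorsal
  posterior, MGIN/MN split left/right). End-to-end recovery of all 830
  calls is exercised per commit.

What passing these tests does *not* show: robustness to non-rigid
deformation, chromatic misregistration between channels, irregular
neuron morphology, heterogeneous mesh resolution, optical PSF structure
beyond Gaussian blur, or specimen-to-specimen variability. Stack
dimensions and spacings above are package defaults (the source imaging
parameters are not published) and are exposed in config.

## Numerical and interface choices

- Mesh interchange is OBJ (primary) and PLY (accepted); volumes by
  signed tetrahedron summation; non-watertight meshes are rejected at
  load with their open-edge count; zero-area faces are dropped with a
  warning. (The original reconstruction reached Unity via DXF exports;
  OBJ/PLY is the open, triangle-native equivalent.)
- 16-bit TIFFs are max-normalized to 0–255 and rounded; physical
  spacing must always be supplied explicitly — it is never guessed.
- Per-plane CSV dumps are headerless, row-major, LF-terminated; cell
  (r, c) is pixel (row r, column c).
- Call matrices encode 1/0 on disk; a `table1_style` flag emits "+"/"0"
  for side-by-side comparison with the printed table. The packaged
  transcription of that table is data, not code; its README lists the
  text-vs-table discrepancies verbatim rather than resolving them.
- Degenerate inputs: all-zero probes yield all-zero relative expression
  (no division); an all-positive truth forces the feasible interval to
  start at the sweep minimum; ties in `nearest` assignment break toward
  the first mesh in input order; equal-percent maxima give several
  neurons relative expression 1.0.
- The synapse edge fixture encodes only prose-stated relations with
  representative ids and is labelled synthetic; it exists to make the
  mismatch/profile queries testable, not to claim the full wiring.

## Problem sizes

Default test and acceptance runs use the two packaged scenes above,
20-scene oracle-equivalence batches of ≤ 20 meshes × ≤ 8,000 voxels,
100-trial registration Monte Carlo, and 10,000-point membership checks
— sizes chosen so the full suite exercises every contract at desk
scale. All sizes are config-exposed; nothing in the code depends on
them.
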