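# Methods

## Density descriptor

Each channel's localizations seed a Voronoï diagram (scipy/Qhull).
Cell measures are polygon areas in 2D (vectorized shoelace over the
diagram's regions) and convex-polytope volumes in 3D.  The first-rank
density of localization *i* pools its cell with its facet-sharing
neighbors,

    delta_i = (n_i + 1) / (A_i + sum_{j in N(i)} A_j),

and is divided by the reference density `delta = n / measure(ROI)` of a
spatially random process with the same count on the same window, giving
the dimensionless `delta_hat_i`.  The ROI defaults to the channel's
axis-aligned bounding box and can be supplied explicitly; for two-
channel runs both channels may share one ROI.  `delta_hat` is invariant
under rigid motions and uniform scaling (ROI transformed alike) and,
for a homogeneous process, its distribution is independent of the
absolute intensity — both properties are exercised by the test suite.

### Boundary treatment

Cells of seeds near the window edge are unbounded in a raw Voronoï
diagram.  Seeds within five mean inter-point spacings of an ROI face
are mirrored across it before tessellating; the bisector between a seed
and its reflection is the face itself, so border cells come out finite
and clipped exactly at the ROI (the cells then tile the ROI, which the
suite asserts to 1e-6).  This is the standard reflection edge
correction for window-limited density estimation.  An earlier design
assigned `delta_hat = 0` to localizations with unbounded neighborhoods
instead; that rule co-zeroes the scatter coordinates of border
localizations in both channels and injects spurious positive rank
correlation (two independent uniform channels measured S ≈ +0.27), so
it was replaced.  The zero rule is retained as a fallback for any cell
that remains unbounded (and `build_tessellation(pad=False)` preserves
the old behavior for study).

Reflection duplicates local fluctuations at the window edge, which
fattens the upper tail of the density distribution there.  This is
harmless for the threshold classification and the coefficients but can
seed false clusters in the segmentation module; `segment` therefore
refuses to select localizations whose first-rank neighborhood touches
the window edge (a guard zone, as is usual in spatial statistics).

## Classification and edge correction

A single global threshold `T >= 0` (default 1) is applied to both
channels, inclusive (`delta_hat >= T` is high).  Partner densities come
from point-in-cell lookup against the other channel's diagram, which
equals nearest-seed search (ties broken toward the lowest seed index).
The five classes partition all localizations of both channels.

The Delaunay edge correction collects, per channel, the simplices whose
`dim + 1` vertices all belong to that channel's high class, discards
members with measure above `q75 + 1.5 * IQR`, and demotes any
colocalized localization of the other channel that falls outside every
kept simplex (boundary inclusive; point-in-simplex goes through the
triangulation's simplex walk with an exhaustive barycentric fallback
for points on shared facets, and the result is asserted identical to a
full scan).  Two conventions were genuinely open:

- **Quartile population.**  Taking q25/q75 over the member simplices
  alone puts the outlier cutoff inside the natural area spread of
  in-cluster triangles; at the reference condition that prunes interior
  triangles covering ~12% of the clustered area and demotes the points
  inside them, which caps the fully colocalized Manders mean near 0.75.
  Taking the quartiles over the whole triangulation's measure
  distribution — so the cutoff reflects the channel's overall triangle
  scale — keeps cluster interiors intact and removes exactly the
  oversized simplices that span between structures or reach into the
  background.  The latter is implemented; it is the only convention
  that reproduces the published fully colocalized values.
- **Percentiles** use linear interpolation between order statistics
  (numpy's default, the common "type 7" rule).
- In 3D, triangles generalize to Delaunay tetrahedra with volume in
  place of area.

The Manders denominators sum own densities over the *pre-correction*
high class; the colocalization indicator comes from the corrected
labels.  Spearman uses average ranks and the product-moment formula,
which reduces to the classical `1 - 6 sum d_i^2 / (n (n^2 - 1))`
expression when no ties exist.  Undefined coefficients (empty high
class, zero rank variance, n < 2) are reported as explicit nulls,
never as 0.

The literal containment rule is not robust when one channel is
*absolutely* sparse (tens of molecules per cluster): rim vertices then
dip below threshold, their triangles leave the member set, and interior
points of the other channel are demoted.  The robustness guarantees
therefore hold in the regime the validation data cover (cluster
occupancies of a hundred molecules and up).

## Simulator

`simulate_pair` places non-overlapping clusters uniformly at random:
100 nm-diameter circles for channel A (spheres in 3D) and 100 nm
squares for channel B (spheres in 3D), each B center displaced from its
partner A center by a distance `d` in a uniformly random direction.
Cluster counts are Poisson with mean `density x cluster measure`,
points uniform within the shape; both channels add a uniform background
at `density / R` over the field, and points leaving the field after
displacement are clipped.  A displaced B cluster may overlap only its
own partner: overlap with any other cluster of either channel is
rejection-sampled away, so `d` alone sets the realized degree of
colocalization (0 nm fully colocalized, 125 nm none for these shapes).

Defaults are the 2D reference condition: 2.5 x 2.5 µm field, in-cluster
density 0.013 mol nm⁻², enrichment R = 10; the 3D reference
(`SimulationConfig.reference_3d`) uses 1.9 x 10⁻⁴ mol nm⁻³, R = 146 on
a 2.5 x 2.5 x 1 µm volume, with anisotropic Gaussian position
scrambling (`sigma_xy`, `sigma_z`) available to emulate localization
precision.  The cluster count per field is not dictated by the
densities; the default of 120 was chosen so that generated data sets
span the localization counts reported for the original validation
simulations (≈37k–165k per two-channel data set across the density
grid) and remain packable at d = 125 nm.  The B-density grid runs in 20
steps of 0.0026 mol nm⁻² from the 1:1 condition (the printed grid
endpoints and step are mutually inconsistent by one step; the count and
step were kept).

What the simulations do *not* emulate: fluorophore blinking and
repeated localizations of one molecule, detection noise and false
localizations, astigmatic PSF distortion, and drift.  Passing the
simulation-based tests therefore shows that the estimator chain is
correct and density-robust on clustered point processes, not that it is
immune to photophysical artifacts in real acquisitions — bead
filtering and registration address only the geometric part of that
gap.

## Preprocessing

Chromatic registration maps channel B into channel A's space, either as
the displacement between the two fiducial barycenters (translation
mode) or as a full bivariate cubic per lateral coordinate fitted by
least squares on ≥ 10 mutual-nearest-neighbor fiducial pairs (poly3
mode; in 3D the axial coordinate gets a barycenter shift).  Bead
filtering removes any localization whose neighbor count within 100 nm
reaches 90% of the acquisition frame count — an always-on fiducial
produces one localization per frame in a tight disc, a blinking
molecule does not.  The neighbor count excludes the localization
itself.

## Cluster analysis

Two-level segmentation: localizations with `delta_i > 2 * delta_I`
(strict, with `delta_I` the whole-image reference density) are grouped
by Delaunay connectivity into level-1 contours; within each contour the
threshold is re-based on the contour's mean member density to extract
level-2 nanoclusters.  Components below 5 members are discarded
(tessellation noise; the floor is a parameter).  Inter-channel cluster
distance is the Euclidean distance between barycenters, each cluster of
one channel to its nearest in the other.

## Problem sizes and determinism

The acceptance sweep runs 3 distances x 20 densities x 3 replicates
(180 simulations of 20k–130k localizations total per pair); the
per-condition means average 60 runs and carry a standard error below
0.01, so the three-replicate choice does not limit comparability.  The
test suite runs thinned versions of the same protocols.  All
randomness flows from explicit seeds through numpy `SeedSequence`
spawning, so every simulation, test and script run is bit-reproducible.
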