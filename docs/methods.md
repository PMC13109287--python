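# Methods

`cirfeat` measures three kinds of complementarity between residues on two
protein surfaces — shape, electrostatic, and hydropathy — feeds them to a
compact convolutional classifier that scores putative *core interacting
residue* pairs, and then asks which of the features actually carry the
predictive information.  Because the PDB-derived datasets such analyses are
usually run on cannot be shipped, the package includes a synthetic-complex
generator whose planted structure is known exactly; every analysis stage is
validated against that ground truth.

## Surfaces, interfaces and residue pairs

A chain is a solvent-accessible surface point cloud: positions (Å), outward
unit normals, a per-point electrostatic potential, and residue provenance.
Producing such clouds from atomic structures (molecular-surface sampling at
~5 points/Å², Poisson–Boltzmann electrostatics) is upstream of this package;
the I/O layer defines the expected columnar format and validates it.

* **Binding site**: the points of one chain strictly within 6 Å of the
  partner surface.  Its **center** is the centroid of the union of the two
  chains' interfacial points.  (Strict `<` is used for every distance rule,
  so the 6 Å interface, 3 Å pair, and 5 Å center cutoffs are mutually
  consistent.)
* **Residue representative**: the centroid of the surface points the residue
  generates.  This representative is used for core-pair detection, neighbor
  selection and annular composition alike.
* **Core interacting pair**: a cross-chain residue pair with centroids
  < 3 Å apart, both < 5 Å from the interface center.  Water-mediated
  contacts are not modelled.
* **Decoy**: residues generating no interfacial surface points, drawn
  uniformly and cross-paired at random.
* **Annular composition**: residues binned into 1 Å rings of distance from
  the interface center (default out to 20 Å), with per-ring frequencies of
  the hydrophobic (H), polar (P) and charged (C) classes.  The class
  partition is: H = GLY ALA VAL LEU ILE MET PHE TYR TRP; P = SER PRO THR CYS
  ASN GLN; C = HIS LYS ARG ASP GLU.

## Patches, projections and 2D Zernike descriptors

A **patch** is the set of surface points inside a 9 Å sphere centred on a
surface point (a patch with fewer than 10 points is rejected).  The patch is
re-oriented so that its least-squares plane normal is the z-axis, with the
solvent-exposed side (mean outward normal) toward +z and the centroid at the
origin.  An apex **C** is placed on the z-axis at the minimal height at
which every secant from C to a patch point makes at most 45° with the axis;
each point is labelled with its distance *r* to C, projected to the x-y
plane, rescaled by the maximal planar radius so the patch rim touches the
unit circle, and binned onto a 25×25 pixel grid.  Pixel values are the mean
*r* (shape image) or mean potential (electrostatic image) of the points in
the pixel; empty pixels, and pixels whose centre falls outside the unit
circle, are masked.

The disk image f(r, ψ) is expanded in the 2D Zernike basis
Z_nm(r, ψ) = R_nm(r) e^{imψ} with the standard radial polynomial

    R_nm(r) = Σ_k (−1)^k (n−k)! / [k! ((n+m)/2 − k)! ((n−m)/2 − k)!] r^{n−2k},

and coefficients c_nm = (n+1)/π ∫∫ Z*_nm f r dr dψ.  The **descriptor** is
the vector of norms |c_nm| for 0 ≤ m ≤ n ≤ 20 with n − m even (121 values),
invariant under rotations about the disk centre.  **Complementarity** between
two patches is the Euclidean distance between their descriptors, computed
with the two patches oriented with opposite z-verses (one solvent side up,
one down); smaller distance = more complementary, and an exactly mirrored
surface scores ≈ 0 by construction.

Numerical choices that matter:

* **Quadrature.**  Coefficients are integrated on a polar grid of 64
  Gauss–Legendre radial nodes × 128 uniform angles.  This integrates the
  basis polynomials themselves exactly (degree ≤ 21 ≪ 127) and is
  spectrally accurate in the angle, so orthogonality and rotation-invariance
  hold to quadrature precision; the piecewise-constant pixel image is
  sampled at the polar nodes (masked pixels contribute zero).  An analytic
  path (`zernike_moments_fn`) accepts a function f(r, ψ) directly for
  convergence and invariance studies.
* **Mean-centring.**  Images are mean-centred over their occupied pixels
  before expansion, so the arbitrary apex offset (shape) or potential
  baseline does not dominate c_00.
* **Canonical in-plane frame.**  Descriptors are rotation-invariant in the
  continuum but pixel binning is not; the oriented patch is therefore
  rotated in-plane so its planar principal axis lies along +x (axis sign
  fixed by the third moment of the projections).  Under this convention a
  mirrored patch lands in the exactly y-mirrored frame and produces a
  bitwise-mirrored image, making self-complementarity exact rather than
  approximate.
* **Sign-blindness.**  Descriptor norms are unchanged when an image is
  negated, so anti-correlated electrostatic patches (plus facing minus)
  score as complementary — which is the desired convention — but the same
  property means shape *anti*-correlation is also read as complementarity.
  The generator avoids planting such artefacts (see below).

## Hydropathy complementarity

Each residue has a hydrophobicity index H ≥ 0 (hydrophobic residues near 0,
charged ones high).  The pair score is the parabola in the index product

    H_r = −a (H_A H_B)² + b (H_A H_B),   a = 0.033, b = 0.363,

whose roots sit at the minimum (0) and maximum (b/a = 11) index products and
whose maximum is b²/4a = 0.99825 ≈ 1 at product b/2a = 5.5.  H_r near zero
means matched hydropathy character (both hydrophobic, or both strongly
hydrophilic); H_r near 1 means a mismatched pair.  The MD-derived
per-residue index values behind the published scale are not public, so the
package ships a clearly-labelled **synthetic surrogate scale**
(`data/hydrophobicity_surrogate.csv`): class-ordered values with the maximum
product placed exactly at the upper root.  Any user scale can be supplied as
a two-column CSV.

## Per-pair feature matrices

For a putative pair (A, B), the partner's neighborhood is the residue B
itself plus its nine nearest residues by centroid distance within 10 Å
(ties broken by residue number; missing neighbors padded).  Column *j* of
the 3×10 matrix holds the shape, electrostatic and hydropathy
complementarities between A and the *j*-th neighborhood entry.  Shape and
electrostatic values are means of descriptor distances over patch pairs
drawn from the two residues' surface points; by default at most 2 evenly
spaced points per residue (≤ 4 patch pairs) are used, with an exact
all-pairs mode available.  Descriptors are cached per (point, kind,
orientation), which is what makes dataset-scale feature building cheap.

Some figures in the source literature depict a 4×10 input; the fourth row's
content is not defined anywhere, and the information analyses consistently
speak of thirty features.  The package therefore uses 3×10 throughout.

Normalisation is per-feature-row min–max to [0, 1], with statistics fitted
on the training split only, persisted for inference, out-of-range test
values clipped (and counted), and padded neighbor columns filled with the
worst-complementarity value 1.0 (an absent neighbor must not look
complementary).

## Classifier

Two convolutional layers (16 and 32 filters, 3×3, 'same' zero padding,
ReLU), dropout 0.25, flatten, a 64-unit dense layer and a sigmoid output.
Training uses Adam (1e-3), binary cross-entropy, batch 64, at most 200
epochs with early stopping (patience 20) on validation loss, restoring the
best weights.  The published architecture leaves filter counts, dropout
rate and optimiser unstated; these defaults are sized for a 3×10 input and
are all exposed in `ClassifierConfig`.  The implementation is pure numpy
(im2col convolutions with hand-derived backprop): at this input size a
framework would add dependency weight without speed, and a fixed seed with
single-threaded execution gives bit-stable training on one platform
(cross-platform runs are statistically, not bitwise, reproducible).

The decision cut-off on the network score defaults to 0.38.

## Information analyses

* **Mutual information** (base-2) between a feature and a binary label uses
  the plug-in estimator on equal-frequency bins, ⌈√(n/5)⌉ bins capped at 32.
  Against a balanced binary target the estimate is ≤ 1 bit, and 1 bit means
  a fully informative feature; the estimator is validated against closed
  forms (identity, independence, 10% noise channel → 1 − H(0.1) ≈ 0.531
  bits).  MI against the network is computed on predictions binarised at the
  0.38 cut-off (a continuous-score option exists).
* **Stratified ROC AUC** between two groups of complementarity values uses
  the convention that *smaller* distance scores as positive.
* **Ablation**: for every non-empty subset of {shape, electrostatic,
  hydropathy} rows, the classifier is retrained per repetition on a fresh
  70/15/15 split; the decision threshold is the validation-accuracy
  maximiser (grid step 0.01) and the test accuracy is recorded.  The
  package default is 10 repetitions (the analysis is stable at that size
  and it keeps a full run in minutes; the repetition count is a config
  field).
* **PCA** standardises the 30 features to zero mean and unit variance and
  reports eigenvalues, explained-variance ratios EVR_i = λ_i/Σλ_j,
  cumulative EVR and loadings.  The scree "elbow" is operationalised as the
  position of the largest consecutive eigenvalue drop, capped at 10
  components.
* **Residue-class thresholds**: per chemical pair class (HH, HP, HC, PP,
  PC, CC), a grid search (step 0.01, F1 ties resolved toward the lower,
  more sensitive threshold) finds the class-specific cut-off; the report
  compares class F1 under the universal and class-specific schemes and the
  two global confusion matrices, expressed as fractions of all pairs
  (the four cells sum to 1).

## The synthetic benchmark

Each complex is built from smooth random height fields (sums of 18 seeded
Gaussian bumps, amplitude ≤ 0.8 Å, widths 2.5–4.5 Å):

* **Interface disks** (radius 20 Å, one per chain, each sampled on its own
  jittered 0.5 Å lattice ≈ 4 points/Å², close to the sampling density the
  descriptor protocol was designed for): chain A carries h_A; chain B
  carries the mirror `gap − h_mix` at a 2.5 Å gap, where
  h_mix = η_s·h_A + (1−η_s)·h' mixes the mirror with an independent field,
  plus 0.2 Å vertical jitter per chain.  η_s ∈ [0, 1] is the planted shape
  fidelity: η_s = 1 with zero noise reproduces a patch's exact mirror,
  η_s = 0 removes the signal entirely.
* **Electrostatics**: interfacial B potentials are
  −ρ_el·φ_A + √(1−ρ_el²)·φ′, so matched interfacial points have correlation
  −ρ_el; non-interfacial potentials are independent.
* **Far disks** (one per chain, laterally offset 48 Å — far beyond the 6 Å
  interface rule) provide the non-interacting surface for decoys.
* **Residues**: Voronoi tilings of ~64 points (~16 Å² at this density); the
  two interface disks share one Voronoi seed set so residues face each
  other across the interface, which is what gives core pairs their matched
  patches.  Chemical classes are sampled from a distance profile —
  hydrophobic-enriched core (p_H = 0.70 at the center, decaying 0.012/Å),
  charged-enriched rim (p_C = 0.07 + 0.013/Å), blending to the uniform
  composition of the remote surface beyond 20–25 Å.  The composition
  profile is what plants the hydropathy signal.

Defaults (60 complexes, η_s = 0.6, ρ_el = 0.6, the profile above) are
calibrated so the three direct complementarities separate core pairs from
decoys with ROC AUCs near the values reported for real complexes — shape
≈ 0.8, hydropathy ≈ 0.7, electrostatics ≈ 0.65 — i.e. strong shape and
hydropathy information and a weaker electrostatic contribution.  Labels are
produced by running the interface/core-pair detection itself on the emitted
clouds, so pair tables are consistent with the geometry by construction,
and the decoy count matches the core count per complex.

Two generator details exist specifically to keep the benchmark unbiased:

* **No minimum-separation rejection by default.**  Rejecting geometries
  whose surfaces come too close conditions the accepted field pair on
  mutual avoidance, i.e. induces |correlation| between them — and the
  sign-blind descriptor reads that as shape complementarity even at
  η_s = 0.  Occasional surface crossings are statistically harmless here,
  so the check is off unless requested.
* **Interior decoy zone.**  Decoy residues are restricted to within 8 Å of
  the far-disk centre so their patches, like core-pair patches, never graze
  the boundary of the finitely sampled disk.  Edge-clipped patches are an
  artefact of sampling a finite sheet (real molecular surfaces are closed)
  and systematically inflate decoy distances, which would fake a shape
  signal.

With η_s = 0 the shape-distance AUC between core pairs and decoys is
0.5 ± 0.05 (n ≥ 500), and the measured interfacial potential correlation is
within ±0.1 of −ρ_el — both are regression-tested.

**What passing on this benchmark does and does not show.**  The generator
reproduces the *statistical* structure the analyses assume — mirrored-patch
geometry with tunable fidelity, sign-complementary potentials, a
hydrophobic-core/charged-rim composition and balanced decoys — but not
physical reality: surfaces are open sheets rather than closed molecular
surfaces, electrostatics is a random field rather than a Poisson–Boltzmann
solution, there is no atomic geometry, side-chain packing or solvent model,
and the hydrophobicity indices are surrogates.  Results on it validate the
machinery (descriptors, estimators, training, threshold logic), not
biological performance; the published dataset-specific numbers (e.g. test
ROC AUC 0.86 on 905 dimers) are properties of non-shipped PDB-derived data
and are out of scope here.

## Degenerate inputs and edge cases

Patches with < 10 points, collinear point sets, and all-on-axis projections
raise typed errors; residues without surface points are excluded from pair
building; empty interfaces are flagged results rather than exceptions;
constant features return MI = 0 with a warning; zero-range normalisation
rows map to 0 with a warning; pair classes missing a label fall back to the
universal threshold.  All stochastic stages derive their seeds from one
master seed recorded in the run manifest.

## Problem sizes

The package defaults — 60 complexes (~560 labeled pairs, ~10,000 surface
points per chain), ≤ 4 patch pairs per residue pair, 10 ablation
repetitions — run the full generate → features → train → analyze chain in
a few minutes on one CPU core.  All of these are configuration fields, and
the exact all-pairs feature mode and 100-repetition ablation are available
where more precision is wanted.
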