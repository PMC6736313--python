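# Methods

This note documents the models implemented in `memlipo`, the defaults
chosen where the published description leaves the design open, and
what the synthetic test data do and do not establish.

## Insertion profiles and their processing

An insertion profile is the apparent transfer free energy
ΔΔG(Ala→aa) of one amino acid as a function of signed membrane depth
z, measured relative to alanine (whose profile is identically zero by
construction).  Raw profiles are expected in kcal/mol on a 27-position
grid, which is mapped linearly onto depths −20…+20 Å (spacing
40/26 ≈ 1.54 Å); the processed grid always has exactly these 27 knots.

Processing order is fixed: **smooth → symmetrise → special cases →
unit conversion → spline**.

* *Smoothing.* A centred moving average, default window 3, shrinking
  at the endpoints.  The exact smoother used on the original data is
  not specified upstream; the moving average is the simplest operator
  consistent with "smoothed", and the window is exposed as a
  parameter.
* *Symmetrisation.* E(z) and E(−z) are averaged for every amino acid
  except Arg, His and Lys, whose insertion energetics are genuinely
  leaflet-dependent (positive-inside rule).  The operation is
  idempotent and requires a symmetric depth grid.
* *Special cases.* His is capped at 2.3 kcal/mol on depths in
  [0, 20] Å (the maximal experimentally observed value); because His
  is exempt from symmetrisation, the cap is applied after the
  symmetrisation stage, which only matters for the order of the two
  no-ops on the inner leaflet.  Cys, rare in membranes and Ser-like in
  polarity, receives a copy of the Ser profile.  Asp/Glu/Gln/Asn were
  sparsely sampled in the underlying experiment; each is flattened to
  its mean energy over the membrane core (|z| ≤ 10 Å) across the whole
  span.  These rules quote kcal/mol values, so they precede unit
  conversion.
* *Unit conversion.* kcal/mol × 2.94 → Rosetta energy units (R.e.u.).
  Converting twice is a state error.
* *Splines.* Natural cubic splines through all 27 knots, continuous
  with continuous first derivative.  Outside ±20 Å the spline is
  clamped to the boundary knot value rather than extrapolated: the
  profiles are only defined within the membrane window, and outside it
  the base water solvation should dominate.  Pro perturbs the backbone
  rather than solvating differently and carries an all-zero profile,
  as does the Ala reference.

## Burial weight

Burial is the product of two logistic functions of the heavy-atom
neighbour counts within 6 and 12 Å of the residue's Cβ (virtual Cβ for
Gly, built from ideal tetrahedral geometry: bond 1.53 Å, angle
N-CA-CB 110.1°, torsion C-N-CA-CB −122.6°).  Counts exclude the
residue's own atoms — burial measures packing against *other* protein
segments — along with hydrogens, waters and hetero-compounds.  The
second logistic factor is a function of N12 with offset O12 (the
printed form of the second factor is garbled in the source
description; a neighbour-count sigmoid is the only reading that
yields a burial measure).  Counts may be real-valued so that
centroid-level pseudo-counts remain differentiable.

## Energy terms

* *Lipophilicity*: `w · spline_aa(z)`, evaluated at the Cα depth.
  Depth is measured at Cα because it exists for every residue and
  indexes position along the span; Cβ is reserved for burial.
* *Solvation mix*: `w · spline_aa(z) + (1 − w) · base(residue)`.  The
  base water-solvation term is a pluggable per-residue callable and
  defaults to 0 (pure-profile mode); any external scorer can be
  injected.
* *Helicality*: `((φ−φc)² + (ψ−ψc)²)²/c⁴ · 1/(1+(z/h)⁴) · w` with
  centre (φc, ψc) = (−60°, −45°), curvature c = 25° and depth
  half-width h = 10 Å.  The centre follows the equation's explicit
  (φ+60), (ψ+45) offsets; the accompanying prose cites (+60°, +45°),
  which lies outside the α-helical Ramachandran region and is taken
  to be a sign typo.  The depth gate is oriented so the penalty is
  maximal at the midplane and decays outside the membrane, matching
  the stated intent (strong helicality constraints in the lipid-facing
  membrane core, attenuation outside); the typeset fraction is
  ambiguous between this and its reciprocal.  Residues with undefined
  dihedrals (termini, chain breaks) contribute zero and are flagged.
* *Span tilt*: the shipped runtime penalty is the printed cubic
  (1.51·10⁻⁴, −8.925·10⁻³, 0.187, −0.532), strictly increasing on
  [0, 60]°, applied per helical span (per-residue application in
  centroid sampling is a possible alternative; per-span is used here).
  Span segments are detected as contiguous runs of ≥ 6 residues with
  |z| ≤ 20 Å, or supplied explicitly.  Helix axes are the principal
  component of the Cα cloud, oriented N→C — robust for the 15–30
  residue spans this targets — and tilt is folded into [0, 90]°.

## Tilt-angle statistics

The derivation pipeline behind the cubic is reproducible for new
angle data: (1) histogram the observed tilt angles (5° bins on
[0, 90]°) and fit a quadratic; (2) convert observed and expected
(sin θ) distributions to energies by inverse Boltzmann and subtract,
`penalty = −(ln f − ln sin θ)`; (3) fit a cubic to that penalty on a
1° grid over [5, 45]° (configurable), the range on which both
densities are strictly positive.  Histogram heights default to
per-bin fractions, the scale on which the shipped quadratic density
was expressed; a unit-area per-degree normalisation is available.
Bins are fitted by weighted least squares with inverse-Poisson-σ
weights (1/√p), the chi-square weighting for multinomial counts,
which keeps the relative fit tight in sparsely populated bins.
Probability densities are defined up to normalisation and energies up
to an additive constant, so `derive_penalty` offers a scale-matched
mode that normalises both densities over the evaluation grid before
taking logs; in that gauge, identical observed and expected
distributions give a penalty of identically zero.  Binning, fit range
and normalisation for the original data are unreported, so the
printed quadratic and cubic coefficients are shipped as constants
rather than re-derived; exact coefficient recovery is not promised,
only functional agreement between cubic and log-ratio penalty.

## Calibration loop

The iterative loop encodes target profiles against an arbitrary base
scorer: each iteration computes ΔΔG(aa, z) = correction + base(aa, z,
correction) on a poly-Ala helix scan and adds the residual
(target − computed) to the correction, stopping at a tolerance
(default 0.01 R.e.u., a choice of this package) or after a maximum of
10 iterations — both stopping rules are implemented because the
original criterion is unstated.  The Ala correction is pinned at 0.
The update step is a full residual step; a damping factor is exposed
for noisy scorers.  With a base scorer whose response to the
correction is the identity, one update suffices; an under-responsive
linear scorer converges geometrically with ratio (1 − response);
bounded scorer noise ε bounds the final residual by ε.  The real
all-atom relax-and-rescore machinery is out of scope and is
represented by the scorer contract plus two shipped toys (zero, and a
smooth hydrophobicity-bell base).

## Model selection

* Filters are explicit column thresholds; metrics only an external
  all-atom scorer can provide (SASA, shape complementarity, binding
  ΔΔG, rotameric strain) are consumed as free columns, and a
  threshold on an absent column is an error unless explicitly
  skipped.  Filter-then-top-fraction is the default pipeline order;
  both orders are composable since the two operations are plain table
  transforms.
* Top-fraction selection keeps ⌈f·n⌉ lowest-energy rows, retaining
  boundary ties.
* Score-wise clustering: the lowest-energy unclustered model seeds a
  cluster and absorbs all unclustered models within the RMSD cutoff
  (default 4 Å); repeat up to `max_clusters` (default 5).
* RMSD is minimal-superposition (Kabsch); for homodimers both chain
  mappings are tried and the minimum reported, since chain identity is
  arbitrary.  Multi-model NMR references use the first model.
* Native contacts are inter-chain residue pairs with Cβ–Cβ distance
  (virtual Cβ for Gly; Cα optional) below 8 Å in the reference.  A
  reference with zero inter-chain contacts has an undefined fraction
  and is reported as such, never silently 0.
* ΔΔG classification takes the per-mutation median over surviving
  models (minus the wild-type median when supplied); medians above the
  threshold (default 0) are destabilising, the boundary counts as
  stabilising, and mutations with no surviving models are excluded
  from the confusion counts.

## Synthetic data

The fixtures module generates every input the tests need.

* *Helices* are built from ideal internal coordinates (NeRF chain
  with Engh–Huber-like bonds/angles, ω = 180°), so requested (φ, ψ)
  are reproduced exactly up to PDB coordinate precision, then rigidly
  placed at a requested tilt and centre depth.  Cβ atoms come from a
  fixed linear combination of backbone vectors, deliberately a
  different construction from the internal-coordinate virtual Cβ so
  the two routes cross-check each other.
* *Raw profiles* are smooth bell curves (amplitude = membrane-core
  transfer energy, width ~12 Å) plus a tanh(z/7) leaflet-asymmetry
  term for Arg/Lys/His and Gaussian noise (σ = 0.08 kcal/mol).
  Amplitudes are anchored to the experimentally motivated values: +2
  kcal/mol for Gly at the midplane, −2 for Leu/Ile/Phe, a 2 kcal/mol
  inner-leaflet preference for Arg/Lys, and a His curve exceeding the
  2.3 kcal/mol cap on the outer half-membrane so the cap is
  exercised.  They emulate the shape and scale of the real curves,
  not the count-level noise of the deep-sequencing assay — so passing
  tests demonstrate the correctness of the processing machinery, not
  the biological accuracy of any particular profile set.  Real tables
  drop in through the same CSV interface.
* *Decoy ensembles* apply fixed rigid-body displacements ("modes") to
  one chain of a dimer plus a small random wobble, with mode index
  tied to energy, so clustering ground truth is known by
  construction.
* *Tilt samples* are drawn exactly (inverse transform) for the sin
  density and by rejection for the quadratic or custom densities.
  All generators are deterministic given their seed.

## Numerical choices and problem sizes

Natural (zero second derivative) boundary conditions for splines;
clamped evaluation outside the knot span; logistic factors evaluated
via `expit` to avoid overflow; dihedrals via the atan2 torsion
formula with the standard sign convention (verified against an
independent library implementation); helix axes via SVD with N→C
orientation disambiguation.  Stochastic checks use 50,000 angles for
the quadratic-density round-trip and 200,000 for the sin null check,
30-model ensembles for clustering ground truth, and 100 random ≤8
model instances for the clustering-rule oracle — sizes at which the
checked statistics are stable while the whole suite runs in seconds.

## Limitations

* The surrounding all-atom energy function is not reimplemented;
  absolute totals are meaningful only in pure-profile mode or with a
  user-supplied base solvation callable.
* Atomic-level solvation and depth-dependent dielectric screening are
  not modelled; the lipophilicity term averages over side-chain
  atoms.
* Profiles derive from single-span bacterial inner-membrane
  measurements; outer-membrane proteins and unusual lipid
  compositions are out of distribution.
* Membrane placement is taken from the input frame (pre-oriented
  structures); no automatic span prediction is performed.
* The helix-axis principal component is unreliable for strongly kinked
  spans shorter than ~6 residues, which are rejected.
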