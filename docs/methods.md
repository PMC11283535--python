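# Methods

This note records the models implemented by `allomorph`, the conventions
and defaults that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Interdomain motion model

βPGM-style enzymes consist of a cap domain (default residues 16–87,
author numbering) and a core domain (1–15 and 88–221) that close over
the active site.  The motion analysis treats both domains as rigid
bodies and describes their relative orientation in each structure
against a single reference.

**Canonical frame.**  The reference structure is rigidly moved so that
the centroid of its cap Cα atoms is at the origin and the principal
axes of the cap Cα positional covariance lie along +x, +y, +z in order
of decreasing variance.  Eigenvector signs are intrinsically ambiguous;
they are fixed deterministically by orienting each axis to have positive
projection onto the core-centroid → cap-centroid vector (falling back to
the file-frame axis of matching rank when that projection is
negligible), then forcing det = +1 by flipping the third axis if
necessary.  The canonicalisation is idempotent and invariant under the
input pose to numerical precision.

**Interdomain rotation.**  Each structure is least-squares superposed on
the canonical reference twice, using the Cα atoms shared between the two
models inside each domain: once on the cap, once on the core.  Cα-only
superposition was chosen because the cap frame itself is defined on Cα
positions and because Cα sets are robust to the sidechain differences
between point variants (D10N, P146A); all-atom RMSD overlays are
computed separately on shared non-H protein atoms.  If T_cap and T_core
are the two superpositions, the interdomain transform is
T_core ∘ T_cap⁻¹ — the map from the cap-aligned pose to the core-aligned
pose, expressed in the canonical frame.

**Euler decomposition.**  The rotation is decomposed with the intrinsic
Tait–Bryan sequence roll → pitch → yaw about the x/y/z axes of the
canonical cap frame (tag `"XYZ"`; R = Rx(roll)·Ry(pitch)·Rz(yaw)).
Since the largest-variance cap axis is x, roll is rotation about the cap's
long axis (twisting), pitch about the second axis (closing) and yaw
about the third (lateral).  The sequence itself is a package convention:
the angle names fix which axis each angle belongs to, but not the
application order, and the tag is stored with every result so other
intrinsic sequences remain selectable (they are delegated to
scipy.spatial.transform).  Near gimbal lock (|pitch| within 1e-6° of
90°) roll and yaw are not separable; roll is set to zero, yaw absorbs
the free angle and a warning is raised.  Angles are reported in degrees.

**Hinge angle.**  The interdomain hinge-closure angle is reported as the
total rotation magnitude θ = arccos((tr R − 1)/2), computed in the
numerically stable atan2 form.  This is a surrogate for hinge-detection
programs (e.g. DynDom), which locate a physical hinge axis by clustering
rotation vectors; under fixed domain definitions the magnitudes agree,
but no hinge-axis position is computed here.

**Superposition.**  Kabsch SVD with the determinant correction, so
reflections are never returned; collinear point sets are rejected as
degenerate.  The independent cross-check in the tests is a quaternion
eigenvalue (Horn) implementation; the two agree to ≤1e-9 on random
instances.

**Conformer classes.**  Classification is by nearest labelled centroid
in (pitch, roll, yaw) space with a cutoff (default 8°) beyond which a
structure is `unassigned`; exact ties break alphabetically and are
logged.  No numeric class boundaries are hard-coded: centroids are meant
to be computed from a user's reference structure set.  Geometric
classification reports NAC III without the twisted/untwisted
distinction, which rests mainly on NMR evidence (the I84 sub-rule
below) unless separate NAC IIIᵗ centroids are supplied.

## Solution-NMR analysis

**Weighted CSP.**  Δδ = [(Δδ_HN)² + (0.13·Δδ_N)²]^½ per residue shared
between two species tables.  Residues absent from either table are
absent from the profile (not zero).  The 0.13 nitrogen weight
compensates for the larger ¹⁵N shift range; the same metric is reused as
the 2-D distance for reporter classification so one weighting governs
both analyses.

**Reporter classification.**  Per reporter, the query's (δ_HN, δ_N) is
assigned to the nearest labelled library cluster; the overall call
requires agreement of all in-range reporters and otherwise returns
`ambiguous` (cutoff default 0.25 ppm, roughly half the smallest useful
reporter separation).  Library points that carry only one dimension
constrain only that dimension.  Specific rules:

- *Isomer state* (A143, D180): cis vs trans of the K145-X146 peptide
  bond.
- *Closure state* (I84, S88): open / NAC I / NAC III / NAC IIIᵗ /
  closed.  Within the NAC III family the I84 ¹HN sub-rule separates
  NAC III (≈7.00 ppm) from NAC IIIᵗ (≈7.17 ppm) at the midpoint
  boundary 7.085 ppm (configurable).
- *Proline isomer*: P146 ¹³Cβ within ±1.0 ppm of 35.0 → cis; within
  ±1.0 ppm of 32.0 (the canonical trans-proline value, configurable) →
  trans; otherwise ambiguous.
- *MgT occupancy*: the A115 ¹HN displacement δ(reference) − δ(query);
  bound when the upfield displacement exceeds half the 1.6 ppm library
  displacement (threshold 0.8 ppm).

The bundled library ships only coordinates that are published (the I84
7.00/7.17 ppm values and the P146 Cβ references); every other cluster
must be supplied by the user from assigned spectra — unpublished
coordinates are never invented.  The test suite uses a clearly labelled
synthetic stand-in library with complete 2-D clusters.

**Correlation matching.**  Pearson r is computed separately over shared
residues' ¹HN and ¹⁵N shifts; candidates are ranked by the conservative
min(r_H, r_N).  The Fisher transform z_r = atanh(r) with sampling
variance 1/(n−3) gives the two-sample statistic
z = (z_r1 − z_r2)/√(1/(n1−3) + 1/(n2−3)); each ranked candidate is
tested against the top-ranked one (which has z = 0, p = 1 by
construction).  |r| = 1 is rejected (infinite transform), as is n ≤ 3.

**Populations and K_d.**  For species in slow exchange, per-residue
intensity fractions I_s/ΣI are averaged over rows where every species is
observed (default minimum 20 rows), with the across-residue SD as the
dispersion; the mean (not median) keeps the fractions summing exactly
to one.  The estimate is invariant under any global intensity scale.
The two-state K_d = L_total·p_free/p_bound uses the excess-ligand
approximation (free ≈ total ligand), appropriate at ~5–50 mM ligand
against ~0.5 mM protein where depletion is ≤10 %; supplying the protein
concentration switches to the exact mass-balance correction
L_free = L_total − p_bound·P_total.  Summary output rounds to one
significant figure (e.g. "~2 mM"); machine output keeps full precision.

## Synthetic-data generators

The generators emulate the *shape* of the study data, not its content:

- **Structures.**  Each domain is a compact antiparallel bundle of ideal
  α-helical Cα segments (rise 1.5 Å, radius 2.3 Å, 100°/residue),
  numbered to the βPGM ranges so the domain defaults apply unchanged.
  A single straight helix would have two equal transverse variances,
  leaving the principal frame degenerate and the rotation about the long
  axis poorly determined under coordinate noise; the bundle layout uses
  deliberately unequal grid spacings (24 × 18 Å — looser than real
  helix packing) so all three variances are well separated and the
  domain superpositions are well conditioned.  The cap is rotated by
  exactly rotation_from_euler(angles) about the hinge Cα (the last core
  residue preceding the cap; the choice is arbitrary since only
  rotations are compared), then isotropic Gaussian noise is added to
  every atom.  These are not protein folds: no sidechains, no packing,
  no secondary-structure connectivity between segments.
- **Shift tables.**  Reporter residues take their library cluster
  coordinates for the requested states; all other residues share a
  random per-residue baseline across species (¹HN ~ N(8.3, 0.45),
  ¹⁵N ~ N(119, 4) ppm), so cross-species correlations are high except
  where states differ.  Gaussian noise is per species.  Real spectra add
  peak overlap, exchange broadening and assignment errors that are not
  modelled.
- **Intensities.**  intensity = base(residue)·population·exp(ε) with
  ε ~ N(0, σ) — log-normal multiplicative noise, a modelling choice;
  real TROSY intensities also vary with relaxation and exchange.

All generators are pure functions of parameters + seed and are
bit-reproducible.  Consequently, passing recovery tests demonstrate the
correctness and numerical behaviour of the estimators under these noise
models, not their robustness to the full complexity of experimental
data.

## Numerical choices and problem sizes

- Rotation validation tolerance 1e-8 (orthonormality, det +1);
  Euler round-trip holds to 1e-9 away from gimbal lock.
- PDB coordinates carry three decimals; file round trips are exact to
  0.0005 Å.  Residue numbers above 9999 are rejected on write.
- Altlocs: blank or 'A' kept, alternates dropped with a log message.
  HETATM records (ligands, ions, waters) are excluded from all
  selections and RMSD overlays by default, with an opt-in flag; the
  overlays are documented as protein-only.
- Recovery suites run at the study-like sizes: 72 + 149 residues per
  structure over a 36-point angle grid, 60-residue intensity tables with
  10 % noise over 100 replicates, 100 random superposition instances.
  The full test suite completes in well under a minute.

## Known limitations

- No hinge-axis localisation or automatic domain detection; domains are
  user-defined residue ranges.
- Geometric NAC III vs NAC IIIᵗ separation needs user-supplied
  per-class centroids; by default the distinction comes from the I84
  sub-rule only.
- The bundled reporter library is intentionally partial (published
  values only) — classification against real spectra requires the
  user's own assigned library.
- mmCIF is read-only; multi-model files use the first model.
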