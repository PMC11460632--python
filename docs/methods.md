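# Methods

This note documents the models implemented in `hyalodyn`, their
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Torsion dynamic model

The solution behaviour of a flexible oligosaccharide terminus is described
per rotatable bond.  A torsion is either *unimodal* — it librates about a
single mean (μ ± σ, degrees, IUPAC sign, wrapped to (−180, 180]) — or a
member of a *codependent group*: several torsions that switch state
together.  A group carries a small number of joint modes; each mode
assigns one (μ, σ) per torsion and has an occupancy π, with Σπ = 1.  For
the 2AA-modified reducing terminus the three backbone torsions of the
opened GlcNAc ring (C2-C3, C1-C2, and the C1-aniline bond) populate five
joint modes with occupancies (0.35, 0.35, 0.22, 0.06, 0.02) and libration
widths of 20.0° (C2-C3), 4.7° (C1-C2) and 4.4° (C1-NH).

Librations are sampled as wrapped normals (a plain normal draw wrapped
into (−180, 180]); for σ ≤ 20° this is indistinguishable from a von Mises
distribution, and only mean-plus-width information is available anyway.
Population sums are validated to 1e−9 after load; sums within 1e−6 of 1
(two-decimal printed occupancies) are renormalized silently, larger
deviations are an input error.

The canonical model file format is JSON (codependent groups are nested and
need structure); a flat CSV dialect is accepted for unimodal-only lists.

## Conformer construction

Conformers are built from internal coordinates by sequential NeRF
placement: the first atom at the origin, the second along +x, the third in
the xy-plane, and every later atom from (bond length, bond angle, signed
dihedral) against three placed references.  Dihedral slots are either
fixed values (rigid geometry) or named torsions, optionally with a
constant offset (so geminal hydrogens track their heavy-atom torsion).
Build→measure round-trips are exact to ≪1e−4°, which the test suite
asserts over random draws.

Ring interiors are rigid: closed pyranoses are approximated as chair-like
bodies with fixed ±55° internal dihedrals, and only the listed rotatable
bonds vary.  The shipped topology templates (`ha4_an`, `ha6_an`,
`ha4_2aa`, `ha6_2aa`) use idealized carbohydrate geometry (C-C 1.53 Å,
C-O 1.43 Å, aromatic C-C 1.39 Å, sp³ 109.47°, sp² 120°) and are
deliberately coarse for the anchor residues: anchors are held bitwise
fixed across an ensemble, so only their role as a rigid superposition
frame matters.  The glycosidic anchor values of the bound conformation are
not published as numbers; the fixtures use documented placeholder values
(φ = −75°, ψ = 120°), and real anchor coordinates can be supplied through
the pocket's anchor reference instead.  Within these templates the 2AA
geometry reproduces the expected internal hydrogen bond from the aniline
N-H to the ortho-carboxylate oxygen (H···O ≈ 1.7 Å in the built
geometry), consistent with the small temperature coefficient
(−2.6 ppb/K) that motivates carrying that bond as an annotation.

One `numpy` generator per ensemble, draw order conformer-major then
groups-then-unimodal in model order, makes ensembles bit-reproducible from
one integer seed.  The default production ensemble size is 250 conformers,
the size used for the docking analysis.

## NMR observables and restraint handling

* NOE effective distances: r_eff = (Σ wᵢ rᵢ⁻⁶)^(−1/6) with uniform
  conformer weights by default (a sampled ensemble already realizes the
  mode occupancies).  NOEs are satisfied when r_eff ≤ upper bound, noNOEs
  when r_eff ≥ lower bound.
* Scalar couplings: Karplus J(θ) = A cos²θ + B cosθ + C, averaged linearly
  over conformers (fast exchange).  Default coefficients
  (A, B, C) = (9.5, −1.6, 1.8) Hz, a standard HCCH parameterization;
  configurable because no coefficients are printed in the source analyses.
* Temperature coefficients are provenance annotations only — no forward
  model exists for them here.
* Hydrogen-bond records are validated geometrically (donor-acceptor
  ≤ 3.5 Å and donor-H···acceptor angle ≥ 120°, in at least the weighted
  majority of conformers); the experiment infers the bond thermodynamically,
  so a standard geometric criterion is adopted for ensemble validation.

### Occupancy recovery

`fit_mode_populations` inverts population-sensitive observables.  Because
both ⟨r⁻⁶⟩ and ⟨J⟩ are linear in π, per-mode conditional ensembles (64
conformers per mode, fixed seed, shared between the restraint simulator
and the fitter) turn prediction into a matrix product, and the objective —
squared ³J deviations scaled by their tolerances plus squared hinge
violations of distance bounds scaled by 0.1 Å — is convex in π.  The fit
enumerates the probability simplex at the requested resolution (0.01 for a
five-mode group); above ~600k grid points it switches to an exact
coarse-to-fine scheme (full 0.05 pass, then bounded local enumeration at
the requested resolution), which convexity makes equivalent to full
enumeration.  Ties are broken toward the uniform distribution.  The
tolerance scaling matters: an unweighted objective lets 0.5 Hz coupling
noise swamp the Å-scale distance information and degrades recovery several
fold.

## Docking

The protocol is rigid-body only, matching an ensemble-docking workflow for
a dynamic ligand: conformers are superposed into the groove by
least-squares proper rotation (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) on the anchor residues,
then scored in place.  Score components, in arbitrary energy units
(only orderings and groupings are meaningful):

* **Hydrogen bonding** — per donor/acceptor pair, a cos²-shaped well with
  optimum 2.9 Å heavy-atom separation, depth 4.0, zero beyond 4.5 Å;
  ligand donors are angle-damped (zero below 120° at the hydrogen).
  Cationic sites act as donors toward carboxylate/acceptor oxygens, so the
  salt bridge is scored through this term.
* **van der Waals** — a soft 4–8 well (depth ε = 0.2 for apolar atoms
  against hydrophobic/aromatic sites, 0.05 otherwise, r₀ = site radius +
  atom radius, 8 Å cutoff) with a clash penalty growing as overlap⁴
  (k = 0.5) capped at 2.0 per pair.  Overlaps beyond 0.5 Å count as
  clashes.
* **Torsion strain** — k·(1 − cos(θ − μ_nearest)) per sampled torsion
  against the nearest mode mean of the dynamic model, k = 0.5.

Reported *favorability* is the negated energy so that higher scores are
more favorable.  Ranking is by favorability, descending, ties kept in
conformer order; per-mode statistics report mean, interquartile range,
minimum and maximum — the boxplot view of the score distribution per
conformer group.  Salt-bridge detection is inclusive: any flagged
carboxylate oxygen within 4.0 Å of a cationic site.

### Pocket fixture

The `link_tsg6_groove` fixture is constructed deterministically around the
joint-mode-2 centroid geometry of the HA₆-2AA terminus: a cationic site
(arginine surrogate) and a second donor site at the hydrogen-bond optimum
from the two carboxylate oxygens, an aromatic shelf against the
opened-ring backbone, three hydrophobic spheres packing the solvent face
of the 2AA ring, and a steric wall along the mode-4 carboxylate direction.
By construction the mode-2 geometry places the ligand carboxylate within
salt-bridge distance of the cation; this encodes, as a synthetic fixture,
the experimentally supported groove arrangement in which the reducing
terminus sits against the tyrosine/arginine end of the binding site.  The
resulting ordinal behaviour — the mode-2 group has the highest mean
favorability and contributes the top pose, modes 4/5 score poorly — is
stable across ensemble seeds.  No absolute score value is meaningful, and
no numeric docking reference exists to compare against; the docking layer
is validated ordinally and by its invariances (rigid-body score
invariance, anchor-RMSD zero on exact matches, carboxylate-distance
monotonicity).

## Binding thermodynamics

Constants: R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹, 1 M standard state,
25 °C = 298.15 K; ΔG = RT ln K_D and −TΔS = ΔG − ΔH hold to 1e−9 for
every fit result (display rounding happens only at output).

**ITC forward model.**  Perfusion (overflow) bookkeeping: after cumulative
injected volume v, cell totals are M = M₀e^(−v/V₀) and
X = X_s(1 − e^(−v/V₀)); the bound complex [RL] is the exact single-site
quadratic root with site concentration N·M; the heat of injection i is
ΔH × (moles of complex formed), counting complex carried out with the
displaced volume at its pre-injection concentration.  The exact identity
"total heat = ΔH × total complex formed" holds for every schedule.  The
textbook limit "total heat → N·ΔH·(cell protein moles)" additionally
requires that almost no protein leaves the cell unbound, i.e. a small
cumulative injection volume *and* strong saturation; the property test
constructs such schedules per c-value, because under the standard 18 × 2 μl
schedule displaced-volume losses are several percent by themselves.

**ITC fit.**  As in instrument practice, the mean of the last three
injection heats is subtracted as the dilution offset.  At c ≈ 28 the final
injections still carry residual binding heat, so that subtraction removes
signal as well; the fit therefore estimates a fourth parameter, a residual
constant per-injection heat, alongside (log₁₀K_D, ΔH, N).  Without it the
zero-noise self-consistency of fit and forward model fails at the percent
level; with it, recovery is exact to solver precision.  A deterministic
multi-start grid (K_D ∈ {0.01, 0.1, 1, 10, 100} μM × ΔH ∈ {−20, −10, −5,
−1} kcal/mol, N = 1) guards against local minima; residuals are normalized
by the maximum heat so convergence tolerances act on the isotherm shape
rather than on the kcal-per-injection magnitude (~1e−9).

**MST.**  Fraction of labelled receptor bound from the exact 1:1
quadratic (no free-ligand approximation; at 10 nM receptor and μM-to-mM
K_D the two coincide to 1e−4), mapped to ΔFnorm = baseline + amplitude ×
fraction_bound, in per mil.  Flat responses (amplitude indistinguishable
from zero) are a fit error, mirroring the fluorescence-interference cases
that could not be analyzed.

**Derived tables.**  %K_B = 100·K_D(unmodified, same length)/K_D(modified)
— an association-constant ratio — and the discrimination ratio
%K_B(TSG-6)/%K_B(CD44), absent (not an error) when either side is missing.
All internal math is at full precision; printed-table values occasionally
differ by one or two units in the last digit because the original tables
were computed from unrounded fit outputs (e.g. 192 vs 191 for the
2AA-hexasaccharide, 19.80 vs 19.82 for one discrimination ratio).  The
package documents these as near-misses; its own outputs are exact given
its inputs.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (truth, seed); every dataset ships with a
serialized truth record.  Defaults encode the study conditions: ITC
18 × 2 μl injections of 0.29 mM ligand into 200 μl of 0.029 mM protein
with Gaussian heat noise (1% of the maximum heat) plus a constant
dilution offset drawn once; MST 16-step 1:1 dilution from 5 mM (bottom of
the series ≈ 0.15 μM, matching the printed range) with 10 nM receptor and
2% amplitude noise; ³J noise 0.3–0.5 Hz in the simulation studies.

The generators emulate idealized instruments: i.i.d. Gaussian noise, no
baseline drift, no injection artifacts, perfect 1:1 dilution, a rigid
protein represented as pseudo-atom sites, and restraints free of
assignment error.  Passing the recovery tests therefore shows that the
estimators are consistent and well-conditioned under the stated noise
models — not that they are robust to the systematic errors of real
spectrometers and calorimeters.  Equally, the coarse ligand templates
support geometry-level conclusions (mode separation, salt-bridge
distances) but not atomic-detail energetics.

## Problem sizes and numerical choices

Test and acceptance runs use the production ensemble size (250) for
docking, 10,000 draws for the sampling-law check, 50 seeds for the noisy
ITC/MST recovery studies, 20 seeds for noisy occupancy recovery, 64
conformers per mode for conditional observables, and a 0.01 occupancy
grid; these sizes keep every check comfortably inside interactive runtimes
while leaving the stochastic tolerances well-resolved.  Degenerate inputs
fail loudly: collinear reference frames, unresolved torsion slots,
all-zero heats, flat dose-responses, empty ensembles and sub-minimal
restraint or injection counts all raise typed errors with the offending
quantity named.

## Known limitations

* Ring puckering, solvent, and energy minimization are out of scope; rings
  are rigid bodies.
* The scoring function is a documented three-component surrogate with
  arbitrary units; it supports ordinal conclusions only, and the pocket is
  a pseudo-atom fixture unless real coordinates are supplied.
* Temperature-coefficient records are carried, never predicted.
* The occupancy fitter assumes the candidate mode geometry is known and
  only π is free — it is a desk-scale inverse, not a full structure
  determination.
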