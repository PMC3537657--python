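# Methods

## Scope and data

The package analyses eleven cytotoxic titanocenes (codes 01TC–26TC)
and their pairings with α-, β- and γ-cyclodextrin. Three transcribed
tables ship as CSV fixtures and are the single source of tabular truth:
activities (IC50 in μM with reported ± uncertainties, per cell line
HeLa/K562/Fem-x), six structural descriptors per compound, and five
energy columns per titanocene–cyclodextrin pairing (33 rows). Loaders
validate the schema and the internal invariants (positive IC50,
IC50/pA presence parity, `E_TC+CD = E_CD + E_TC` to 0.01 kcal/mole,
positive interaction energies) and fail loudly with the offending row
key. Missing activities (Fem-x for 18TC; K562 and Fem-x for
23TC/24TC/26TC) are explicit nulls and propagate as such.

Two conventions matter downstream:

* **pA is recomputed, not read.** The stored pA columns mirror the
  printed table for display, but all statistics use
  `pA = 6 − log10(IC50_μM)` at full precision. The printed 2-dp pA
  values lose the digits needed to recover the published slopes (the
  Fem-x slope comes out 0.38 instead of 0.39 from rounded pA).
* **The interaction-energy and complex-energy columns are kept exactly
  as printed** (2 dp and 1 dp respectively), so
  `E_int ≠ E_sum − E_complex` at the printed precision by up to
  0.04 kcal/mole; the complex column was evidently rounded after E_int
  was computed. Nothing in the package re-derives E_int from the
  rounded complex energies.

## Monolinear models

`fit_monolinear` is ordinary least squares `y = a₀ + b·x` on
pairwise-complete cases (statsmodels OLS supplies the coefficient
standard errors). Models are reported with the signed Pearson r and
`F = r²(n−2)/(1−r²)`, which is enforced as a dataclass invariant. The
seven published pairings are: pA(HeLa)/pA(K562)/pA(Fem-x) vs logP
(n = 11/8/7), pA(K562) vs Rf (n = 8), E_int(αCD) vs E_hydr, and
E_int(βCD), E_int(γCD) vs logP (n = 11 each).

The K562-vs-Rf model is fitted with n = 8 although the published
caption says n = 11: only eight compounds have a K562 activity, and the
published F = 10.5 is exactly what n = 8 yields. This is flagged in the
comparison report rather than silently corrected.

Cross-validation (`cross_validate_lho`) is leave-half-out: hold out
⌊n/2⌋ points, fit on the rest, predict the held-out half; all C(n,⌊n/2⌋)
balanced splits are enumerated when there are at most 1000 (always true
at n ≤ 11, making the result deterministic), otherwise seeded random
splits. Held-out predictions are pooled and
`q² = 1 − PRESS/TSS` with TSS about the full-sample mean. Training
halves with zero predictor variance are skipped and counted. The
published q²cv values use an unstated split convention and are not
comparable: a PRESS-based q² cannot exceed the model's r² in
expectation, yet the published K562 value (0.88) exceeds its r² (0.49).
The package reports its own q² and never asserts the published ones.

### Which published values are asserted

Slopes, r and F survive the rounding of the inputs and are asserted at
the printed precision; they all reproduce. Three groups are documented
rather than asserted, because they provably cannot be recomputed from
the printed inputs:

* the activity-model intercepts (rounding-fragile in the third digit);
* the descriptor intercorrelation table (direct computation from the
  printed descriptors gives e.g. r(Rf,Pol) = 0.98 where the published
  matrix prints 1.00, and r(S,V) = 0.91 text vs 0.87 printed);
* the printed HeLa prediction column: it derives from the published
  *rounded* equation (3.40 + 0.69·logP) evaluated at higher logP
  precision than the descriptor table prints. No least-squares refit of
  the printed inputs can match it digit-for-digit (any such fit passes
  through the sample mean, which pins 01TC at 4.00, not 3.99, once 24TC
  is pinned at 4.53). The package's prediction table uses the
  full-precision refit; every entry agrees with the printed one within
  one unit in the last printed digit, and the comparison report carries
  both variants.

## Descriptors

Computed from a `Molecule` (elements, 3D coordinates, bonds with
orders; aromatic bonds are order 4; contribution classes are assigned
from the bond orders as given, with no aromaticity or hybridization
re-perception).

* **V^vdW** — grid counting: a cubic grid (default pitch 0.2 Å, < 1%
  error on test spheres; pitch recorded in the result) anchored at the
  bounding box minus one maximum-radius margin; volume = points inside
  the union of atomic spheres × pitch³.
* **S^vdW** — exposed area of the sphere union, sampled per atom with a
  deterministic Fibonacci lattice (default 960 points/atom); per-atom
  exposed areas are returned for reuse.
* **E_hydr** — Σ exposed area × atom-class coefficient; negative
  favours hydration (the pyridinium-bearing compounds are the negative
  ones in the shipped table).
* **logP, Rf** — sums of atomic contributions. Metal atoms (all d-/f-
  block elements) are skipped, following the study's exclusion rule;
  germanium is parameterized by default with a strict mode that skips
  it like a metal (its treatment in the source analysis is ambiguous).
* **Pol** — additive atom-type increments, metals included.

The parameter registry (`PARAMS_V1`) is package-authored in the style
of the cited literature families — Gavezzotti-type van der Waals radii,
Ghose–Crippen-type logP/refractivity contributions, Miller-type
polarizability increments, Ooi-type hydration coefficients per exposed
Å² — with a provenance string per entry and a version tag recorded in
every result. The original tool's internal tables are unpublished, so
**absolute agreement with the published descriptor table is not
expected and is nowhere asserted**; correctness is established against
oracles (Monte-Carlo union volume, random surface sampling, hand-summed
contribution totals) and properties (exact additivity over disjoint
fragments, rigid-motion invariance, grid convergence).

## Molecular mechanics

Energy terms: harmonic stretch `k(r−r₀)²`, harmonic bend `k(θ−θ₀)²`,
cosine torsion `A(1 + cos(nφ−δ))`, 12-6 Lennard-Jones
`ε((r_m/r)¹² − 2(r_m/r)⁶)` over pairs excluding 1-2 and 1-3 (combining
rules ε = √(εᵢεⱼ), r_m = rᵢ+rⱼ; optional sharp cutoff), and bond-dipole
electrostatics as point dipoles at bond midpoints with the
`14.3928·(μᵢμⱼ/D r³)(û_i·û_j − 3(û_i·r̂)(û_j·r̂))` kernel and an
effective dielectric D = 1.5. A hydrogen-bond term is not included.
The analytic gradient of every term is validated against central finite
differences (1e-4 relative). The shipped generic parameter set is a
small documented table adequate for the toy systems; absolute energies
are deliberately not comparable to any published force-field
implementation, which is why the published complex-energy table enters
the pipeline as fixture data rather than as a regeneration target.

Minimization is Polak–Ribière conjugate gradient with Armijo
backtracking and quadratic interpolation, restarting to steepest
descent every 3N directions or when β < 0; defaults are the protocol's
RMS-gradient stop of 0.005 kcal/mole/Å and a cycle cap of 15 × atom
count. The trajectory of (cycle, energy) is recorded; a line-search
failure returns the best-so-far geometry. Atom subsets can be frozen.

The conformational search drives declared flexible torsions with
displacements drawn uniformly from ±[60°, 180°] (seeded RNG), minimizes
each trial, rejects conformers more than 4 kcal/mole above the running
minimum, removes duplicates, and retains at most 20 conformers from at
most 1000 trials, sorted by energy. The duplicate rule OR-combines the
protocol's three criteria — heavy-atom displacement < 0.5 Å after
optimal (Kabsch) superposition, all flexible-torsion differences < 15°
(circular), or |ΔE| < 0.05 kcal/mole — keeping the lower-energy member.
Hydrogens are excluded from the distance test and torsion enumeration
only, not from the energy.

## Complexation protocol

The guest is rotated (minimal rotation) so its largest-variance
principal axis is perpendicular to the host's mean plane and placed
with the centroids 8 Å apart (default) on the chosen face side; the
primary face is taken from a host annotation when present, otherwise
as the side of the least-variance plane holding fewer atoms (the
narrower rim), with a deterministic tie-break for symmetric toys.
Placement is idempotent. The complex is then minimized and
`E_int = (E_host + E_guest) − E_complex` reported with a per-cycle
trajectory, the monomer energies coming from separately minimized
structures. `screen_library` runs every guest × host on both faces,
keeps the better face per pair, shares monomer minimizations, collects
per-pair failures without aborting, and emits records in the same
schema as the packaged energy table.

## Synthetic data

* QSAR datasets: `y = a₀ + b·x + N(0,σ)`, defaults mirroring the
  strongest activity model (a₀ = 3.40, b = 0.69, x ∈ [0.3, 1.7],
  n = 11) with σ = 0.15 pA units — the scale of the observed
  experimental-minus-predicted differences. Used for parameter-recovery
  tests (true slope within 3·se in ≥ 95% of 1000 seeded replicates).
* Random molecules: connected trees grown with bond lengths in
  1.0–1.8 Å and no pair closer than 0.8 Å; deterministic per seed.
* Toy complexes: a stiffly-bonded Lennard-Jones ring (8 particles,
  argon-like ε = 0.185 kcal/mole, r_m = 3.4 Å) standing in for the
  cyclodextrin cavity, plus an axial guest (distinct element so the rod
  carries its own bonded terms). The optimal axial interaction energy
  is computed by dense grid search (0.005 Å pitch) along the ring axis
  — an oracle independent of the minimizer. A ring at r_m is a snug
  cavity; wider rings give a strictly convex axial optimum at the
  centre (used when the converged guest position is asserted); a
  3-atom rod against a too-narrow ring reproduces the steric-exclusion
  ordering seen for the smallest cyclodextrin.

These toys capture the geometry and energetics the protocol exercises —
cavity fit, face asymmetry, separation decay — but not sugar-ring
chemistry, hydrogen bonding, or solvent; passing tests demonstrate
protocol fidelity and internal consistency, not prediction of real
cyclodextrin binding.

## Numerical conventions

Display rounding is half-up (ties away from zero) to 2 decimals, which
matches every reproduced printed value. Degenerate geometries are
guarded: near-linear angles clamp sinθ, degenerate dihedrals are
skipped, coincident nonbonded atoms are skipped, collinear hosts raise.
Problem sizes used by the test-suite simulations (10⁶-sample
Monte-Carlo volumes, 10⁵-point surface sampling, 1000-replicate
recovery runs, toy rings of 8 particles) were chosen as the smallest
sizes at which the respective oracles are comfortably tighter than the
asserted tolerances.

## Known limitations

* Descriptor absolute values depend on the shipped parameter registry;
  rankings and additivity are trustworthy, individual values are not
  comparable across parameter sets.
* The force field is generic and minimal; no solvent, no hydrogen-bond
  term, no charge equilibration. Interaction energies are meaningful
  relative to each other within one parameterization only.
* Leave-half-out q² at n ≤ 11 is harsh (training halves of 4–6 points)
  and lands far below r²; it is reported for transparency, not
  comparability with the published values.
* The conformational search is random torsion driving, adequate for
  few-torsion systems; it makes no completeness claim.
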