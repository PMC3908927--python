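# Methods

## Scope and shape of the problem

The package operates on pairs of molecular structures of lanthanide (Dy³⁺,
Ho³⁺, Er³⁺) complexes: an experimental crystal geometry and a
model-calculated one.  All accuracy statements are made on the coordination
polyhedron only — the center, its donor atoms, and the internal distances
and angles among them.  No superposition or RMSD-after-fit is ever used;
internal coordinates make the metrics invariant under rigid motion by
construction.  Crystallographic concerns (symmetry expansion, disorder,
R-factor screening) are out of scope; structures are expected as plain
Cartesian XYZ or the package's JSON dialect.

## Coordination polyhedron

The experimental literature rarely states how donor atoms were assigned, so
the package makes the rule explicit and controllable: an atom is a donor if
its distance to the center is at most covalent_radius(Ln) +
covalent_radius(X) + 0.45 Å (radii from gemmi).  This reproduces typical
2.2–2.9 Å lanthanide–donor ranges; the tolerance and per-pair cutoffs are
overridable, and the JSON dialect can pin the donor list explicitly, which
takes precedence.  Hydrogens are never donors.  In dilanthanide complexes
each center gets its own polyhedron and a partner lanthanide within
3.6–6.6 Å is recorded as a donor of class `Ln-Ln`.  Angles are A–Ln–B
vertex angles for donor pairs with both elements in {O, N, C, S, Cl, Br}
(phosphorus donors contribute distances but not angles).

## Error metrics

* `UME_(Ln-L)`: mean |Δd| over center–donor and Ln–Ln distances.
* `UME` (full): the same plus every donor–donor (`L-L'`) distance, which
  encodes the angular quality of the polyhedron indirectly.
* `R_i`: Σ_j Σ_k |Δd_jk|/σ_j + Σ_l |Δθ_l|/σ_θ.  The σ's are **population**
  (divide-by-N) standard deviations of the *experimental* values pooled
  over the whole universe, one per bond class and a single pooled angle σ
  (the angles form one homogeneous set).  Normalising by σ makes bond and
  angle terms commensurable.  A class with fewer than two values or zero
  variance is dropped from the σ map with a warning and skipped in R_i.
  The term exponent is configurable (`power ∈ {1, 2}`); the default 1
  (absolute errors) matches the UME philosophy of the distance metrics.

Aggregation comes in two deliberately distinct flavours: per-complex tables
(one UME per complex) and count-weighted per-type pooling, in which the
pooled UME of a class equals the flat mean over all individual |Δd| of that
class.  The pooled `Ln-L` row includes Ln–Ln; the combined row adds
`L-L'`.

## Training-set selection (DIANA)

Divisive analysis clustering over the 1-D R_i values, dissimilarity
|R_i − R_j|: start with one cluster; repeatedly split the cluster of
largest diameter by seeding a splinter with the object of maximal average
dissimilarity and migrating objects whose average dissimilarity to the
splinter is smaller than to the remainder; stop at singletons.  A
parameterization set of size k is read off by cutting into k clusters (in
decreasing-diameter order) and emitting each cluster's medoid.  All ties —
splinter seeding, split order, medoids — resolve by lexicographic id, so
selection is deterministic.  Small and large sets are generated
independently per k, so the small set is not forced to be a subset of the
large one.

## Parameterization

The objective is Σ R_i over a training set, with the calculated geometries
produced by a backend contract `backend(structure, params) → (relaxed
structure, converged)`.  A failed or non-converged relaxation contributes a
finite penalty of 10⁶ so the search never crashes; if every training
complex fails, the evaluation errors out.  Active parameters are searched
in scaled units (each mapped to [0, 1] by its bound window) to condition
the problem.

* **GSA.**  Tsallis generalized simulated annealing with visiting index
  q_v = 2.62, acceptance index q_a = −5, T(t) = T₀·(2^(q_v−1) − 1) /
  ((1+t)^(q_v−1) − 1), T₀ = 5000, out-of-box proposals reflected into the
  box, acceptance temperature T(t)/t, all exposed in `GSASchedule`.
  q_a = −∞ degenerates to strictly greedy acceptance.  Runs are
  bit-reproducible for a fixed seed.
* **Simplex.**  Nelder–Mead with the standard coefficients (reflection 1,
  expansion 2, contraction 0.5, shrink 0.5; delegated to
  scipy.optimize), xatol 10⁻⁸ / fatol 10⁻¹⁰.  Because the Σ R_i landscape
  near its minimum is a narrow curved valley in which a single simplex
  collapses early, the refinement used by `parameterize` is a ladder of
  restarts with fresh axis-aligned initial simplexes of decreasing edge
  (0.05 → 0.001 in scaled units), keeping the best point.
* **Protocol.**  Stage 1 anneals + polishes on the small set; stage 2
  repeats both from the stage-1 optimum on the large set.

On noise-free synthetic data generated with known surrogate parameters,
this protocol recovers α, a₁ and c₁ to well under 2% relative error
(20 mononuclear complexes, coordination numbers 6–12, GSA 150 iterations
per stage, polish ladder capped at 400 evaluations per rung — about two
minutes of CPU).  These problem sizes are the package's chosen desk-scale
defaults for the recovery experiments in the test suite and the acceptance
script.

## Statistical validation

UMEs are non-negative, so their populations are modelled as gamma
distributions fitted by moment matching (shape = m²/v, scale = v/m — the
fitted mean and variance equal the sample's exactly, to 10⁻¹²).  Fit
quality is assessed with a one-sample Kolmogorov–Smirnov test,
D = max_i max(i/n − F(x_(i)), F(x_(i)) − (i−1)/n), p-value from the
asymptotic Kolmogorov distribution of √n·D by default (an exact finite-n
mode is available and flagged in the report).  Two caveats are inherent
and documented rather than corrected: the gamma parameters are estimated
from the same sample (no Lilliefors-style recalibration), and the variance
convention is population by default with the convention recorded in the
report.  Only the p > 0.05 decision is treated as reproducible; exact
p-values are implementation-dependent.

## The sparkle-potential surrogate

The surrogate stands in for a quantum-chemical geometry engine.  It is a
classical potential sharing the sparkle functional form and the core-core
parameter semantics (α; Gaussian heights a_i, inverse broadnesses b_i,
displacements c_i).  Per center-donor pair at distance r:

    E(r) = k_e q_Ln q_d / r                                  (Coulomb)
         + k_e |q_Ln q_d| / r · exp(−α r)                    (wall)
         + k_e |q_Ln q_d| / r · Σ_i a_i exp(−b_i (r − c_i)²)

plus s/r¹² over all donor pairs.  The short-range exponential and Gaussian
terms act between the positive cores, hence the magnitude of the charge
product: they must be repulsive for the potential to have a bound
equilibrium at all (a signed prefactor would make them attractive and the
ligands would implode).  With the defaults the inner Gaussian builds a
wall near 1.5 Å behind which the radial profile has its physical local
minimum; the global minimum at r → 0 is unreachable across the wall under
the trust-radius-limited relaxation, and distances below 0.1 Å raise an
error.  Donors interact with **every** center, so in dinuclear complexes
no donor can sit unnoticed inside the partner's core.

Defaults: α = 1.35 Å⁻¹, a₁ = 1.13, b₁ = 4.0 Å⁻², c₁ = 1.54 Å,
a₂ = 0.068, b₂ = 7.51 Å⁻², c₂ = 3.23 Å, q_Ln = +3 e, q_d = −0.5 e,
s = 10⁴ eV·Å¹².  b₁ and s were calibrated once so that a relaxed O-donor
shell equilibrates near 2.4 Å across coordination numbers 6–12 (2.43–2.50 Å
observed) — the typical lanthanide–donor bond length — and are not
revisited.  Increasing α strictly shortens the equilibrium distance, which
is the sensitivity the parameter-recovery experiments rely on.

Relaxation is first-order descent with Barzilai–Borwein step sizes, Armijo
backtracking, a 0.3 Å per-atom trust radius (so the line search cannot
tunnel a donor through the wall into the core region), centers held fixed,
convergence at max-gradient < 10⁻⁵ eV/Å within 10⁴ steps (the universe
generator grants itself 10⁵ steps because large dinuclear shells have
nearly flat angular modes).  Relaxation is deterministic and
energy-monotone across accepted steps.

## Synthetic universes

`generate_universe` emulates, at desk scale, a curated crystallographic
universe: per complex it samples a coordination number in 6–12, donor
elements from a mix dominated by O and C (O 0.37, C 0.40, N 0.14, S 0.03,
P 0.01, Cl 0.03, Br 0.02 — loosely following the composition of published
lanthanide benchmark sets), places donors at 2.2–2.9 Å in directions at
least 30° apart (and at least 2 Å from every center), makes a quarter of
the complexes dinuclear with the second center at 3.6–6.6 Å, relaxes under
the surrogate to obtain the "calculated" truth, and adds i.i.d. per-
coordinate Gaussian noise (default σ = 0.05 Å) to every atom to produce
the "experimental" partner.  Everything derives from one seeded
`numpy` generator, so universes are bit-reproducible.

The noise default is chosen so the resulting mean UME_(Ln-L) (≈ 2σ/√π
plus a small transverse-bias correction, ~0.057 Å) sits at the scale of
the published per-complex errors (~0.05 Å).  What the generator does *not*
emulate: chemically distinct donor equilibria per element (all donors share
one charge, so bond-class σ's in noise-free universes are nearly
degenerate — supply explicit σ's for noise-free optimization experiments),
ligand connectivity and rigidity, correlated crystallographic error, and
any electronic effect.  Passing tests on synthetic universes therefore
validate the *machinery* (metrics, clustering, optimization, statistics),
not the chemical accuracy of any parameter set.

## Published-table reproduction and known discrepancies

The shipped benchmark tables are checksum-pinned.  From them the report
recomputes: count-weighted pooled per-type rows (which reproduce the
printed `Ln-L` and combined rows at printed precision for all three ions),
the whole-set Ln–C aggregates (509 distances; 0.04 Å weighted mean for the
orbital model vs 0.30 Å five-sparkle-model average), and the per-complex
summary statistics.  Two discrepancies are surfaced, not reconciled:

* The printed summary means of the per-complex tables coincide exactly
  with the count-weighted pooled per-type UMEs — distance-level statistics
  — and **not** with the averages of the printed per-complex columns
  (e.g. Dy UME_(Ln-L): per-complex mean 0.0557/variance 0.0008 vs printed
  0.0539/0.0032).  The printed variances belong to the distance-level
  population, which cannot be recomputed from any printed data.  The
  report shows both numbers side by side with deltas.
* The Er summary row is printed with N = 58 while the Er per-complex table
  lists 59 complexes; recomputation uses all 59 and flags the difference.

## MOPAC interface

The parameter sets export to the MOPAC `EXTERNAL` dialect (`KEY element
value`, fixed-point 8 decimals, 22 keys: USS/UPP/UDD, ZS/ZP/ZD,
BETAS/BETAP/BETAD, F0SD/G2SD, ALP, ZSN/ZPN/ZDN, FN11/FN21/FN31,
FN12/FN22/FN32, and CORE for the additive core term).  The adapter writes
`.mop` inputs and reads output geometries but never runs MOPAC; the
keyword spelling for the core term and the two-electron integrals should
be verified against the target MOPAC build.

## Known limitations

* The surrogate is not an electronic-structure method; only the geometric
  response to the core-core parameters is meaningful.
* KS p-values with moment-estimated parameters are optimistic; treat the
  0.05 threshold as a screening rule.
* DIANA operates on the 1-D R_i values only; multivariate clustering is
  intentionally out of scope.
* Re-deriving the published 22-parameter sets is not attempted: it would
  require the quantum-chemistry backend and the original crystallographic
  universe.
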