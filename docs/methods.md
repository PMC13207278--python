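# Methods

## Model

Every quantity in the pipeline is a triangular fuzzy number (TFN)
`Ã = (l, m, u)`, `l ≤ m ≤ u`: a pessimistic bound, a modal value and an
optimistic bound. Arithmetic is the standard component-wise convention:
addition is exact; products and reciprocals of triangular numbers are not
triangular in exact fuzzy arithmetic, so the package uses the component-wise
approximation `(l₁l₂, m₁m₂, u₁u₂)` and `(1/u, 1/m, 1/l)`, valid on the
non-negative (respectively strictly positive) domain the pipeline stays in.
`tfn_mul` rejects negative components rather than silently producing a
non-bracketing triple. Distance between TFNs is the vertex metric
`d(Ã,B̃) = √{⅓[(l₁−l₂)² + (m₁−m₂)² + (u₁−u₂)²]}`, which reduces to `|a − b|`
on crisp numbers — the crisp-reduction property the test suite leans on
throughout.

### Fuzzification

A reported evidence interval `[a, b]` becomes `(a, (a+b)/2, b)`. The
packaged study matrix stores the published triples directly, because several
published modal values are *not* interval midpoints; re-deriving them would
silently change the data. Linguistic judgments map through the fixed
five-term scale VL (1,1,3), L (1,3,5), M (3,5,7), H (5,7,9), VH (7,9,9).

### Fuzzy AHP

A panel of reciprocal TFN comparison matrices is consolidated by entry-wise
geometric mean. Geometric means of reciprocal entries are reciprocal in
exact arithmetic but drift in floating point, so the aggregated lower
triangle is recomputed as the exact reciprocal of the aggregated upper
triangle — the type invariant holds exactly rather than within a tolerance.

Crisp weights come from Chang's extent analysis (synthetic extents,
possibility degrees, normalized minimum degrees). Two of its documented
behaviours matter in practice:

* **Zero weights are genuine.** When one criterion's extent is dominated by
  every other, its minimum possibility degree is exactly 0. The package
  surfaces this as a warning and keeps the zero rather than renormalizing
  over fewer criteria; if *all* degrees are zero a
  `DegenerateWeightsError` is raised.
* **Crisp consistent matrices degenerate.** If the comparison matrix is
  fully crisp (zero fuzzy spread), the extents are disjoint crisp numbers,
  possibility degrees are 0/1, and extent analysis returns winner-take-all
  weights. Order-recovery oracles therefore use matrices with a modest
  fuzzy half-width (spread 0.5 in the tests), where the extents overlap and
  the possibility degrees grade all criteria; recovery of the generating
  order was verified for n = 3…6 at weight ratio 1.3.

Consistency is checked on the defuzzified matrix via the principal
eigenvalue (`numpy` dense eigendecomposition, largest real part):
`CI = (λ_max − n)/(n − 1)`, `CR = CI/RI` with the standard random-index
constants for 3 ≤ n ≤ 10, pass at CR < 0.10. On a perfectly consistent
crisp matrix this gives CR = 0 to 1e−9, which Saaty's row-average
approximation would not.

Defuzzification offers `centroid` `(l+m+u)/3` (default) and `graded_mean`
`(l+4m+u)/6`. Neither reproduces the study's published global percentages
exactly from its published local triples (centroid normalization gives
≈24.6% for the top criterion against a printed 25.2%), so the published
global weights are treated as authoritative inputs in "weights-given" mode
and are never re-derived.

### Fuzzy TOPSIS

1. **Target-range transform.** A criterion that is best inside a window
   (here: degradation 12–26 weeks, matched to cortical-bone healing) maps
   through a trapezoidal desirability `g`: `t/lo` below the window, 1
   inside, linear decay to 0 at a `decay_anchor` above it. `g` is not
   monotone, so vertex images are re-sorted to restore TFN ordering. The
   packaged anchor is 200 weeks — the largest upper vertex in the study's
   degradation column, i.e. the slowest degradation any candidate might
   exhibit is assigned zero desirability. Both window and anchor are
   per-criterion configuration.
2. **Normalization.** Benefit column: divide every vertex by the column's
   largest upper vertex (`u*`). Cost column: smallest lower vertex (`l⁻`)
   over each vertex, reversing orientation. Both land in `[0,1]³` and make
   the ranking exactly invariant to rescaling any single column (tested to
   1e−12).
3. **Weighting and ideals.** Each normalized cell is multiplied by its
   criterion's fuzzy weight. FPIS/FNIS are the component-wise
   maximum/minimum weighted TFN per criterion across alternatives —
   data-driven extrema, not the fixed (1,1,1)/(0,0,0) convention, so
   distances stay commensurate when fuzzy weights differ strongly across
   criteria.
4. **Distances and ranking.** `d* `and `d⁻` are sums over criteria of vertex
   distances to FPIS and FNIS; `CC = d⁻/(d* + d⁻)`; ranking is by
   descending CC with ties broken by ascending alternative code
   (deterministic). Classification labels are report annotations supplied by
   configuration, never computed.

The crisp counterpart collapses every cell and weight to its modal value and
reruns the same pipeline; on degenerate (crisp) TFNs every stage reduces to
classical TOPSIS with ratio normalization and absolute-difference distances,
so fuzzy and crisp runs agree exactly on crisp inputs (tested at 1e−9 over
100 random instances).

## Sensitivity analysis

Scenarios are declarative: per-criterion `multiply` factors and/or `set_to`
shares. Factors act on crisp weights; fuzzy triples are scaled by the same
scalar, and a final renormalization divides both by the crisp total, so the
crisp weights sum to one in every scenario and CC values remain comparable
across scenarios. `set_to` pins shares first, then scales the free criteria
proportionally into the complement. The default battery: baseline
(identity); biological focus (×2 on viability and degradation, ×0.5 on
strength and modulus); mechanical focus (the converse); equal weights
(each 1/n); cost focus (cost share pinned at 0.40). Porosity and cost stay
at baseline in the two focus scenarios because they belong to neither the
mechanical nor the biological group.

## Synthetic data

The generators stand in for literature-derived inputs, which are not
deposited anywhere:

* `gen_dominant_matrix` plants a weakly dominant alternative — the
  component-wise maximum of all other rows on benefit columns (scaled up 5%)
  and minimum on cost columns (scaled down 5%). Such an alternative must
  rank first under any non-negative weights; this is the weight-independent
  oracle used in 200-instance dominance tests. Non-dominant rows share one
  base value per criterion with multiplicative log-normal spread
  (`noise_scale` = log-sd; 0 makes them identical). Target-range columns are
  not supported here: dominance is not well defined through a non-monotone
  desirability.
* `gen_interval_evidence` simulates n studies measuring a property with
  log-normal noise and returns the (min, max) range; the fuzzified modal
  value converges to the true value as noise → 0 (tested as a monotone
  trend over 100 replicates).
* `gen_consistent_comparison_matrix` builds reciprocal comparison matrices
  centred on known weight ratios with multiplicative perturbation and fuzzy
  half-width `spread`; reciprocity is exact by construction.

All noise is multiplicative log-normal because every quantity involved is
strictly positive, which the TFN product/reciprocal domains require. Each
generator owns a `numpy` generator seeded per call; no global state.

What the generators do **not** emulate: correlated criteria (real material
properties trade off against each other), heavy-tailed or asymmetric
inter-study variation, and the actual distribution of any published study's
measurements. Passing tests on synthetic data therefore demonstrate
algorithmic correctness (dominance consistency, order recovery, crisp
reduction, determinism), not predictive validity on real materials data.

## The packaged study fixture

Five composite scaffold candidates × six criteria. Criteria C1–C5
(compressive strength MPa, elastic modulus GPa, porosity %, degradation
weeks, cell viability %) hold the published TFNs verbatim (golden-tested).
The published matrix does not include numeric values for C6 (manufacturing
cost index, 1–9, cost direction); the fixture assigns documented default
linguistic ratings — PLA/HA L, PCL/HA L, PLGA/BG M, PLA/CNT H, PLA/Mg M —
justified by each composite's processing route (melt-processable benchmark
systems cheapest; reactive-filler co-processing intermediate; nanotube
dispersion and purification most costly). The column is overridable via
`load_study_fixture(cost_ratings=...)`, and every C6-dependent headline is
understood to hold under this assumption.

Under these defaults the fuzzy ranking places PLA/HA first (CC 0.812) and
keeps it first in all five weighting scenarios; the crisp midpoint
counterpart also ranks it first on this fixture. Distance magnitudes and
lower ranks are sensitive to the C4 desirability parameters and the assumed
C6 column, and are reported, not promised.

## Numerical choices

* Floating comparisons: absolute tolerance 1e−9 unless a test states
  otherwise; TFN reciprocal involution verified at 1e−12.
* Reciprocity of comparison matrices enforced exactly by reconstruction
  from the upper triangle.
* CC values are reported at full precision with a separate 3-decimal
  display column in CSV output.
* Tie-break on equal CC: ascending alternative code.
* Degenerate inputs raise typed errors: fewer than two alternatives
  (`DegenerateProblemError`), an alternative coinciding with both ideals
  (undefined CC), all-zero extent degrees (`DegenerateWeightsError`),
  cost columns containing zeros, matrix orders outside the random-index
  table.

## Problem sizes in the test suite

Property suites run at deliberately small scale — matrices up to 6×6, 100–200
random instances per property, 25 brute-force oracle instances at 3×3 —
chosen so each oracle is exhaustive enough to be convincing while the whole
suite stays in the low seconds. The acceptance script runs the full packaged
study (5 alternatives × 6 criteria), which is the problem's natural size.

## Known limitations

* Extent analysis is used as specified, but its zero-weight behaviour is a
  known criticism of the method; the package warns rather than repairs.
* The component-wise TFN product is an approximation; downstream CC values
  inherit it (as they do in standard practice).
* The desirability transform for target-range criteria is a package choice;
  published analyses rarely state theirs, so distance magnitudes are not
  comparable across implementations.
* Group TOPSIS with per-expert decision matrices, interval type-2 fuzzy
  sets, and other MCDM families (VIKOR, PROMETHEE, ELECTRE) are out of
  scope.
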