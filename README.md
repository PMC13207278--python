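# fuzzymcda

Fuzzy AHP–TOPSIS multi-criteria decision analysis, built for (but not limited
to) biomaterial selection problems where the evidence comes from scattered
experimental literature rather than a single dataset.

## The problem

Choosing a scaffold material for load-bearing bone tissue engineering means
balancing conflicting requirements — compressive strength and stiffness close
to cortical bone, high interconnected porosity, degradation synchronized with
the 3–6 month healing window, high cell viability, manageable manufacturing
cost. Property values reported across independent studies for the same
composite vary widely with fabrication route and testing protocol. Collapsing
each reported range to a single number discards exactly the uncertainty a
clinically conservative selection should weigh.

`fuzzymcda` keeps that uncertainty explicit. Every quantity is a **triangular
fuzzy number** (TFN) `Ã = (l, m, u)`: pessimistic bound, modal value,
optimistic bound. A reported interval `[a, b]` fuzzifies to `(a, (a+b)/2, b)`;
expert judgments map through a five-term linguistic scale
(VL (1,1,3) … VH (7,9,9)).

## The method

**Criterion weights — fuzzy AHP.** Expert pairwise-comparison matrices are
consolidated by entry-wise geometric mean, and crisp weights derived by
Chang's extent analysis: synthetic extents
`S_i = Σ_j M_ij ⊗ (Σ_k Σ_j M_kj)^-1`, possibility degrees
`V(S₂ ≥ S₁)`, and normalized minimum degrees
`d'(i) = min_{k≠i} V(S_i ≥ S_k)`. Panel coherence is checked with the
eigenvalue consistency ratio `CR = CI/RI`, `CI = (λ_max − n)/(n − 1)`
(CR < 0.10 passes).

**Ranking — fuzzy TOPSIS.** (i) normalize the decision matrix
(benefit: divide by the column's largest upper vertex; cost: smallest lower
vertex over each vertex; target-range criteria first pass through a
trapezoidal desirability window) and multiply by the fuzzy weights;
(ii) take the fuzzy positive/negative ideal solutions as per-criterion
component-wise extrema across alternatives; (iii) sum per-criterion vertex
distances `d(Ã,B̃) = √{⅓[(l₁−l₂)² + (m₁−m₂)² + (u₁−u₂)²]}` to each ideal;
(iv) rank by the closeness coefficient `CC_i = d_i⁻/(d_i* + d_i⁻) ∈ [0,1]`.

A **crisp counterpart** collapses everything to modal values and re-runs the
pipeline — the comparison arm for asking how much of the decision is driven
by uncertainty. A **sensitivity module** re-ranks under five weighting
profiles (baseline, biological focus, mechanical focus, equal, cost focus)
and reports rank stability.

The package ships a worked case study of five composite candidates
(PLA/HA, PCL/HA, PLGA/BG, PLA/CNT, PLA/Mg) on six criteria. The published
master matrix covers criteria C1–C5; the manufacturing-cost column (C6) is a
documented package default (linguistic ratings from each composite's
processing route) and can be overridden — any C6-dependent result holds under
that assumption.

## Worked example

```python
from fuzzymcda import load_study_fixture, load_study_weights, run_fuzzy_topsis

matrix = load_study_fixture()
weights = load_study_weights()
result = run_fuzzy_topsis(matrix, weights)
for s in result.rows_by_rank():
    print(s.rank, s.code, round(s.cc, 3))
```

prints

```
1 A1 0.812
2 A5 0.528
3 A4 0.51
4 A3 0.379
5 A2 0.246
```

A1 (PLA/HA) ranks first: its weighted fuzzy profile is the closest to the
per-criterion ideal — not the strongest on any single axis, but the only
candidate without a disqualifying weakness. The nanotube composite (A4) has
the best modal strength but is pulled down by the wide pessimistic bound on
its cell-viability TFN; the bioactive-glass composite (A3) degrades faster
than the healing window tolerates. Running `examples/04_sensitivity.py`
shows A1 stays first under all five weighting profiles. The other scripts in
`examples/` each demonstrate one capability (crisp comparison, expert-panel
weighting, synthetic oracles).

There is also a thin CLI:

```
fuzzymcda rank              # ranking of the packaged study
fuzzymcda sensitivity       # five-scenario stability report
fuzzymcda ahp --panel p.json
fuzzymcda simulate --kind dominant --seed 7
```

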