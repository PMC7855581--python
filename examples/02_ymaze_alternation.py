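"""Y-maze spontaneous alternation from a synthetic track.

A Markov walker tours the maze; its visit sequence is rendered as a
nose+COG track, re-extracted with the both-points zone-crossing rule, and
scored as the fraction of overlapping visit triads covering all three
arms.  Chance is 2/9 (22.2%) for an unbiased visitor; the permutation null
re-scores shuffles of the observed labels.
"""

from phenocage.simulate import WalkerParams, expected_alternation_pct, \
    simulate_ymaze_walker, walker_track
from phenocage.ymaze import alternation_percentage, chance_level, \
    extract_arm_visits, permutation_null, total_arm_entries

params = WalkerParams(p_repeat=0.1, p_alt=0.8)  # a fairly good alternator
seq = simulate_ymaze_walker(params, seed=11)
track = walker_track(seq)
visits = extract_arm_visits(track)
print(f"{total_arm_entries(visits)} arm visits in 10 min:",
      "".join(visits.labels))

result = alternation_percentage(visits)
print(f"alternation: {result.n_correct}/{result.n_triads} correct triads "
      f"= {result.alternation_pct:.1f}%")
print(f"walker's expected alternation: {expected_alternation_pct(params):.1f}%")
print(f"iid-uniform chance level: {chance_level('iid_uniform'):.2f}%")

null = permutation_null(visits, n_perm=10_000, seed=1)
print(f"permutation null for this sequence: {null.mean_pct:.1f} "
      f"+/- {null.sd_pct:.1f}%")
# scoring above the permutation null indicates genuine alternation tendency,
# i.e. the working-memory-like behaviour the assay is meant to index
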