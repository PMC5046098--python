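"""Observer-study statistics: preference pairs, percent agreement, kappa.

Reproduces the published observer-study aggregation from the bundled
per-case tables, then runs a simulated reading session: randomized
best/worst pairs judged by a synthetic rater who prefers the truly better
image 80% of the time.
"""

from vqmselect import (
    aggregate_overall,
    average_kappa,
    cohens_kappa,
    computer_responses,
    contingency_table,
    kappa_category,
    make_preference_pairs,
    percent_agreement,
    simulate_rater,
)
from vqmselect.datasets import COMPARISONS, OBSERVER_STUDY
from vqmselect.vqm import SelectionResult

# --- published per-case tables -> overall rows ------------------------------
n = OBSERVER_STUDY["n_pairs"]
print(f"total pairs across the 7 cases: {sum(n)}")
for comp in COMPARISONS:
    pct = aggregate_overall(OBSERVER_STUDY["percent_agreement"][comp], n)
    kap = average_kappa(OBSERVER_STUDY["kappa"][comp])
    print(f"{comp:14s}: overall agreement {pct}%, average kappa {kap:.2f} "
          f"({kappa_category(kap)})")

# --- simulated reading session ----------------------------------------------
selections = [
    SelectionResult(i, ("70%", f"b{i}"), ("40%", f"b{i}"),
                    [("70%", f"b{i}", 100.0), ("40%", f"b{i}", 50.0)], True)
    for i in range(200)
]
pairs = make_preference_pairs(selections, seed=17)
rater = simulate_rater(pairs, {s.group_id: s.best for s in selections},
                       p_correct=0.8, seed=99)
computer = computer_responses(pairs)
pct = percent_agreement(computer, rater)
kap = cohens_kappa(contingency_table(computer, rater))
print(f"\nsimulated rater (p_correct=0.8), {len(pairs)} pairs: "
      f"agreement {100 * pct:.0f}%, kappa {kap:.2f} ({kappa_category(kap)})")
# Agreement tracks the rater's reliability p; kappa corrects it for the
# 50% chance agreement of the randomized left/right layout.
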