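"""Filter a model ensemble by pocket volume and pick the best models.

Draws a 100-model ensemble with a 2600 ± 200 Å³ pocket-volume
distribution (the spread real inactive class A receptors show), applies
the median ±200 Å³ volume filter, selects the five best-scoring
survivors, classifies volume differences against a reference, and
counts successful docking poses from the interface scores.
"""

from gpcrpocket.ensemble import (
    classify_volume_difference,
    count_docking_successes,
    filter_by_volume,
    select_best,
)
from gpcrpocket.structure_io import read_score_table
from gpcrpocket.synthetic import make_ensemble

records, score_text = make_ensemble(100, median_target=2600.0, sd=200.0,
                                    seed=12)
outcome = filter_by_volume(records, band=200.0)
scores = {lab: row["total_score"]
          for lab, row in read_score_table(score_text).items()}
best = select_best(outcome, scores, k=5)
print(f"ensemble median volume : {outcome.median_volume:.1f} A^3")
print(f"models passing +/-200  : {len(outcome.passing)} / 100")
print(f"best 5 by total score  : {', '.join(best)}")
print("  (~68% pass is what a 2600 +/- 200 normal volume law predicts)")

reference = 2600.0
for label in best[:3]:
    rec = next(r for r in records if r.label == label)
    diff = classify_volume_difference(rec.volume - reference)
    print(f"{label}: delta={diff.delta:+7.1f} A^3 -> {diff.category}"
          + (f" ({diff.direction})" if diff.direction != "none" else ""))

iface = [row["interface_delta_X"]
         for row in read_score_table(score_text).values()]
n_ok = count_docking_successes(iface, cutoff=-6.0)
print(f"docking successes (interface score <= -6 REU): {n_ok} / {len(iface)}")
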