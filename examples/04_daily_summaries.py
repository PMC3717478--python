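"""Daily PA measures, affect composites, and descriptives on a
simulated study.

Simulates diaries and affect responses for 6 children x 8 days, scores
the affect items, and prints the descriptive table (grand mean, SD,
average within-child SD, ICC) for the four affect factors.
"""

import actiflux as af

study = af.simulate_study(6, 8, seed=3)
affect = af.affect_day_table(study.affect_responses)
panel = affect.merge(study.day_truth[["child_id", "date", "pa_fraction_true"]],
                     on=["child_id", "date"])

table = af.descriptives(panel, list(af.AFFECT_FACTORS), icc_method="anova")
print(table.round(2).to_string())
print("\nmean/SD pool all child-days; average ISD is each child's own")
print("across-day SD, averaged over children; the ICC is the share of")
print("variance due to stable between-child differences (1 - ICC is the")
print("within-child share).")
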