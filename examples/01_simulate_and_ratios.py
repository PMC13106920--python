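"""Simulate one adult song contribution and inspect its rhythmic ratios.

Units are grouped into phrases: short within-phrase intervals (~2 s)
alternate with long between-phrase intervals (~4 s), so the ratio
r_k = t_k / (t_k + t_{k+1}) clusters at 1/2 (isochrony) with excursions
to 1/3 and 2/3 at the phrase boundaries.
"""

from collections import Counter

from songrhythm import (
    AgeClass,
    Sex,
    classify_ratio,
    compute_iois,
    compute_ratios,
    default_class_params,
    simulate_contribution,
)

params = default_class_params(AgeClass.ADULT, Sex.F)
contribution = simulate_contribution(params, rng_seed=1)
iois = compute_iois(contribution)  # 5 s cap, breaks at over-cap gaps
ratios = compute_ratios(iois)

print(f"notes: {contribution.n_notes}, kept IOIs: {len(iois)}, ratios: {len(ratios)}")
print("first five IOIs (s):", [round(t, 2) for t in iois.values[:5]])
print("first five ratios:  ", [round(r, 3) for r in ratios[:5]])

bins = Counter(classify_ratio(r) or "outside" for r in ratios)
print("ratios per bin:", dict(bins))
# on_R11 dominates (within-phrase isochrony); on_R12/on_R21 mark the
# short->long and long->short transitions at phrase boundaries.
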