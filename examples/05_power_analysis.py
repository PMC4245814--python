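"""How much data does a recent invasion require?

Four related analyses: the harmonic-sum effect of larger samples in a
constant population; the much larger effect under post-founding growth;
the expected ancestral lineages / genealogy length trade-off (matched
scenarios); and a desk-scale power-vs-loci curve with its inversion at
90% power.
"""

import numpy as np

from invasionabc.growthcoal import GrowthScenario
from invasionabc.powerlab import (
    EXAMPLE_MATCHED_PAIRS,
    fit_power_curve,
    harmonic_gain,
    model_choice_power,
    new_mutation_pmf,
    pmf_overlap,
    sample_size_gain,
)

rng = np.random.default_rng(9)

print("sample-size effect (expected mutation count, 25 -> 50 samples):")
print(f"  constant population (closed form): +{harmonic_gain(25, 50):.1f}%")
sc = GrowthScenario(10_000.0, f=62.0, tau=29.0)
g = sample_size_gain(sc, 25, 50, reps=1500, rng=rng)
print(f"  recent founding (f=62, tau=29, growth to 10^4): +{g:.1f}%")
print("  -> extra samples buy much more new diversity in growing invaders,")
print("     but loci still scale information faster than samples\n")

print("matched scenarios (same E(L_A), different founding age) separate")
print("as loci accumulate (overlap of new-mutation distributions):")
s1, s2 = EXAMPLE_MATCHED_PAIRS["B"]
for l in (96, 1536):
    d1 = new_mutation_pmf(s1, l_loci=l, reps=1500, rng=rng)
    d2 = new_mutation_pmf(s2, l_loci=l, reps=1500, rng=rng)
    print(f"  {l:5d} loci: overlap = {pmf_overlap(d1, d2):.2f}")
print()

print("model-choice power vs number of loci (desk scale: 400 sims/model,")
print("120 pods per point; expect Monte-Carlo noise of several points —")
print("scripts/acceptance.py runs the same experiment at full size):")
counts, powers = [], []
for n_loci in (6, 24, 96):
    p, se = model_choice_power(n_loci, n_sims=400, n_pods=120, k=40, seed=100 + n_loci)
    counts.append(n_loci)
    powers.append(p)
    print(f"  {n_loci:3d} loci: power = {100*p:.0f}% (se {100*se:.0f})")
curve = fit_power_curve(counts, powers)
need, extrapolated = curve.loci_for(0.90)
mb = curve.sequence_requirement_mb(0.90)
note = " (extrapolated far beyond the fitted range)" if extrapolated else ""
print(f"  fit: power = {curve.a:.2f} + {curve.b:.2f} log10(loci)")
print(f"  90% power needs ~{need:,.0f} loci = {mb:,.0f} Mb at 450 bp{note}")
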