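"""Contrast frequency-aware pruning with the random-pruning null.

On data with strong co-occurrence-frequency heterogeneity, the
interaction-rate model concentrates links on generalists (slope of
log realized on log potential degree above 1), while random pruning keeps
each link with the same probability f and preserves the degree-distribution
family of the co-occurrence network.
"""

import numpy as np

from coprune import (
    MetacommunityParams,
    calibrate_p,
    cooccurrence_frequencies,
    cooccurrence_network,
    ensemble,
    ensemble_slopes,
    generate_dataset,
    interaction_network,
    link_fraction,
    species_summaries,
)
from coprune.degree_fit import DegreeSample, select_best

syn = generate_dataset(MetacommunityParams.frequency_heterogeneous(seed=0))
ds = syn.dataset
freq = cooccurrence_frequencies(ds.consumers, ds.resources)
cooc = cooccurrence_network(freq)
inter = interaction_network(ds)
lf = link_fraction(cooc, inter)
cal = calibrate_p(freq, lf)
summ = species_summaries(freq, cooc, inter)

ir = ensemble(freq, cal.p, "ir", n_realizations=30, seed=0)
slopes = np.array(ensemble_slopes(summ, ir))
print(f"frequency-aware (rate) pruning, 30 realizations at p={cal.p:.3f}:")
print(f"  slope of realized on potential degree: mean {slopes.mean():.2f}, "
      f">1 in {(slopes > 1).mean():.0%} of realizations")

rnd = ensemble(cooc, lf.f, "random", n_realizations=30, seed=0)
fams = []
for net in rnd.realizations:
    d = net.adjacency.sum(axis=1)
    fams.append(select_best(DegreeSample(degrees=d[d >= 1])).best_family)
kept = max(set(fams), key=fams.count)
deg = cooc.adjacency.sum(axis=1)
base = select_best(DegreeSample(degrees=deg[deg >= 1])).best_family
print(f"random pruning at f={lf.f:.3f}: modal best-fit family over 30 "
      f"realizations is '{kept}'")
print(f"  (co-occurrence network itself: '{base}')")
print("-> random pruning is shape-preserving; rate pruning is superlinear,")
print("   letting generalists keep a disproportionate share of their partners.")
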