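# coprune

Inferring consumer–resource interaction networks from co-occurrence data.

## The scientific problem

Interaction networks — which pollinators visit which plants, which
parasitoids attack which hosts — are expensive to observe: most pairs of
species that *could* interact are never recorded doing so. Species
occurrence data are far cheaper. `coprune` implements an analysis built on a
simple bridge between the two: a consumer α and a resource i that co-occur
in `N_αi` spatial units interact with probability

    P_αi = 1 − (1 − p)^N_αi,

a single per-site interaction rate `p` compounded over shared sites.
Conditioning every consumer on retaining at least one resource (a consumer
with none would not persist), the expected number of realized links is

    E[L(p)] = Σ_α Σ_i (1 − (1−p)^N_αi) / (1 − (1−p)^N_α),   N_α = Σ_i N_αi.

`E[L]` rises monotonically from the number of consumers (as `p → 0`, each
keeps exactly its one conditioned link) to the number of co-occurrence links
`L_c` (at `p = 1`), so given the observed realized-link fraction
`f = L_int / L_c` the rate `p` is identified by bisection.

The package provides:

- **network construction** from site-level occurrence and interaction
  records (`cooccurrence_frequencies`, `cooccurrence_network`,
  `interaction_network`, `link_fraction`);
- **degree-distribution model selection** by discrete maximum likelihood and
  AIC over four families — exponential (geometric), power law, truncated
  power law, discretized log-normal (`coprune.degree_fit`);
- the **interaction-rate pruning model**: calibration of `p`, conditional
  link expectations, and reproducible ensembles of pruned networks
  (`calibrate_p`, `expected_links`, `ensemble`);
- a **random-pruning null** that keeps each co-occurrence link with fixed
  probability `f`, blind to co-occurrence frequency (`random_prune`);
- a **synthetic metacommunity generator** with known ground truth, the exact
  generative dual of the inference model (`generate_dataset`);
- an **end-to-end pipeline** returning one serializable report per dataset
  (`run_pipeline`).

## Worked example

```python
from coprune import (MetacommunityParams, generate_dataset, calibrate_p,
                     cooccurrence_frequencies, cooccurrence_network,
                     interaction_network, link_fraction)

syn = generate_dataset(MetacommunityParams(seed=0, true_p=0.08))
ds = syn.dataset
freq = cooccurrence_frequencies(ds.consumers, ds.resources)
lf = link_fraction(cooccurrence_network(freq), interaction_network(ds))
cal = calibrate_p(freq, lf)
print(lf.f, cal.p)
```

prints

```
observed f = 0.1346 (200 of 1486 potential links realized)
calibrated p = 0.0854   (data were generated with p = 0.08)
```

The `examples/` directory holds one short narrative script per capability;
each prints computed numbers with a line of interpretation. For instance
`python examples/02_fit_degree_distributions.py`:

```
consumer degrees: n=80, mean=18.6, max=78
family                       AIC    dAIC  params
exponential                625.1     0.0  lambda=0.055
truncated_power_law        626.9     1.8  gamma=0.074, kappa=0.052
log_normal                 629.6     4.5  mu=2.451, sigma=1.054
power_law                  720.6    95.5  gamma=1.342
```

and `python examples/04_prune_ensembles.py` contrasts the two pruning modes
on frequency-heterogeneous data:

```
frequency-aware (rate) pruning, 30 realizations at p=0.088:
  slope of realized on potential degree: mean 1.12, >1 in 93% of realizations
random pruning at f=0.146: modal best-fit family over 30 realizations is 'log_normal'
  (co-occurrence network itself: 'log_normal')
```

A thin CLI wraps the same functions for shell use on CSV files:
`coprune simulate`, `coprune prune`, `coprune run` (see `coprune --help`).

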