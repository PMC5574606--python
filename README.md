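# isotroph

Stable-isotope trophic analysis of benthic macrofaunal communities.

`isotroph` is for benthic ecologists working with δ¹³C/δ¹⁵N signatures of
sediment macroinfauna sampled by replicate cores — the typical design of
Arctic polynya and shelf studies, where the question is which primary food
source (ice algae vs. pelagic particulate organic matter) sustains the
community and how the food web is structured. It provides:

- **δ-notation arithmetic** against the international standards
  (VPDB for C, atmospheric N₂ for N) and the +1‰ δ¹³C correction for
  formalin-preserved tissue;
- a **Bayesian diet mixing model** with an in-package MCMC sampler,
  estimating the posterior of diet proportions *p* under
  *X_i = Σ_j p_j (S_j + C_j) + ε_i* with Normal sources *S_j*, Normal
  trophic enrichment *C_j* (defaults 1‰/level for δ¹³C, 3.8‰/level for
  δ¹⁵N), residual ε, and a Dirichlet prior on *p*;
- **trophic levels** referenced to a per-site sediment δ¹⁵N baseline,
  TL = (δ¹⁵N_consumer − δ¹⁵N_sediment)/3.8 + 1, with food-web length and
  integer trophic-class tallies;
- **Layman community metrics**: mean distance to the δ¹³C–δ¹⁵N centroid
  (CD, trophic diversity) and mean nearest-neighbour distance (NND,
  inverse trophic redundancy);
- **replicate-core community summaries**: areal density and C/N biomass
  (mean ± SE over cores), layer pooling, relative composition and guild
  tables, a megafauna outlier screen, and the comparison statistics used
  in this literature (Welch/Student t, Mann-Whitney U, one-/two-way
  ANOVA, Kruskal-Wallis, Welch ANOVA and Games-Howell post hoc —
  the latter two implemented here);
- a **synthetic-data generator** producing consumer signatures from the
  mixing model's generative form and overdispersed replicate-core counts,
  plus packaged fixture tables for a fully offline, testable pipeline;
- a **CLI** (`isotroph run|simulate|fit-mixing|trophic|community|compare`)
  with YAML config, seeded determinism and a checksummed run manifest.

## Worked example

```python
import numpy as np
from isotroph import (BaselineSignature, DietMixingModel, SourceSpec,
                      TEFSpec, reported_trophic_level)

now = BaselineSignature(site="NOW", d15n_sediment=7.4, sd=0.1, n=3)
reported_trophic_level(9.2, now)    # 1.5  (surface deposit feeder)
reported_trophic_level(14.4, now)   # 2.8  (site's food-web length)

sources = (
    SourceSpec("ice_algae",   mean=(-16.1, 6.8), sd=(1.2, 0.8)),
    SourceSpec("pelagic_pom", mean=(-24.6, 5.6), sd=(1.3, 0.9)),
)
consumers = np.array([[-23.4, 9.2], [-23.0, 9.8], [-23.8, 9.5]])
model = DietMixingModel(sources=sources, tef=TEFSpec(mean=(1.0, 3.8)),
                        chains=4, iterations=4000, random_state=1)
model.fit(consumers)
print(model.summary_.round(3))
```

```
              mean  median  ci_0.025  ci_0.975
source
ice_algae    0.082   0.078     0.005     0.196
pelagic_pom  0.918   0.922     0.804     0.995
```

The trophic levels say these δ¹⁵N-depleted deposit feeders sit between
primary and secondary consumers; the mixing model attributes ~92% of
their diet to pelagic POM (95% credible interval 0.80–1.00), with
convergence confirmed by R-hat ≤ 1.02 across 4 chains.
`DietMixingModel` follows scikit-learn's estimator conventions
(`get_params`/`set_params`, fitted attributes with trailing underscores),
so it composes with sklearn tooling.

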