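# msatpop

Population-genetic analysis of diploid microsatellite data, built for
vector-population studies of the tsetse fly *Glossina fuscipes
fuscipes* in the Lake Victoria basin — and for any study system with
the same shape: a few dozen sample sites, 10–20 microsatellite loci,
seasonal resampling, and lethal trapping.

The package covers the full workflow such a study runs:

* **Genepop I/O and dataset assembly** — 2/3-digit allele coding,
  metadata joining (site, coordinates, sex, season), temporal pooling;
* **diversity statistics** — H_O, H_E, uH_E, F_IS, rarefied allelic
  richness, exact Hardy–Weinberg / linkage / differentiation tests with
  Benjamini–Hochberg FDR control;
* **differentiation** — Weir–Cockerham θ (global, pairwise, permutation
  p-values) and hierarchical F-statistics over nested levels
  (regions > clusters > populations > individuals);
* **clustering and migrants** — PCA + k-means with a BIC criterion,
  discriminant analysis of principal components, leave-one-out
  frequency-likelihood assignment and Λ-threshold migrant detection;
* **sex-biased dispersal** — per-sex F_ST, mAIc, vAIc and mean pairwise
  relatedness (Queller–Goodnight) with within-group sex-permutation
  significance;
* **isolation by distance** — Rousset regressions (1D: d, 2D: ln d) of
  F_ST/(1−F_ST) with Mantel tests, inverted to dispersal parameters
  σ, σ², Wright's neighborhood size W_N = 1/slope, and m = σ²/ε²;
* **population size** — N_E by the linkage-disequilibrium method and by
  temporal (moment and pseudo-likelihood) methods; census size N_C by a
  sequential Bayesian estimator adapted to removal (without-replacement)
  sampling, with 95% HPD intervals and N_E/N_C reporting;
* **a forward-time Wright–Fisher simulator** — stepwise-mutation
  microsatellites, sex-biased migration, founder-group structure,
  lattice/torus geometries, and literal lethal sampling — providing
  study-shaped synthetic datasets with known truth for every estimator.

The model at the core of the novel census estimator: trapping removes
flies, so catches deplete the population.  With cumulative removals
K_{t−1} before occasion t, the catch is n_t ~ Binomial(N − K_{t−1}, p);
a uniform grid prior over (N, p) updated occasion-by-occasion yields a
posterior for the census size N with its highest-posterior-density
interval.

## Worked example

```python
import numpy as np
from msatpop import Grouping, wc_fst, summary_statistics, ldne_estimate
from msatpop.synthetic_data import (paper_like_config, sample_dataset,
                                    simulate_metapopulation)

cfg = paper_like_config(seed=2)                  # 14 sites, 3 groups, 15 loci
run = simulate_metapopulation(cfg)
ds = sample_dataset(run, {d.label: 30 for d in cfg.demes}, seed=12)

stats = summary_statistics(ds)
print(stats.means[["H_O", "H_E"]].mean().round(3))
#  H_O    0.492
#  H_E    0.484

groups = Grouping("groups", dict(cfg.founder_groups))
pw, theta = wc_fst(ds, groups)
print(round(theta, 3), np.round(pw.theta[np.triu_indices(3, 1)], 3))
#  0.125 [0.141 0.14  0.108]

ne = ldne_estimate(ds, ["BV", "BY", "BZ", "LI"])   # the island subset of group 3
print(round(ne.point, 0), np.round(ne.ci, 0))
#  664.0 [206.  inf]
```

Mean heterozygosity ≈ 0.48 and between-group θ of 0.11–0.14 sit inside
the ranges reported for the Lake Victoria system.  The LD-method N_E of
the four-island subset is several hundred with a wide upper CI — the
order of the whole connected group it belongs to (7 demes × 120
breeders), as expected when migration links the sampled sites to the
rest of their cluster.  The `examples/` directory holds one short
narrative script per capability (diversity/HWE, F-statistics and
clustering, migrants and sex bias, IBD and dispersal, population size);
each prints the numbers it computes and says what they mean.

A thin CLI mirrors the pipeline (`msatpop simulate`, `msatpop all
--config config.yaml`, plus one subcommand per stage); every stage
writes its tables and records its seed in a JSON manifest, so a rerun
with the same configuration reproduces every number byte for byte.

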