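# dietnet

Multidimensional dietary-profile analysis for FFQ cohort studies:
food-frequency-questionnaire ingestion, BMI-for-age anthropometric
classification, two-way Ward clustering of consumption, and — at its core —
**bootstrap-stabilized Spearman correlation networks** whose density is
compared across anthropometric strata.

The package is written for nutritional epidemiologists who want to ask not
whether one group of participants eats *more* of a food group, but whether
the *joint structure* of consumption differs between groups: does eating
more of one food group predict eating more — or, tellingly, less — of
others?  In the adolescent cohort this package models, mean consumption did
not differ by anthropometric status at all, yet overweight and obese
participants showed inverse consumption correlations (selective eating) and
sparser correlation networks than their eutrophic peers.

## The statistic

For each stratum, the 14×14 Spearman matrix ρ over food-group daily grams
is computed and Holm-adjusted over its 91 pairs, then submitted to a
B = 100× participant bootstrap.  An edge (i, j) enters the network iff

* adjusted p_ij < 0.05,
* |ρ_ij| > 0.5, and
* the pair remains adjusted-significant in ≥ 50% of bootstrap replicates.

Each replicate b also yields a **network density**

    D_b = L_b / (N(N−1)/2),   N = 14,

with L_b the number of significant pairs in that replicate; the B densities
per stratum are compared across strata by Kruskal-Wallis with Dunn's
post-test.  Node degree (included incident edges) profiles which food
groups anchor each stratum's consumption structure.

Because no raw cohort is distributable, a seeded Gaussian-copula generator
(`dietnet.synthetic_cohort`) produces cohorts with the published stratum
sizes (120/1155/132/89), published-median log-normal marginals, and
configurable per-stratum Spearman targets, so every stage is testable
against planted truth.  See `docs/methods.md` for the full model.

## Worked example

```python
import numpy as np
import dietnet as dn

cohort = dn.simulate_cohort(dn.default_simulation_config(seed=1))
nets, dens = {}, {}
for s in ("underweight", "eutrophy", "overweight", "obesity"):
    ids = cohort.roster.loc[cohort.roster.anthro_class == s, "id"]
    net, samples = dn.bootstrap_network(
        cohort.consumption.loc[ids], stratum=s, B=100, seed=7)
    nets[s], dens[s] = net, samples
    print(s, "edges", len(net.edges), "neg", net.negative_count,
          "mean density", round(np.mean([x.density for x in samples]), 3))
h, p, dunn = dn.compare_density(dens)
print("KW H=%.1f p=%.2g" % (h, p))
```

prints

```
underweight edges 29 neg 0 mean density 0.864
eutrophy edges 90 neg 0 mean density 1.0
overweight edges 18 neg 7 mean density 0.601
obesity edges 29 neg 16 mean density 0.498
KW H=358.8 p=1.8e-77
```

— the eutrophy-like stratum forms an (almost) complete all-positive
network, negative edges appear only in the overweight/obesity-like strata,
and bootstrap network density drops monotonically toward obesity, which the
Kruskal-Wallis test on the per-replicate densities detects decisively.

The same analysis runs end-to-end from the shell:

```bash
dietnet all --outdir run1 --seed 1
```

writing roster/consumption CSVs, the classified roster, summary tables,
Newick dendrograms with bootstrap support, GraphML networks, per-replicate
density samples and a JSON run manifest.

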