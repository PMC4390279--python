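# metafoci

Hierarchical Bayesian spatial point-process meta-analysis of
neuroimaging activation foci.

## The problem

Coordinate-based meta-analysis pools the peak-activation coordinates
("foci", x/y/z in MNI mm) that neuroimaging studies report, to ask
where the brain is consistently engaged by a class of tasks — here,
categories such as distinct emotions.  Kernel summary methods (ALE,
MKDA) produce descriptive maps but are not generative: they cannot
assign a likelihood to a new study's foci, so they cannot classify a
study, and they carry no joint (co-activation) structure.

`metafoci` implements a generative alternative for researchers doing
coordinate-based meta-analysis: a Bayesian spatial point process (BSPP)
with three levels per category,

* latent **population centers** ~ homogeneous Poisson(η) on the brain
  mask B,
* per-study **study activation centers** and **singly reported foci**
  scattered N(center, σ²_study I) around population centers at rate
  μ_cent per center (plus uniform background),
* **multiply reported foci** — each study center emits 1 + Poisson(μ_multi)
  foci scattered N(·, σ²_foci I),

fitted by MCMC with spatial birth–death moves for the number and
locations of population centers.  The fitted posterior yields:

* **intensity maps** — posterior expected activation centers per voxel,
  whose integral over any region is the expected center count there;
* **classification** — the posterior predictive probability of each
  category for a new study's foci (Bayes' rule with flat priors),
  validated by importance-sampled leave-one-study-out cross-validation;
* **region signatures** — T×R matrices of per-iteration region mean
  intensities, their across-category nonparametric profile tests (FDR
  controlled over the C(C−1)/2 pairs), and rank-k NNMF profiles (A = WH
  by alternating least squares, k = 2 by default);
* **co-activation networks** — region–region Pearson correlations
  across MCMC iterations, thresholded by a max-statistic permutation
  test, with 2−r edge distances, betweenness centrality, grouped
  global efficiency, and a Fruchterman–Reingold layout.

See `docs/methods.md` for the model, the sampler, and all numerical
choices.

## Worked example

Everything below is synthetic — the package ships a generator that
draws databases from the model itself with known ground truth:

```bash
metafoci simulate --scenario separated --seed 7 --out-dir out/
metafoci fit  --foci out/foci.csv --mask out/mask.nii.gz --seed 7 --out-dir out/
metafoci loocv --foci out/foci.csv --mask out/mask.nii.gz \
               --samples out/samples.pkl --out-dir out/
```

or in Python:

```python
import numpy as np
from metafoci import (MaskGeometry, MCMCConfig, Priors, ScenarioConfig,
                      generate_database, run_mcmc, loocv_importance,
                      performance_metrics, summarize_population_centers)

cfg = ScenarioConfig(n_categories=3, studies_per_category=10, n_centers=2,
                     sigma_study=6.0, separation=36.0)
db, truth, mask, atlas = generate_database(cfg, seed=7)
geom = MaskGeometry(mask)
data = {c: [r.foci for r in db.by_category(c)] for c in db.categories}
samples = run_mcmc(data, geom, Priors(),
                   MCMCConfig(n_iter=900, burn_in=300, seed=11))
print(summarize_population_centers(samples)["cat_a"])
results = loocv_importance(db, samples, geom)
table = performance_metrics(results, categories=db.categories)
print("LOOCV accuracy:", table.accuracy)
```

which prints (numbers from this exact configuration):

```
{'mean': 2.026666666666667, 'sd': 0.16124170376780775, 'median': 2.0, 'ci_low': 2.0, 'ci_high': 3.0}
LOOCV accuracy: 1.0
```

The center-count summary says the posterior concentrates on 2
population centers per category — the ground truth for this scenario
(the occasional K = 3 state carries a near-empty extra center) — and
with 6-σ separation between category center sets, leave-one-study-out
classification recovers every study's category.  On the
label-exchangeable null (`ScenarioConfig(separation=0.0)`, identical
centers for all categories) the same pipeline scores at the 5-way
chance level of 20%.

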