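# multifc

Multi-metric functional connectivity (FC) for BOLD fMRI time series.

Conventional FC assigns each pair of brain regions a single Pearson
correlation. That captures only linear, time-domain, zero-lag dependence:
two regions can be strongly coupled in the frequency or wavelet domain, at
a lag, or non-linearly, while their correlation stays near zero. `multifc`
implements nine pairwise dependence measures between region time series
x, y ∈ R^t —

| measure | kind | scalar FC value |
|---|---|---|
| `corr` | similarity | Pearson's r = cov(x,y)/(σ_x σ_y) |
| `xcorr` | similarity | peak normalized cross-correlation over lags \|m\| ≤ ⌊t/4⌋ |
| `coherence` | similarity | peak magnitude-squared coherence \|P_xy\|²/(P_xx P_yy) in 0.01–0.1 Hz |
| `wcoherence` | similarity | peak smoothed Morlet wavelet coherence outside the cone of influence |
| `mutual_info` | similarity | plug-in I(x; y) in nats over rank-binned joints |
| `euclidean` | dissimilarity | ‖x − y‖₂ |
| `cityblock` | dissimilarity | ‖x − y‖₁ |
| `dtw` | dissimilarity | dynamic-time-warping path cost |
| `emd` | dissimilarity | 1-D optimal-transport cost between amplitude distributions |

— plus the composite multi-metric FC: the concatenation
ρ_composite = (ρ_corr | ρ_xcorr | ρ_coh | ρ_wcoh | ρ_mi | ρ_eucl | ρ_city |
ρ_dtw | ρ_emd) of the nine upper-triangle feature vectors, length
9·n(n−1)/2 for an n-region network.

Three analysis pipelines are built on the measures:

- **Consistency** — group-mean FC thresholded at one standard deviation
  above the pooled grand mean, compared by Sørensen-Dice overlap
  2|A∩B|/(|A|+|B|) between conditions and against an idealized
  block-diagonal network pattern.
- **Classification** — two-group discrimination from vectorized network FC
  with neighborhood-component-analysis feature selection embedded in
  nested leave-one-out cross-validation and a linear-kernel SVM.
- **Reconfiguration** — alternative brain configurations from each
  measure: symmetric shuffling, L1 (k-medians) clustering of region
  connectivity profiles over many restarts, Dice scoring of each candidate
  configuration, and stepwise brain-behavior regression comparing the best
  alternative against the a-priori network layout.

Because the motivating cohort data are not publicly deposited, the package
includes a first-class synthetic BOLD generator (band-limited latent-factor
signals, 68 regions in 10 networks, TR = 2.6 s, t = 227 by default) with
planted within-/between-network dependence, group effects, and a behavior
score coupled to one network — everything the pipelines need for
ground-truth validation.

## Worked example

Recover a planted 10-network configuration from the group-mean correlation
FC of a synthetic cohort:

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from multifc import (SyntheticSpec, CohortSpec, generate_cohort, pairwise_fc,
                     to_similarity, group_mean_fc, pooled_threshold,
                     reconfiguration_search)

spec = SyntheticSpec(within_strength=0.6, seed=0)   # 68 regions, 10 networks, t=227
cohort = generate_cohort(spec, CohortSpec(n_group_a=10, n_group_b=2, seed=0))

sims = [to_similarity(pairwise_fc(s.bold, "corr")) for s in cohort.subjects]
group = group_mean_fc(sims)
result = reconfiguration_search(group, cohort.partition, k=10, restarts=100,
                                seed=1, threshold=pooled_threshold(sims))
ari = adjusted_rand_score(cohort.partition.labels_array(),
                          result.best_partition.labels_array())
print(f"a-priori configuration Dice   {result.original_dice:.3f}")
print(f"best reconfiguration Dice     {result.best_dice:.3f}  (restart {result.best_restart})")
print(f"ARI vs planted networks       {ari:.3f}")
```

Output:

```
a-priori configuration Dice   1.000
best reconfiguration Dice     1.000  (restart 22)
ARI vs planted networks       1.000
```

The thresholded group matrix overlaps the idealized block pattern of the
planted partition perfectly (Dice 1.000), and the best-of-100-restarts
clustering reconfiguration recovers exactly the planted networks (adjusted
Rand index 1.0) — at a planted within-network correlation of 0.6 the
configuration is fully identifiable from 10 subjects.

A command-line umbrella wraps the same pipelines:

```sh
multifc simulate --out cohort/ --seed 1 --subjects-a 10 --subjects-b 5
multifc fc --bold cohort/sub-001.tsv --measure corr --out fc.tsv
multifc reconfigure --group-fc fc.tsv --partition cohort/partition.json \
        --k 10 --restarts 1000 --seed 1 --out reconfig.json
```

Every command writes a resolved-configuration JSON next to its output so a
run can be reproduced bitwise.

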