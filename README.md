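# seedshadow

Estimation and comparison of animal-mediated **seed dispersal distances
(SDD)** — the straight-line distance from a seed's source plant to its
deposition site — for plants dispersed by frugivorous primates.

The package is written for movement ecologists and plant population
geneticists who want to estimate dispersal kernels from heterogeneous
evidence and understand how much the choice of method matters.  It
implements five complementary estimators as one tested pipeline:

| tag | estimator | evidence used |
|-----|-----------|---------------|
| OSD | observed seed dispersal events | feeding → defecation locations |
| GSC | genotyped seed coats | exact multilocus match of maternal seed-coat tissue to an adult |
| PAS | parentage analysis of seedlings/saplings | maximum-likelihood LOD scores with simulated confidence |
| CMG | movement × gut passage | distances between positional scans at lags inside the gut-passage window |
| IBM | individual-based model | energy-driven foraging simulation depositing seeds after gut passage |

plus the statistics used to compare them: bootstrap means (n = 10,000
resamplings), nonparametric dispersal kernels with bootstrap envelopes
(n = 100), empirical CDFs, two-sample Kolmogorov–Smirnov tests,
Kruskal–Wallis, and pairwise Wilcoxon rank-sum tests with Bonferroni
correction.

A synthetic-data generator emulates two contrasting tamarin-dispersed
study systems — a sparse canopy tree (~1 adult/ha, large fruit crops,
gut passage 30–240 min) and a dense understory tree (5–11 adults/ha,
tiny crops visited in trap-lining sequences, gut passage 120–240 min) —
inside a 25–50 ha home range scanned every 30 min, with Mendelian
inheritance at 9–11 microsatellite loci.  Because the generator returns
complete ground truth (true mothers, fathers and distances), every
estimator is validated by parameter recovery.

## The core statistics

**GSC.** Seed-coat tissue is maternal, so a zero-mismatch multilocus
match between a seed coat and an adult identifies the mother.  The
expected number of chance matches, Σ over unrelated adults of
Π over loci P(identical genotype), certifies when a match is conclusive.

**PAS.** For offspring *o* and candidate parent *c* the LOD score is

LOD(o, c) = Σ<sub>loci</sub> ln [ ((1−e)·T(g<sub>o</sub>|g<sub>c</sub>) + e·P(g<sub>o</sub>)) / P(g<sub>o</sub>) ]

with T the single-parent Mendelian transition probability,
P the Hardy–Weinberg genotype probability and *e* the genotyping error
rate.  Confidence uses the Δ statistic (best LOD minus runner-up): the
critical Δ is the smallest threshold such that ≥95% of above-threshold
assignments on self-simulated candidate sets are correct.  Either
assigned parent may be the mother, so all assigned parent–offspring
pairs enter the distance sample; pairs beyond 700 m (the home-range
diameter) are excluded as presumed pollen flow.

**CMG.** Every within-day pair of positional scans yields a (lag,
distance) observation; distances whose lag falls inside the species'
gut-passage window — the 5% and 80% sample quantiles of observed
passage times, or min–max for tiny samples — are pooled as plausible SDD.

**IBM.** A group agent feeds to maintain energetic homeostasis in a
mapped tree landscape; ingested seeds deposit wherever the group is
when a uniformly drawn gut timer expires; seeds still in the gut at day
end accumulate under the sleeping site.

## Worked example

```python
import numpy as np
from seedshadow import (
    parkia_like, parkia_ibm_config, simulate_ibm,
    gut_passage_window, estimate_cmg, compare_methods, DistanceSample,
)
from seedshadow.synthetic import generate_landscape, generate_tracks

cfg = parkia_like(seed=7)                       # ~1 adult/ha, 38.9 ha
adults, polygon = generate_landscape(cfg, 7)
tracks = generate_tracks(cfg, n_days=31, rng=8, polygon=polygon)

gut = np.random.default_rng(9).uniform(30, 240, 60)   # passage times, min
window = gut_passage_window(gut)                      # 5%/80% quantiles
cmg = estimate_cmg(tracks, window, species="canopy")

ibm = simulate_ibm(parkia_ibm_config(n_days=200), adults, rng=10)
report = compare_methods([cmg, ibm.distance_sample("canopy")], seed=11)
print(report.summary())
```

```
Method comparison
=================

   CMG: n=2697  mean=  226.8 m (bootstrap 226.9 m, 95% CI 221.9–231.8)
   IBM: n=9250  mean=  116.3 m (bootstrap 116.3 m, 95% CI 114.5–118.1)

Kruskal–Wallis: H(1) = 1630.4, p = 0
Pairwise Wilcoxon (Bonferroni ×1) and KS matrices written alongside.
```

The CMG sample pools 2,697 scan-pair distances with lags between the
gut-window bounds; the IBM deposits 9,250 seeds over 200 simulated
days.  The phenomenological estimate sits higher than the mechanistic
one because it integrates all movement, not only post-feeding movement —
exactly the kind of between-method difference the comparison battery is
built to expose.

A full scenario (all five methods plus the comparison) is one command:

```
dispersal run --config src/seedshadow/configs/parkia.toml --seed 1 --out out/
```

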