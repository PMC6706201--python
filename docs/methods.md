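# Methods

This note documents the models behind each estimator, the synthetic
study systems used to validate them, the numerical choices, and the
limits of what the tests demonstrate.

## Spatial conventions

All coordinates are planar metres in a single UTM-like frame; every
distance in the package is Euclidean.  No geodesy or CRS handling is
included: at the spatial scale of a primate home range (hundreds of
metres) projection distortion is far below GPS error.  Home ranges are
modelled as rectangles of the configured area; the containment and
reflection logic accepts any shapely polygon.

## Genotypes

Genotypes are diploid, multilocus and codominant (microsatellite-style),
stored as unordered allele pairs with the GenAlex convention that allele
code 0 marks missing data.  A half-missing call is rejected at load
time.  Allele frequencies are simple counts over non-missing allele
copies; loci with no data are dropped with a warning rather than passed
silently to likelihoods.

## Synthetic study systems

The generator creates the conditions the estimators were designed for:

* **Landscape** — adults placed by a homogeneous Poisson process
  (count ~ Poisson(density × area)) in the home range.  Defaults follow
  the two study systems: ~1 adult/ha for the sparse canopy tree and
  5–11/ha (default 8) for the dense understory tree, in home ranges of
  38.9/38.1 ha.
* **Genotypes** — per-locus allele frequencies drawn once from a flat
  Dirichlet (default 8 alleles at 9 or 11 loci), adults in
  Hardy–Weinberg proportions, offspring Mendelian.  Optional
  genotyping-error (observed call replaced by a fresh Hardy–Weinberg
  draw) and missing-data rates corrupt a *copy*, so the truth is always
  retained.
* **Seed coats** — exact copies of the maternal genotype, since the
  tissue is maternal.
* **True kernel** — deposition points are the mother's location plus an
  exponential distance (mean 200 m by default) in a uniform direction.
  This kernel is a synthetic device for creating known ground truth, not
  a claim about real dispersal; its mean sits inside the range of
  field estimates for these systems.
* **Movement** — a correlated random walk sampled every 30 min over a
  9-h activity period (19 scans/day).  Step lengths are gamma with
  moments matched so daily path length has mean 1,700 m and spread
  consistent with the reported 600–3,000 m range (per-step mean =
  daily mean / k steps; per-step SD = daily SD / √k, with daily SD
  defaulting to one sixth of the range).  Headings follow a
  wrapped-normal turning process (SD 0.7 rad) and reflect off the
  home-range boundary.
* **Dispersal events** — feeding scans chosen uniformly per day; the
  source tree is the nearest adult to the feeding scan and the source
  location is the scan position itself, so that the recorded distance
  is exactly the displacement along the track and the path-integral
  bound (SDD ≤ path walked during gut passage) holds by construction.
  Gut times are uniform on the species window; seeds still in the gut
  at the last scan deposit there (the sleeping site) and are flagged,
  mirroring observed seed accumulation under sleeping sites.

What the generator does **not** emulate: habitat heterogeneity,
phenology, multi-group dynamics, secondary dispersal, density-dependent
seedling mortality, linkage or null alleles.  Recovery tests therefore
show that the estimators are implemented correctly and calibrated
under their own assumptions — not that field data meet those
assumptions.

## Seed-coat matching (GSC)

An adult matches a seed coat iff zero mismatching loci over at least
`min_compared_loci` (default 5) compared loci; loci missing in either
genotype are ignored.  Exactly one matching adult yields an assignment;
zero or several (e.g. clonal duplicates) yield none — a conservative
choice over nearest-adult tie-breaking.  The expected number of chance
matches for an unrelated adult, Π over typed loci of the
Hardy–Weinberg identity probability, is exposed so users can check that
their panel makes exact matching conclusive.

## Parentage (PAS)

The likelihood model is the classic single-parent LOD for codominant
markers: per locus, ln of ((1−e)·T + e·P₀)/P₀ where T is the Mendelian
transition probability of the offspring genotype given the candidate
(the second allele drawn from the population) and P₀ its Hardy–Weinberg
probability.  The error model — with probability *e* the observed call
is an independent Hardy–Weinberg draw — was chosen because it is the
simplest model consistent with a single error rate, it keeps every
likelihood finite at e > 0, and it is exactly the corruption model the
synthetic generator applies, so calibration can be verified end to end.
Parent-pair likelihoods are deliberately out of scope: with nuclear
markers in a monoecious system either parent may be the seed parent, so
the analysis treats each assigned parent as a potential mother.

Confidence follows the simulate-then-threshold recipe: candidate sets
of the configured size containing the true parent with probability
`proportion_sampled`, observed genotypes carrying the error rate, and
the Δ = LOD(best) − LOD(second best) statistic.  The critical Δ is the
smallest value whose above-threshold assignments are ≥95% correct
(strict confidence).  10,000 simulations run in under a second because
all LOD computations are vectorised over (simulation, candidate,
locus).  The runner-up candidate is additionally assigned when it
independently clears the threshold against the field excluding the
best, allowing up to two potential parents per offspring; both
distances enter the sample undeduplicated.  Pairs beyond 700 m —
the diameter of a disperser home range — are excluded as presumed
pollen flow; the boundary itself is kept (the cut is strictly greater
than 700 m) and the limit is configurable.

The kernel-recovery experiment uses a scenario with complete maternal
sampling and pollen immigration (fathers outside the candidate set):
with both parents local and equally assignable, a distance sample that
pools mother and father distances estimates a seed+pollen mixture, not
the seed kernel, and no parentage method can separate the two without
uniparentally inherited markers.

## Movement × gut passage (CMG)

All within-day ordered scan pairs contribute (lag, distance)
observations — deliberately including scans far from any feeding event,
which is what makes the method applicable to remotely tracked animals.
The gut window is the 5%/80% empirical sample quantile pair (linear
interpolation between order statistics, numpy's default); whether the
original description's "5%/80% CI" meant sample quantiles or confidence
bounds on quantiles is ambiguous, and sample quantiles were chosen as
the plain reading.  Below `small_n` = 10 observations quantiles are
unreliable and the observed min–max is used, generalising the treatment
of an n = 3 passage-time sample.  A ±5 min lag tolerance (0 for exact
synthetic grids) absorbs field scan jitter.  The asymmetric upper
quantile discounts passage times inflated by resting, which adds time
but not displacement.

## Foraging simulation (IBM)

The original mechanistic model this estimator parallels is documented
only at the level of its narrative (energy homeostasis, predefined gut
passage, 200 simulated days), so every internal rule here is an
explicit, configurable design choice of this package:

* **Energy budget** — arbitrary units; decay 0.8/min plus 0.02/m,
  feeding gain 20/bout for the sugar-rich canopy fruit and
  20 × 528.5/811 for the understory fruit (ratio of soluble-sugar
  contents, midpoint of 415–642 vs 811 mg/g).  Below a threshold (70 of
  100) the group forages; energy is clamped to [0, 100].
* **Tree choice** — among trees with crop left and the daily revisit cap
  unmet, the candidate set is the 3 nearest and the choice within it is
  softmax in distance (λ = 150 m).  Restricting to the nearest few trees
  ties hop length to local tree spacing, which is what makes denser
  stands yield shorter dispersal — the qualitative pattern expected for
  these systems; a pure distance-kernel choice over all trees was tried
  first and rejected because the growth of the number of trees with
  distance makes hop length (and hence SDD) independent of density.
  The just-fed tree is excluded from the immediate next choice.
* **Movement** — straight legs at 12 m/min; no within-leg tortuosity.
* **Crops and revisits** — crop resets each morning; canopy profile:
  8 bouts/day, revisit cap 4, 11.8-min bouts, no other food species;
  understory profile: 2 bouts, cap 1, 1.9-min bouts, plus background
  fruit trees that supply energy but produce no records.
* **Gut passage** — uniform on the species window (30–240 or
  120–240 min), 2 seeds per bout; seeds deposit at the group's position
  when the timer expires, *before* that minute's movement, so
  displacement can never exceed speed × gut time.  Seeds still carried
  at day end deposit at the sleeping site, flagged.
* **Days are independent** (no overnight hunger carry-over), matching
  the 200-day design of concatenated daily simulations.

The decay/gain/λ/k constants were calibrated once so that simulated
daily path lengths at the canopy scenario's density fall inside the
observed 600–3,000 m range with a mean near 1,700 m; they are not fitted
to any dispersal outcome.

## Statistics

* **Bootstrap means** — n = 10,000 resamples, percentile 95% intervals.
  Percentile (not BCa) intervals are the simplest method consistent
  with the analysis being replicated.
* **Dispersal kernels** — Gaussian KDE with the rule-of-thumb bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5) (the default of R's `density()`),
  evaluated on a 512-point grid from 0 to 1.1 × max, with mass below
  zero reflected at the origin.  A KDE stands in for the original
  smooth-spline fit: the cited routine specifies its bandwidth source
  but not the spline internals, and the KDE satisfies the same contract
  (nonparametric, smooth, mass-conserving density).  The envelope is
  the pointwise 2.5/97.5 percentile band of 100 bootstrap densities,
  clipped to contain the point estimate.
* **Comparison battery** — Kruskal–Wallis with tie correction
  (df = k−1, so df = 4 for five methods); pairwise Mann–Whitney/
  Wilcoxon rank-sum with normal approximation and Bonferroni
  multiplication by C(k,2) capped at 1; pairwise two-sample
  Kolmogorov–Smirnov with the asymptotic p-value.  All of these go
  through scipy and are cross-checked against brute-force and
  permutation oracles in the test suite.

## Determinism

Every randomised operation takes an explicit seed or
`numpy.random.Generator`.  The pipeline derives per-stage generators
from one master seed via `SeedSequence.spawn`, records them in the run
manifest together with SHA-256 hashes of every output file, and a rerun
with the same config and seed is byte-identical.

## Problem sizes

The bundled demo scenarios use 31 tracked days, 150 genotyped
offspring, 120 seed coats, 10,000 confidence simulations and 200
simulated foraging days; recovery experiments use cohorts of 200–300.
These sizes give binomial/Monte-Carlo error well below the tolerances
the tests assert while keeping a full scenario run under a minute on
one core.

## Known limitations

* The CMG estimator inherits the scan interval's resolution: movement
  between scans is invisible, so short gut windows are summarised by
  few lags.
* The IBM is a minimal homeostasis model; it ignores memory beyond the
  current day, social foraging, and phenology, and its absolute SDD
  scale depends on the calibrated movement constants.
* PAS accuracy statements hold at the simulation's own assumptions
  (candidate counts, sampling proportion, error rate); misspecifying
  those in real data shifts the realised confidence.
* With both parents present among candidates and no uniparental
  markers, PAS distance samples mix seed and pollen movement; the 700 m
  filter trims only the extreme tail of that mixture.
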