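# Methods

## Model cell and normalization

The simulator operates on a *normalized* cell rather than raw expression
measurements: a fixed miRNA pool (default 50,000 molecules) and mRNA pool
(default 25,000 molecules), i.e. a 2:1 miRNA:mRNA stoichiometry. Raw
abundances are apportioned onto the pools by largest-remainder (Hamilton)
rounding with ties broken lexicographically by id — the procedure is
deterministic, scale-invariant in the input weights, and conserves the pool
total exactly. Species falling below the detection floor (1 miRNA molecule;
5 mRNA molecules, i.e. 0.02% of the mRNA pool) are dropped and the pool is
re-apportioned **once** over the survivors. A second pass can in principle
leave a survivor just below the floor again; we accept this rather than
iterate, because a fixed two-stage procedure is deterministic and the floor
is a detection heuristic, not a conservation law.

## Score-to-probability map

TargetScan-style context scores s ≤ 0 map to binding probabilities
p = 1 − 2^s. The map is exact arithmetic; note that in float64 it
saturates at p = 1.0 for s below about −50, far outside the range of real
context scores (≳ −2). MirSVR-style scores have no published probability
map; since they are ranking scores, |s| is min-max rescaled over the loaded
table to [0, 0.999] — monotone in the ranking, with the 0.999 ceiling
keeping every probability strictly below 1. The mapping is a documented
dialect plug-in point, not an estimate of binding affinity.

## Simulator kernel

One iteration = one potential binding encounter:

1. **miRNA draw** ~ free-molecule counts.
2. **Target draw** among the drawn miRNA's target genes, weighted by each
   gene's count of *eligible* molecules; then a molecule uniformly, then an
   eligible site uniformly. Eligibility enforces steric exclusion between
   RISCs: a site can be occupied only if its start position lies at least
   `spacing_nt` (default 50) from every occupied start position on that
   molecule. The rule compares site **start** positions; no footprint length
   is modeled.
3. **Bernoulli binding** with the site's probability. A failed draw, an
   empty eligible set, or an exhausted free pool still consumes the
   iteration, keeping iteration counts comparable across conditions.
4. **Delayed degradation**: the first successful binding on a molecule
   schedules its removal `removal_delay` (default 1,000) iterations later.
   The timer starts at the *first* binding and is not reset by later
   bindings — this bounds molecule lifetime and creates the cooperative
   window in which further miRNAs can bind the same molecule. A molecule
   awaiting removal remains a legitimate binding target. On removal all its
   bound miRNAs return to the free pool: miRNAs recycle and are never
   destroyed, so the total miRNA count is invariant over a run.
5. **Optional decay** removes each *unbound* molecule with a fixed
   per-iteration probability (bound molecules are already committed to the
   removal queue). **Optional transcription** adds a fixed number of
   molecules every fixed interval, apportioned to the initial gene
   distribution by largest remainder.

Iterations are counted 1-based: a molecule first bound during iteration t
is degraded while processing iteration t + removal_delay.

**State representation.** Unbound molecules of one gene are statistically
exchangeable — every one has the same sites and no occupancy history — so
the state stores them as a per-gene integer count and materializes explicit
`MoleculeState` records only for occupied molecules. The sampling
distribution is provably identical to a one-record-per-molecule
implementation (the uniform molecule draw splits into "one of the n
unbound" vs "one specific occupied"), while memory and per-step cost stay
proportional to the number of occupied molecules, which the removal delay
bounds. For target weighting the engine maintains a matrix E[miRNA, gene] of
eligible occupied-molecule counts, recomputed for a gene only when its
occupancy pattern changes; per-step work is then a handful of vectorized
operations.

**Randomness.** One `numpy` PCG64 stream per run, seeded from the config;
the draw order is fixed by the step structure above, so identical inputs
give bit-identical trajectories. State (including the RNG) serializes to a
plain dict for restart-from-checkpoint runs.

**Retention** of a gene is 100 × unbound / initial molecules. Molecules
bound but not yet degraded are *not* retained — retention measures escape
from miRNA engagement, not physical presence. With transcription enabled
retention can exceed 100%; the default configuration leaves it in [0, 100]
and non-increasing.

## Screens

The overexpression screen runs one full simulation per (miRNA, factor)
pair over the ladder x1, x3, x9, x18, x90, x300, x1000. A miRNA undetected
in the naive cell is first spiked in at 0.02% of the miRNA pool (10
molecules at the default pool) as its x1 baseline. By default the miRNA
pool is re-apportioned to its original total after multiplication
(`renormalize=True`), modelling a cell with fixed miRNA capacity but
shifted composition; the un-renormalized mode is available because either
reading of "multiply the abundance" is defensible. Per-run seeds derive
deterministically from (base seed, miRNA id, factor index), so a screen is
reproducible from a single integer.

Ratio matrices divide final retentions elementwise between two factors.
Zero handling (the source procedure leaves zeros unaddressed): 0/0 → 1
(neutral — the gene is fully degraded in both conditions, so the dose
change revealed nothing), positive/0 → +inf (labelled up). Discretization:
ratio > 2 up, < 0.5 down, else neutral. Log2 ratio profiles for OXR
classification clamp infinities at ±10 — beyond any ratio observable with
≥ 1 retained molecule on realistic pools.

The hybrid-cell comparison keeps one cell's transcriptome and swaps in
another's miRNA repertoire, runs both cells with the same seed, and
correlates per-gene retention vectors (Pearson or Spearman — the source
material alternates between the two, so both are exposed and neither is
canonical) on the shared gene universe at every checkpoint. Identical
vectors correlate at 1.0 by convention even where variance is zero (e.g.
at iteration 0).

## Classification

**Dyn-classes** cluster genes by their retention trajectory (k-means,
scikit-learn, 10 restarts, fixed seeding; trajectories are already on a
common 0–100 scale, so no further standardization). Classes are relabelled
so centroid final retention decreases with class index: class 1 is the
stable bulk. **OXR-classes** cluster the 6-component log2 consecutive-ratio
vectors; every reported cluster must exceed 5 genes — undersized clusters
are dissolved and their members reassigned to the nearest surviving
centroid (one pass suffices: reassignment only grows survivors). Classes
sort by size descending.

**Elbow selection of k** computes the explained-variance fraction
EVF(k) = between-cluster / total variance on a k grid (anchored at the
grid's edges) and picks the k maximizing the relative slope change
(EVF(k) − EVF(k−1)) / (EVF(k+1) − EVF(k) + 1e-3). The absolute
second-difference variant was rejected during design: whenever cluster
separations are uneven, the k=1→2 gain dominates every curvature term and
the criterion collapses to k=2; the relative form recovers the planted k on
both blob and trajectory-archetype fixtures. The 1e-3 floor (on the EVF
scale of ~1) guards against division by the near-zero gains past the knee.

## Synthetic cells and what they do (not) show

The generator reproduces the structural features that drive the dynamics:

- miRNA abundance as a rank power law (exponent 2.2 by default, putting
  ~90% of the pool on the top handful of a 100-miRNA cell over a long low
  tail);
- lognormal mRNA abundance (σ = 1);
- Poisson site counts per gene placed on a 2,000-nt 3′-UTR with the 50-nt
  spacing respected by construction;
- scores from a shifted negative exponential (offset 0.074, scale 0.9,
  floor −3.32) chosen so typical site probabilities span ~[0.05, 0.9];
- optional planted targets and 5 decay archetypes (stable, slow, medium,
  fast, immediate — the last two converging at the endpoint) with exact
  fraction splits and ground-truth labels.

Two frozen benchmark cells define the validation experiments: the
*planted-regulator* cell (one equal-scored site per gene from a uniformly
drawn miRNA, so a gene's fate depends only on which miRNA targets it — the
signal that table randomization destroys) and the *sentinel dose-response*
cell (one strong site, p ≈ 0.98, for an initially undetected miRNA, so the
sentinel gene's retention must fall monotonically along the factor ladder
from the 0.02% spike-in baseline).

What passing tests on these cells does **not** show: real cells have
correlated site composition and expression, miRNA families with shared
seeds, alternative and edited 3′-UTRs, subcellular miRNA partitioning,
ceRNA titration, and binding that represses translation without
degradation. None of these are modeled; conclusions about specific genes in
specific cell lines require the corresponding measured profiles and tables.

## Problem sizes and numerical choices

Validation runs use deliberately scaled cells — tens to hundreds of genes,
5–20 miRNA types, 10k–15k iterations — which preserve every invariant being
tested (conservation, spacing, delay accounting, monotone dose-response)
while keeping a full validation pass to minutes on one CPU. Reference
production settings (100k iterations, full pools, hundreds of screened
miRNAs) are the defaults in `SimConfig` and the factor ladder.

Other fixed choices: duplicate (miRNA, gene, position) rows collapse to the
best (most negative) score with a warning; table randomization permutes
miRNA labels over (miRNA, gene) pairs, preserving per-miRNA pair counts and
per-gene site multisets exactly (label collisions are resolved by swap
sweeps, deterministic given the seed); correlations with zero-variance
inputs return 1.0 when the vectors are identical and NaN otherwise; k-means
uses `random_state=0` everywhere unless the caller supplies a seed.

## Known limitations

- Per-iteration cost is O(targets of the sampled miRNA); cells with
  thousands of genes and dense tables run at roughly 15k iterations/s on
  one core. The kernel is exact, not an approximation — there is no
  tau-leaping or event aggregation.
- The spacing rule uses site start positions only.
- Random decay applies to unbound molecules only, per the source
  procedure's wording; occupied molecules always live exactly
  `removal_delay` iterations after first binding.
- The MirSVR probability mapping is a monotone convention, not a calibrated
  affinity; cross-dialect comparisons should be read as rank agreement.
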