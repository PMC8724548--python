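# comicsim

Stochastic, molecule-level simulation of miRNA-mediated mRNA degradation in
a normalized model cell, with exhaustive in-silico overexpression screens
and retention-based gene classification.

## The problem

MicroRNAs (miRNAs) silence genes by binding scored sites (MBS) on the
3′-UTRs of mRNAs, and the outcome in a living cell is governed less by any
single interaction than by stoichiometry: a few dominant miRNA species
compete over tens of thousands of transcripts carrying millions of
candidate sites. `comicsim` models this combinatorial competition directly
at the molecule level. It is aimed at systems biologists who want to ask
what happens to a transcriptome when the miRNA repertoire shifts — for
example under the kind of miRNA dysregulation that accompanies cancer
progression — without committing to kinetic rate constants that are rarely
measurable.

## The model

A model cell holds fixed pools, by default 50,000 miRNA and 25,000 mRNA
molecules (a 2:1 stoichiometry), apportioned from expression profiles by
largest-remainder rounding; species below 1 miRNA / 5 mRNA molecules
(0.02% of the pool) are dropped. Interaction scores *s* from a
TargetScan-style table become binding probabilities

> p = 1 − 2^s  (s ≤ 0),

so a score of 0 never binds and strong context scores approach certainty.
Each iteration of the simulator:

1. samples one miRNA type in proportion to its free-molecule count,
2. samples one of its target genes in proportion to eligible molecules,
   one molecule uniformly, and one eligible site uniformly — a site is
   eligible when it lies ≥ 50 nt from every RISC already bound on that
   molecule,
3. binds with probability *p*; a first binding schedules the molecule for
   degradation 1,000 iterations later (a delay that opens a window for
   cooperative multi-miRNA binding),
4. degrades due molecules, returning their miRNAs to the free pool —
   miRNAs recycle, they never degrade,
5. optionally applies spontaneous decay of unbound molecules and scheduled
   transcription of new ones.

The observable is **retention**: the percentage of a gene's initial
molecules still unbound, tracked per gene over a (typically 100k-iteration)
run. On top of the kernel sit:

- **overexpression screens** — multiply one miRNA's abundance by each
  factor of the ladder x1, x3, x9, x18, x90, x300, x1000 (an undetected
  miRNA starts from a 0.02% spike-in, i.e. 10 molecules) and collect the
  genes × miRNAs matrix M_f of final retentions per factor f;
- **ratio matrices** M_f/M_k with an up/neutral/down discretization at
  >2 and <0.5;
- **Dyn-classes** — k-means over retention trajectories (class 1 = most
  stable);
- **OXR-classes** — k-means over per-gene log2 ratio profiles across the 6
  consecutive factor pairs, with every reported cluster required to hold
  more than 5 genes.

A synthetic-cell generator (`comicsim.synth`) produces cells with the
structural features that drive the dynamics — a handful of miRNAs carrying
~90% of the pool, long low-expression tails, tens of spaced sites per
3′-UTR — plus planted targets and decay archetypes with ground truth.

## Worked example

```python
import comicsim as c

# a 30-gene, 10-miRNA synthetic cell with known ground truth
spec = c.SynthSpec(n_genes=30, n_mirnas=10, sites_per_gene_mean=5, seed=7)
profile, table, truth = c.make_cell(spec)
print(f"top-5 miRNA pool share: {truth['top5_mirna_share']:.1%}")

cfg = c.SimConfig(total_iterations=20_000, seed=3)
traj = c.run(profile, table, cfg)
print(f"mean final retention: {traj.final().mean():.1f}%")
```

prints

```
top-5 miRNA pool share: 96.0%
mean final retention: 74.9%
```

— the generated cell is dominated by its top miRNAs, and after 20k
iterations the average gene still retains ~75% of its molecules: most genes
resist miRNA pressure while the strongly targeted minority decays, which is
the behavior the retention-based classifications quantify. The same
pipeline is available from the shell:

```sh
comics synth --out cell/ --seed 7
comics run --mirna-profile cell/mirna_profile.tsv \
           --mrna-profile cell/mrna_profile.tsv \
           --table cell/interactions.tsv \
           --iterations 20000 --seed 3 --out run.tsv
comics classify dyn --trajectory run.tsv --k 5 --out-prefix dyn
```

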