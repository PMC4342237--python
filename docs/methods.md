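# Methods

## Scope and data model

`mycopan` analyses the relationship between gene content and categorical
phenotypes across a set of bacterial genomes — the setting is the genus
*Mycobacterium* and the polycyclic aromatic hydrocarbon (PAH) degradation
phenotype, but every operation is generic. The substrate is a gene-family ×
genome matrix of non-negative integer counts, with *presence* defined as
count ≥ 1. Family identities are taken as given (the output of an upstream
orthology clustering); the package performs no sequence-level inference.
Phenotypes are closed-vocabulary categorical attributes per strain:
lifestyle (free-living FL, facultatively host-associated FHA, obligately
intracellular OI), growth rate (fast/slow), pathogenicity, and PAH
metabolism (degrading/non-degrading). A transcription of the published
phenotype table for 27 completely sequenced mycobacteria ships as a
packaged fixture; its genome-size/GC/gene-count columns are carried as
metadata and never used in computation.

## Phenotype network and connection strength

Each observed attribute value becomes a node whose members are the strains
carrying it. Nodes from the same attribute partition the strains and are
never adjacent; nodes from different attributes are joined iff they share at
least one member strain. The edge weight is the connection strength

    CS(Gx, Gy) = [ρ(Gx) + ρ(Gy)] × 50,   ρ(Gx) = |Gx ∩ Gy| / |Gx|,

i.e. the mean of the two shared-membership percentages. CS is symmetric,
bounded in [0, 100], equals 100 iff the member sets coincide and 0 iff they
are disjoint. The edge-existence rule is "shared members ≥ 1", equivalently
CS > 0; no threshold is applied. On the 27-strain fixture this reproduces
the published topology exactly: CS(FL, Non-pathogenic) = 100, the
PAH-non-degrading hub with degree 7, and the isolated PAH-degrading node
with degree 3.

One documented discrepancy: the published figure caption describes the four
weak edges as lying in 8.8 < CS < 9.5, but the formula evaluated on the
printed group sizes gives 8.75 (Fast-growing–Pathogenic), 9.03
(Fast-growing–FHA) and 9.52 (both edges into PAH-non-degrading). The
implementation follows the formula verbatim and emits the numeric CS, so
the caption's rounding never affects results.

## Pan/core set algebra

For a genome set S, pan(S) is the union and core(S) the intersection of the
members' family sets; dispensable(S) = pan(S) \ core(S). All derived
operations reduce to this algebra: progressive-addition curves report
pan/core over growing prefixes of a caller-supplied ordering (a helper uses
a tree's left-to-right leaf order, the natural phylogeny-based ordering);
Venn regions over 2–3 group cores are computed by membership tests per
family; unique genes of a focal group against a background are
core(focal) \ pan(background). Cross-tabulations (COG letters, functional
modules RCP/SCP/CAP, HGT × core/dispensable, expression filtering) are
direct per-family classifications over an optional annotation overlay;
unannotated families default to no COG letters, module `none`, hgt false,
expressed false. Multi-label COG families count once per letter, and the
distinct-family total is reported separately, since percentage conventions
differ between the two counting schemes. Genome clustering by count
profiles uses average-linkage agglomeration on Euclidean distances
(scipy), with the deterministic dendrogram leaf order returned.

## Wagner parsimony

Ancestral gene content is reconstructed per family by Wagner parsimony over
integer states 0..max_state. A branch from parent state a to child state b
costs `gain_penalty·max(0, b−a) + loss_penalty·max(0, a−b)`; both penalties
default to 1. The bottom-up dynamic program computes, for every node and
state, the minimal subtree cost (multifurcations handled by summing child
minima); the root takes a cost-minimizing state and a top-down backtrace
assigns each internal node its best state given its parent. Ties are broken
toward the **smaller** state at the root and at every backtrace step — a
deterministic "fewer ancestral genes" policy. Branch lengths are ignored by
the parsimony model; the default character coding is presence/absence even
when counts exceed 1, with count-valued states available via `max_state`.
Per-branch events are reported as (units gained, units lost) keyed by child
node, and `branch_event_summary` aggregates them over named gene groups,
also counting, per node, the groups with at least one member present —
mirroring the usual display of catabolic gene-group history on a tree.

The DP is validated against exhaustive enumeration of all internal-state
assignments on trees with up to 6 leaves (500+ random binary-state
instances across penalty settings in the acceptance suite).

## Trajectory enumeration

With n independent horizontal acquisition events there are n! possible
orderings (5! = 120 for the five transfers assembling a complete PAH
pathway). Epistatic precedence constraints ("a before b") prune this space;
`count_trajectories` enumerates permutations explicitly and counts the
compatible ones, capped at n ≤ 10 and returning 0 with a warning for cyclic
constraint sets. Enumeration rather than a counting formula keeps arbitrary
constraint posets correct by construction.

## Synthetic data generator

The simulator supplies ground-truthed inputs with the structure the
analyses assume, not a fit to any particular dataset:

- **Trees** are pure-birth (Yule) with unit birth rate: with k lineages the
  next split waits Exp(k), a uniformly chosen lineage splits, and a final
  Exp(n) segment extends the pendant branches. Leaves are named g001..gNNN.
- **Gene content** evolves independently per family as a two-state
  presence process: root presence with probability `root_presence_prob`
  (default 0.5), and along a branch of length t an absent family appears
  with probability 1 − exp(−gain_rate·t) and a present one disappears with
  probability 1 − exp(−loss_rate·t). Defaults gain 0.1, loss 0.3 per unit
  branch length give the loss-biased turnover regime in which a large
  dispensable genome accumulates while the core erodes — the qualitative
  behaviour seen in host-adapted lineages. At most one flip occurs per
  family per branch (the exact exponential probability is used, but double
  transitions within a branch are not modelled — a documented limitation,
  adequate at these rates).
- **HGT modules** are blocks of families inserted on a named branch and
  co-inherited by the descending clade, optionally thinned by
  post-insertion loss — emulating the conserved ~150-kb catabolic gene
  clusters of the PAH-degraders.
- **Phenotypes** follow a module-completeness rule: a strain is `degrading`
  iff it carries *every* family of all named catabolic modules (RCP, SCP,
  CAP); partial gene sets leave it a non-degrader, matching the observation
  that non-degraders hold incomplete PAH gene sets. Lifestyle comes from a
  caller-supplied map; growth rate and pathogenicity default to the
  free-living pattern (FL → fast + non-pathogenic) unless overridden.

Every root draw and flip is logged, and replaying the log reproduces the
emitted matrix bit-exactly; all randomness flows from a single integer
seed through `numpy.random.default_rng`, so runs are reproducible across
platforms.

What the generator does **not** emulate: gene copy-number dynamics beyond
presence (simulated counts are 0/1), within-branch multiple hits,
donor-aware transfer (modules appear de novo), genome size and GC
structure, and correlated family evolution outside the inserted modules.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not calibration against real mycobacterial data — the
published strain table is the only real-data input, and only the
phenotype-network results are checked against published values.

## Validation strategy and problem sizes

The test suite checks every set operation against explicit brute-force
membership oracles (500 random matrices up to 500 families × 12 genomes),
the parsimony DP against exhaustive minimisation (500 instances, trees ≤ 6
leaves, penalties 0.5/1/2), planted-module recovery (loss rate 0: the
insertion branch carries exactly the module's gains; loss rate 0.05: the
insertion branch attains the maximum module-gain count in ≥ 95 of 100
seeded replicates on 12-leaf trees with 8-family modules), and the CS
invariants (symmetry, bounds, CS(G,G)=100, same-attribute exclusion) on
1,000 random phenotype tables. These sizes keep the full suite around ten
seconds while exercising every code path the larger published analyses
would use.

## Numerical and degenerate-input choices

- Presence threshold is fixed at count ≥ 1; no fractional "soft core".
- Progressive-curve orderings are caller-supplied; repeated genomes are an
  error rather than silently deduplicated.
- Venn arity is limited to 2–3 groups (matching standard diagrams); more
  groups raise an error.
- `degree_stats` collapses duplicate directed edges, counts a self-loop in
  both degrees, and warns; an empty edge list yields an empty mapping.
- Explicitly unrooted newick input (`[&U]`) is rejected; trees without a
  rooting token are treated as rooted. Internal nodes without labels get
  deterministic preorder ids `node1, node2, ...`.
- Tree round-trips preserve clade sets exactly and branch lengths to
  10⁻⁹ relative tolerance.
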