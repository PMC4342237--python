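# mycopan

Comparative functional pan-genome analysis for sets of bacterial genomes,
built around the genus *Mycobacterium* and the polycyclic aromatic
hydrocarbon (PAH) degradation phenotype. The package is aimed at
microbial comparative genomicists who have (i) a gene-family × genome
presence/count matrix from an orthology clustering, (ii) a table of
categorical phenotypes per strain, and (iii) a rooted phylogeny, and who
want to connect genome dynamics to phenotype evolution.

It provides:

- **Phenotype networks** — one node per phenotype category (e.g. FL,
  Fast-growing, PAH-degrading), an undirected edge wherever two categories
  from different attributes share member strains, weighted by the
  connection strength

  `CS(Gx, Gy) = [ρ(Gx) + ρ(Gy)] × 50`, with `ρ(Gx) = |Gx ∩ Gy| / |Gx|`,

  so CS = 100 means identical membership and CS = 0 disjoint groups;
  node degrees and hub identification come with it.
- **Pan/core set algebra** — pan-, core- and dispensable genomes of any
  genome set or phenotype group, progressive-addition curves, Venn regions
  over group cores, unique genes (`core(focal) \ pan(background)`), and
  COG/functional-module/HGT/expression cross-tabulations.
- **Gene gain/loss on a phylogeny** — Wagner parsimony with configurable
  gain/loss penalties (default 1/1), per-branch event summaries aggregated
  over named gene groups, and enumeration of HGT trajectories under
  precedence constraints (5 unconstrained events → 5! = 120 orderings).
- **A seeded simulator** — Yule trees, per-branch gain/loss evolution of
  gene families with a bit-exact event log, HGT-module insertion on a known
  branch, and module-completeness phenotypes, for ground-truthed testing.

The phenotype table of the 27 completely genome-sequenced mycobacteria is
packaged as a fixture (`mycopan.load_mycobacteria_phenotypes()`).

## Worked example

```python
>>> from mycopan import load_mycobacteria_phenotypes, build_network, node_degree
>>> phen = load_mycobacteria_phenotypes()
>>> len(phen.strains)
27
>>> net = build_network(phen)
>>> sorted(net.node_names)
['FHA', 'FL', 'Fast-growing', 'Non-pathogenic', 'OI', 'PAH-degrading',
 'PAH-non-degrading', 'Pathogenic', 'Slow-growing']
>>> net.cs("FL", "Non-pathogenic")
100.0
>>> node_degree(net, "PAH-non-degrading"), node_degree(net, "PAH-degrading")
(7, 3)
```

The seven free-living strains are exactly the seven non-pathogens, so those
two nodes connect at the maximum CS of 100. PAH-non-degrading is the hub of
the network (degree 7 of a possible 7), while its dichotomy partner
PAH-degrading is the most isolated phenotype (degree 3), touching only the
free-living-centric nodes — the network-level signature of PAH degradation
being confined to a phylogenetically isolated group.

The same analysis from the shell:

```sh
$ mycopan mpn --out mpn_out
mpn: 9 nodes, 20 edges -> mpn_out/
$ cat mpn_out/nodes.tsv
node    size    degree
FHA     18      4
FL      7       4
Fast-growing    8       6
Non-pathogenic  7       4
OI      2       3
PAH-degrading   6       3
PAH-non-degrading       21      7
Pathogenic      20      5
Slow-growing    19      4
```

Counting the orderings in which five HGT events can assemble a pathway,
with epistasis forcing event 1 before 2 before 3:

```sh
$ mycopan trajectories --events 5 --constraint '1<2' --constraint '2<3'
{"n_events": 5, "total": 120, "valid": 20}
```

Other subcommands: `simulate` (seeded synthetic data with event log),
`pangenome`, `curve`, `venn`, `unique-genes`, `crosstab`, `gainloss`
(per-branch Wagner-parsimony events plus an annotated newick), and
`report`. See `mycopan <cmd> --help`.

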