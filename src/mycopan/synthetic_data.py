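"""Synthetic trees, gene-content matrices, and rule-based phenotypes.

The generator emulates the statistical structure the analyses assume: gene
families evolving independently on a rooted tree by per-branch gain and
loss, a horizontally transferred module inserted on a known branch and
co-inherited by the descending clade (mirroring the conserved ~150-kb
catabolic gene clusters of the PAH-degraders), and a phenotype determined
by completeness of the catabolic modules — a strain degrades the substrate
only if it carries *every* family of all three functional modules (RCP,
SCP, CAP), while partial gene sets leave it a non-degrader.

Presence evolves as a two-state process: along a branch of length ``t`` an
absent family appears with probability ``1 - exp(-gain_rate * t)`` and a
present one disappears with probability ``1 - exp(-loss_rate * t)``, with
at most one flip per family per branch.  Every flip is logged, and
replaying the log from the root states reproduces the emitted matrix
bit-exactly — the ground truth for planted-signal tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .data_model import GeneFamilyMatrix, PhenotypeTable, Phylogeny
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "EventLog",
    "simulate_tree",
    "simulate_gene_content",
    "insert_hgt_module",
    "assign_phenotypes",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one gene-content simulation.

    Rates are events per unit branch length; ``hgt_modules`` lists
    ``(branch_id, module_size)`` pairs — each inserts ``module_size`` fresh
    families on the branch above the named node.  The seed fixes all
    randomness end to end.
    """

    n_leaves: int = 27
    n_families: int = 2000
    gain_rate: float = 0.1
    loss_rate: float = 0.3
    root_presence_prob: float = 0.5
    hgt_modules: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValidationError("rates must be non-negative")
        if not 0.0 <= self.root_presence_prob <= 1.0:
            raise ValidationError("root_presence_prob must be in [0, 1]")


@dataclass
class EventLog:
    """Recorded ground truth of a simulation.

    ``root_states`` holds each family's state at the root; ``flips`` maps
    ``(family, child_node_id)`` to ``'gain'`` or ``'loss'`` — the state a
    lineage switches *to* on that branch (1 for gain, 0 for loss).
    ``insertions`` records HGT-module placements as ``(branch, families)``.
    """

    root_states: dict[str, int] = field(default_factory=dict)
    flips: dict[tuple[str, str], str] = field(default_factory=dict)
    insertions: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def replay(self, tree: Phylogeny) -> pd.DataFrame:
        """Recompute the leaf presence matrix from root states and flips."""
        leaves = tree.leaf_names
        fams = sorted(self.root_states)
        out = pd.DataFrame(0, index=fams, columns=leaves, dtype=np.int64)
        for fam in fams:
            state = {tree.root_id: self.root_states[fam]}
            for node in tree.preorder():
                if node == tree.root_id:
                    continue
                s = state[tree.parent(node)]
                ev = self.flips.get((fam, node))
                if ev == "gain":
                    s = 1
                elif ev == "loss":
                    s = 0
                state[node] = s
            for lf in leaves:
                out.at[fam, lf] = state[lf]
        return out


def simulate_tree(n_leaves: int, seed: int) -> Phylogeny:
    """A pure-birth (Yule) rooted binary tree with exponential waiting times.

    Leaves are named ``g001..gNNN`` left to right; branch lengths are the
    simulated waiting times.  Deterministic given the seed.
    """
    if n_leaves < 2:
        raise ValidationError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    root.edge.length = None
    active: list[dendropy.Node] = [root]
    while len(active) < n_leaves:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for node in active:
            node.edge.length = (node.edge.length or 0.0) + dt if node is not root else None
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        children = []
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            children.append(child)
        active.extend(children)
    # grow the final pendant segment so leaves sit on positive-length branches
    dt = rng.exponential(1.0 / n_leaves)
    for node in active:
        if node is not root:
            node.edge.length = (node.edge.length or 0.0) + dt
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(f"g{i:03d}")
    return Phylogeny(tree)


def _flip_prob(rate: float, t: float) -> float:
    return 1.0 - math.exp(-rate * t)


def simulate_gene_content(tree: Phylogeny, config: SimulationConfig
                          ) -> tuple[GeneFamilyMatrix, EventLog]:
    """Evolve presence/absence of ``n_families`` families down the tree.

    Families are independent.  HGT modules listed in the config are then
    inserted with fresh family ids (``hgtNNN_K``), subject to post-insertion
    loss at ``loss_rate`` within the receiving clade.
    """
    rng = np.random.default_rng(config.seed)
    log = EventLog()
    leaves = tree.leaf_names
    fam_ids = [f"f{i:04d}" for i in range(1, config.n_families + 1)]
    data = np.zeros((config.n_families, len(leaves)), dtype=np.int64)
    leaf_pos = {lf: j for j, lf in enumerate(leaves)}
    order = [n for n in tree.preorder() if n != tree.root_id]
    blen = {n: float(tree.branch_length(n) or 0.0) for n in order}
    for i, fam in enumerate(fam_ids):
        root_state = int(rng.random() < config.root_presence_prob)
        log.root_states[fam] = root_state
        state: dict[str, int] = {tree.root_id: root_state}
        for node in order:
            s = state[tree.parent(node)]
            t = blen[node]
            if s == 0:
                if rng.random() < _flip_prob(config.gain_rate, t):
                    s = 1
                    log.flips[(fam, node)] = "gain"
            else:
                if rng.random() < _flip_prob(config.loss_rate, t):
                    s = 0
                    log.flips[(fam, node)] = "loss"
            state[node] = s
        for lf in leaves:
            data[i, leaf_pos[lf]] = state[lf]
    matrix = GeneFamilyMatrix(pd.DataFrame(data, index=fam_ids, columns=leaves))
    for m, (branch, size) in enumerate(config.hgt_modules, start=1):
        module = [f"hgt{m:03d}_{k}" for k in range(1, size + 1)]
        matrix, log = insert_hgt_module(
            matrix, tree, branch, module, log,
            loss_rate=config.loss_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
    return matrix, log


def insert_hgt_module(matrix: GeneFamilyMatrix, tree: Phylogeny, branch: str,
                      module_families: Sequence[str], event_log: EventLog,
                      loss_rate: float = 0.0,
                      seed: int | None = None
                      ) -> tuple[GeneFamilyMatrix, EventLog]:
    """Insert a co-transferred family block on one branch.

    The module becomes present at the named child node and is inherited by
    its whole clade, optionally thinned by post-insertion loss simulation
    at ``loss_rate``.  States of module families outside the clade are left
    as they were (fresh families are absent there).  The insertion and any
    downstream losses are recorded in the event log.
    """
    if branch not in tree.node_ids:
        raise ValidationError(f"unknown branch (child node id): {branch!r}")
    if branch == tree.root_id:
        raise ValidationError("cannot insert on the root (it has no branch)")
    rng = np.random.default_rng(seed)
    leaves = tree.leaf_names
    counts = matrix.counts.copy()
    for fam in module_families:
        if fam not in counts.index:
            counts.loc[fam] = 0
            event_log.root_states.setdefault(fam, 0)
    # clade traversal order under the insertion point
    sub_order = [n for n in tree.preorder()
                 if n != branch and branch in _ancestors(tree, n)]
    blen = {n: float(tree.branch_length(n) or 0.0) for n in sub_order}
    clade_leaves = tree.leaf_set(branch)
    for fam in module_families:
        # drop any previously logged events inside the clade, then re-derive
        for n in sub_order + [branch]:
            event_log.flips.pop((fam, n), None)
        event_log.flips[(fam, branch)] = "gain"
        state: dict[str, int] = {branch: 1}
        for node in sub_order:
            s = state[_parent_in(tree, node)]
            if s == 1 and loss_rate > 0 and rng.random() < _flip_prob(loss_rate, blen[node]):
                s = 0
                event_log.flips[(fam, node)] = "loss"
            state[node] = s
        for lf in leaves:
            if lf in clade_leaves:
                counts.at[fam, lf] = state[lf] if lf != branch else 1
        if branch in leaves:
            counts.at[fam, branch] = 1
    event_log.insertions.append((branch, tuple(module_families)))
    return GeneFamilyMatrix(counts), event_log


def _ancestors(tree: Phylogeny, node: str) -> set[str]:
    out = set()
    p = tree.parent(node)
    while p is not None:
        out.add(p)
        p = tree.parent(p)
    return out


def _parent_in(tree: Phylogeny, node: str) -> str:
    p = tree.parent(node)
    assert p is not None
    return p


def assign_phenotypes(matrix: GeneFamilyMatrix,
                      module_definitions: Mapping[str, Iterable[str]],
                      lifestyle_map: Mapping[str, str],
                      growth_map: Mapping[str, str] | None = None,
                      pathogenicity_map: Mapping[str, str] | None = None
                      ) -> PhenotypeTable:
    """Derive a phenotype table from gene content and a lifestyle map.

    A strain is ``degrading`` iff it carries every family of all the named
    catabolic modules (module-completeness rule); any missing family makes
    it ``non-degrading``.  Lifestyle comes from ``lifestyle_map`` (which
    must cover every genome); growth rate and pathogenicity default to the
    free-living pattern (FL -> fast + non-pathogenic, otherwise slow +
    pathogenic) unless explicit maps are given.
    """
    modules = {name: list(fams) for name, fams in module_definitions.items()}
    for name, fams in modules.items():
        if not fams:
            raise ValidationError(f"module {name!r} is empty")
        unknown = [f for f in fams if f not in matrix.counts.index]
        if unknown:
            raise ValidationError(f"module {name!r} has unknown families: {unknown}")
    all_module_fams = [f for fams in modules.values() for f in fams]
    pres = matrix.presence
    rows = {}
    for genome in matrix.genome_ids:
        if genome not in lifestyle_map:
            raise ValidationError(f"lifestyle_map does not cover leaf {genome!r}")
        lifestyle = lifestyle_map[genome]
        complete = all(pres.at[f, genome] for f in all_module_fams)
        growth = (growth_map or {}).get(
            genome, "fast" if lifestyle == "FL" else "slow")
        patho = (pathogenicity_map or {}).get(
            genome, "non-pathogenic" if lifestyle == "FL" else "pathogenic")
        rows[genome] = {
            "lifestyle": lifestyle,
            "growth_rate": growth,
            "pathogenicity": patho,
            "pah_metabolism": "degrading" if complete else "non-degrading",
        }
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("strain_id")
    return PhenotypeTable(df)
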