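"""Gene gain/loss reconstruction and HGT-trajectory enumeration.

Ancestral gene content is reconstructed with Wagner parsimony: ancestral
states are non-negative integers and a branch from parent state ``a`` to
child state ``b`` costs ``gain_penalty * max(0, b - a) + loss_penalty *
max(0, a - b)``.  A bottom-up dynamic program over states ``0..max_state``
finds the minimum total cost; a top-down backtrace assigns each internal
node a cost-minimizing state, breaking ties toward the smaller state
(fewer ancestral genes) so results are deterministic.  Branch lengths play
no role — this is pure parsimony.

Trajectory enumeration counts the orderings in which a set of HGT events
can occur: with ``n`` events there are ``n!`` orderings in principle
(e.g. 5! = 120 for the five transfers needed for a complete PAH pathway),
and precedence constraints — epistasis forcing one acquisition before
another — prune that space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import GeneFamilyMatrix, Phylogeny
from .errors import ValidationError

__all__ = [
    "ParsimonyResult",
    "BranchEventSummary",
    "TrajectorySpace",
    "wagner_parsimony",
    "branch_event_summary",
    "count_trajectories",
]


@dataclass(frozen=True)
class ParsimonyResult:
    """Most-parsimonious ancestral states and per-branch events for one family."""

    family_id: str
    states: dict[str, int]          # node id -> state (leaves included)
    events: dict[str, tuple[int, int]]  # child node id -> (gains, losses), unit-counted
    total_cost: float

    @property
    def total_gains(self) -> int:
        return sum(g for g, _ in self.events.values())

    @property
    def total_losses(self) -> int:
        return sum(l for _, l in self.events.values())


def wagner_parsimony(tree: Phylogeny, leaf_states: Mapping[str, int],
                     gain_penalty: float = 1.0, loss_penalty: float = 1.0,
                     max_state: int | None = None,
                     family_id: str = "") -> ParsimonyResult:
    """Reconstruct integer ancestral states under Wagner parsimony.

    Parameters
    ----------
    tree:
        Rooted phylogeny; multifurcations are allowed.
    leaf_states:
        Observed non-negative integer state per leaf id.
    gain_penalty, loss_penalty:
        Cost per unit gained/lost on a branch; both must be positive.
    max_state:
        Upper bound of the ancestral state range; defaults to the maximum
        observed leaf state.
    """
    if gain_penalty <= 0 or loss_penalty <= 0:
        raise ValidationError("penalties must be positive")
    leaves = tree.leaf_names
    for lf in leaves:
        if lf not in leaf_states:
            raise ValidationError(f"missing state for leaf {lf!r}")
        if leaf_states[lf] < 0:
            raise ValidationError(f"negative state for leaf {lf!r}")
    if max_state is None:
        max_state = max(leaf_states[lf] for lf in leaves)
    for lf in leaves:
        if leaf_states[lf] > max_state:
            raise ValidationError(
                f"leaf {lf!r} state {leaf_states[lf]} exceeds max_state {max_state}"
            )
    n_states = max_state + 1
    states = np.arange(n_states)
    # trans[a, b]: cost of parent state a -> child state b
    diff = states[None, :] - states[:, None]
    trans = gain_penalty * np.maximum(diff, 0) + loss_penalty * np.maximum(-diff, 0)

    # bottom-up: cost[node][s] = min total cost of the subtree if node has state s
    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            vec = np.full(n_states, np.inf)
            vec[leaf_states[node]] = 0.0
            cost[node] = vec
        else:
            vec = np.zeros(n_states)
            for child in tree.children(node):
                # for each parent state a: min_b trans[a,b] + cost[child][b]
                vec = vec + (trans + cost[child][None, :]).min(axis=1)
            cost[node] = vec

    # top-down backtrace, ties toward the smaller state
    assignment: dict[str, int] = {}
    root = tree.root_id
    assignment[root] = int(np.argmin(cost[root]))  # argmin returns first (smallest)
    for node in tree.preorder():
        if node == root:
            continue
        a = assignment[tree.parent(node)]
        assignment[node] = int(np.argmin(trans[a] + cost[node]))

    events: dict[str, tuple[int, int]] = {}
    for node in tree.preorder():
        if node == root:
            continue
        a = assignment[tree.parent(node)]
        b = assignment[node]
        events[node] = (max(0, b - a), max(0, a - b))
    total = float(cost[root][assignment[root]])
    return ParsimonyResult(family_id, assignment, events, total)


@dataclass(frozen=True)
class BranchEventSummary:
    """Per-branch gain/loss totals aggregated over named gene groups.

    ``branch_events`` maps (child node id, group name) to (gains, losses)
    summed over the group's member families.  ``node_group_presence`` maps
    a node id to the number of groups with at least one member family
    present (reconstructed state >= 1 at internal nodes, observed at tips).
    """

    groups: dict[str, tuple[str, ...]]
    branch_events: dict[tuple[str, str], tuple[int, int]]
    node_group_presence: dict[str, int]
    per_family: dict[str, ParsimonyResult] = field(repr=False, default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = [
            (branch, group, g, l)
            for (branch, group), (g, l) in sorted(self.branch_events.items())
        ]
        return pd.DataFrame(rows, columns=["child_node", "group", "gains", "losses"])


def branch_event_summary(tree: Phylogeny, matrix: GeneFamilyMatrix,
                         groups: Mapping[str, Iterable[str]],
                         gain_penalty: float = 1.0,
                         loss_penalty: float = 1.0,
                         presence_only: bool = True) -> BranchEventSummary:
    """Wagner-parsimony gain/loss events per branch, aggregated by gene group.

    Each family in each group is reconstructed independently (presence/
    absence coding by default); gains and losses are then summed within
    groups per branch.  Leaves of the tree must be matrix genomes.
    """
    known_fams = set(matrix.family_ids)
    clean_groups: dict[str, tuple[str, ...]] = {}
    for name, fams in groups.items():
        fams = tuple(fams)
        if not fams:
            raise ValidationError(f"group {name!r} is empty")
        unknown = [f for f in fams if f not in known_fams]
        if unknown:
            raise ValidationError(f"group {name!r} has unknown families: {unknown}")
        clean_groups[name] = fams
    missing = [lf for lf in tree.leaf_names if lf not in matrix.genome_ids]
    if missing:
        raise ValidationError(f"tree leaves absent from matrix: {missing}")

    per_family: dict[str, ParsimonyResult] = {}
    branch_events: dict[tuple[str, str], tuple[int, int]] = {}
    presence_counts: dict[str, int] = {n: 0 for n in tree.node_ids}
    for gname, fams in clean_groups.items():
        group_present = {n: False for n in tree.node_ids}
        for f in fams:
            if f not in per_family:
                raw = matrix.counts.loc[f]
                if presence_only:
                    leaf_states = {g: int(raw[g] >= 1) for g in tree.leaf_names}
                else:
                    leaf_states = {g: int(raw[g]) for g in tree.leaf_names}
                per_family[f] = wagner_parsimony(
                    tree, leaf_states, gain_penalty, loss_penalty, family_id=f
                )
            res = per_family[f]
            for branch, (g, l) in res.events.items():
                pg, pl = branch_events.get((branch, gname), (0, 0))
                branch_events[(branch, gname)] = (pg + g, pl + l)
            for n, s in res.states.items():
                if s >= 1:
                    group_present[n] = True
        for n, present in group_present.items():
            if present:
                presence_counts[n] += 1
    return BranchEventSummary(clean_groups, branch_events, presence_counts,
                              per_family)


@dataclass(frozen=True)
class TrajectorySpace:
    """Counts of total and constraint-satisfying event orderings."""

    n_events: int
    constraints: frozenset[tuple[int, int]]
    total_orderings: int
    valid_orderings: int


def _has_cycle(n: int, constraints: Iterable[tuple[int, int]]) -> bool:
    adj: dict[int, set[int]] = {i: set() for i in range(1, n + 1)}
    for a, b in constraints:
        adj[a].add(b)
    color = {i: 0 for i in adj}  # 0 unvisited, 1 on stack, 2 done

    def visit(u: int) -> bool:
        color[u] = 1
        for v in adj[u]:
            if color[v] == 1 or (color[v] == 0 and visit(v)):
                return True
        color[u] = 2
        return False

    return any(color[u] == 0 and visit(u) for u in adj)


def count_trajectories(n_events: int,
                       constraints: Iterable[tuple[int, int]] = ()
                       ) -> TrajectorySpace:
    """Count event orderings compatible with precedence constraints.

    Events are labelled ``1..n_events``; a constraint ``(a, b)`` requires
    event ``a`` to occur before event ``b``.  All ``n_events!`` permutations
    are enumerated explicitly, so ``n_events`` is capped at 10.  Cyclic
    constraint sets yield zero valid orderings with a warning.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    if n_events > 10:
        raise ValidationError(
            f"n_events={n_events} exceeds the enumeration cap of 10"
        )
    cons = frozenset((int(a), int(b)) for a, b in constraints)
    for a, b in cons:
        if not (1 <= a <= n_events and 1 <= b <= n_events):
            raise ValidationError(f"constraint ({a}, {b}) out of range 1..{n_events}")
        if a == b:
            raise ValidationError(f"constraint ({a}, {b}) is reflexive")
    total = math.factorial(n_events)
    if _has_cycle(n_events, cons):
        warnings.warn("precedence constraints contain a cycle; no valid orderings",
                      stacklevel=2)
        return TrajectorySpace(n_events, cons, total, 0)
    valid = 0
    for perm in permutations(range(1, n_events + 1)):
        pos = {e: i for i, e in enumerate(perm)}
        if all(pos[a] < pos[b] for a, b in cons):
            valid += 1
    return TrajectorySpace(n_events, cons, total, valid)
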