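"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import random
from itertools import product

import numpy as np
import pandas as pd
import pytest

from mycopan import GeneFamilyMatrix, PhenotypeTable, Phylogeny
from mycopan.data_model import load_mycobacteria_phenotypes


@pytest.fixture(scope="session")
def table1() -> PhenotypeTable:
    return load_mycobacteria_phenotypes()


def make_matrix(data: dict[str, dict[str, int]]) -> GeneFamilyMatrix:
    """Build a matrix from {family: {genome: count}} (missing cells -> 0)."""
    df = pd.DataFrame(data).T.fillna(0).astype(np.int64)
    return GeneFamilyMatrix(df)


def random_matrix(rng: np.random.Generator, n_families: int,
                  n_genomes: int, density: float = 0.5) -> GeneFamilyMatrix:
    counts = (rng.random((n_families, n_genomes)) < density).astype(np.int64)
    # sprinkle some copy numbers > 1
    bumps = rng.random((n_families, n_genomes)) < 0.1
    counts = counts + bumps * counts
    fams = [f"f{i:04d}" for i in range(n_families)]
    gens = [f"g{j:03d}" for j in range(n_genomes)]
    return GeneFamilyMatrix(pd.DataFrame(counts, index=fams, columns=gens))


# ---------------------------------------------------------------------------
# brute-force oracles (explicit membership lists / exhaustive enumeration)


def brute_pan_core(matrix: GeneFamilyMatrix, genomes) -> tuple[set, set]:
    membership = []
    for g in genomes:
        membership.append({f for f in matrix.family_ids
                           if matrix.counts.at[f, g] >= 1})
    pan = set().union(*membership)
    core = set.intersection(*membership)
    return pan, core


def brute_venn(cores: dict[str, set]) -> dict[tuple[str, ...], int]:
    names = list(cores)
    union = set().union(*cores.values())
    regions: dict[tuple[str, ...], int] = {}
    for fam in union:
        key = tuple(sorted(n for n in names if fam in cores[n]))
        regions[key] = regions.get(key, 0) + 1
    return regions


def exhaustive_parsimony_cost(tree: Phylogeny, leaf_states: dict[str, int],
                              gain_penalty: float, loss_penalty: float,
                              max_state: int = 1) -> float:
    """Minimum Wagner cost by enumerating all internal-state assignments."""
    internals = [n for n in tree.postorder() if not tree.is_leaf(n)]

    def trans(a: int, b: int) -> float:
        return gain_penalty * max(0, b - a) + loss_penalty * max(0, a - b)

    best = float("inf")
    for assign in product(range(max_state + 1), repeat=len(internals)):
        states = dict(zip(internals, assign))
        states.update(leaf_states)
        cost = 0.0
        for node in tree.preorder():
            parent = tree.parent(node)
            if parent is not None:
                cost += trans(states[parent], states[node])
        best = min(best, cost)
    return best


def random_tree_newick(n_leaves: int, seed: int,
                       multifurcate: bool = False) -> str:
    """A random rooted tree shape over leaves A, B, C, ... via repeated joins."""
    rnd = random.Random(seed)
    nodes = [chr(ord("A") + i) for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 3 if multifurcate and len(nodes) >= 3 and rnd.random() < 0.4 else 2
        picks = [nodes.pop(rnd.randrange(len(nodes))) for _ in range(k)]
        nodes.append("(" + ",".join(picks) + ")")
    return nodes[0] + ";"
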