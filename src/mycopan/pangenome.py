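"""Pan/core/dispensable set algebra over gene-family content.

The *pan-genome* of a genome set is the union of gene families present in
at least one member; the *core-genome* is the intersection present in every
member; the *dispensable genome* is their difference.  Presence means a
count of at least 1.  On top of the basic algebra this module provides
progressive-addition curves, phenotype-group pan/core, Venn regions over
group cores, unique-gene identification (core of a focal group minus the
pan of a background group), annotation cross-tabulations, per-genome COG
profiles, and profile-based genome clustering.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import FamilyAnnotation, GeneFamilyMatrix, PhenotypeTable
from .errors import ValidationError

__all__ = [
    "PanCoreResult",
    "ProgressiveCurve",
    "CrossTab",
    "pan_core",
    "progressive_curve",
    "group_pan_core",
    "core_venn",
    "unique_genes",
    "functional_breakdown",
    "hgt_contribution",
    "filter_expressed",
    "cog_profile",
    "cluster_genomes_by_profile",
    "COG_LETTER_ORDER",
    "POORLY_CHARACTERIZED",
]

#: Fixed row order for COG-letter cross-tabs and profiles (alphabetical).
COG_LETTER_ORDER = tuple(string.ascii_uppercase)

#: Label used for families without any annotation.
POORLY_CHARACTERIZED = "poorly characterized"


@dataclass(frozen=True)
class PanCoreResult:
    """Pan/core/dispensable families of one genome set."""

    genome_set: frozenset[str]
    pan_families: frozenset[str]
    core_families: frozenset[str]

    @property
    def dispensable_families(self) -> frozenset[str]:
        return self.pan_families - self.core_families

    @property
    def pan_size(self) -> int:
        return len(self.pan_families)

    @property
    def core_size(self) -> int:
        return len(self.core_families)

    @property
    def dispensable_size(self) -> int:
        return len(self.dispensable_families)


@dataclass(frozen=True)
class ProgressiveCurve:
    """Pan/core sizes along a progressive genome addition.

    ``steps`` has one row per added genome with columns ``genome``,
    ``pan_size``, ``core_size`` and ``new_families`` (families the genome
    contributed to the pan-genome of the preceding prefix).
    """

    ordering: tuple[str, ...]
    steps: pd.DataFrame


@dataclass(frozen=True)
class CrossTab:
    """A small labelled contingency table.

    ``table`` holds non-negative integer cells.  ``n_families`` is the
    number of distinct input families; for multi-label rows (COG letters)
    the cell total may exceed it, so both are reported.
    """

    table: pd.DataFrame
    n_families: int

    @property
    def cell_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def proportions(self) -> pd.DataFrame:
        """Cells as percentages of the cell total."""
        total = self.cell_total
        if total == 0:
            return self.table.astype(float)
        return self.table / total * 100.0


def _resolve_genomes(matrix: GeneFamilyMatrix, genomes: Iterable[str]) -> list[str]:
    genomes = list(genomes)
    if not genomes:
        raise ValidationError("genome set must be non-empty")
    known = set(matrix.genome_ids)
    for g in genomes:
        if g not in known:
            raise ValidationError(f"unknown genome id: {g!r}")
    if len(set(genomes)) != len(genomes):
        raise ValidationError("genome set contains duplicates")
    # keep matrix column order for determinism
    gset = set(genomes)
    return [g for g in matrix.genome_ids if g in gset]


def pan_core(matrix: GeneFamilyMatrix, genomes: Iterable[str]) -> PanCoreResult:
    """Pan, core and dispensable families of a genome set."""
    cols = _resolve_genomes(matrix, genomes)
    pres = matrix.presence[cols]
    pan = frozenset(pres.index[pres.any(axis=1)])
    core = frozenset(pres.index[pres.all(axis=1)])
    return PanCoreResult(frozenset(cols), pan, core)


def progressive_curve(matrix: GeneFamilyMatrix,
                      ordering: Sequence[str]) -> ProgressiveCurve:
    """Pan/core dynamics under progressive addition of genomes.

    Step ``k`` reports pan and core sizes over the first ``k`` genomes of
    ``ordering`` plus the number of families the k-th genome is the first
    to contribute.
    """
    cols = list(ordering)
    if len(set(cols)) != len(cols):
        dupes = sorted({g for g in cols if cols.count(g) > 1})
        raise ValidationError(f"ordering repeats genome(s): {dupes}")
    _resolve_genomes(matrix, cols)
    pres = matrix.presence
    pan: set[str] = set()
    core: set[str] | None = None
    rows = []
    for g in cols:
        fams = set(pres.index[pres[g]])
        new = len(fams - pan)
        pan |= fams
        core = fams if core is None else core & fams
        rows.append((g, len(pan), len(core), new))
    steps = pd.DataFrame(rows, columns=["genome", "pan_size", "core_size",
                                        "new_families"])
    steps.index = pd.RangeIndex(1, len(cols) + 1, name="step")
    return ProgressiveCurve(tuple(cols), steps)


def group_pan_core(matrix: GeneFamilyMatrix, phenotypes: PhenotypeTable,
                   attribute: str, value: str) -> PanCoreResult:
    """Pan/core over the strains of one phenotype group.

    The group is the phenotype-table strains holding ``value`` for
    ``attribute``, intersected with the matrix's genomes.
    """
    members = phenotypes.group(attribute, value)
    members &= set(matrix.genome_ids)
    if not members:
        raise ValidationError(
            f"phenotype group {attribute}={value!r} has no members in the matrix"
        )
    return pan_core(matrix, members)


def core_venn(matrix: GeneFamilyMatrix,
              groups: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Venn-region counts over the core-genomes of 2 or 3 genome groups.

    Each region is keyed by the sorted tuple of group names whose cores
    contain its families (and whose excluded groups' cores do not).
    Region counts sum to the size of the union of the cores.
    """
    names = list(groups)
    if len(names) not in (2, 3):
        raise ValidationError(f"core_venn supports 2 or 3 groups, got {len(names)}")
    cores = {name: pan_core(matrix, members).core_families
             for name, members in groups.items()}
    regions: dict[tuple[str, ...], int] = {}
    union = set().union(*cores.values())
    for fam_set, key in _venn_regions(cores):
        regions[key] = len(fam_set)
    assert sum(regions.values()) == len(union)
    return regions


def _venn_regions(cores: Mapping[str, frozenset[str]]):
    from itertools import combinations

    names = list(cores)
    for r in range(len(names), 0, -1):
        for included in combinations(names, r):
            fams = set.intersection(*(set(cores[n]) for n in included))
            for excluded in names:
                if excluded not in included:
                    fams -= cores[excluded]
            yield fams, tuple(sorted(included))


def unique_genes(matrix: GeneFamilyMatrix, focal_group: Iterable[str],
                 background_group: Iterable[str]) -> frozenset[str]:
    """Families in every focal genome and absent from all background genomes.

    This is ``core(focal) \\ pan(background)`` — e.g. the genes found only
    in the core-genome of the PAH-degraders and missing from the whole
    pan-genome of the non-degraders.
    """
    focal = set(focal_group)
    background = set(background_group)
    shared = focal & background
    if shared:
        raise ValidationError(
            f"focal and background groups overlap: {sorted(shared)}"
        )
    core = pan_core(matrix, focal).core_families
    pan_bg = pan_core(matrix, background).pan_families
    return core - pan_bg


def functional_breakdown(families: Iterable[str], annotation: FamilyAnnotation,
                         by: str = "cog_category") -> CrossTab:
    """Tabulate a family set by COG category or functional module.

    With ``by='cog_category'`` each family counts once per COG letter it
    carries (multi-label incidence); families without letters fall under
    ``poorly characterized``.  With ``by='functional_module'`` each family
    counts once, under its module or ``poorly characterized`` when the
    module is ``none``.  ``n_families`` always reports the distinct-family
    total.
    """
    fams = sorted(set(families))
    if not fams:
        raise ValidationError("family set must be non-empty")
    counts: dict[str, int] = {}
    if by == "cog_category":
        for f in fams:
            letters = annotation.cog_letters(f)
            if not letters:
                counts[POORLY_CHARACTERIZED] = counts.get(POORLY_CHARACTERIZED, 0) + 1
            for c in letters:
                counts[c] = counts.get(c, 0) + 1
        order = [c for c in COG_LETTER_ORDER if c in counts]
        if POORLY_CHARACTERIZED in counts:
            order.append(POORLY_CHARACTERIZED)
    elif by == "functional_module":
        for f in fams:
            mod = annotation.module(f)
            label = POORLY_CHARACTERIZED if mod == "none" else mod
            counts[label] = counts.get(label, 0) + 1
        order = [m for m in ("RCP", "SCP", "CAP", "other") if m in counts]
        if POORLY_CHARACTERIZED in counts:
            order.append(POORLY_CHARACTERIZED)
    else:
        raise ValidationError(
            f"'by' must be 'cog_category' or 'functional_module', got {by!r}"
        )
    table = pd.DataFrame({"count": [counts[k] for k in order]}, index=order)
    table.index.name = by
    return CrossTab(table, n_families=len(fams))


def hgt_contribution(matrix: GeneFamilyMatrix, annotation: FamilyAnnotation,
                     genomes: Iterable[str]) -> CrossTab:
    """2x2 partition of a group's pan-genome: {hgt, non-hgt} x {core, dispensable}."""
    result = pan_core(matrix, genomes)
    cells = {("hgt", "core"): 0, ("hgt", "dispensable"): 0,
             ("non-hgt", "core"): 0, ("non-hgt", "dispensable"): 0}
    for f in result.pan_families:
        row = "hgt" if annotation.is_hgt(f) else "non-hgt"
        col = "core" if f in result.core_families else "dispensable"
        cells[(row, col)] += 1
    table = pd.DataFrame(
        [[cells[("hgt", "core")], cells[("hgt", "dispensable")]],
         [cells[("non-hgt", "core")], cells[("non-hgt", "dispensable")]]],
        index=pd.Index(["hgt", "non-hgt"], name="origin"),
        columns=["core", "dispensable"],
    )
    return CrossTab(table, n_families=result.pan_size)


def filter_expressed(families: Iterable[str],
                     annotation: FamilyAnnotation) -> frozenset[str]:
    """Subset of families flagged as expressed (proteomic support)."""
    return frozenset(f for f in families if annotation.is_expressed(f))


def cog_profile(matrix: GeneFamilyMatrix,
                annotation: FamilyAnnotation) -> pd.DataFrame:
    """Per-genome counts of present families per COG letter.

    Returns a genomes x letters DataFrame; letters are ordered
    alphabetically (see :data:`COG_LETTER_ORDER`) and multi-label families
    count in each of their letters.
    """
    letters_used = sorted({c for f in matrix.family_ids
                           for c in annotation.cog_letters(f)})
    cols = [c for c in COG_LETTER_ORDER if c in letters_used]
    prof = pd.DataFrame(0, index=matrix.genome_ids, columns=cols, dtype=np.int64)
    pres = matrix.presence
    for f in matrix.family_ids:
        letters = annotation.cog_letters(f)
        if not letters:
            continue
        present_in = pres.columns[pres.loc[f]]
        for c in letters:
            prof.loc[present_in, c] += 1
    prof.index.name = "genome_id"
    return prof


@dataclass(frozen=True)
class GenomeClustering:
    """Average-linkage clustering of genome count vectors."""

    leaf_order: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix over genome_ids order
    genome_ids: tuple[str, ...]

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]


def cluster_genomes_by_profile(matrix: GeneFamilyMatrix) -> GenomeClustering:
    """Agglomerative clustering of genomes by their family count vectors.

    Uses average linkage on Euclidean distances; the returned leaf order is
    the deterministic dendrogram order.  Restrict the matrix to a family
    subset first to cluster on a signature (e.g. PAH-degradation genes).
    """
    if len(matrix.genome_ids) < 2:
        raise ValidationError("clustering needs at least 2 genomes")
    vectors = matrix.counts.T.to_numpy(dtype=float)
    dist = pdist(vectors, metric="euclidean")
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    ids = tuple(matrix.genome_ids)
    return GenomeClustering(tuple(ids[i] for i in order), link, ids)
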