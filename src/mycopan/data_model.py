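"""Domain types and readers/writers for gene-content and phenotype data.

The package operates on four kinds of input:

* a gene-family x genome integer count matrix (presence = count >= 1),
* a per-strain categorical phenotype table (lifestyle, growth rate,
  pathogenicity, PAH metabolism, optional plasmid flag),
* an optional per-family annotation overlay (COG letters, functional
  module, HGT and expression flags, RHO type),
* a rooted phylogeny whose leaves name genomes.

A transcription of the published phenotype table for the 27 completely
genome-sequenced mycobacteria ships as a packaged fixture and is loaded
with :func:`load_mycobacteria_phenotypes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GeneFamilyMatrix",
    "PhenotypeTable",
    "FamilyAnnotation",
    "Phylogeny",
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation",
    "read_tree",
    "write_tree",
    "load_mycobacteria_phenotypes",
    "LIFESTYLES",
    "GROWTH_RATES",
    "PATHOGENICITIES",
    "PAH_METABOLISMS",
    "FUNCTIONAL_MODULES",
    "RHO_TYPES",
]

# ---------------------------------------------------------------------------
# closed vocabularies

LIFESTYLES = ("FL", "FHA", "OI")
GROWTH_RATES = ("fast", "slow")
PATHOGENICITIES = ("pathogenic", "non-pathogenic")
PAH_METABOLISMS = ("degrading", "non-degrading")
FUNCTIONAL_MODULES = ("RCP", "SCP", "CAP", "other", "none")
RHO_TYPES = ("II", "IV", "V", "X", "none")

PHENOTYPE_ATTRIBUTES = ("lifestyle", "growth_rate", "pathogenicity", "pah_metabolism")

# accepted spellings, canonicalized case-insensitively
_CANON: dict[str, dict[str, str]] = {
    "lifestyle": {v.lower(): v for v in LIFESTYLES},
    "growth_rate": {
        "fast": "fast",
        "slow": "slow",
        "fast-growing": "fast",
        "slow-growing": "slow",
    },
    "pathogenicity": {
        "pathogenic": "pathogenic",
        "non-pathogenic": "non-pathogenic",
        "nonpathogenic": "non-pathogenic",
        "non_pathogenic": "non-pathogenic",
    },
    "pah_metabolism": {
        "degrading": "degrading",
        "non-degrading": "non-degrading",
        "nondegrading": "non-degrading",
        "pah-degrading": "degrading",
        "pah-non-degrading": "non-degrading",
    },
}


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# GeneFamilyMatrix


@dataclass(frozen=True)
class GeneFamilyMatrix:
    """Integer counts of each gene family in each genome.

    ``counts`` is a families x genomes DataFrame of non-negative integers;
    a family is *present* in a genome when its count is >= 1.  All the
    pan/core set algebra downstream needs only presence, but copy numbers
    are preserved for heat-map style analyses.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "family id")
        _check_unique(self.counts.columns, "genome id")
        for fid in self.counts.index:
            if not str(fid).strip():
                raise ValidationError("empty family id")
        for gid in self.counts.columns:
            if not str(gid).strip():
                raise ValidationError("empty genome id")
        if not all(np.issubdtype(dt, np.integer) for dt in self.counts.dtypes):
            raise ValidationError("matrix cells must be integers")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("matrix cells must be non-negative")

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean families x genomes presence table (count >= 1)."""
        return self.counts >= 1

    def families_of(self, genome: str) -> set[str]:
        """Family ids present in one genome."""
        if genome not in self.counts.columns:
            raise ValidationError(f"unknown genome id: {genome!r}")
        col = self.counts[genome]
        return set(col.index[col >= 1])

    def restrict(self, families: Iterable[str] | None = None,
                 genomes: Iterable[str] | None = None) -> "GeneFamilyMatrix":
        """Sub-matrix over the given families and/or genomes (order preserved)."""
        df = self.counts
        if families is not None:
            fams = [f for f in self.family_ids if f in set(families)]
            df = df.loc[fams]
        if genomes is not None:
            gset = set(genomes)
            unknown = gset - set(self.genome_ids)
            if unknown:
                raise ValidationError(f"unknown genome id(s): {sorted(unknown)}")
            df = df[[g for g in self.genome_ids if g in gset]]
        return GeneFamilyMatrix(df.copy())


def read_matrix(path: str | Path) -> GeneFamilyMatrix:
    """Read a gene-family count matrix from TSV.

    First column holds family ids, the header row genome ids.  Blank cells
    become 0.  Non-integer or negative cells raise :class:`ParseError`
    naming the offending row and column.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: matrix needs at least one genome column")
        genome_ids = header[1:]
        _check_unique(genome_ids, "genome id")
        family_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            fid = cells[0].strip()
            if not fid:
                raise ValidationError(f"{path}: empty family id in row {lineno}")
            row: list[int] = []
            for j, cell in enumerate(cells[1:], start=1):
                cell = cell.strip()
                if cell == "":
                    row.append(0)
                    continue
                try:
                    v = int(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-integer cell {cell!r} at row {lineno}, "
                        f"column {header[j] if j < len(header) else j}"
                    ) from None
                if v < 0:
                    raise ParseError(
                        f"{path}: negative count {v} at row {lineno}, "
                        f"column {header[j] if j < len(header) else j}"
                    )
                row.append(v)
            # absent trailing cells are zeros
            row.extend(0 for _ in range(len(genome_ids) - len(row)))
            family_ids.append(fid)
            rows.append(row)
    _check_unique(family_ids, "family id")
    counts = pd.DataFrame(rows, index=family_ids, columns=genome_ids, dtype=np.int64)
    return GeneFamilyMatrix(counts)


def write_matrix(matrix: GeneFamilyMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with a ``family_id`` first column."""
    df = matrix.counts.copy()
    df.index.name = "family_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PhenotypeTable


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-strain categorical phenotype assignments.

    ``table`` is indexed by strain id and carries the four canonical
    attribute columns plus an optional boolean ``plasmid`` column and any
    extra metadata columns (genome size, GC fraction ...) which are ignored
    by all computations.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "strain id")
        missing = [a for a in PHENOTYPE_ATTRIBUTES if a not in self.table.columns]
        if missing:
            raise ValidationError(f"phenotype table missing column(s): {missing}")
        for attr in PHENOTYPE_ATTRIBUTES:
            vocab = set(_CANON[attr].values())
            for strain, value in self.table[attr].items():
                if value not in vocab:
                    raise ValidationError(
                        f"strain {strain!r}: invalid {attr} value {value!r} "
                        f"(expected one of {sorted(vocab)})"
                    )

    @property
    def strains(self) -> list[str]:
        return list(self.table.index)

    def group(self, attribute: str, value: str) -> set[str]:
        """Strain ids holding ``value`` for ``attribute``."""
        if attribute not in PHENOTYPE_ATTRIBUTES:
            raise ValidationError(f"unknown phenotype attribute: {attribute!r}")
        value = _CANON[attribute].get(str(value).strip().lower(), value)
        return set(self.table.index[self.table[attribute] == value])

    def values_of(self, attribute: str) -> list[str]:
        """Observed values of an attribute, in first-appearance order."""
        if attribute not in PHENOTYPE_ATTRIBUTES:
            raise ValidationError(f"unknown phenotype attribute: {attribute!r}")
        return list(dict.fromkeys(self.table[attribute]))


def _canon_value(attr: str, raw: str, strain: str) -> str:
    key = str(raw).strip().lower()
    try:
        return _CANON[attr][key]
    except KeyError:
        raise ValidationError(
            f"strain {strain!r}: unknown {attr} value {raw!r}"
        ) from None


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype table from TSV, canonicalizing vocabulary case."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "strain_id" not in df.columns:
        raise ParseError(f"{path}: missing 'strain_id' column")
    df = df.set_index("strain_id")
    missing = [a for a in PHENOTYPE_ATTRIBUTES if a not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s): {missing}")
    for attr in PHENOTYPE_ATTRIBUTES:
        df[attr] = [
            _canon_value(attr, v, s) for s, v in df[attr].items()
        ]
    if "plasmid" in df.columns:
        truthy = {"1", "true", "yes"}
        falsy = {"0", "false", "no"}
        parsed = []
        for s, v in df["plasmid"].items():
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                parsed.append(pd.NA)
            elif str(v).strip().lower() in truthy:
                parsed.append(True)
            elif str(v).strip().lower() in falsy:
                parsed.append(False)
            else:
                raise ValidationError(f"strain {s!r}: invalid plasmid value {v!r}")
        df["plasmid"] = pd.array(parsed, dtype="boolean")
    return PhenotypeTable(df)


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    df = phenotypes.table.copy()
    df.index.name = "strain_id"
    df.to_csv(path, sep="\t")


def load_mycobacteria_phenotypes() -> PhenotypeTable:
    """The packaged phenotype table of the 27 completely sequenced mycobacteria."""
    ref = resources.files("mycopan") / "data" / "mycobacteria_phenotypes.tsv"
    with resources.as_file(ref) as p:
        return read_phenotypes(p)


# ---------------------------------------------------------------------------
# FamilyAnnotation


_ANNOT_DEFAULT = {
    "cog_categories": "",
    "functional_module": "none",
    "hgt": False,
    "expressed": False,
    "rho_type": "none",
}


@dataclass(frozen=True)
class FamilyAnnotation:
    """Optional per-family functional annotation overlay.

    Families absent from the table take the defaults: no COG letters,
    module ``none``, not horizontally transferred, not expressed, RHO type
    ``none``.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=list(_ANNOT_DEFAULT)).rename_axis("family_id")
    )

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "family id")
        for col in _ANNOT_DEFAULT:
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        for fid, mod in self.table["functional_module"].items():
            if mod not in FUNCTIONAL_MODULES:
                raise ValidationError(f"family {fid!r}: invalid module {mod!r}")
        for fid, rho in self.table["rho_type"].items():
            if rho not in RHO_TYPES:
                raise ValidationError(f"family {fid!r}: invalid RHO type {rho!r}")

    def cog_letters(self, family_id: str) -> tuple[str, ...]:
        if family_id in self.table.index:
            letters = str(self.table.at[family_id, "cog_categories"] or "")
            return tuple(dict.fromkeys(c for c in letters if c.strip()))
        return ()

    def module(self, family_id: str) -> str:
        if family_id in self.table.index:
            return str(self.table.at[family_id, "functional_module"])
        return "none"

    def is_hgt(self, family_id: str) -> bool:
        if family_id in self.table.index:
            return bool(self.table.at[family_id, "hgt"])
        return False

    def is_expressed(self, family_id: str) -> bool:
        if family_id in self.table.index:
            return bool(self.table.at[family_id, "expressed"])
        return False

    def rho_type(self, family_id: str) -> str:
        if family_id in self.table.index:
            return str(self.table.at[family_id, "rho_type"])
        return "none"

    @classmethod
    def from_records(cls, records: Mapping[str, Mapping[str, object]]) -> "FamilyAnnotation":
        """Build from ``{family_id: {column: value, ...}}`` with defaults filled in."""
        rows = {}
        for fid, rec in records.items():
            row = dict(_ANNOT_DEFAULT)
            row.update(rec)
            rows[fid] = row
        df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("family_id")
        if df.empty:
            df = pd.DataFrame(columns=list(_ANNOT_DEFAULT)).rename_axis("family_id")
        return cls(df[list(_ANNOT_DEFAULT)])


def read_annotation(path: str | Path) -> FamilyAnnotation:
    """Read the per-family annotation TSV (hgt/expressed as 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "family_id" not in df.columns:
        raise ParseError(f"{path}: missing 'family_id' column")
    records: dict[str, dict[str, object]] = {}
    for _, row in df.iterrows():
        rec: dict[str, object] = {}
        if "cog_categories" in df.columns:
            rec["cog_categories"] = row["cog_categories"].strip()
        if "functional_module" in df.columns and row["functional_module"].strip():
            rec["functional_module"] = row["functional_module"].strip()
        if "hgt" in df.columns and row["hgt"].strip():
            rec["hgt"] = row["hgt"].strip() in ("1", "true", "True")
        if "expressed" in df.columns and row["expressed"].strip():
            rec["expressed"] = row["expressed"].strip() in ("1", "true", "True")
        if "rho_type" in df.columns and row["rho_type"].strip():
            rec["rho_type"] = row["rho_type"].strip()
        records[row["family_id"]] = rec
    return FamilyAnnotation.from_records(records)


# ---------------------------------------------------------------------------
# Phylogeny


class Phylogeny:
    """A rooted tree over genome identifiers, backed by dendropy.

    Every node carries a stable string id: leaves use their taxon label,
    internal nodes their newick label when given, otherwise generated
    ``nodeK`` ids assigned in preorder.  Branches are keyed by their child
    node id.
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None:
            raise ValidationError("tree has no root")
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        _check_unique(labels, "leaf name")
        # assign stable ids
        used = set(labels)
        counter = 1
        self._ids: dict[dendropy.Node, str] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                self._ids[node] = node.taxon.label
            elif node.label and node.label not in used:
                self._ids[node] = node.label
                used.add(node.label)
            else:
                while f"node{counter}" in used:
                    counter += 1
                self._ids[node] = f"node{counter}"
                used.add(f"node{counter}")
                counter += 1
        self._by_id = {v: k for k, v in self._ids.items()}

    # -- structure -----------------------------------------------------
    @property
    def root_id(self) -> str:
        return self._ids[self._tree.seed_node]

    @property
    def leaf_names(self) -> list[str]:
        """Leaf ids in left-to-right (newick) order."""
        return [self._ids[lf] for lf in self._tree.leaf_node_iter()]

    @property
    def node_ids(self) -> list[str]:
        """All node ids in preorder."""
        return [self._ids[n] for n in self._tree.preorder_node_iter()]

    def is_leaf(self, node_id: str) -> bool:
        return self._node(node_id).is_leaf()

    def children(self, node_id: str) -> list[str]:
        return [self._ids[c] for c in self._node(node_id).child_nodes()]

    def parent(self, node_id: str) -> str | None:
        p = self._node(node_id).parent_node
        return self._ids[p] if p is not None else None

    def postorder(self) -> list[str]:
        return [self._ids[n] for n in self._tree.postorder_node_iter()]

    def preorder(self) -> list[str]:
        return [self._ids[n] for n in self._tree.preorder_node_iter()]

    def branch_length(self, node_id: str) -> float | None:
        """Length of the branch above ``node_id`` (None for the root or unset)."""
        return self._node(node_id).edge.length

    def leaf_set(self, node_id: str) -> frozenset[str]:
        """Leaf ids of the clade rooted at ``node_id``."""
        return frozenset(self._ids[lf] for lf in self._node(node_id).leaf_iter())

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes — the rooted topology signature."""
        return {
            self.leaf_set(self._ids[n])
            for n in self._tree.preorder_internal_node_iter()
        }

    def _node(self, node_id: str) -> dendropy.Node:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise ValidationError(f"unknown tree node: {node_id!r}") from None

    # -- io -------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        if newick.count("(") != newick.count(")"):
            raise ParseError("unbalanced parentheses in newick string")
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="default-rooted",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            if "Duplicate taxon" in str(exc):
                raise ValidationError(f"duplicate leaf names: {exc}") from exc
            raise ParseError(f"could not parse newick: {exc}") from exc
        if not tree.is_rooted:
            raise ValidationError("unrooted trees are not accepted")
        return cls(tree)

    def newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.newick())

    def annotated_newick(self, labels: Mapping[str, str]) -> str:
        """Newick string with internal-node labels replaced from ``labels``.

        Leaf names are never altered; internal nodes without an entry keep
        their existing label (if any).
        """
        import copy as _copy

        t2 = _copy.deepcopy(self._tree)
        for n_old, n_new in zip(self._tree.preorder_node_iter(),
                                t2.preorder_node_iter()):
            if n_new.is_leaf():
                continue
            lab = labels.get(self._ids[n_old])
            if lab is not None:
                n_new.label = lab
        return t2.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted newick tree from a file."""
    text = Path(path).read_text(encoding="utf-8").strip()
    return Phylogeny.from_newick(text)


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n", encoding="utf-8")
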