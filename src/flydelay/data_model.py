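"""Core domain types and readers/writers for every external format.

The pipeline works on four plain-text inputs:

* a gene x sample raw count matrix (TSV, genes in rows),
* a sample design table (CSV: sample, sex in {F, M}, age_days, replicate),
* a gene annotation table (TSV: gene_id, chromosome[, detected, annotated]),
* optionally a gene-set collection (GMT) and an ontology edge list (TSV)
  for term clustering.

Counts are strict non-negative integers; fractional input is rejected, not
rounded, because the intended input is raw read counts.  Sample-to-column
matching is always by name so that design/counts mismatches fail loudly.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, FormatError

SEXES = ("F", "M")
DEFAULT_AGES = (3, 7, 14)

#: Wang-measure edge-weight defaults (standard values; strictly inside (0, 1)).
DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


# ---------------------------------------------------------------------------
# ExpressionMatrix


@dataclass
class ExpressionMatrix:
    """Raw integer counts, genes x samples, with unique ordered labels."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            fractional = values[np.asarray(values, float) != np.floor(np.asarray(values, float))]
            if fractional.size:
                raise FormatError(
                    f"non-integer count {fractional.flat[0]!r}; raw read counts required"
                )
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            g, s = np.argwhere(df.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count {df.iat[g, s]} for gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        df = df.astype(np.int64)
        df.index = df.index.astype(str).rename("gene_id")
        df.columns = df.columns.astype(str).rename(None)
        self.counts = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ConsistencyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.counts[list(sample_ids)].copy())


def read_counts(path) -> ExpressionMatrix:
    """Read a TSV count table: first column gene ids, one column per sample."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise FormatError(f"malformed count table: {exc}") from exc
    if df.empty and df.shape[1] == 0:
        raise FormatError("count table has no sample columns")
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = df.to_numpy()[numeric.isna().to_numpy()][0]
        raise FormatError(f"non-numeric count entry {bad!r}")
    frac = numeric.to_numpy() != np.floor(numeric.to_numpy())
    if frac.any():
        raise FormatError(
            f"non-integer count {numeric.to_numpy()[frac][0]!r}; raw read counts required"
        )
    return ExpressionMatrix(numeric.astype(np.int64))


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# SampleDesign


@dataclass
class SampleDesign:
    """Per-sample sex, age and replicate; defines the sex-age groups.

    The table preserves input sample order.  ``(sex, age_days, replicate)``
    triples must be unique and each sample id appears exactly once.
    """

    table: pd.DataFrame  # columns: sample, sex, age_days, replicate

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample", "sex", "age_days", "replicate"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"design missing columns {missing}")
        if len(t) == 0:
            raise FormatError("design table is empty")
        t = t[required].copy()
        t["sample"] = t["sample"].astype(str)
        t["sex"] = t["sex"].astype(str).str.strip().str.upper().str[:1]
        bad_sex = sorted(set(t["sex"]) - set(SEXES))
        if bad_sex:
            raise FormatError(f"unknown sex token(s) {bad_sex}; expected F or M")
        t["age_days"] = pd.to_numeric(t["age_days"], errors="raise").astype(int)
        t["replicate"] = pd.to_numeric(t["replicate"], errors="raise").astype(int)
        if (t["replicate"] < 1).any():
            raise FormatError("replicate numbers must be positive")
        if t["sample"].duplicated().any():
            dup = t["sample"][t["sample"].duplicated()].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in design")
        triples = t[["sex", "age_days", "replicate"]]
        if triples.duplicated().any():
            dup = tuple(triples[triples.duplicated()].iloc[0])
            raise FormatError(f"duplicate (sex, age, replicate) triple {dup}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def ages(self) -> list[int]:
        return sorted(self.table["age_days"].unique())

    def groups(self) -> dict[tuple[str, int], list[str]]:
        """Partition samples by (sex, age); covers every sample exactly once."""
        out: dict[tuple[str, int], list[str]] = {}
        for row in self.table.itertuples(index=False):
            out.setdefault((row.sex, row.age_days), []).append(row.sample)
        return out

    def samples_for(self, sex: str, age_days: int) -> list[str]:
        return self.groups().get((sex, age_days), [])

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        keep = self.table[self.table["sample"].isin(set(sample_ids))]
        return SampleDesign(keep.copy())

    def check_against(self, matrix: ExpressionMatrix) -> None:
        missing = sorted(set(self.sample_ids) - set(matrix.sample_ids))
        if missing:
            raise ConsistencyError(f"design samples absent from counts: {missing}")


def read_design(path) -> SampleDesign:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("design file is empty") from exc
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeneAnnotation


@dataclass
class GeneAnnotation:
    """Per-gene chromosome plus detected/annotated flags.

    ``detected`` and ``annotated`` default to True; the combination defines
    the enrichment background ("detected annotated genes").
    """

    table: pd.DataFrame  # columns: gene_id, chromosome, detected, annotated

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "gene_id" not in t.columns or "chromosome" not in t.columns:
            raise FormatError("annotation needs gene_id and chromosome columns")
        t["gene_id"] = t["gene_id"].astype(str)
        t["chromosome"] = t["chromosome"].astype(str)
        if (t["chromosome"].str.len() == 0).any():
            raise FormatError("empty chromosome label")
        if t["gene_id"].duplicated().any():
            dup = t["gene_id"][t["gene_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r} in annotation")
        for col in ("detected", "annotated"):
            if col not in t.columns:
                t[col] = True
            else:
                t[col] = t[col].map(_to_bool)
        self.table = t[["gene_id", "chromosome", "detected", "annotated"]].reset_index(drop=True)

    def is_x(self, gene_id: str) -> bool:
        row = self.table[self.table["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return row["chromosome"].iloc[0] == "X"

    @property
    def x_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["chromosome"] == "X", "gene_id"])

    def background(self, x_only: bool = False) -> set[str]:
        """Detected annotated genes, optionally restricted to the X."""
        t = self.table
        mask = t["detected"] & t["annotated"]
        if x_only:
            mask &= t["chromosome"] == "X"
        return set(t.loc[mask, "gene_id"])


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "t", "yes"}
    return bool(v)


def read_annotation(path) -> GeneAnnotation:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("annotation file is empty") from exc
    return GeneAnnotation(df)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ComparisonSpec and the Table-1-style battery

_WITHIN = re.compile(r"^([FM])(\d+)v(\d+)$")
_BETWEEN = re.compile(r"^F(\d+)vM(\d+)$")


@dataclass(frozen=True)
class ComparisonSpec:
    """A named two-group contrast between sex-age groups.

    Orientation convention (recorded in every result): group B over group A.
    Within-sex comparisons are oriented later-age vs earlier-age; between-sex
    comparisons are oriented female vs male, so positive LFC means higher in
    females.
    """

    name: str
    group_a: tuple[str, int]  # (sex, age) — denominator / reference
    group_b: tuple[str, int]  # numerator

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ConfigError(f"comparison {self.name!r}: identical groups")

    @property
    def orientation(self) -> str:
        if self.group_a[0] == self.group_b[0]:
            return "later vs earlier age"
        return "female vs male"

    @classmethod
    def from_name(cls, name: str) -> "ComparisonSpec":
        m = _WITHIN.match(name)
        if m:
            sex, a, b = m.group(1), int(m.group(2)), int(m.group(3))
            # later vs earlier: earlier age is the reference
            return cls(name, (sex, min(a, b)), (sex, max(a, b)))
        m = _BETWEEN.match(name)
        if m:
            fa, ma = int(m.group(1)), int(m.group(2))
            return cls(name, ("M", ma), ("F", fa))  # female vs male
        raise ConfigError(f"unparseable comparison name {name!r}")


def comparison_battery(ages: Iterable[int] = DEFAULT_AGES) -> list[ComparisonSpec]:
    """The full battery: all within-sex age pairs plus all F-age x M-age pairs.

    For the standard three ages this is 6 within-sex + 9 between-sex = 15.
    """
    ages = sorted(ages)
    specs = []
    for sex in SEXES:
        for a, b in itertools.combinations(ages, 2):
            specs.append(ComparisonSpec.from_name(f"{sex}{a}v{b}"))
    for fa in ages:
        for ma in ages:
            specs.append(ComparisonSpec.from_name(f"F{fa}vM{ma}"))
    return specs


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)


@dataclass
class GeneSet:
    set_id: str
    set_name: str
    member_gene_ids: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate set id {dup!r}")
        for s in self.sets:
            if not s.member_gene_ids:
                raise FormatError(f"gene set {s.set_id!r} has no members")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: set_id, description, then member ids, tab-delimited."""
    sets = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: need set_id, description, >=1 member")
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise FormatError(f"GMT line {lineno}: empty member list")
            sets.append(GeneSet(fields[0], fields[1], members))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.set_name, *sorted(s.member_gene_ids)]) + "\n")


# ---------------------------------------------------------------------------
# OntologyDAG


@dataclass
class OntologyDAG:
    """Directed acyclic term graph with edge-relation weights.

    Edges point child -> parent.  Relation weights are the Wang-measure
    contribution factors, strictly between 0 and 1.
    """

    graph: nx.DiGraph
    relation_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATION_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for rel, w in self.relation_weights.items():
            if not 0.0 < w < 1.0:
                raise ConfigError(f"relation weight for {rel!r} must be in (0, 1), got {w}")
        for child, parent, data in self.graph.edges(data=True):
            rel = data.get("relation")
            if rel not in self.relation_weights:
                raise ConfigError(f"no weight configured for relation {rel!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"ontology contains a cycle: {cycle}")

    @property
    def term_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> list[tuple[str, float]]:
        """(parent, weight) pairs for the term's outgoing edges."""
        return [
            (p, self.relation_weights[d["relation"]])
            for _, p, d in self.graph.out_edges(term, data=True)
        ]


def read_ontology(path, relation_weights: dict[str, float] | None = None) -> OntologyDAG:
    """Read a 3-column TSV edge list: child, parent, relation."""
    g = nx.DiGraph()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"ontology line {lineno}: expected 3 fields, got {len(fields)}")
            child, parent, relation = fields
            g.add_edge(child, parent, relation=relation)
    weights = dict(DEFAULT_RELATION_WEIGHTS)
    if relation_weights:
        weights.update(relation_weights)
    return OntologyDAG(g, weights)


def write_ontology(dag: OntologyDAG, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for child, parent, data in dag.graph.edges(data=True):
            fh.write(f"{child}\t{parent}\t{data['relation']}\n")
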