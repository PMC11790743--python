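"""Enrichment statistics: X-chromosome Fisher tests, gene-set
over-representation, Wang semantic similarity over an ontology DAG, and
hierarchical clustering of terms and of LFC profiles.

The enrichment tests are one-sided ("greater") by default, matching the
over-representation question; two-sided is available.  The g:SCS-style
correction of web enrichment tools is not reimplemented — BH stands in,
stated in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_model import GeneAnnotation, GeneSetCollection, OntologyDAG
from .de import adjust_bh
from .errors import ConfigError, EstimationError

MULTIPLE_TESTING_NOTE = "BH adjustment (g:SCS-style correction not reimplemented)"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d): query&category, query-only, category-only, neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigError("contingency cells must be nonnegative")

    @property
    def query_size(self) -> int:
        return self.a + self.b

    @property
    def category_size(self) -> int:
        return self.a + self.c

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    query_size: int
    set_size: int
    background_size: int
    odds_ratio: float  # np.inf sentinel on a zero denominator
    p_raw: float
    p_adj: float = np.nan


def fisher_2x2(table: ContingencyTable2x2, alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test; returns (odds ratio ad/bc, p).

    The odds ratio gets an ``inf`` sentinel when b*c == 0 and a*d > 0, and
    NaN when both products are zero.
    """
    if alternative not in {"greater", "two-sided", "less"}:
        raise ConfigError(f"unknown alternative {alternative!r}")
    arr = [[table.a, table.b], [table.c, table.d]]
    _, p = stats.fisher_exact(arr, alternative=alternative)
    num, den = table.a * table.d, table.b * table.c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = np.inf
    else:
        odds = np.nan
    return odds, float(p)


def make_table(query: set, category: set, background: set) -> ContingencyTable2x2:
    if not query <= background:
        raise ConfigError("query must be a subset of the background")
    cat = category & background
    a = len(query & cat)
    return ContingencyTable2x2(a, len(query) - a, len(cat) - a, len(background) - len(query | cat))


def x_enrichment(
    deg_genes: set,
    annotation: GeneAnnotation,
    background: set | None = None,
    alternative: str = "greater",
) -> EnrichmentResult:
    """X-linkage enrichment of a DEG set over the detected-annotated background.

    Genes missing from the annotation are excluded (their count is exposed
    via the background intersection).
    """
    if background is None:
        background = annotation.background()
    annotated = set(annotation.table["gene_id"])
    background = set(background) & annotated
    query = set(deg_genes) & background
    table = make_table(query, annotation.x_genes, background)
    odds, p = fisher_2x2(table, alternative)
    return EnrichmentResult(
        set_id="X_chromosome",
        overlap=table.a,
        query_size=table.query_size,
        set_size=table.category_size,
        background_size=table.total,
        odds_ratio=odds,
        p_raw=p,
    )


def ora(
    query: set,
    sets: GeneSetCollection,
    background: set,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Over-representation of a query list against each gene set, BH-adjusted.

    Sets with no background presence are skipped.  Results are sorted by
    raw p (ties by set id) for stable reporting.
    """
    if not background:
        raise ConfigError("empty background")
    query = set(query) & set(background)
    results = []
    for s in sets:
        members = s.member_gene_ids & set(background)
        if not members:
            continue
        table = make_table(query, members, set(background))
        odds, p = fisher_2x2(table, alternative)
        results.append(
            EnrichmentResult(
                set_id=s.set_id,
                overlap=table.a,
                query_size=table.query_size,
                set_size=table.category_size,
                background_size=table.total,
                odds_ratio=odds,
                p_raw=p,
            )
        )
    if results:
        adj = adjust_bh([r.p_raw for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
    results.sort(key=lambda r: (r.p_raw, r.set_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    df.attrs["multiple_testing"] = MULTIPLE_TESTING_NOTE
    return df


# ---------------------------------------------------------------------------
# Wang semantic similarity


def _svalues(dag: OntologyDAG, term: str) -> dict[str, float]:
    """S-values of a term's ancestor closure (term itself included, S=1).

    S(t) for an ancestor t is the maximum over edges (c -> t) on paths from
    the term of weight(c -> t) * S(c), computed by dynamic programming
    upward from the term.
    """
    if term not in dag:
        raise KeyError(f"term {term!r} not in ontology")
    s: dict[str, float] = {term: 1.0}
    frontier = [term]
    while frontier:
        nxt = []
        for node in frontier:
            for parent, weight in dag.parents(node):
                cand = weight * s[node]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return s


def wang_similarity(dag: OntologyDAG, term_a: str, term_b: str) -> float:
    """Wang graph-based semantic similarity in [0, 1].

    sim = sum over shared ancestors t of (S_A(t) + S_B(t)) divided by
    (SV(A) + SV(B)), where SV is the sum of a term's S-values.  Identical
    terms give 1; terms with disjoint ancestor closures give 0.
    """
    sa = _svalues(dag, term_a)
    sb = _svalues(dag, term_b)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    return float(sum(sa[t] + sb[t] for t in shared) / (sum(sa.values()) + sum(sb.values())))


def similarity_matrix(dag: OntologyDAG, terms: list[str]) -> pd.DataFrame:
    """Symmetric term-term Wang similarity matrix with unit diagonal."""
    svals = {t: _svalues(dag, t) for t in terms}
    svsums = {t: sum(svals[t].values()) for t in terms}
    n = len(terms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = svals[terms[i]], svals[terms[j]]
            shared = set(sa) & set(sb)
            val = (
                sum(sa[t] + sb[t] for t in shared) / (svsums[terms[i]] + svsums[terms[j]])
                if shared
                else 0.0
            )
            sim[i, j] = sim[j, i] = val
    return pd.DataFrame(sim, index=terms, columns=terms)


def cluster_terms(
    similarity: pd.DataFrame, k: int = 9, linkage_method: str = "average"
) -> pd.Series:
    """Cut an agglomerative clustering of 1 - similarity into k clusters.

    Average linkage by default (Ward is available for the LFC heatmaps).
    scipy's deterministic nearest-neighbor-chain ordering fixes tie-breaks.
    """
    terms = list(similarity.index)
    if k > len(terms):
        raise ConfigError(f"k={k} exceeds the {len(terms)} terms")
    if k == len(terms):
        return pd.Series(range(1, k + 1), index=terms, name="cluster")
    dist = 1.0 - similarity.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=terms, name="cluster")


# ---------------------------------------------------------------------------
# LFC heatmap clustering


def cluster_genes(lfc_matrix: pd.DataFrame) -> dict:
    """Ward clustering of genes on Euclidean distance over LFC profiles.

    NaN rows are excluded (their ids are reported).  Returns the linkage,
    leaf order, and the row-reordered matrix for heatmap export.
    """
    finite = lfc_matrix.dropna(axis=0, how="any")
    if finite.shape[0] < 2:
        raise EstimationError("need >= 2 genes with finite LFC profiles")
    linkage = hierarchy.linkage(finite.to_numpy(), method="ward")
    order = hierarchy.leaves_list(linkage)
    return {
        "linkage": linkage,
        "leaf_order": [finite.index[i] for i in order],
        "ordered_matrix": finite.iloc[order],
        "excluded": [g for g in lfc_matrix.index if g not in finite.index],
    }
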