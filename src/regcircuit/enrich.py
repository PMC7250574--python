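"""Hypergeometric term enrichment over a gene-annotation ontology.

Annotations follow the true-path rule: a gene annotated to a term is
annotated to all of the term's ancestors.  Term frequencies p(t) are
computed over the annotated universe, information content is
IC(t) = -ln p(t), and semantic similarity between two terms is SimRel:

    simrel(a, b) = (2 * IC(MICA) / (IC(a) + IC(b))) * (1 - p(MICA))

where MICA is the common ancestor with maximal IC.  Redundancy among
significant terms is reduced by a greedy sweep in ascending p-value:
a term starts a new family iff its similarity to every existing family
representative is below the cutoff, otherwise it joins its most similar
representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Ontology",
    "AnnotationMap",
    "propagate",
    "enrich",
    "simrel",
    "reduce_terms",
    "read_ontology_tsv",
    "read_gene2term_tsv",
    "write_ontology_tsv",
    "write_gene2term_tsv",
]


class Ontology:
    """DAG of terms; edges point child -> parent."""

    def __init__(self, edges: Iterable[tuple[str, str]], names: Optional[Mapping[str, str]] = None):
        self.graph = nx.DiGraph()
        for child, parent in edges:
            self.graph.add_edge(child, parent)
        self.names = dict(names or {})
        try:
            cycle = nx.find_cycle(self.graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self._anc_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term)) if term in self.graph else set()

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term``, excluding the term itself."""
        if term not in self._anc_cache:
            anc = nx.descendants(self.graph, term) if term in self.graph else set()
            self._anc_cache[term] = frozenset(anc)
        return self._anc_cache[term]

    def roots(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)


@dataclass
class AnnotationMap:
    """Gene-to-term map after ancestor propagation, with term frequencies."""

    gene2terms: dict[str, frozenset[str]]
    term2genes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term2genes:
            acc: dict[str, set[str]] = {}
            for gene, terms in self.gene2terms.items():
                for t in terms:
                    acc.setdefault(t, set()).add(gene)
            self.term2genes = {t: frozenset(g) for t, g in acc.items()}

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.gene2terms)

    def p(self, term: str) -> float:
        """Term frequency |genes(term)| / |annotated universe|."""
        n = len(self.gene2terms)
        if n == 0:
            return 0.0
        return len(self.term2genes.get(term, ())) / n

    def ic(self, term: str) -> float:
        p = self.p(term)
        return float(-np.log(p)) if p > 0 else float("inf")


def propagate(ontology: Ontology, raw_annotations: Mapping[str, Iterable[str]]) -> AnnotationMap:
    """Close raw gene-to-term annotations over the ancestor relation."""
    gene2terms = {}
    for gene, terms in raw_annotations.items():
        closed: set[str] = set()
        for t in terms:
            closed.add(t)
            closed |= ontology.ancestors(t)
        gene2terms[gene] = frozenset(closed)
    return AnnotationMap(gene2terms)


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    ann: AnnotationMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every annotated term.

    P(X >= k) for k query genes among K universe genes carrying the term,
    with a query of size n drawn from a universe of size N.  BH FDR is
    applied across the tested terms; terms with K = 0 are skipped.
    """
    query = set(query)
    universe = set(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes absent from universe: {stray}")
    N = len(universe)
    n = len(query)
    rows = []
    for term in sorted(ann.term2genes):
        genes_t = ann.term2genes[term] & universe
        K = len(genes_t)
        if K == 0:
            continue
        members = sorted(genes_t & query)
        k = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term, k, K, n, N, p, ",".join(members)))
    out = pd.DataFrame(
        rows, columns=["term_id", "k", "K", "n", "N", "p_value", "member_genes"]
    )
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] <= alpha
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def simrel(a: str, b: str, ann: AnnotationMap, ontology: Ontology) -> float:
    """SimRel semantic similarity in [0, 1); 0 without a common ancestor."""
    ca = (ontology.ancestors(a) | {a}) & (ontology.ancestors(b) | {b})
    ca = {t for t in ca if ann.p(t) > 0}
    if not ca:
        return 0.0
    mica = max(ca, key=lambda t: (ann.ic(t), t))
    denom = ann.ic(a) + ann.ic(b)
    if denom == 0:
        return 0.0
    return (2.0 * ann.ic(mica) / denom) * (1.0 - ann.p(mica))


def reduce_terms(
    results: pd.DataFrame,
    ann: AnnotationMap,
    ontology: Ontology,
    cutoff: float = 0.4,
    only_significant: bool = True,
) -> pd.DataFrame:
    """Greedy SimRel redundancy reduction of enrichment results.

    Terms are swept in ascending p-value (ties by term id); a term becomes
    a new family representative iff its similarity to every existing
    representative is <= cutoff, otherwise it joins its most similar
    representative.  Returns one row per term with its representative and
    the family rank (0 = most significant family).
    """
    df = results
    if only_significant and "significant" in df:
        df = df[df["significant"]]
    df = df.drop_duplicates("term_id").sort_values(
        ["p_value", "term_id"], kind="stable"
    )
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for term in df["term_id"]:
        sims = [(simrel(term, r, ann, ontology), r) for r in reps]
        if not sims or max(s for s, _ in sims) <= cutoff:
            reps.append(term)
            assignment[term] = term
        else:
            best = max(sims, key=lambda sr: (sr[0], -reps.index(sr[1])))
            assignment[term] = best[1]
    rank = {r: i for i, r in enumerate(reps)}
    out = df[["term_id", "p_value"]].copy()
    out["representative"] = [assignment[t] for t in out["term_id"]]
    out["family_rank"] = [rank[assignment[t]] for t in out["term_id"]]
    return out.reset_index(drop=True)


def family_tree(families: pd.DataFrame) -> dict:
    """Three-level vertex -> family representative -> member terms tree."""
    tree: dict[str, list[str]] = {}
    for rep, grp in families.groupby("representative", sort=True):
        tree[rep] = sorted(grp["term_id"])
    return {"all_terms": tree}


# ---------------------------------------------------------------------------
# I/O


def read_ontology_tsv(path: str | Path) -> Ontology:
    """Parent-edge TSV with columns child, parent, name (name of child)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = list(zip(df["child"], df["parent"]))
    names = dict(zip(df["child"], df.get("name", df["child"])))
    return Ontology(edges, names)


def write_ontology_tsv(ontology: Ontology, path: str | Path) -> None:
    rows = sorted(
        (c, p, ontology.names.get(c, c)) for c, p in ontology.graph.edges
    )
    pd.DataFrame(rows, columns=["child", "parent", "name"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene2term_tsv(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_gene2term_tsv(raw: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = sorted((g, t) for g, terms in raw.items() for t in terms)
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)
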