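"""GO-based functional evaluation of predicted triplets.

A predicted triplet is called *putative* when its three genes share at
least one Biological Process annotation after ancestor expansion; the
fraction of putative triplets among those whose three genes are all
annotated (N_putative / N_all) measures prediction accuracy.  Because
pathway members are often annotated at different granularity, each gene's
term set is expanded with ontology ancestors, but only down to a minimum
depth under the root (default 4) so that near-root, uninformative terms do
not inflate sharing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyGraph",
    "OntologyFormatError",
    "UndefinedAccuracyError",
    "read_ontology",
    "read_annotations",
    "expand_annotations",
    "call_putative",
    "accuracy",
    "accuracy_by_bin",
    "cumulative_accuracy",
]

BIOLOGICAL_PROCESS = "biological_process"


class OntologyFormatError(ValueError):
    """Raised for structurally invalid ontologies (e.g. is_a cycles)."""


class UndefinedAccuracyError(ValueError):
    """Raised when no triplet has all three genes annotated."""


@dataclass
class OntologyGraph:
    """An is_a DAG of ontology terms with per-term namespace and depth.

    ``depth`` is the minimum number of is_a edges from the term's namespace
    root (roots have depth 0); minimum path length is used because a term
    in a DAG can be reached along paths of different lengths.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str]
    depth: dict[str, int]
    roots: set[str] = field(default_factory=set)

    def ancestors(self, term: str) -> set[str]:
        """All transitive is_a ancestors of ``term`` (excluding itself)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        return out


def read_ontology(source) -> OntologyGraph:
    """Parse an OBO stream into an is_a DAG with depths.

    Only is_a edges are kept; obsolete terms are dropped.  Terms without
    is_a parents are namespace roots (depth 0).
    """
    import networkx as nx
    import obonet

    g = obonet.read_obo(source)  # child -> parent MultiDiGraph, skips obsolete
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        terms.add(node)
        namespace[node] = data.get("namespace", BIOLOGICAL_PROCESS)
        parents[node] = set()
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    dag = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    dag.add_nodes_from(terms)
    if not nx.is_directed_acyclic_graph(dag):
        raise OntologyFormatError("is_a cycle detected")
    roots = {t for t in terms if not parents[t]}
    # BFS down from the roots over reversed edges gives minimum depths
    children: dict[str, set[str]] = {t: set() for t in terms}
    for c, ps in parents.items():
        for p in ps:
            children[p].add(c)
    depth: dict[str, int] = {r: 0 for r in roots}
    frontier = list(roots)
    while frontier:
        nxt = []
        for t in frontier:
            for ch in children[t]:
                if ch not in depth:
                    depth[ch] = depth[t] + 1
                    nxt.append(ch)
        frontier = nxt
    return OntologyGraph(
        terms=terms, parents=parents, namespace=namespace, depth=depth, roots=roots
    )


def read_annotations(source, namespace_column: bool | None = None) -> dict[str, set[str]]:
    """Read a gene -> term table (gene2go-style TSV).

    Expects columns ``gene_id`` and ``term_id`` (header optional extras are
    ignored); returns the raw, unexpanded annotation map.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "term_id" not in df.columns:
        raise ValueError("annotation table needs gene_id and term_id columns")
    raw: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        raw.setdefault(gene, set()).add(term)
    return raw


def expand_annotations(
    raw: dict[str, set[str]],
    g: OntologyGraph,
    min_depth: int = 4,
    namespace: str = BIOLOGICAL_PROCESS,
) -> dict[str, set[str]]:
    """Expand each gene's terms with ancestors at depth >= ``min_depth``.

    Direct annotations in the chosen namespace are always kept (roots
    excluded); ancestors shallower than ``min_depth`` — the most generic
    levels under the root — are suppressed.  Unknown terms are skipped with
    a logged count.  The operation is idempotent.
    """
    skipped = 0
    out: dict[str, set[str]] = {}
    for gene, terms in raw.items():
        expanded: set[str] = set()
        for term in terms:
            if term not in g.terms:
                skipped += 1
                continue
            if g.namespace.get(term) != namespace or term in g.roots:
                continue
            expanded.add(term)
            for anc in g.ancestors(term):
                if anc in g.roots:
                    continue
                if g.namespace.get(anc) != namespace:
                    continue
                if g.depth.get(anc, 0) >= min_depth:
                    expanded.add(anc)
        out[gene] = expanded
    if skipped:
        logger.warning("expand_annotations: skipped %d unknown terms", skipped)
    return out


def _labels(results, ann: dict[str, set[str]]) -> list[str]:
    labels = []
    for r in results:
        sets = [ann.get(g, set()) for g in (r.gene_a, r.gene_b, r.gene_c)]
        if any(not s for s in sets):
            labels.append("unannotated")
        elif sets[0] & sets[1] & sets[2]:
            labels.append("putative")
        else:
            labels.append("non-putative")
    return labels


def call_putative(results, ann: dict[str, set[str]]) -> list[str]:
    """Label each triplet putative / non-putative / unannotated.

    Putative means the three expanded term sets share at least one term;
    unannotated triplets (some gene with an empty set) are excluded from
    accuracy denominators.
    """
    return _labels(results, ann)


def accuracy(results, ann: dict[str, set[str]]) -> float:
    """N_putative / N_all over triplets with all three genes annotated."""
    labels = _labels(results, ann)
    n_ann = sum(lab != "unannotated" for lab in labels)
    if n_ann == 0:
        raise UndefinedAccuracyError("no triplet has all three genes annotated")
    n_put = sum(lab == "putative" for lab in labels)
    return n_put / n_ann


_BIN_EDGE_TOL = 1e-9


def _bin_index(du: float, width: float) -> int:
    # values within 1e-9 of an upper bin edge are assigned to the next
    # (half-open) bin, so exact multiples of the width start a new bin
    return int(np.floor(du / width + _BIN_EDGE_TOL))


def accuracy_by_bin(
    results, ann: dict[str, set[str]], bin_width: float = 0.05
) -> pd.DataFrame:
    """Per-bin triplet counts and accuracy over half-open dU bins [x, x+w).

    Bins are labelled by their centre, so with the default width the bin
    centred at 0.125 covers dU in [0.10, 0.15).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    labels = _labels(results, ann)
    stats: dict[int, list[int]] = {}
    for r, lab in zip(results, labels):
        idx = _bin_index(r.delta_u, bin_width)
        n, n_ann, n_put = stats.setdefault(idx, [0, 0, 0])
        stats[idx][0] = n + 1
        if lab != "unannotated":
            stats[idx][1] = n_ann + 1
            if lab == "putative":
                stats[idx][2] = n_put + 1
    rows = []
    for idx in sorted(stats):
        n, n_ann, n_put = stats[idx]
        rows.append(
            {
                "bin_center": round((idx + 0.5) * bin_width, 10),
                "n_triplets": n,
                "n_annotated": n_ann,
                "n_putative": n_put,
                "accuracy": (n_put / n_ann) if n_ann else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["bin_center", "n_triplets", "n_annotated", "n_putative", "accuracy"],
    )


def cumulative_accuracy(results, ann: dict[str, set[str]], top_k: int) -> pd.DataFrame:
    """Cumulative putative fraction along the descending-dU ranking.

    At each rank r <= ``top_k`` the fraction of putative triplets among the
    annotated triplets seen so far is reported; the curve truncates at the
    number of available results.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ordered = sorted(
        results,
        key=lambda r: (-r.delta_u, r.gene_a, r.gene_b, r.gene_c, r.type_id),
    )[:top_k]
    labels = _labels(ordered, ann)
    rows = []
    n_ann = n_put = 0
    for rank, (r, lab) in enumerate(zip(ordered, labels), start=1):
        if lab != "unannotated":
            n_ann += 1
            if lab == "putative":
                n_put += 1
        rows.append(
            {
                "rank": rank,
                "delta_u": round(r.delta_u, 6),
                "n_annotated": n_ann,
                "n_putative": n_put,
                "cumulative_accuracy": (n_put / n_ann) if n_ann else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["rank", "delta_u", "n_annotated", "n_putative", "cumulative_accuracy"],
    )
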