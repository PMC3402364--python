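"""Triplet enumeration, scoring, ranking and export.

The hypothesis space for three distinct genes contains, per choice of the
output gene c, one hypothesis for each symmetric logic type and two ordered
hypotheses for each of the order-sensitive types (a AND NOT b, NOT a OR b):
3 x (6 + 2*2) = 30 hypotheses with all eight types enabled.

Two filters from the method's operating point are applied before scoring:
profiles must carry at least ``min_state_count`` genomes in each of their
two states (applied at the matrix level), and each of the four ab
coevolution cells of a hypothesis's input pair must hold at least
``min_scenario_count`` genomes.  A hypothesis is reported under the member
of its complement pair whose truth table agrees with c on more than half of
the (weighted) mass; at exactly half, both members are suppressed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .logic import (
    LOGIC_TYPES,
    INPUT_NEGATION,
    DegenerateTargetError,
    ScenarioCounts,
    balance,
    _score_weights,
)
from .profile_matrix import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "TripletHypothesis",
    "TripletResult",
    "enumerate_hypotheses",
    "score_triplet",
    "search",
    "permutation_null",
    "scenario_imbalance_summary",
    "results_table",
    "export_results",
    "read_results",
    "build_graph",
    "export_graph",
]

RESULT_COLUMNS = (
    ["gene_a", "gene_b", "gene_c", "type_id", "order_flag"]
    + ["delta_u", "u_cf", "u_ca", "u_cb", "agreement"]
    + [f"n{i}{j}{k}" for i in range(2) for j in range(2) for k in range(2)]
    + ["significant"]
)


@dataclass(frozen=True)
class SearchConfig:
    """Operating point of a triplet search.

    Defaults mirror the method's published settings for 182 genomes:
    state/scenario minima of 18 genomes, significance at dU >= 0.3,
    reporting from dU >= 0.1, balanced weighting on.
    """

    min_state_count: int = 18
    min_scenario_count: int = 18
    du_threshold: float = 0.3
    balanced: bool = True
    types: frozenset[int] = frozenset(range(1, 9))
    gene_subset: tuple[str, ...] | None = None
    report_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.min_state_count < 0 or self.min_scenario_count < 0:
            raise ValueError("count thresholds must be non-negative")
        if not -1 <= self.du_threshold <= 1:
            raise ValueError("du_threshold must lie in [-1, 1]")
        bad = set(self.types) - set(LOGIC_TYPES)
        if bad:
            raise ValueError(f"unknown logic types: {sorted(bad)}")
        object.__setattr__(self, "types", frozenset(self.types))
        if self.gene_subset is not None:
            object.__setattr__(self, "gene_subset", tuple(self.gene_subset))


@dataclass(frozen=True)
class TripletHypothesis:
    """An assignment of three genes to roles: output c <- f(a, b)."""

    gene_c: str
    gene_a: str
    gene_b: str
    type_id: int

    def __post_init__(self) -> None:
        if len({self.gene_a, self.gene_b, self.gene_c}) != 3:
            raise ValueError("hypothesis requires three distinct genes")


@dataclass
class TripletResult:
    """One scored and disambiguated (c, type, order) hypothesis."""

    gene_a: str
    gene_b: str
    gene_c: str
    type_id: int
    delta_u: float
    u_cf: float
    u_ca: float
    u_cb: float
    agreement: float
    counts: ScenarioCounts
    balanced: bool
    significant: bool

    @property
    def hypothesis(self) -> TripletHypothesis:
        return TripletHypothesis(self.gene_c, self.gene_a, self.gene_b, self.type_id)


def enumerate_hypotheses(
    genes, types=frozenset(range(1, 9))
) -> list[TripletHypothesis]:
    """All role assignments of three distinct genes for the given types.

    For symmetric types the input pair is listed in lexicographic order;
    the order-sensitive types contribute both orders.
    """
    genes = list(genes)
    if len(genes) != 3 or len(set(genes)) != 3:
        raise ValueError("exactly three distinct genes required")
    out: list[TripletHypothesis] = []
    for c in genes:
        x, y = sorted(g for g in genes if g != c)
        for tid in sorted(types):
            if LOGIC_TYPES[tid].symmetric:
                out.append(TripletHypothesis(c, x, y, tid))
            else:
                out.append(TripletHypothesis(c, x, y, tid))
                out.append(TripletHypothesis(c, y, x, tid))
    return out


def _count_tensor(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    code = 4 * p1.astype(np.int64) + 2 * p2.astype(np.int64) + p3.astype(np.int64)
    return np.bincount(code, minlength=8).reshape(2, 2, 2)


def _score_hypotheses(
    tensor: np.ndarray,
    gene_order: tuple[str, str, str],
    hypotheses: list[TripletHypothesis],
    cfg: SearchConfig,
) -> list[TripletResult]:
    """Score hypotheses from a precomputed (g1, g2, g3) count tensor."""
    axis = {g: k for k, g in enumerate(gene_order)}
    results: list[TripletResult] = []
    for hyp in hypotheses:
        counts_arr = np.transpose(
            tensor, (axis[hyp.gene_a], axis[hyp.gene_b], axis[hyp.gene_c])
        )
        n_ij = counts_arr.sum(axis=2)
        if (n_ij < cfg.min_scenario_count).any():
            continue
        counts = ScenarioCounts(counts_arr)
        if cfg.balanced:
            try:
                w = balance(counts).p
            except ValueError:
                continue
        else:
            total = counts.total
            if total == 0:
                continue
            w = counts_arr / total
        try:
            score = _score_weights(w, LOGIC_TYPES[hyp.type_id].table_2x2)
        except DegenerateTargetError:
            continue
        if score.agreement <= 0.5:
            # the complement type explains c at least as well; report (or
            # suppress, at exactly 0.5) under the complement instead
            continue
        results.append(
            TripletResult(
                gene_a=hyp.gene_a,
                gene_b=hyp.gene_b,
                gene_c=hyp.gene_c,
                type_id=hyp.type_id,
                delta_u=score.delta_u,
                u_cf=score.u_cf,
                u_ca=score.u_ca,
                u_cb=score.u_cb,
                agreement=score.agreement,
                counts=counts,
                balanced=cfg.balanced,
                significant=score.delta_u >= cfg.du_threshold,
            )
        )
    return results


def score_triplet(
    m: ProfileMatrix, genes, cfg: SearchConfig = SearchConfig()
) -> list[TripletResult]:
    """Score every surviving hypothesis for one gene triple.

    Returns the disambiguated results (agreement > 0.5) that pass the
    per-input-pair scenario filter, unsorted; ``search`` applies ordering
    and report thresholds.
    """
    genes = tuple(genes)
    profiles = [m.profile(g) for g in genes]  # raises KeyError when absent
    order = tuple(genes)
    tensor = _count_tensor(*profiles)
    hyps = enumerate_hypotheses(genes, cfg.types)
    return _score_hypotheses(tensor, order, hyps, cfg)


def _sort_key(r: TripletResult):
    return (-r.delta_u, r.gene_a, r.gene_b, r.gene_c, r.type_id)


def search(m: ProfileMatrix, cfg: SearchConfig = SearchConfig()) -> list[TripletResult]:
    """Exhaustively score all gene triples (or a subset) and rank results.

    Yields every disambiguated hypothesis with dU >= ``report_threshold``,
    sorted by descending dU then lexicographic (gene_a, gene_b, gene_c,
    type_id); results at dU >= ``du_threshold`` carry ``significant=True``.
    """
    if cfg.gene_subset is not None:
        missing = [g for g in cfg.gene_subset if g not in m]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        genes = list(cfg.gene_subset)
    else:
        genes = list(m.gene_ids)
    results: list[TripletResult] = []
    n_triples = 0
    n_kept = 0
    for triple in itertools.combinations(genes, 3):
        n_triples += 1
        for r in score_triplet(m, triple, cfg):
            if r.delta_u >= cfg.report_threshold:
                results.append(r)
                n_kept += 1
    logger.info(
        "search: %d triples scanned, %d hypotheses reported", n_triples, n_kept
    )
    results.sort(key=_sort_key)
    return results


def permutation_null(
    m: ProfileMatrix,
    genes,
    cfg: SearchConfig = SearchConfig(),
    n_perm: int = 99,
    seed: int = 0,
) -> dict[TripletHypothesis, float]:
    """Empirical p-values by permuting the output profile across genomes.

    For each hypothesis that passes the scenario filter, the c profile is
    shuffled ``n_perm`` times with a seeded generator and

        p = (1 + #{dU_perm >= dU_obs}) / (n_perm + 1).

    A stand-in for an analytic null of the dU statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = tuple(genes)
    rng = np.random.default_rng(seed)
    nodisamb = replace(cfg, report_threshold=-2.0)
    observed: dict[TripletHypothesis, float] = {}
    profiles = {g: m.profile(g) for g in genes}
    tensor = _count_tensor(*(profiles[g] for g in genes))
    hyps = enumerate_hypotheses(genes, cfg.types)
    axis = {g: k for k, g in enumerate(genes)}
    for hyp in hyps:
        counts_arr = np.transpose(
            tensor, (axis[hyp.gene_a], axis[hyp.gene_b], axis[hyp.gene_c])
        )
        if (counts_arr.sum(axis=2) < cfg.min_scenario_count).any():
            continue
        try:
            score = _delta_u_from_array(counts_arr, hyp.type_id, cfg.balanced)
        except (DegenerateTargetError, ValueError):
            continue
        observed[hyp] = score
    exceed = {hyp: 0 for hyp in observed}
    by_c: dict[str, list[TripletHypothesis]] = {}
    for hyp in observed:
        by_c.setdefault(hyp.gene_c, []).append(hyp)
    for c_gene, c_hyps in sorted(by_c.items()):
        base_c = profiles[c_gene]
        for _ in range(n_perm):
            perm_c = rng.permutation(base_c)
            for hyp in c_hyps:
                arr = _count_tensor(
                    profiles[hyp.gene_a], profiles[hyp.gene_b], perm_c
                )
                try:
                    du_perm = _delta_u_from_array(arr, hyp.type_id, cfg.balanced)
                except (DegenerateTargetError, ValueError):
                    continue
                if du_perm >= observed[hyp]:
                    exceed[hyp] += 1
    return {
        hyp: (1 + exceed[hyp]) / (n_perm + 1) for hyp in observed
    }


def _delta_u_from_array(arr: np.ndarray, type_id: int, balanced: bool) -> float:
    counts = ScenarioCounts(arr)
    if balanced:
        w = balance(counts).p
    else:
        w = arr / arr.sum()
    return _score_weights(w, LOGIC_TYPES[type_id].table_2x2).delta_u


def scenario_imbalance_summary(
    m: ProfileMatrix, sample_size: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Quantify how unevenly genomes spread over the four ab scenarios.

    Samples ``sample_size`` gene pairs, counts the four ab cells of each,
    and returns (mean cell count over all sampled cells, mean of per-pair
    sample standard deviations).  A mean sd comparable to the mean itself
    indicates strong scenario imbalance in the matrix.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if m.n_genes < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    all_cells = []
    sds = []
    for _ in range(sample_size):
        i, j = rng.choice(m.n_genes, size=2, replace=False)
        code = 2 * m.values[i].astype(np.int64) + m.values[j].astype(np.int64)
        cells = np.bincount(code, minlength=4).astype(float)
        all_cells.append(cells)
        sds.append(float(np.std(cells, ddof=1)))
    return float(np.mean(all_cells)), float(np.mean(sds))


def results_table(results: list[TripletResult]) -> pd.DataFrame:
    """Flatten results to the canonical export table."""
    rows = []
    for r in results:
        row = {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "gene_c": r.gene_c,
            "type_id": r.type_id,
            "order_flag": int(not LOGIC_TYPES[r.type_id].symmetric),
            "delta_u": round(r.delta_u, 6),
            "u_cf": round(r.u_cf, 6),
            "u_ca": round(r.u_ca, 6),
            "u_cb": round(r.u_cb, 6),
            "agreement": round(r.agreement, 6),
        }
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    row[f"n{i}{j}{k}"] = int(r.counts.counts[i, j, k])
        row["significant"] = int(r.significant)
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def export_results(results: list[TripletResult], destination) -> None:
    """Write the result table as TSV (dU and U terms at 6 decimals)."""
    results_table(results).to_csv(destination, sep="\t", index=False)


def read_results(source) -> pd.DataFrame:
    """Read a result TSV back into the canonical table layout."""
    df = pd.read_csv(source, sep="\t")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"result table missing columns: {sorted(missing)}")
    return df[list(RESULT_COLUMNS)]


def build_graph(results: list[TripletResult], significant_only: bool = True):
    """Directed multigraph of triplet relationships: edges a->c and b->c,
    labelled with the logic type and whether the input enters negated."""
    import networkx as nx

    g = nx.MultiDiGraph()
    for r in results:
        if significant_only and not r.significant:
            continue
        neg_a, neg_b = INPUT_NEGATION[r.type_id]
        for gene, negated in ((r.gene_a, neg_a), (r.gene_b, neg_b)):
            g.add_edge(
                gene,
                r.gene_c,
                type_id=r.type_id,
                negated=bool(negated),
                delta_u=round(r.delta_u, 6),
            )
    return g


def export_graph(
    results: list[TripletResult],
    destination,
    fmt: str = "graphml",
    significant_only: bool = True,
) -> None:
    """Write the triplet graph as GraphML or DOT."""
    import networkx as nx

    g = build_graph(results, significant_only=significant_only)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(g, destination)
    elif fmt == "dot":
        lines = ["digraph triplets {"]
        for node in g.nodes:
            lines.append(f'    "{node}";')
        for u, v, data in g.edges(data=True):
            label = f"{'~' if data['negated'] else ''}{data['type_id']}"
            lines.append(f'    "{u}" -> "{v}" [label="{label}"];')
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)
    else:
        raise ValueError(f"unknown graph format {fmt!r} (use graphml or dot)")
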