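"""Synthetic profile matrices with known ground truth.

The generator emulates the features of real ortholog matrices that matter
to triplet scoring: heterogeneous gene frequencies (many near-universal and
many rare genes), skewed weights over the four ab coevolution scenarios,
and planted logic triplets whose output gene follows c = f(a, b) up to a
per-genome flip probability.  Background genes are independent Bernoulli
rows, so any detected structure among them is noise by construction.

Defaults mirror the study conditions of the reference analysis: 182
genomes, a U-shaped Beta(0.5, 0.5) frequency law for background genes, and
a light flip noise of 0.02 on planted outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .go_eval import OntologyGraph, read_ontology
from .logic import LOGIC_TYPES
from .profile_matrix import ProfileMatrix

__all__ = [
    "PlantSpec",
    "PlantedHypothesis",
    "SyntheticTruth",
    "generate_background",
    "plant_triplet",
    "generate_benchmark",
    "write_truth",
    "read_truth",
    "generate_toy_ontology",
    "toy_obo_text",
]

DEFAULT_N_GENOMES = 182
DEFAULT_NOISE = 0.02
DEFAULT_FREQUENCY = (0.5, 0.5)  # Beta(a, b): U-shaped, common + rare genes


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one planted logic triplet.

    ``scenario_weights`` are the multinomial probabilities of the four ab
    cells (00, 01, 10, 11); ``noise_epsilon`` is the per-genome probability
    that the output c is flipped away from f(a, b).
    """

    logic_type: int
    scenario_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise_epsilon: float = DEFAULT_NOISE
    n_genomes: int = DEFAULT_N_GENOMES

    def __post_init__(self) -> None:
        if self.logic_type not in LOGIC_TYPES:
            raise ValueError(f"unknown logic type {self.logic_type}")
        w = np.asarray(self.scenario_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ValueError("scenario_weights must be 4 non-negatives summing to 1")
        if not 0 <= self.noise_epsilon <= 0.5:
            raise ValueError("noise_epsilon must lie in [0, 0.5]")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")


@dataclass(frozen=True)
class PlantedHypothesis:
    gene_a: str
    gene_b: str
    gene_c: str
    type_id: int
    scenario_weights: tuple[float, float, float, float]
    noise_epsilon: float


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a benchmark matrix."""

    hypotheses: list[PlantedHypothesis]
    background_frequencies: dict[str, float]
    n_genomes: int
    seed: int


def _resolve_frequencies(frequency, n_genes: int, rng: np.random.Generator):
    if callable(frequency):
        freqs = np.asarray(frequency(rng, n_genes), dtype=float)
    elif np.isscalar(frequency):
        freqs = np.full(n_genes, float(frequency))
    else:
        a, b = frequency
        freqs = rng.beta(a, b, size=n_genes)
    if freqs.shape != (n_genes,) or (freqs < 0).any() or (freqs > 1).any():
        raise ValueError("gene frequencies must lie in [0, 1]")
    return freqs


def generate_background(
    n_genes: int,
    n_genomes: int = DEFAULT_N_GENOMES,
    frequency=DEFAULT_FREQUENCY,
    seed: int = 0,
    gene_prefix: str = "BG",
) -> tuple[ProfileMatrix, dict[str, float]]:
    """Independent Bernoulli background genes.

    ``frequency`` may be a fixed float, a (alpha, beta) pair for a Beta law
    over per-gene frequencies, or a callable ``(rng, size) -> array``.
    Returns the matrix and the per-gene frequencies actually used.
    """
    if n_genes < 1 or n_genomes < 1:
        raise ValueError("n_genes and n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = _resolve_frequencies(frequency, n_genes, rng)
    values = (rng.random((n_genes, n_genomes)) < freqs[:, None]).astype(np.int8)
    width = len(str(n_genes))
    gene_ids = [f"{gene_prefix}{i:0{width}d}" for i in range(n_genes)]
    genome_ids = [f"genome{j:03d}" for j in range(n_genomes)]
    return (
        ProfileMatrix(gene_ids, genome_ids, values),
        dict(zip(gene_ids, freqs.tolist())),
    )


def plant_triplet(
    spec: PlantSpec, rng: np.random.Generator | None = None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw three profiles following c = f(a, b) XOR Bernoulli(epsilon).

    Genomes are assigned to the four ab cells by a multinomial draw over
    ``scenario_weights``; genome order is then shuffled so planted structure
    is not positional.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cell_sizes = rng.multinomial(spec.n_genomes, spec.scenario_weights)
    a = np.concatenate(
        [np.full(n, i, dtype=np.int8) for (i, _), n in zip(((0, 0), (0, 1), (1, 0), (1, 1)), cell_sizes)]
    )
    b = np.concatenate(
        [np.full(n, j, dtype=np.int8) for (_, j), n in zip(((0, 0), (0, 1), (1, 0), (1, 1)), cell_sizes)]
    )
    order = rng.permutation(spec.n_genomes)
    a, b = a[order], b[order]
    c = LOGIC_TYPES[spec.logic_type](a, b).astype(np.int8)
    flips = rng.random(spec.n_genomes) < spec.noise_epsilon
    c = (c ^ flips.astype(np.int8)).astype(np.int8)
    return a, b, c


def _default_spec_distribution(rng: np.random.Generator, index: int) -> PlantSpec:
    """Cycle through the eight logic types with uniform scenario weights."""
    return PlantSpec(logic_type=(index % 8) + 1)


def generate_benchmark(
    n_background: int,
    n_planted: int,
    spec_distribution=None,
    n_genomes: int = DEFAULT_N_GENOMES,
    seed: int = 0,
    background_frequency=DEFAULT_FREQUENCY,
) -> tuple[ProfileMatrix, SyntheticTruth]:
    """Background genes plus planted triplets, with shuffled row order.

    ``spec_distribution(rng, i) -> PlantSpec`` controls the planted
    triplets; the default cycles through the eight types with uniform
    scenario weights and flip noise 0.02.  Planted gene ids are prefixed
    ``P``, background ``BG``; row order is shuffled but labels preserved.
    """
    if n_background < 0 or n_planted < 0:
        raise ValueError("sizes must be >= 0")
    if n_background + n_planted == 0:
        raise ValueError("benchmark must contain at least one gene")
    if spec_distribution is None:
        spec_distribution = _default_spec_distribution
    ss = np.random.SeedSequence(seed)
    bg_seed, plant_seed, shuffle_seed = ss.spawn(3)
    rng_plant = np.random.default_rng(plant_seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    bg_freqs: dict[str, float] = {}
    if n_background:
        bg, bg_freqs = generate_background(
            n_background,
            n_genomes,
            frequency=background_frequency,
            seed=bg_seed,
        )
        gene_ids.extend(bg.gene_ids)
        rows.extend(bg.values)
    hypotheses: list[PlantedHypothesis] = []
    for i in range(n_planted):
        spec = spec_distribution(rng_plant, i)
        if spec.n_genomes != n_genomes:
            spec = PlantSpec(
                spec.logic_type, spec.scenario_weights, spec.noise_epsilon, n_genomes
            )
        a, b, c = plant_triplet(spec, rng=rng_plant)
        names = (f"P{i:03d}a", f"P{i:03d}b", f"P{i:03d}c")
        gene_ids.extend(names)
        rows.extend([a, b, c])
        hypotheses.append(
            PlantedHypothesis(
                gene_a=names[0],
                gene_b=names[1],
                gene_c=names[2],
                type_id=spec.logic_type,
                scenario_weights=tuple(spec.scenario_weights),
                noise_epsilon=spec.noise_epsilon,
            )
        )
    rng_shuffle = np.random.default_rng(shuffle_seed)
    order = rng_shuffle.permutation(len(gene_ids))
    gene_ids = [gene_ids[i] for i in order]
    values = np.vstack(rows)[order]
    genome_ids = [f"genome{j:03d}" for j in range(n_genomes)]
    matrix = ProfileMatrix(gene_ids, genome_ids, values)
    truth = SyntheticTruth(
        hypotheses=hypotheses,
        background_frequencies=bg_freqs,
        n_genomes=n_genomes,
        seed=seed,
    )
    return matrix, truth


def write_truth(truth: SyntheticTruth, dest) -> None:
    """One TSV row per planted hypothesis, plus generator parameters."""
    rows = [
        {
            "gene_a": h.gene_a,
            "gene_b": h.gene_b,
            "gene_c": h.gene_c,
            "type_id": h.type_id,
            "w00": h.scenario_weights[0],
            "w01": h.scenario_weights[1],
            "w10": h.scenario_weights[2],
            "w11": h.scenario_weights[3],
            "noise_epsilon": h.noise_epsilon,
            "n_genomes": truth.n_genomes,
            "seed": truth.seed,
        }
        for h in truth.hypotheses
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "gene_c", "type_id",
            "w00", "w01", "w10", "w11",
            "noise_epsilon", "n_genomes", "seed",
        ],
    ).to_csv(dest, sep="\t", index=False)


def read_truth(source) -> SyntheticTruth:
    df = pd.read_csv(source, sep="\t")
    hypotheses = [
        PlantedHypothesis(
            gene_a=str(r.gene_a),
            gene_b=str(r.gene_b),
            gene_c=str(r.gene_c),
            type_id=int(r.type_id),
            scenario_weights=(float(r.w00), float(r.w01), float(r.w10), float(r.w11)),
            noise_epsilon=float(r.noise_epsilon),
        )
        for r in df.itertuples()
    ]
    n_genomes = int(df["n_genomes"].iloc[0]) if len(df) else DEFAULT_N_GENOMES
    seed = int(df["seed"].iloc[0]) if len(df) else 0
    return SyntheticTruth(hypotheses, {}, n_genomes, seed)


def result_matches_truth(result, truth_hyp: PlantedHypothesis, level: str = "hypothesis") -> bool:
    """Does a scored result recover a planted hypothesis?

    ``level='triple'`` matches on the gene set alone (the counting unit of
    GO-based triplet evaluation).  ``level='hypothesis'`` additionally
    requires the correct output gene, logic type and, for the
    order-sensitive types, input order — except for the XOR family (types
    7/8), where the three role assignments are logically equivalent
    descriptions of the same parity constraint on (a, b, c) and any of them
    counts as a recovery.
    """
    r_set = {result.gene_a, result.gene_b, result.gene_c}
    t_set = {truth_hyp.gene_a, truth_hyp.gene_b, truth_hyp.gene_c}
    if r_set != t_set:
        return False
    if level == "triple":
        return True
    if level != "hypothesis":
        raise ValueError("level must be 'triple' or 'hypothesis'")
    if truth_hyp.type_id in (7, 8):
        return result.type_id == truth_hyp.type_id
    if result.gene_c != truth_hyp.gene_c or result.type_id != truth_hyp.type_id:
        return False
    if LOGIC_TYPES[truth_hyp.type_id].symmetric:
        return {result.gene_a, result.gene_b} == {truth_hyp.gene_a, truth_hyp.gene_b}
    return (result.gene_a, result.gene_b) == (truth_hyp.gene_a, truth_hyp.gene_b)


def top_k_precision(
    results, truth: SyntheticTruth, k: int, level: str = "triple"
) -> float:
    """Fraction of the k best-ranked results that recover a planted
    hypothesis (see :func:`result_matches_truth`); 0 when no results."""
    top = results[:k]
    if not top:
        return 0.0
    hits = sum(
        any(result_matches_truth(r, h, level) for h in truth.hypotheses)
        for r in top
    )
    return hits / len(top)


def toy_obo_text(depth: int = 5, branching: int = 2) -> tuple[str, list[str], str]:
    """A complete-tree Biological Process ontology in OBO text.

    Returns (obo text, leaf term ids, root term id).  Term ids are GO-style
    zero-padded integers assigned breadth-first from the root.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    counter = 1
    root = f"GO:{counter:07d}"
    levels: list[list[str]] = [[root]]
    for _ in range(depth):
        nxt = []
        for _parent in levels[-1]:
            for _ in range(branching):
                counter += 1
                nxt.append(f"GO:{counter:07d}")
        levels.append(nxt)
    blocks = ["format-version: 1.2", ""]
    parent_of: dict[str, str] = {}
    for lvl in range(1, len(levels)):
        parents = levels[lvl - 1]
        for idx, term in enumerate(levels[lvl]):
            parent_of[term] = parents[idx // branching]
    for lvl, terms in enumerate(levels):
        for term in terms:
            blocks.append("[Term]")
            blocks.append(f"id: {term}")
            blocks.append(f"name: toy term level {lvl}")
            blocks.append("namespace: biological_process")
            if term in parent_of:
                blocks.append(f"is_a: {parent_of[term]} ! parent")
            blocks.append("")
    return "\n".join(blocks), levels[-1], root


def generate_toy_ontology(
    depth: int = 5,
    branching: int = 2,
    n_genes: int = 30,
    sharing_rate: float = 0.5,
    seed: int = 0,
) -> tuple[OntologyGraph, dict[str, set[str]]]:
    """Toy ontology plus annotations with controllable term sharing.

    Genes are taken in consecutive groups of three; with probability
    ``sharing_rate`` all three genes of a group are annotated to the same
    random leaf term, otherwise each gets a distinct leaf.  Gene ids are
    ``G000``, ``G001``, ... so callers can align groups with planted
    triplets.
    """
    if not 0 <= sharing_rate <= 1:
        raise ValueError("sharing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    text, leaves, _root = toy_obo_text(depth, branching)
    graph = read_ontology(io.StringIO(text))
    genes = [f"G{i:03d}" for i in range(n_genes)]
    raw: dict[str, set[str]] = {}
    for start in range(0, n_genes, 3):
        group = genes[start : start + 3]
        if len(group) == 3 and rng.random() < sharing_rate:
            leaf = leaves[rng.integers(len(leaves))]
            for g in group:
                raw[g] = {leaf}
        else:
            picks = rng.choice(len(leaves), size=len(group), replace=False)
            for g, p in zip(group, picks):
                raw[g] = {leaves[p]}
    return graph, raw
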