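"""Information-theoretic core for Boolean logic relationships among gene
triplets.

For an ordered gene triplet (a, b, c) the eight joint presence/absence
scenarios (a, b, c) = (i, j, k) are counted over genomes.  A candidate logic
relationship c <-> f(a, b) (one of the eight two-input Boolean functions of
Table :data:`LOGIC_TYPES`) is scored with the uncertainty coefficient

    U(c|y) = I(c, y) / H(c) = [H(c) + H(y) - H(c, y)] / H(c)

and the triplet statistic

    dU = U(c|f(a, b)) - max(U(c|a), U(c|b)),

the gain of the joint logic explanation of c over the best single input.
dU ranges over [-1, 1]; large values indicate a genuine three-way
relationship rather than one driven by a single strong pair.

Because genome collections over-represent some of the four ab coevolution
scenarios (00, 01, 10, 11), the raw joint distribution p_ijk can make dU
reflect genome composition instead of logic.  The *balanced* distribution
p'_ijk gives each non-empty ab cell equal total mass while preserving the
conditional split of c within the cell:

    p'_ijk = (1/M) * n_ijk / n_ij,   M = number of non-empty ab cells,

so p'_ij0 / p'_ij1 = n_ij0 / n_ij1 and all p'_ij are equal (0.25 when all
four cells are populated).  All entropies use log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogicType",
    "LOGIC_TYPES",
    "ScenarioCounts",
    "BalancedDistribution",
    "TripletScore",
    "DegenerateTargetError",
    "entropy",
    "uncertainty_coefficient",
    "scenario_counts",
    "balance",
    "apply_logic",
    "delta_u",
    "compatibility_report",
]

_NORM_TOL = 1e-9
_CLAMP_TOL = 1e-12
# entropies this small arise only from rounding on a degenerate marginal
_DEGEN_TOL = 1e-12


class DegenerateTargetError(ValueError):
    """The target profile has zero entropy under the weighting in use, so
    U(target|.) is undefined; callers should skip the hypothesis."""


@dataclass(frozen=True)
class LogicType:
    """One of the eight two-input Boolean relationships c <-> f(a, b).

    ``table`` lists (f(0,0), f(0,1), f(1,0), f(1,1)).  ``symmetric`` is True
    when f(a, b) = f(b, a); only the two one-directional types (a AND NOT b,
    NOT a OR b) are order-sensitive.  ``complement_of`` names the type whose
    truth table is the bitwise negation; the two members of such a pair are
    indistinguishable by U and are separated by the agreement fraction.
    """

    type_id: int
    name: str
    table: tuple[int, int, int, int]
    symmetric: bool
    complement_of: int

    @property
    def table_2x2(self) -> np.ndarray:
        return np.array(self.table, dtype=np.int8).reshape(2, 2)

    def __call__(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self.table_2x2[np.asarray(a), np.asarray(b)]


LOGIC_TYPES: dict[int, LogicType] = {
    1: LogicType(1, "a AND b", (0, 0, 0, 1), True, 2),
    2: LogicType(2, "NOT (a AND b)", (1, 1, 1, 0), True, 1),
    3: LogicType(3, "a OR b", (0, 1, 1, 1), True, 4),
    4: LogicType(4, "NOT (a OR b)", (1, 0, 0, 0), True, 3),
    5: LogicType(5, "a AND NOT b", (0, 0, 1, 0), False, 6),
    6: LogicType(6, "NOT a OR b", (1, 1, 0, 1), False, 5),
    7: LogicType(7, "a XOR b", (0, 1, 1, 0), True, 8),
    8: LogicType(8, "NOT (a XOR b)", (1, 0, 0, 1), True, 7),
}

#: Which of the two inputs (a, b) appears complemented in each relationship,
#: used for edge annotation in graph exports.
INPUT_NEGATION: dict[int, tuple[bool, bool]] = {
    1: (False, False),
    2: (True, True),
    3: (False, False),
    4: (True, True),
    5: (False, True),
    6: (True, False),
    7: (False, False),
    8: (False, False),
}


def entropy(dist) -> float:
    """Shannon entropy in bits of a finite discrete distribution.

    Entries must be non-negative and sum to 1 (tolerance 1e-9); the
    convention 0 * log 0 = 0 applies.
    """
    p = np.asarray(dist, dtype=float).ravel()
    if (p < 0).any():
        raise ValueError("negative probability entry")
    total = p.sum()
    if abs(total - 1.0) > _NORM_TOL:
        raise ValueError(f"distribution sums to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _entropy_unchecked(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def uncertainty_coefficient(joint) -> float:
    """U(x|y) from a joint probability table ``joint[x, y]``.

    U = [H(x) + H(y) - H(x, y)] / H(x), the fraction of the target's entropy
    explained by the predictor; 0 means independence, 1 complete dependency.
    Raises :class:`DegenerateTargetError` when H(x) = 0.
    """
    j = np.asarray(joint, dtype=float)
    if (j < 0).any():
        raise ValueError("negative probability entry")
    if abs(j.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"joint sums to {j.sum()}, not 1")
    hx = _entropy_unchecked(j.sum(axis=1))
    if hx < _DEGEN_TOL:
        raise DegenerateTargetError("target marginal has zero entropy")
    hy = _entropy_unchecked(j.sum(axis=0))
    hxy = _entropy_unchecked(j.ravel())
    u = (hx + hy - hxy) / hx
    if u < -_CLAMP_TOL or u > 1 + _CLAMP_TOL:
        # larger excursions indicate an invalid joint, not rounding
        raise ValueError(f"uncertainty coefficient {u} outside [0, 1]")
    return float(min(max(u, 0.0), 1.0))


@dataclass
class ScenarioCounts:
    """Genome counts of the eight joint states of an ordered triplet.

    ``counts[i, j, k]`` is the number of genomes with gene a in state i,
    gene b in state j and gene c in state k.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2, 2):
            raise ValueError("counts must have shape (2, 2, 2)")
        if (self.counts < 0).any():
            raise ValueError("negative scenario count")

    @property
    def n_ij(self) -> np.ndarray:
        """Totals of the four ab coevolution scenarios."""
        return self.counts.sum(axis=2)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def swap_inputs(self) -> "ScenarioCounts":
        return ScenarioCounts(self.counts.transpose(1, 0, 2))


def scenario_counts(a, b, c) -> ScenarioCounts:
    """Count the eight (a, b, c) joint states position by position."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    if not (a.shape == b.shape == c.shape) or a.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"profile {name} contains non-binary values")
    code = 4 * a + 2 * b + c
    return ScenarioCounts(np.bincount(code, minlength=8).reshape(2, 2, 2))


@dataclass
class BalancedDistribution:
    """Joint probabilities p'_ijk after equal-weighting of the ab cells."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (2, 2, 2):
            raise ValueError("p must have shape (2, 2, 2)")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("balanced distribution must sum to 1")


def balance(counts: ScenarioCounts) -> BalancedDistribution:
    """Reweight scenario counts so every non-empty ab cell carries equal
    total mass while the conditional split of c within each cell is kept:
    p'_ijk = (1/M) * n_ijk / n_ij over the M non-empty cells."""
    n_ij = counts.n_ij
    nonempty = n_ij > 0
    m = int(nonempty.sum())
    if m == 0:
        raise ValueError("all ab scenario cells are empty")
    p = np.zeros((2, 2, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = counts.counts / n_ij[:, :, None]
    p[nonempty] = cond[nonempty] / m
    return BalancedDistribution(p)


def apply_logic(t: LogicType, a, b) -> np.ndarray:
    """Apply the truth table of ``t`` position-wise to two binary profiles."""
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    return t.table_2x2[a, b]


@dataclass
class TripletScore:
    """The dU decomposition for one (triplet, logic type) hypothesis."""

    delta_u: float
    u_cf: float
    u_ca: float
    u_cb: float
    agreement: float


def _score_weights(w: np.ndarray, table: np.ndarray) -> TripletScore:
    """Score a weighted joint distribution w[i, j, k] against a truth table."""
    p_c = w.sum(axis=(0, 1))
    h_c = _entropy_unchecked(p_c)
    if h_c < _DEGEN_TOL:
        raise DegenerateTargetError("output gene has zero entropy under weighting")
    # joints with target (c) on axis 0
    j_ca = w.sum(axis=1).T
    j_cb = w.sum(axis=0).T
    j_cf = np.zeros((2, 2))
    agreement = 0.0
    for i in range(2):
        for j in range(2):
            f = table[i, j]
            j_cf[0, f] += w[i, j, 0]
            j_cf[1, f] += w[i, j, 1]
            agreement += w[i, j, f]
    u_cf = uncertainty_coefficient(j_cf)
    u_ca = uncertainty_coefficient(j_ca)
    u_cb = uncertainty_coefficient(j_cb)
    return TripletScore(
        delta_u=u_cf - max(u_ca, u_cb),
        u_cf=u_cf,
        u_ca=u_ca,
        u_cb=u_cb,
        agreement=float(agreement),
    )


def delta_u(
    counts: ScenarioCounts, t: LogicType, balanced: bool = True
) -> TripletScore:
    """Compute dU = U(c|f(a,b)) - max(U(c|a), U(c|b)) for one hypothesis.

    With ``balanced=True`` every U term (and the agreement fraction) is
    computed from the balanced distribution p'_ijk; otherwise from the raw
    proportions n_ijk / N.  Mixing weightings would make the difference
    incoherent, so the whole statistic switches together.
    """
    if balanced:
        w = balance(counts).p
    else:
        n = counts.total
        if n == 0:
            raise ValueError("empty scenario counts")
        w = counts.counts / n
    return _score_weights(w, t.table_2x2)


def compatibility_report(counts: ScenarioCounts, t: LogicType):
    """Tabulate, per abc scenario, the genome count and whether the scenario
    is compatible with the relationship (k = f(i, j)).

    Incompatible scenarios with many genomes depress dU and typically signal
    a partial (one-directional) relationship rather than a full iff one.
    """
    import pandas as pd

    table = t.table_2x2
    rows = []
    for i in range(2):
        for j in range(2):
            for k in range(2):
                rows.append(
                    {
                        "scenario": f"{i}{j}{k}",
                        "n_genomes": int(counts.counts[i, j, k]),
                        "compatible": bool(table[i, j] == k),
                    }
                )
    return pd.DataFrame(rows)
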