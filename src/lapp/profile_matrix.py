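"""Binary phylogenetic profile matrices and their preprocessing.

A phylogenetic profile matrix records, for each gene (row) and each genome
(column), whether an ortholog of the gene is present (1) or absent (0).
Before triplet scoring the matrix is preprocessed in three steps:

1. near-duplicate genomes are removed (Hamming distance below a fraction of
   the row count), keeping the genome with fewer absences so that the
   retained genomes stay phylogenetically spread;
2. genes with bitwise-identical profiles are collapsed to one representative
   row per distinct profile;
3. low-entropy profiles (too few 0s or too few 1s to be informative) are
   dropped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "RowCluster",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "deduplicate_genomes",
    "cluster_identical_rows",
    "filter_low_entropy_profiles",
    "write_clusters",
    "read_clusters",
]


class MatrixParseError(ValueError):
    """Raised when a profile-matrix file cannot be parsed."""


@dataclass
class ProfileMatrix:
    """A gene x genome presence/absence indicator matrix.

    Parameters
    ----------
    gene_ids
        Unique row identifiers, in row order.
    genome_ids
        Unique column identifiers, in column order.
    values
        Integer array of shape ``(len(gene_ids), len(genome_ids))`` with
        entries in {0, 1}; 1 means an ortholog is present.
    """

    gene_ids: list[str]
    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_genes, n_genomes = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"row count {n_genes} != number of gene ids {len(self.gene_ids)}"
            )
        if n_genomes != len(self.genome_ids):
            raise ValueError(
                f"column count {n_genomes} != number of genome ids "
                f"{len(self.genome_ids)}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome identifiers")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry at gene {self.gene_ids[r]!r}, "
                f"genome {self.genome_ids[c]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.values.shape[1]

    def profile(self, gene_id: str) -> np.ndarray:
        """Return the binary profile (row) of one gene."""
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.genome_ids
        )


@dataclass
class RowCluster:
    """Genes whose profiles are bitwise identical.

    ``representative`` is the first-encountered member in input order and is
    always contained in ``members``.
    """

    representative: str
    members: set[str] = field(default_factory=set)


def _sniff_sep(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


def read_matrix(source, sep: str | None = None) -> ProfileMatrix:
    """Read a delimited profile matrix (header = genome ids, first column =
    gene ids, body cells 0/1).

    ``sep`` defaults to auto-sniffing tab vs comma from the header line.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_matrix(fh, sep=sep)
    text = source.read()
    if not text.strip():
        raise MatrixParseError("empty input (line 1)")
    if sep is None:
        sep = _sniff_sep(text.splitlines()[0])
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise MatrixParseError(f"malformed header or body: {exc}") from exc
    if df.shape[1] == 0:
        raise MatrixParseError("header holds no genome identifiers (line 1)")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise MatrixParseError("duplicate gene or genome identifier in header/index")
    gene_ids = [str(g) for g in df.index]
    genome_ids = [str(g) for g in df.columns]
    raw = df.to_numpy(dtype=object)
    values = np.zeros(raw.shape, dtype=np.int8)
    ok = np.zeros(raw.shape, dtype=bool)
    for token, val in (("0", 0), ("1", 1)):
        hit = raw == token
        values[hit] = val
        ok |= hit
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValueError(
            f"non-binary cell {raw[r, c]!r} at gene {gene_ids[r]!r}, "
            f"genome {genome_ids[c]!r}"
        )
    return ProfileMatrix(gene_ids, genome_ids, values)


def write_matrix(m: ProfileMatrix, dest, sep: str = "\t") -> None:
    """Write a matrix in the dialect ``read_matrix`` accepts."""
    if isinstance(dest, (str, Path)):
        with open(dest, "wt") as fh:
            write_matrix(m, fh, sep=sep)
        return
    m.to_frame().to_csv(dest, sep=sep)


def deduplicate_genomes(
    m: ProfileMatrix, threshold_fraction: float = 0.05
) -> tuple[ProfileMatrix, list[str]]:
    """Greedily remove near-duplicate genome columns.

    Columns are compared left to right in input order; when two retained
    genomes differ in fewer than ``threshold_fraction`` of the rows (strict
    inequality), the genome with more absent genes (more zeros) is removed;
    on a tie the lexicographically greater identifier is removed. A removed
    genome takes part in no further comparisons.

    Returns the reduced matrix and the removed genome ids in removal order.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError(
            f"threshold_fraction must be in (0, 1], got {threshold_fraction}"
        )
    threshold = threshold_fraction * m.n_genes
    cols = m.values.T
    zeros = (cols == 0).sum(axis=1)
    alive = np.ones(m.n_genomes, dtype=bool)
    removed: list[str] = []
    for i in range(m.n_genomes):
        if not alive[i]:
            continue
        for j in range(i + 1, m.n_genomes):
            if not alive[j]:
                continue
            dist = int(np.count_nonzero(cols[i] != cols[j]))
            if dist >= threshold:
                continue
            if zeros[j] > zeros[i]:
                drop = j
            elif zeros[i] > zeros[j]:
                drop = i
            else:
                drop = max(i, j, key=lambda k: m.genome_ids[k])
            alive[drop] = False
            removed.append(m.genome_ids[drop])
            if drop == i:
                break
    kept = [g for g, a in zip(m.genome_ids, alive) if a]
    return ProfileMatrix(list(m.gene_ids), kept, m.values[:, alive]), removed


def cluster_identical_rows(
    m: ProfileMatrix,
) -> tuple[ProfileMatrix, list[RowCluster]]:
    """Collapse bitwise-identical gene profiles to one representative each.

    The representative is the first-encountered member in input order; the
    output matrix keeps representatives in first-encounter order.
    """
    clusters: dict[bytes, RowCluster] = {}
    keep_rows: list[int] = []
    for idx, gene in enumerate(m.gene_ids):
        key = m.values[idx].tobytes()
        cluster = clusters.get(key)
        if cluster is None:
            clusters[key] = RowCluster(representative=gene, members={gene})
            keep_rows.append(idx)
        else:
            cluster.members.add(gene)
    out = ProfileMatrix(
        [m.gene_ids[i] for i in keep_rows],
        list(m.genome_ids),
        m.values[keep_rows],
    )
    return out, list(clusters.values())


def filter_low_entropy_profiles(
    m: ProfileMatrix, min_state_count: int = 18
) -> ProfileMatrix:
    """Drop genes whose profile has fewer than ``min_state_count`` zeros or
    fewer than ``min_state_count`` ones (too little entropy to score)."""
    if min_state_count < 0:
        raise ValueError("min_state_count must be non-negative")
    ones = m.values.sum(axis=1)
    keep = (ones >= min_state_count) & (m.n_genomes - ones >= min_state_count)
    return ProfileMatrix(
        [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.genome_ids),
        m.values[keep],
    )


def write_clusters(clusters: list[RowCluster], dest) -> None:
    """Write a member -> representative map as two-column TSV."""
    rows = [
        (member, c.representative)
        for c in clusters
        for member in sorted(c.members)
    ]
    pd.DataFrame(rows, columns=["member", "representative"]).to_csv(
        dest, sep="\t", index=False
    )


def read_clusters(source) -> list[RowCluster]:
    df = pd.read_csv(source, sep="\t", dtype=str)
    by_rep: dict[str, RowCluster] = {}
    for member, rep in zip(df["member"], df["representative"]):
        by_rep.setdefault(rep, RowCluster(representative=rep)).members.add(member)
    return list(by_rep.values())
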