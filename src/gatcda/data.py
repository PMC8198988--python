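"""Containers and I/O for bipartite interaction networks and similarity matrices.

The pipeline consumes three bipartite networks — circRNA-disease associations
(the prediction target ``Y``), circRNA-miRNA interactions (miRNA-sponge
evidence) and disease-mRNA interactions — plus an optional precomputed
symptom-based disease similarity matrix. Everything is indexed by
:class:`EntityIndex`, which normalises identifiers (whitespace-trim +
case-fold) and orders them lexicographically so that results never depend on
input file ordering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENTITY_KINDS = ("circRNA", "disease", "miRNA", "mRNA")
SIMILARITY_KINDS = ("CNS", "DNS", "CES", "DES", "DSS", "ICS", "IDS")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def normalize_name(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, deduplicated set of entity identifiers of one kind.

    Names are canonicalised by whitespace-trim + case-fold and ordered
    lexicographically; the index is a bijection name -> 0..n-1.
    """

    kind: str
    names: tuple[str, ...]
    _lookup: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise DataError(f"unknown entity kind {self.kind!r}")
        if list(self.names) != sorted(set(self.names)):
            raise DataError("EntityIndex names must be unique and sorted")
        object.__setattr__(
            self, "_lookup", {n: i for i, n in enumerate(self.names)}
        )

    @classmethod
    def from_names(cls, kind: str, names: Iterable[str]) -> "EntityIndex":
        canonical = sorted({normalize_name(n) for n in names if normalize_name(n)})
        return cls(kind=kind, names=tuple(canonical))

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._lookup

    def position(self, name: str) -> int:
        key = normalize_name(name)
        if key not in self._lookup:
            raise KeyError(f"{self.kind} {name!r} not in index")
        return self._lookup[key]


@dataclass
class BipartiteNetwork:
    """Binary interaction matrix between two entity kinds (never symmetrised)."""

    row_index: EntityIndex
    col_index: EntityIndex
    matrix: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.row_index), len(self.col_index)):
            raise DataError(
                f"matrix shape {self.matrix.shape} does not match indices "
                f"({len(self.row_index)}, {len(self.col_index)})"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise DataError("bipartite matrix entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum())

    def copy(self) -> "BipartiteNetwork":
        return BipartiteNetwork(
            self.row_index, self.col_index, self.matrix.copy(), self.name
        )

    def save(self, path: str | Path) -> None:
        """Write a labelled TSV plus a JSON sidecar with indices and shape."""
        path = Path(path)
        df = pd.DataFrame(
            self.matrix, index=self.row_index.names, columns=self.col_index.names
        )
        df.to_csv(path, sep="\t")
        sidecar = {
            "name": self.name,
            "row_kind": self.row_index.kind,
            "col_kind": self.col_index.kind,
            "shape": list(self.shape),
            "rows": list(self.row_index.names),
            "cols": list(self.col_index.names),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "BipartiteNetwork":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(
            row_index=EntityIndex(sidecar["row_kind"], tuple(sidecar["rows"])),
            col_index=EntityIndex(sidecar["col_kind"], tuple(sidecar["cols"])),
            matrix=df.to_numpy(),
            name=sidecar["name"],
        )


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative square similarity matrix keyed to an entity list."""

    index: EntityIndex
    matrix: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.index)
        if self.matrix.shape != (n, n):
            raise DataError(f"similarity shape {self.matrix.shape}, expected {(n, n)}")
        if self.kind not in SIMILARITY_KINDS:
            raise DataError(f"unknown similarity kind {self.kind!r}")
        if not np.isfinite(self.matrix).all():
            raise DataError(f"{self.kind}: non-finite entries")
        if (self.matrix < 0).any():
            raise DataError(f"{self.kind}: negative entries")
        if np.abs(self.matrix - self.matrix.T).max(initial=0.0) > 1e-9:
            raise DataError(f"{self.kind}: asymmetry exceeds 1e-9")

    def save(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=self.index.names, columns=self.index.names
        ).to_csv(path, sep="\t")


def load_edge_list(
    path: str | Path,
    row_kind: str,
    col_kind: str,
    name: str = "",
    header: bool = False,
) -> BipartiteNetwork:
    """Read a two-column TSV/CSV edge list into a binary interaction matrix.

    An entry (i, j) is 1 iff the pair appears at least once; duplicates
    collapse. Indices contain exactly the distinct names present, ordered
    lexicographically. ``header=True`` skips the first line (headers are never
    auto-detected).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"edge list not found: {path}")
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                fields = line.rstrip("\n").split(",")
            fields = [f for f in fields if f.strip()]
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            r, c = normalize_name(fields[0]), normalize_name(fields[1])
            pairs.add((r, c))
    if not pairs:
        raise DataError(f"{path}: no valid edges")
    rows = EntityIndex.from_names(row_kind, (r for r, _ in pairs))
    cols = EntityIndex.from_names(col_kind, (c for _, c in pairs))
    mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for r, c in pairs:
        mat[rows.position(r), cols.position(c)] = 1
    return BipartiteNetwork(rows, cols, mat, name=name or path.stem)


def load_similarity_matrix(
    path: str | Path,
    expected: EntityIndex | None = None,
    kind: str = "DSS",
) -> SimilarityMatrix:
    """Read a labelled square similarity table (e.g. the symptom-similarity DSS).

    Small asymmetries (max |M - M.T| <= 1e-6) are symmetrised as (M + M.T)/2;
    anything larger is an error. When ``expected`` is given, entities missing
    from the table are padded with a zero row/column and unit diagonal, and
    entities absent from ``expected`` are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"similarity matrix not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    row_labels = [normalize_name(str(x)) for x in df.index]
    col_labels = [normalize_name(str(x)) for x in df.columns]
    if len(row_labels) != len(col_labels):
        raise DataError(f"{path}: table is not square")
    if sorted(row_labels) != sorted(col_labels):
        raise DataError(f"{path}: row and column labels differ")
    mat = df.to_numpy(dtype=float)
    # reorder columns to match row order
    col_pos = {c: i for i, c in enumerate(col_labels)}
    mat = mat[:, [col_pos[r] for r in row_labels]]
    if (mat < 0).any():
        raise DataError(f"{path}: negative similarity entries")
    asym = np.abs(mat - mat.T).max(initial=0.0)
    if asym > 1e-6:
        raise DataError(f"{path}: asymmetry {asym:.3g} exceeds tolerance 1e-6")
    mat = (mat + mat.T) / 2.0

    if expected is None:
        index = EntityIndex.from_names("disease", row_labels)
        order = [row_labels.index(n) for n in index.names]
        return SimilarityMatrix(index, mat[np.ix_(order, order)], kind)

    extra = [n for n in row_labels if n not in expected]
    if extra:
        warnings.warn(
            f"{path}: dropping {len(extra)} entities not in the expected index",
            stacklevel=2,
        )
    n = len(expected)
    out = np.zeros((n, n))
    np.fill_diagonal(out, 1.0)
    keep = [(i, expected.position(nm)) for i, nm in enumerate(row_labels) if nm in expected]
    if keep:
        src, dst = map(np.array, zip(*keep))
        out[np.ix_(dst, dst)] = mat[np.ix_(src, src)]
        np.fill_diagonal(out, np.clip(np.diag(out), 1.0, None))
    return SimilarityMatrix(expected, out, kind)


def reindex_rows(net: BipartiteNetwork, rows: EntityIndex) -> BipartiteNetwork:
    """Project ``net`` onto the row index ``rows``; missing rows become zero."""
    mat = np.zeros((len(rows), len(net.col_index)), dtype=np.int8)
    n_shared = 0
    for i, nm in enumerate(net.row_index.names):
        if nm in rows:
            mat[rows.position(nm)] = net.matrix[i]
            n_shared += 1
    if n_shared == 0:
        warnings.warn(
            f"{net.name or 'network'}: no overlap with target row index; "
            "similarity contributions will be zero",
            stacklevel=2,
        )
    logger.info(
        "%s: %d/%d rows shared with target index",
        net.name or "network",
        n_shared,
        len(net.row_index),
    )
    return BipartiteNetwork(rows, net.col_index, mat, name=net.name)


def align_networks(
    cd: BipartiteNetwork,
    cm: BipartiteNetwork | None,
    dm: BipartiteNetwork | None,
) -> tuple[BipartiteNetwork, BipartiteNetwork | None, BipartiteNetwork | None]:
    """Align auxiliary networks to the circRNA/disease axes of ``cd``.

    circRNAs (diseases) of ``cd`` that have no miRNA (mRNA) partners keep
    all-zero rows, so the association matrix retains its full shape.
    """
    cm_aligned = reindex_rows(cm, cd.row_index) if cm is not None else None
    dm_aligned = reindex_rows(dm, cd.col_index) if dm is not None else None
    return cd, cm_aligned, dm_aligned
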