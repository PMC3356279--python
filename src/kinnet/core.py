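"""Domain types, dyadic-matrix container, tabular I/O and run plumbing.

The package analyses dyadic social behaviour: every statistic operates on
square individual-by-individual matrices whose diagonal is structurally
excluded.  This module defines the typed records produced by field
observation protocols (rosters, focal samples, dyadic interaction events,
coalition events), the :class:`DyadicMatrix` container shared by all
downstream stages, and CSV readers/writers for each of them.

All tabular formats are comma-separated with a header row.  Identifier and
allele fields are treated as opaque strings and never re-parsed as numbers.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "AGE_CLASSES",
    "BEHAVIORS",
    "Individual",
    "FocalSample",
    "InteractionEvent",
    "CoalitionEvent",
    "DyadicMatrix",
    "RunConfig",
    "KinnetError",
    "ParseError",
    "VocabularyError",
    "InvariantError",
    "ReferentialError",
    "UndefinedDyadError",
    "derive_rng",
    "read_roster",
    "write_roster",
    "read_events",
    "write_events",
    "read_genotypes",
    "write_genotypes",
    "matrix_to_edgelist",
    "edgelist_to_matrix",
    "read_matrix",
    "write_matrix",
]

SEXES = ("F", "M")
AGE_CLASSES = ("juvenile", "subadult", "adult")
BEHAVIORS = ("groom", "mutual_groom", "aggression")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class KinnetError(Exception):
    """Base class for all package errors."""


class ParseError(KinnetError):
    """A tabular file could not be parsed; the message names the line."""


class VocabularyError(KinnetError):
    """A categorical field held a token outside its closed vocabulary."""


class InvariantError(KinnetError):
    """A structural invariant of a record or matrix was violated."""


class ReferentialError(KinnetError):
    """An id did not resolve against the supplied roster."""


class UndefinedDyadError(KinnetError):
    """A dyadic statistic was requested for a dyad with no defined value."""


# ---------------------------------------------------------------------------
# Randomness plumbing
# ---------------------------------------------------------------------------

def derive_rng(seed: int, stream: str) -> np.random.Generator:
    """Return a generator for a named substream of the master seed.

    Each pipeline stage draws from its own substream so that stages are
    independently reproducible: re-running one stage with the same master
    seed yields identical output no matter what other stages consumed.
    """
    digest = hashlib.sha256(stream.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclass(frozen=True)
class RunConfig:
    """Reproducibility envelope for a pipeline run."""

    seed: int = 0
    n_permutations: int = 2000
    alpha: float = 0.05
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InvariantError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise InvariantError("n_permutations must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return derive_rng(self.seed, stream)


# ---------------------------------------------------------------------------
# Observation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    """One roster entry: an animal in one group-year."""

    id: str
    sex: str
    age_class: str
    group_id: str
    year: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise VocabularyError(f"unknown sex token {self.sex!r} for {self.id!r}")
        if self.age_class not in AGE_CLASSES:
            raise VocabularyError(
                f"unknown age_class token {self.age_class!r} for {self.id!r}"
            )


@dataclass(frozen=True)
class FocalSample:
    """A focal observation: one focal animal and its within-radius neighbours."""

    sample_id: str
    focal_id: str
    neighbor_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.focal_id in self.neighbor_ids:
            raise InvariantError(
                f"focal {self.focal_id!r} listed as its own neighbor in "
                f"sample {self.sample_id!r}"
            )

    @property
    def present_ids(self) -> frozenset[str]:
        """All individuals in the sample's spatial cluster (focal included)."""
        return self.neighbor_ids | {self.focal_id}


@dataclass(frozen=True)
class InteractionEvent:
    """A dyadic interaction: grooming, mutual grooming, or decided aggression."""

    actor_id: str
    recipient_id: str
    behavior: str
    winner_id: str | None = None

    def __post_init__(self) -> None:
        if self.actor_id == self.recipient_id:
            raise InvariantError(f"self-interaction for {self.actor_id!r}")
        if self.behavior not in BEHAVIORS:
            raise VocabularyError(f"unknown behavior token {self.behavior!r}")
        if self.winner_id is not None and self.winner_id not in (
            self.actor_id,
            self.recipient_id,
        ):
            raise InvariantError(
                f"winner {self.winner_id!r} is neither actor nor recipient"
            )
        if self.behavior == "aggression" and self.winner_id is None:
            raise InvariantError(
                f"aggression event {self.actor_id!r}->{self.recipient_id!r} "
                "lacks a winner"
            )


@dataclass(frozen=True)
class CoalitionEvent:
    """A coalition: a supporter joins the supported individual against a target."""

    supporter_id: str
    supported_id: str
    target_id: str

    def __post_init__(self) -> None:
        ids = (self.supporter_id, self.supported_id, self.target_id)
        if len(set(ids)) != 3:
            raise InvariantError(f"coalition ids not distinct: {ids}")


# ---------------------------------------------------------------------------
# Dyadic matrix container
# ---------------------------------------------------------------------------

@dataclass
class DyadicMatrix:
    """A square individual-by-individual matrix with an excluded diagonal.

    The diagonal stores 0 as a sentinel but is structurally flagged excluded:
    no statistic in the package ever reads it.  ``defined`` marks off-diagonal
    cells carrying a real value; undefined dyads (e.g. a half-weight index for
    a never-observed pair) are excluded rather than imputed.

    Parameters
    ----------
    ids
        Node labels in row/column order.
    values
        The n x n weight matrix.
    directed
        If False the matrix must be symmetric and each unordered dyad is a
        single datum.
    defined
        Optional boolean mask of defined cells; defaults to all off-diagonal
        cells defined.
    """

    ids: list[str]
    values: np.ndarray
    directed: bool = False
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvariantError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise InvariantError("duplicate ids in matrix")
        np.fill_diagonal(self.values, 0.0)
        if self.defined is None:
            self.defined = ~np.eye(n, dtype=bool)
        else:
            self.defined = np.asarray(self.defined, dtype=bool).copy()
            if self.defined.shape != (n, n):
                raise InvariantError("defined mask shape mismatch")
            np.fill_diagonal(self.defined, False)
        if not self.directed:
            sym_ok = np.allclose(self.values, self.values.T, atol=1e-12)
            mask_ok = bool(np.all(self.defined == self.defined.T))
            if not (sym_ok and mask_ok):
                raise InvariantError("undirected matrix must be symmetric")

    # -- basic facts -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self.ids.index(node_id)
        except ValueError:
            raise ReferentialError(f"id {node_id!r} not in matrix") from None

    def value(self, a: str, b: str) -> float:
        i, j = self.index_of(a), self.index_of(b)
        if i == j:
            raise InvariantError("diagonal cells are excluded")
        if not self.defined[i, j]:
            raise UndefinedDyadError(f"dyad ({a!r}, {b!r}) is undefined")
        return float(self.values[i, j])

    def undefined_dyads(self) -> list[tuple[str, str]]:
        """Off-diagonal dyads with no defined value (each unordered pair once
        for undirected matrices)."""
        out = []
        n = self.n
        for i in range(n):
            start = 0 if self.directed else i + 1
            for j in range(start, n):
                if i != j and not self.defined[i, j]:
                    out.append((self.ids[i], self.ids[j]))
        return out

    # -- transforms ------------------------------------------------------
    def reorder(self, ids: Sequence[str]) -> "DyadicMatrix":
        """Return a copy with rows/columns in the given id order."""
        idx = [self.index_of(i) for i in ids]
        if len(idx) != self.n or len(set(idx)) != self.n:
            raise InvariantError("reorder ids must be a permutation of matrix ids")
        ix = np.asarray(idx)
        return DyadicMatrix(
            ids=list(ids),
            values=self.values[np.ix_(ix, ix)],
            directed=self.directed,
            defined=self.defined[np.ix_(ix, ix)],
        )

    def canonical(self) -> "DyadicMatrix":
        """Copy with ids sorted lexicographically (stable output ordering)."""
        return self.reorder(sorted(self.ids))

    def symmetrized(self) -> "DyadicMatrix":
        """(M + M^T)/2 as an undirected matrix."""
        return DyadicMatrix(
            ids=self.ids,
            values=(self.values + self.values.T) / 2.0,
            directed=False,
            defined=self.defined & self.defined.T,
        )


# ---------------------------------------------------------------------------
# Roster I/O
# ---------------------------------------------------------------------------

_ROSTER_COLS = ["id", "sex", "age_class", "group_id", "year"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_roster(path: str | Path) -> list[Individual]:
    """Read a roster CSV (id, sex, age_class, group_id, year).

    Raises
    ------
    ParseError
        Malformed file or a bad row (the message names the data line).
    VocabularyError
        Unknown sex or age-class token.
    InvariantError
        Duplicate id within one group-year.
    """
    df = _read_csv(path, _ROSTER_COLS)
    roster: list[Individual] = []
    seen: set[tuple[str, str, int]] = set()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            year = int(row.year)
        except ValueError:
            raise ParseError(
                f"{path} line {line_no}: year {row.year!r} is not an integer"
            ) from None
        ind = Individual(
            id=row.id, sex=row.sex, age_class=row.age_class,
            group_id=row.group_id, year=year,
        )
        key = (ind.id, ind.group_id, ind.year)
        if key in seen:
            raise InvariantError(
                f"{path} line {line_no}: duplicate id {ind.id!r} in "
                f"group {ind.group_id!r} year {ind.year}"
            )
        seen.add(key)
        roster.append(ind)
    return roster


def write_roster(roster: Iterable[Individual], path: str | Path) -> None:
    df = pd.DataFrame(
        [(i.id, i.sex, i.age_class, i.group_id, i.year) for i in roster],
        columns=_ROSTER_COLS,
    )
    df.to_csv(path, index=False)


def roster_ids(roster: Iterable[Individual]) -> set[str]:
    return {i.id for i in roster}


# ---------------------------------------------------------------------------
# Event I/O
# ---------------------------------------------------------------------------

EventKind = Literal["focal", "interaction", "coalition"]

_EVENT_COLS: dict[str, list[str]] = {
    "focal": ["sample_id", "focal_id", "neighbor_ids"],
    "interaction": ["actor_id", "recipient_id", "behavior", "winner_id"],
    "coalition": ["supporter_id", "supported_id", "target_id"],
}

_NEIGHBOR_SEP = ";"


def read_events(
    path: str | Path,
    kind: EventKind,
    roster: Sequence[Individual] | None = None,
):
    """Read focal samples, interaction events or coalition events from CSV.

    When a roster is supplied every id is cross-checked against it and an
    unknown id raises :class:`ReferentialError`.
    """
    if kind not in _EVENT_COLS:
        raise VocabularyError(f"unknown event kind {kind!r}")
    df = _read_csv(path, _EVENT_COLS[kind])
    known = roster_ids(roster) if roster is not None else None

    def check(ids: Iterable[str], line_no: int) -> None:
        if known is None:
            return
        for i in ids:
            if i not in known:
                raise ReferentialError(
                    f"{path} line {line_no}: id {i!r} not in roster"
                )

    out: list = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if kind == "focal":
            nbrs = frozenset(
                tok for tok in row.neighbor_ids.split(_NEIGHBOR_SEP) if tok
            )
            check([row.focal_id, *nbrs], line_no)
            out.append(
                FocalSample(
                    sample_id=row.sample_id, focal_id=row.focal_id,
                    neighbor_ids=nbrs,
                )
            )
        elif kind == "interaction":
            winner = row.winner_id or None
            check([row.actor_id, row.recipient_id], line_no)
            out.append(
                InteractionEvent(
                    actor_id=row.actor_id, recipient_id=row.recipient_id,
                    behavior=row.behavior, winner_id=winner,
                )
            )
        else:
            check([row.supporter_id, row.supported_id, row.target_id], line_no)
            out.append(
                CoalitionEvent(
                    supporter_id=row.supporter_id,
                    supported_id=row.supported_id,
                    target_id=row.target_id,
                )
            )
    return out


def write_events(events: Sequence, kind: EventKind, path: str | Path) -> None:
    if kind not in _EVENT_COLS:
        raise VocabularyError(f"unknown event kind {kind!r}")
    rows = []
    for e in events:
        if kind == "focal":
            rows.append((e.sample_id, e.focal_id,
                         _NEIGHBOR_SEP.join(sorted(e.neighbor_ids))))
        elif kind == "interaction":
            rows.append((e.actor_id, e.recipient_id, e.behavior,
                         e.winner_id or ""))
        else:
            rows.append((e.supporter_id, e.supported_id, e.target_id))
    pd.DataFrame(rows, columns=_EVENT_COLS[kind]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype I/O (long format: individual, locus, allele1, allele2)
# ---------------------------------------------------------------------------

_GENO_COLS = ["individual_id", "locus", "allele1", "allele2"]


def read_genotypes(path: str | Path) -> dict[str, dict[str, tuple[str, str]]]:
    """Read a long-format genotype CSV into {individual: {locus: (a1, a2)}}.

    Allele codes are opaque strings.  A row with empty alleles marks a
    missing (untyped) locus and is dropped.
    """
    df = _read_csv(path, _GENO_COLS)
    table: dict[str, dict[str, tuple[str, str]]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if not row.allele1 and not row.allele2:
            continue
        if not row.allele1 or not row.allele2:
            raise ParseError(
                f"{path} line {line_no}: a typed locus needs exactly 2 alleles"
            )
        loci = table.setdefault(row.individual_id, {})
        if row.locus in loci:
            raise InvariantError(
                f"{path} line {line_no}: duplicate locus {row.locus!r} "
                f"for {row.individual_id!r}"
            )
        loci[row.locus] = (row.allele1, row.allele2)
    return table


def write_genotypes(
    genotypes: Mapping[str, Mapping[str, tuple[str, str]]], path: str | Path
) -> None:
    rows = [
        (ind, locus, a1, a2)
        for ind in sorted(genotypes)
        for locus, (a1, a2) in sorted(genotypes[ind].items())
    ]
    pd.DataFrame(rows, columns=_GENO_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrix <-> edge list and matrix CSV
# ---------------------------------------------------------------------------

def matrix_to_edgelist(matrix: DyadicMatrix) -> pd.DataFrame:
    """Nonzero defined off-diagonal cells as (source, target, weight) records.

    Undirected matrices emit each unordered dyad once, with source < target
    lexicographically.  The transform is lossless for off-diagonal structure
    given the full id list.
    """
    rows = []
    n = matrix.n
    for i in range(n):
        start = 0 if matrix.directed else i + 1
        for j in range(start, n):
            if i == j or not matrix.defined[i, j]:
                continue
            w = matrix.values[i, j]
            if w != 0.0:
                a, b = matrix.ids[i], matrix.ids[j]
                if not matrix.directed and a > b:
                    a, b = b, a
                rows.append((a, b, w))
    rows.sort()
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def edgelist_to_matrix(
    edges: pd.DataFrame, ids: Sequence[str], directed: bool
) -> DyadicMatrix:
    n = len(ids)
    index = {v: k for k, v in enumerate(ids)}
    values = np.zeros((n, n))
    for row in edges.itertuples(index=False):
        try:
            i, j = index[row.source], index[row.target]
        except KeyError as exc:
            raise ReferentialError(f"edge id {exc} not in id list") from None
        values[i, j] = float(row.weight)
        if not directed:
            values[j, i] = float(row.weight)
    return DyadicMatrix(ids=list(ids), values=values, directed=directed)


def write_matrix(matrix: DyadicMatrix, path: str | Path) -> None:
    """Write a matrix as CSV with an id header row and id index column.

    Undefined cells are written empty so that undefinedness round-trips.
    """
    obj = matrix.values.astype(object)
    obj[~matrix.defined & ~np.eye(matrix.n, dtype=bool)] = ""
    df = pd.DataFrame(obj, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, index_label="id")


def read_matrix(path: str | Path, directed: bool) -> DyadicMatrix:
    df = pd.read_csv(path, index_col="id", keep_default_na=False)
    df.index = df.index.astype(str)
    ids = [str(c) for c in df.columns]
    if list(df.index) != ids:
        raise ParseError(f"{path}: row and column ids differ")
    raw = df.to_numpy(dtype=object)
    defined = ~np.eye(len(ids), dtype=bool)
    values = np.zeros_like(raw, dtype=float)
    for i in range(len(ids)):
        for j in range(len(ids)):
            cell = raw[i, j]
            if i == j:
                continue
            if cell == "":
                defined[i, j] = False
            else:
                values[i, j] = float(cell)
    return DyadicMatrix(ids=ids, values=values, directed=directed, defined=defined)


def to_networkx(matrix: DyadicMatrix):
    """Export to a (Di)Graph with a ``weight`` tie attribute (for GraphML)."""
    import networkx as nx

    g = nx.DiGraph() if matrix.directed else nx.Graph()
    g.add_nodes_from(matrix.ids)
    for row in matrix_to_edgelist(matrix).itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    return g
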