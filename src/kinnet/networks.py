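"""Association and interaction networks with centrality metrics.

Association is measured by the half-weight index (HWI), a dyadic
coefficient that corrects co-sighting counts for unequal sampling effort:

    HWI = X / (X + 0.5 * (Ya + Yb) + Yab)

where X counts samples in which the two animals occurred together, Ya and
Yb count samples containing only one of them, and Yab counts samples where
both were seen but in separate parties (always 0 for a single-group
observation stream).  Grooming and aggression networks are directed count
matrices: the tie from i to j weighs the number of events i directed at j
(for aggression, the number of contests i won against j).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    DyadicMatrix,
    FocalSample,
    Individual,
    InteractionEvent,
    InvariantError,
    ReferentialError,
    UndefinedDyadError,
    VocabularyError,
)

__all__ = [
    "DyadCounts",
    "half_weight_index",
    "tabulate_dyad_counts",
    "build_association_matrix",
    "build_interaction_matrix",
    "strength_centrality",
    "eigenvector_centrality",
    "centrality_table",
]


@dataclass(frozen=True)
class DyadCounts:
    """Co-sighting tallies for one unordered dyad (a, b)."""

    X: int
    Ya: int
    Yb: int
    Yab: int = 0

    def __post_init__(self) -> None:
        if min(self.X, self.Ya, self.Yb, self.Yab) < 0:
            raise InvariantError("dyad counts must be non-negative")

    @property
    def total(self) -> int:
        return self.X + self.Ya + self.Yb + self.Yab


def half_weight_index(counts: DyadCounts) -> float:
    """Half-weight association index X / (X + 0.5*(Ya+Yb) + Yab).

    Equals 1 when the dyad is always together and 0 when never together.
    A dyad never observed at all has no defined index and raises
    :class:`UndefinedDyadError`; callers omit such dyads rather than
    imputing a value.
    """
    if counts.total == 0:
        raise UndefinedDyadError("dyad never observed; half-weight undefined")
    return counts.X / (counts.X + 0.5 * (counts.Ya + counts.Yb) + counts.Yab)


def tabulate_dyad_counts(
    samples: Sequence[FocalSample], roster: Sequence[Individual]
) -> dict[tuple[str, str], DyadCounts]:
    """Tally X/Ya/Yb per unordered dyad over focal samples.

    A focal sample defines one spatial cluster: the focal plus everything
    within the sampling radius.  Any two members of that cluster — focal
    with neighbour or neighbour with neighbour — count as "together", which
    keeps the counts symmetric in the dyad.  Keys are (a, b) with a < b
    lexicographically.
    """
    if not samples:
        raise InvariantError("no focal samples supplied")
    ids = sorted({ind.id for ind in roster})
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    present = np.zeros((len(samples), n), dtype=bool)
    for s_idx, s in enumerate(samples):
        for i in s.present_ids:
            if i not in index:
                raise ReferentialError(
                    f"sample {s.sample_id!r} references id {i!r} not in roster"
                )
            present[s_idx, index[i]] = True
    together = present.astype(np.int64).T @ present.astype(np.int64)
    seen = present.sum(axis=0)
    out: dict[tuple[str, str], DyadCounts] = {}
    for a_idx in range(n):
        for b_idx in range(a_idx + 1, n):
            x = int(together[a_idx, b_idx])
            out[(ids[a_idx], ids[b_idx])] = DyadCounts(
                X=x,
                Ya=int(seen[a_idx]) - x,
                Yb=int(seen[b_idx]) - x,
                Yab=0,
            )
    return out


def build_association_matrix(
    samples: Sequence[FocalSample], roster: Sequence[Individual]
) -> DyadicMatrix:
    """Symmetric matrix of half-weight indices over the roster.

    Dyads in which at least one member was never observed have no defined
    index; they are flagged undefined in the matrix mask and listed by
    :meth:`DyadicMatrix.undefined_dyads` rather than imputed as zero.
    """
    counts = tabulate_dyad_counts(samples, roster)
    ids = sorted({ind.id for ind in roster})
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    values = np.zeros((n, n))
    defined = ~np.eye(n, dtype=bool)
    for (a, b), c in counts.items():
        i, j = index[a], index[b]
        # a dyad is only sampled when both members were seen at least once;
        # otherwise its index is undefined, not 0
        if c.X + c.Ya == 0 or c.X + c.Yb == 0:
            defined[i, j] = defined[j, i] = False
            continue
        values[i, j] = values[j, i] = half_weight_index(c)
    return DyadicMatrix(ids=ids, values=values, directed=False, defined=defined)


def build_interaction_matrix(
    events: Iterable[InteractionEvent],
    roster: Sequence[Individual],
    behavior: str,
) -> DyadicMatrix:
    """Directed count matrix for grooming or aggression events.

    Grooming: entry (i, j) counts grooming bouts by i on j; a mutual-grooming
    bout increments both directions by 1.  Aggression: entry (i, j) counts
    decided contests i won against j (winner -> loser orientation), so tie
    direction follows the outcome, not who initiated.
    """
    if behavior not in ("groom", "aggression"):
        raise VocabularyError(
            f"behavior must be 'groom' or 'aggression', got {behavior!r}"
        )
    ids = sorted({ind.id for ind in roster})
    index = {v: k for k, v in enumerate(ids)}
    values = np.zeros((len(ids), len(ids)))
    for e in events:
        if e.actor_id not in index or e.recipient_id not in index:
            raise ReferentialError(
                f"event ({e.actor_id!r}, {e.recipient_id!r}) references an "
                "id not in the roster"
            )
        if behavior == "groom":
            if e.behavior == "groom":
                values[index[e.actor_id], index[e.recipient_id]] += 1
            elif e.behavior == "mutual_groom":
                values[index[e.actor_id], index[e.recipient_id]] += 1
                values[index[e.recipient_id], index[e.actor_id]] += 1
        else:
            if e.behavior == "aggression":
                loser = (
                    e.recipient_id if e.winner_id == e.actor_id else e.actor_id
                )
                values[index[e.winner_id], index[loser]] += 1
    return DyadicMatrix(ids=ids, values=values, directed=True)


def strength_centrality(matrix: DyadicMatrix, direction: str = "in") -> dict[str, dict[str, float]]:
    """Weighted degree (strength) per node, raw and normalised by n-1.

    In-strength sums incoming tie weights (column sums), out-strength sums
    outgoing weights (row sums).  Normalisation divides by the number of
    possible partners (group size minus one) so values are comparable
    across groups of different size.
    """
    if direction not in ("in", "out"):
        raise VocabularyError(f"direction must be 'in' or 'out', got {direction!r}")
    if matrix.n < 2:
        raise InvariantError("strength centrality needs at least 2 nodes")
    vals = np.where(matrix.defined, matrix.values, 0.0)
    raw = vals.sum(axis=0) if direction == "in" else vals.sum(axis=1)
    return {
        node: {"raw": float(r), "normalized": float(r) / (matrix.n - 1)}
        for node, r in zip(matrix.ids, raw)
    }


def eigenvector_centrality(matrix: DyadicMatrix) -> dict[str, float]:
    """Dominant-eigenvector centrality, max-scaled to 1.

    Directed matrices are symmetrised to (M + M^T)/2 first, which guarantees
    a real dominant eigenpair with a non-negative eigenvector
    (Perron–Frobenius).  On a disconnected graph the score is computed per
    connected component and each component is max-scaled independently;
    isolated nodes score 0.
    """
    if np.any(np.where(matrix.defined, matrix.values, 0.0) < 0):
        raise InvariantError("eigenvector centrality needs non-negative weights")
    sym = matrix if not matrix.directed else matrix.symmetrized()
    adj = np.where(sym.defined, sym.values, 0.0)
    n = sym.n
    scores = np.zeros(n)
    # connected components of the nonzero adjacency
    unvisited = set(range(n))
    while unvisited:
        stack = [unvisited.pop()]
        comp = {stack[0]}
        while stack:
            v = stack.pop()
            for u in np.nonzero(adj[v])[0]:
                if u in unvisited:
                    unvisited.discard(int(u))
                    comp.add(int(u))
                    stack.append(int(u))
        comp_ix = sorted(comp)
        sub = adj[np.ix_(comp_ix, comp_ix)]
        if len(comp_ix) == 1 or not sub.any():
            continue
        w, v = np.linalg.eigh(sub)
        vec = v[:, np.argmax(w)]
        vec = np.abs(vec)  # Perron vector is sign-indeterminate from eigh
        vec /= vec.max()
        scores[comp_ix] = vec
    return {node: float(s) for node, s in zip(sym.ids, scores)}


def centrality_table(matrix: DyadicMatrix) -> "pd.DataFrame":
    """Per-node centrality summary: in/out strength (raw and normalised)
    and max-scaled eigenvector centrality."""
    import pandas as pd

    ins = strength_centrality(matrix, "in")
    outs = strength_centrality(matrix, "out")
    eig = eigenvector_centrality(matrix)
    rows = [
        {
            "id": node,
            "in_strength": ins[node]["raw"],
            "in_strength_norm": ins[node]["normalized"],
            "out_strength": outs[node]["raw"],
            "out_strength_norm": outs[node]["normalized"],
            "eigenvector": eig[node],
        }
        for node in matrix.ids
    ]
    return pd.DataFrame(rows).set_index("id")
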