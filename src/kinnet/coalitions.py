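"""Coalitionary-support analysis against a random-support null.

Field protocols record a coalition when a third individual joins an
agonistic event on one side.  The analysis here asks whether adult females
that support juveniles are disproportionately their mothers: the observed
mother-support count is compared with the expectation under a null in
which, for each event, one adult female of the juvenile's group-year
supports it uniformly at random (the mother included).  A second test asks
whether supporters are unusually related to the juveniles they support,
comparing supporter-dyad relatedness against the group's dyad pool with a
one-way ANOVA F plus a label-permutation p-value (reported alongside the
parametric p because dyadic r values are not independent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    CoalitionEvent,
    DyadicMatrix,
    Individual,
    InvariantError,
    UndefinedDyadError,
    derive_rng,
)
from .relatedness import MaternityAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "CoalitionSummary",
    "RelatednessComparison",
    "expected_mother_support",
    "nonmother_support_fraction",
    "supporter_relatedness_test",
]


@dataclass(frozen=True)
class CoalitionSummary:
    """Observed vs expected mother support across coalition events."""

    n_events: int
    n_mother_support: int
    nonmother_fraction: float
    expected_mother_support: float = float("nan")
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_mother_support > self.n_events:
            raise InvariantError("mother-support count exceeds event count")

    @property
    def mother_fraction(self) -> float:
        return 1.0 - self.nonmother_fraction

    @property
    def nonmother_percent(self) -> int:
        """Non-mother support share rounded to the nearest whole percent."""
        return round(self.nonmother_fraction * 100)


def _as_mother_map(
    maternity: Mapping[str, str | None] | MaternityAssignment,
) -> Mapping[str, str | None]:
    if isinstance(maternity, MaternityAssignment):
        return maternity.mothers
    return maternity


def _roster_index(roster: Sequence[Individual]) -> dict[str, Individual]:
    by_id: dict[str, Individual] = {}
    for ind in roster:
        if ind.id in by_id:
            raise InvariantError(
                f"id {ind.id!r} appears twice in the analysis roster; "
                "analyse one group-year set at a time"
            )
        by_id[ind.id] = ind
    return by_id


def expected_mother_support(
    events: Sequence[CoalitionEvent],
    maternity: Mapping[str, str | None] | MaternityAssignment,
    roster: Sequence[Individual],
) -> float:
    """Expected mother-support count if support were random among adult females.

    For each event the supported juvenile's group-year contributes
    1/(number of adult females in that group-year) when the juvenile's
    mother is one of those females, and 0 when the mother is absent or
    unassigned.  Linear in events: concatenating event sets sums their
    expectations.
    """
    mothers = _as_mother_map(maternity)
    by_id = _roster_index(roster)
    females_by_gy: dict[tuple[str, int], set[str]] = {}
    for ind in roster:
        if ind.age_class == "adult" and ind.sex == "F":
            females_by_gy.setdefault((ind.group_id, ind.year), set()).add(ind.id)
    expected = 0.0
    for e in events:
        juv = by_id.get(e.supported_id)
        if juv is None:
            raise InvariantError(f"supported id {e.supported_id!r} not in roster")
        females = females_by_gy.get((juv.group_id, juv.year), set())
        if not females:
            raise InvariantError(
                f"group-year ({juv.group_id}, {juv.year}) has no adult females"
            )
        mom = mothers.get(e.supported_id)
        if mom is not None and mom in females:
            expected += 1.0 / len(females)
    return expected


def nonmother_support_fraction(
    events: Sequence[CoalitionEvent],
    maternity: Mapping[str, str | None] | MaternityAssignment,
) -> CoalitionSummary:
    """Fraction of coalition events in which the supporter was not the mother.

    Events whose supported juvenile has no assigned mother cannot be
    classified; they are excluded and logged, and the fractions refer to
    the classified events only.
    """
    if not events:
        raise InvariantError("no coalition events supplied")
    mothers = _as_mother_map(maternity)
    n_used = 0
    n_mother = 0
    n_excluded = 0
    for e in events:
        mom = mothers.get(e.supported_id)
        if mom is None:
            n_excluded += 1
            logger.info(
                "coalition event excluded: no assigned mother for supported "
                "juvenile %r", e.supported_id,
            )
            continue
        n_used += 1
        if e.supporter_id == mom:
            n_mother += 1
    if n_used == 0:
        raise InvariantError("no classifiable coalition events (all unassigned)")
    return CoalitionSummary(
        n_events=n_used,
        n_mother_support=n_mother,
        nonmother_fraction=(n_used - n_mother) / n_used,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class RelatednessComparison:
    """Supporter-dyad vs group-dyad relatedness comparison."""

    mean_supporter_r: float
    mean_group_r: float
    f_statistic: float
    df: tuple[int, int]
    p_parametric: float
    p_permutation: float
    n_supporter_dyads: int
    n_group_dyads: int


def supporter_relatedness_test(
    events: Sequence[CoalitionEvent],
    relatedness: DyadicMatrix,
    roster: Sequence[Individual],
    n_permutations: int = 2000,
    seed: int = 0,
    include_supporter_dyads_in_pool: bool = True,
) -> RelatednessComparison:
    """Test whether supporters are unusually related to supported juveniles.

    One sample holds r for each (supporter, supported) event dyad; the
    other holds r for all defined dyads within each event-involved group
    (the supporter dyads included in that pool by default, matching a
    complete-pool comparison; set the flag to exclude them).  Returns the
    one-way ANOVA F with a label-permutation p-value computed by shuffling
    the supporter labels over the pooled values (add-one rule).
    """
    by_id = _roster_index(roster)
    supporter_r: list[float] = []
    groups_involved: set[tuple[str, int]] = set()
    for e in events:
        juv = by_id.get(e.supported_id)
        sup = by_id.get(e.supporter_id)
        if juv is None or sup is None:
            raise InvariantError("coalition event references ids not in roster")
        groups_involved.add((juv.group_id, juv.year))
        try:
            supporter_r.append(relatedness.value(e.supporter_id, e.supported_id))
        except UndefinedDyadError:
            logger.info(
                "supporter dyad (%s, %s) has undefined relatedness; skipped",
                e.supporter_id, e.supported_id,
            )
    pool_r: list[float] = []
    pool_pairs: set[tuple[str, str]] = set()
    supporter_pairs = {
        tuple(sorted((e.supporter_id, e.supported_id))) for e in events
    }
    for gy in groups_involved:
        members = sorted(
            ind.id for ind in roster if (ind.group_id, ind.year) == gy
        )
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = (members[i], members[j])
                if pair in pool_pairs:
                    continue
                if not include_supporter_dyads_in_pool and pair in supporter_pairs:
                    continue
                pool_pairs.add(pair)
                try:
                    pool_r.append(relatedness.value(*pair))
                except UndefinedDyadError:
                    pass
    if len(supporter_r) < 2 or len(pool_r) < 2:
        raise InvariantError("need at least 2 dyads in each comparison set")

    a = np.asarray(supporter_r)
    b = np.asarray(pool_r)
    f_obs, p_param = stats.f_oneway(a, b)
    df = (1, len(a) + len(b) - 2)

    pooled = np.concatenate([a, b])
    k = len(a)
    rng = derive_rng(seed, "coalition-relatedness")
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        f_p, _ = stats.f_oneway(perm[:k], perm[k:])
        if f_p >= f_obs:
            count += 1
    p_perm = (1 + count) / (n_permutations + 1)

    return RelatednessComparison(
        mean_supporter_r=float(a.mean()),
        mean_group_r=float(b.mean()),
        f_statistic=float(f_obs),
        df=df,
        p_parametric=float(p_param),
        p_permutation=float(p_perm),
        n_supporter_dyads=len(a),
        n_group_dyads=len(b),
    )
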