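"""Microsatellite relatedness, maternity by exclusion, and dyadic predictors.

Pairwise genetic relatedness is estimated with the Queller–Goodnight
allele-sharing estimator.  For a dyad (x, y) with x carrying alleles (a, b)
and y carrying (c, d) at one locus, the contribution with x as reference is

    num_x = 0.5 * (I[a=c] + I[a=d] + I[b=c] + I[b=d]) - p_a - p_b
    den_x = 1 + I[a=b] - p_a - p_b

where p are reference-panel allele frequencies.  Numerators and
denominators are summed across loci before dividing (ratio of sums), and
the two reference directions are averaged, giving a symmetric estimate
with expectation 0 for unrelated dyads, 0.25 for half-siblings and 0.5 for
parent–offspring or full siblings.  Allele frequencies come from the adult
reference panel by default, mirroring field practice of estimating
population frequencies from the resident adults.

Maternity is assigned by exclusion: a candidate mother mismatches the
offspring at a locus when the two share no allele there; the unique
candidate with at most ``max_mismatch`` mismatching loci is assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DyadicMatrix,
    Individual,
    InvariantError,
    UndefinedDyadError,
    VocabularyError,
)

__all__ = [
    "AlleleFrequencies",
    "MaternityAssignment",
    "allele_frequencies",
    "queller_goodnight",
    "relatedness_matrix",
    "maternity_by_exclusion",
    "mother_offspring_matrix",
    "homophily_matrix",
]

Genotypes = Mapping[str, Mapping[str, tuple[str, str]]]


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-locus allele frequency reference panel."""

    freqs: dict[str, dict[str, float]]
    reference_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise InvariantError(
                    f"frequencies at locus {locus!r} sum to {total}, not 1"
                )

    def monomorphic_loci(self) -> list[str]:
        return [l for l, t in self.freqs.items() if len(t) == 1]


def allele_frequencies(
    genotypes: Genotypes, reference_ids: Sequence[str]
) -> AlleleFrequencies:
    """Estimate per-locus allele frequencies by counting allele copies in the
    reference panel.  Loci untyped in the entire panel are dropped."""
    if not reference_ids:
        raise InvariantError("reference panel is empty")
    counts: dict[str, dict[str, int]] = {}
    for ind in reference_ids:
        for locus, (a1, a2) in genotypes.get(ind, {}).items():
            table = counts.setdefault(locus, {})
            table[a1] = table.get(a1, 0) + 1
            table[a2] = table.get(a2, 0) + 1
    if not counts:
        raise InvariantError("no typed loci in the reference panel")
    freqs = {
        locus: {a: c / sum(table.values()) for a, c in sorted(table.items())}
        for locus, table in sorted(counts.items())
    }
    return AlleleFrequencies(freqs=freqs, reference_ids=tuple(reference_ids))


def _qg_direction(
    gx: Mapping[str, tuple[str, str]],
    gy: Mapping[str, tuple[str, str]],
    freqs: AlleleFrequencies,
) -> tuple[float, float]:
    """Summed (numerator, denominator) with x as the reference individual.

    Loci whose denominator contribution is 0 (reference homozygous for a
    fixed allele) carry no information for this direction and are skipped.
    """
    num = 0.0
    den = 0.0
    for locus, (a, b) in gx.items():
        if locus not in gy or locus not in freqs.freqs:
            continue
        p = freqs.freqs[locus]
        if a not in p or b not in p:
            # allele absent from reference panel: locus unusable for x
            continue
        c, d = gy[locus]
        den_l = 1.0 + (a == b) - p[a] - p[b]
        if abs(den_l) < 1e-12:
            continue
        share = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        num += share - p[a] - p[b]
        den += den_l
    return num, den


def queller_goodnight(
    genotypes: Genotypes,
    freqs: AlleleFrequencies,
    dyad: tuple[str, str],
    exclude_pair_from_freqs: bool = False,
) -> float:
    """Symmetric Queller–Goodnight relatedness estimate for one dyad.

    Ratio-of-sums across loci in each reference direction, then the two
    directions averaged.  With ``exclude_pair_from_freqs`` the two focal
    individuals are removed from the reference panel before frequencies are
    recomputed (a bias correction some programs apply; off by default).

    Raises
    ------
    UndefinedDyadError
        No shared informative locus in either direction.
    """
    x, y = dyad
    if x == y:
        raise InvariantError("relatedness of an individual with itself is not a dyad")
    if exclude_pair_from_freqs:
        panel = [i for i in freqs.reference_ids if i not in (x, y)]
        if panel:
            freqs = allele_frequencies(genotypes, panel)
    gx = genotypes.get(x, {})
    gy = genotypes.get(y, {})
    ratios = []
    for gref, gother in ((gx, gy), (gy, gx)):
        num, den = _qg_direction(gref, gother, freqs)
        if abs(den) > 1e-12:
            ratios.append(num / den)
    if not ratios:
        raise UndefinedDyadError(
            f"dyad ({x!r}, {y!r}) shares no informative typed locus"
        )
    return float(np.mean(ratios))


def relatedness_matrix(
    genotypes: Genotypes,
    freqs: AlleleFrequencies,
    roster: Sequence[Individual],
    exclude_pair_from_freqs: bool = False,
) -> DyadicMatrix:
    """Symmetric matrix of pairwise r over the roster.

    Dyads with no informative shared locus are flagged undefined and are
    excluded from all downstream means and regressions.
    """
    ids = sorted({ind.id for ind in roster})
    n = len(ids)
    values = np.zeros((n, n))
    defined = ~np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = queller_goodnight(
                    genotypes, freqs, (ids[i], ids[j]),
                    exclude_pair_from_freqs=exclude_pair_from_freqs,
                )
                values[i, j] = values[j, i] = r
            except UndefinedDyadError:
                defined[i, j] = defined[j, i] = False
    return DyadicMatrix(ids=ids, values=values, directed=False, defined=defined)


def group_relatedness_summary(
    matrix: DyadicMatrix, roster: Sequence[Individual]
) -> "pd.DataFrame":
    """Mean ± SD of pairwise r per group and for each group's adult females."""
    import pandas as pd

    by_group: dict[str, list[Individual]] = {}
    for ind in roster:
        by_group.setdefault(ind.group_id, []).append(ind)
    rows = []
    for group, members in sorted(by_group.items()):
        for label, subset in (
            ("all", members),
            ("adult_females",
             [m for m in members if m.age_class == "adult" and m.sex == "F"]),
        ):
            ids = sorted({m.id for m in subset})
            vals = []
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    try:
                        vals.append(matrix.value(ids[i], ids[j]))
                    except UndefinedDyadError:
                        pass
            if len(vals) >= 1:
                rows.append(
                    {"group_id": group, "subset": label, "n_dyads": len(vals),
                     "mean_r": float(np.mean(vals)),
                     "sd_r": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Maternity by exclusion
# ---------------------------------------------------------------------------

@dataclass
class MaternityAssignment:
    """Exclusion-based maternity results.

    ``mothers`` maps each offspring to its assigned mother, or None when no
    candidate passed or more than one did (ambiguous).  ``mismatches`` holds
    the per-candidate mismatching-locus counts actually tested.
    """

    mothers: dict[str, str | None]
    mismatches: dict[tuple[str, str], int] = field(default_factory=dict)
    max_mismatch: int = 0

    def assigned(self) -> dict[str, str]:
        return {o: m for o, m in self.mothers.items() if m is not None}


def count_mismatches(
    gx: Mapping[str, tuple[str, str]], gy: Mapping[str, tuple[str, str]]
) -> int:
    """Number of loci typed in both individuals where they share no allele."""
    return sum(
        1
        for locus, (a, b) in gx.items()
        if locus in gy and not ({a, b} & set(gy[locus]))
    )


def maternity_by_exclusion(
    genotypes: Genotypes,
    offspring_ids: Sequence[str],
    candidate_mother_ids: Sequence[str],
    max_mismatch: int = 0,
) -> MaternityAssignment:
    """Assign each offspring the unique candidate mother compatible with it.

    A candidate is compatible when she mismatches the offspring at no more
    than ``max_mismatch`` loci (a mismatch is a shared-typed locus with no
    shared allele).  Zero or multiple compatible candidates leave the
    offspring unassigned; ambiguity is not broken by mismatch count, since
    exclusion provides no likelihood ordering among passers.
    """
    mothers: dict[str, str | None] = {}
    mismatches: dict[tuple[str, str], int] = {}
    for off in offspring_ids:
        passers = []
        for cand in candidate_mother_ids:
            if cand == off:
                continue
            mm = count_mismatches(genotypes.get(off, {}), genotypes.get(cand, {}))
            mismatches[(off, cand)] = mm
            if mm <= max_mismatch:
                passers.append(cand)
        mothers[off] = passers[0] if len(passers) == 1 else None
    return MaternityAssignment(
        mothers=mothers, mismatches=mismatches, max_mismatch=max_mismatch
    )


# ---------------------------------------------------------------------------
# Binary dyadic predictors
# ---------------------------------------------------------------------------

def mother_offspring_matrix(
    maternity: Mapping[str, str | None] | MaternityAssignment,
    roster: Sequence[Individual],
) -> DyadicMatrix:
    """Binary predictor: 1 for (adult female, her juvenile offspring) dyads.

    Mother–subadult dyads are deliberately coded 0 — the predictor captures
    active maternal care of dependent young, not pedigree links per se.
    """
    if isinstance(maternity, MaternityAssignment):
        maternity = maternity.mothers
    by_id = {ind.id: ind for ind in roster}
    ids = sorted(by_id)
    index = {v: k for k, v in enumerate(ids)}
    values = np.zeros((len(ids), len(ids)))
    for off, mom in maternity.items():
        if mom is None or off not in by_id or mom not in by_id:
            continue
        o, m = by_id[off], by_id[mom]
        if o.age_class == "juvenile" and m.age_class == "adult" and m.sex == "F":
            values[index[off], index[mom]] = 1.0
            values[index[mom], index[off]] = 1.0
    return DyadicMatrix(ids=ids, values=values, directed=False)


def homophily_matrix(roster: Sequence[Individual], attribute: str) -> DyadicMatrix:
    """Binary predictor: 1 when both dyad members share the attribute.

    ``attribute='sex'`` marks same-sex dyads; an age-class name
    (``'adult'``, ``'subadult'``, ``'juvenile'``) marks dyads in which both
    members belong to that class.
    """
    ids = sorted({ind.id for ind in roster})
    by_id = {ind.id: ind for ind in roster}
    if attribute == "sex":
        trait = {i: by_id[i].sex for i in ids}
        same = np.array(
            [[trait[a] == trait[b] for b in ids] for a in ids], dtype=float
        )
    elif attribute in ("adult", "subadult", "juvenile"):
        in_class = np.array([by_id[i].age_class == attribute for i in ids])
        same = np.outer(in_class, in_class).astype(float)
    else:
        raise VocabularyError(
            f"attribute must be 'sex' or an age class, got {attribute!r}"
        )
    np.fill_diagonal(same, 0.0)
    return DyadicMatrix(ids=ids, values=same, directed=False)
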