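"""Synthetic field studies with known ground truth.

Generates everything the pipeline consumes — rosters, multilocus
microsatellite genotypes with a mother–offspring pedigree, focal
association samples, grooming and aggression events, and coalition events
— for a small female-philopatric carnivore society: a handful of resident
adult females, one adult male, and cohorts of subadults and juveniles per
group.  Effect multipliers put kin structure into association and grooming
(mother–juvenile dyads associate and groom more, juveniles cluster with
juveniles, everyone grooms the adult male) while aggression rates depend
only on age-sex class, so each configured effect has a recoverable target
in the corresponding pipeline statistic.

Design choices: paternal gametes are drawn from population allele
frequencies (fathers are not modelled as individuals, since only maternity
is analysed); each simulated group-year is an independent unit with its
own pedigree; class base rates follow the qualitative field pattern (adult
females groom most, adult males aggress most and attract grooming).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .coalitions import (
    expected_mother_support,
    nonmother_support_fraction,
    supporter_relatedness_test,
)
from .core import (
    CoalitionEvent,
    DyadicMatrix,
    FocalSample,
    Individual,
    InteractionEvent,
    InvariantError,
    derive_rng,
    write_events,
    write_genotypes,
    write_matrix,
    write_roster,
)
from .mrqap import MRQAPResult, mrqap_dsp
from .networks import build_association_matrix, build_interaction_matrix, centrality_table
from .relatedness import (
    allele_frequencies,
    homophily_matrix,
    maternity_by_exclusion,
    mother_offspring_matrix,
    relatedness_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "simulate_pedigree_and_genotypes",
    "simulate_focal_samples",
    "simulate_interactions",
    "simulate_coalitions",
    "simulate_study",
    "run_end_to_end",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one synthetic study; the defaults are the reference
    conditions every calibration and recovery check runs under.

    Group composition mirrors a mid-sized study group (4 adult females,
    one adult male, 3 subadults, 6 juveniles = 14 animals); two groups per
    year and two years give four group-year analysis units spanning the
    observed 12–29 range in aggregate.  Genotypes use 15 microsatellite
    loci with 2–7 alleles each.  Multipliers are unitless rate/probability
    factors (1 = no effect).
    """

    n_groups: int = 2
    years: tuple[int, ...] = (2003, 2004)
    n_adult_females: int = 4
    n_adult_males: int = 1
    n_subadults: int = 3
    n_juveniles: int = 6

    # genetics
    n_loci: int = 15
    alleles_min: int = 2
    alleles_max: int = 7
    founder_concentration: float = 1.0

    # association (focal samples)
    n_focal_samples: int = 800
    baseline_association: float = 0.15
    mother_offspring_association: float = 3.0
    juvenile_homophily_association: float = 2.0

    # grooming: mean events per directed dyad by actor age-sex class
    grooming_base_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "adult_female": 1.2, "adult_male": 0.3,
            "subadult_female": 0.4, "subadult_male": 0.4,
            "juvenile_female": 0.2, "juvenile_male": 0.2,
        }
    )
    mother_offspring_grooming: float = 8.0
    adult_homophily_grooming: float = 2.0
    male_grooming_attraction: float = 3.0
    mutual_groom_rate: float = 0.05

    # aggression: mean events per directed dyad by actor class (no kin terms)
    aggression_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "adult_female": 0.6, "adult_male": 2.0,
            "subadult_female": 0.3, "subadult_male": 0.5,
            "juvenile_female": 0.4, "juvenile_male": 1.0,
        }
    )

    # coalitions
    n_coalition_events: int = 10
    mother_support_weight: float = 3.0
    mother_always_supports: bool = False

    genotyping_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline_association <= 1.0):
            raise InvariantError("baseline_association must be a probability")
        for name in (
            "mother_offspring_association", "juvenile_homophily_association",
            "mother_offspring_grooming", "adult_homophily_grooming",
            "male_grooming_attraction", "mother_support_weight",
        ):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be non-negative")
        if any(v < 0 for v in self.grooming_base_rates.values()):
            raise InvariantError("grooming base rates must be non-negative")
        if any(v < 0 for v in self.aggression_rates.values()):
            raise InvariantError("aggression rates must be non-negative")
        if self.alleles_min < 2 or self.alleles_max < self.alleles_min:
            raise InvariantError("allele count range must be >= 2 and ordered")
        if not (0.0 <= self.genotyping_error < 1.0):
            raise InvariantError("genotyping_error must be in [0, 1)")

    def null(self) -> "SyntheticScenario":
        """Copy with every effect switched off (all multipliers 1)."""
        return replace(
            self,
            mother_offspring_association=1.0,
            juvenile_homophily_association=1.0,
            mother_offspring_grooming=1.0,
            adult_homophily_grooming=1.0,
            male_grooming_attraction=1.0,
            mother_support_weight=1.0,
        )


@dataclass
class GroundTruth:
    """What the generator actually did: the pedigree (offspring -> mother),
    the configured effect multipliers, and per-dyad expected rates."""

    pedigree: dict[str, str]
    effects: dict[str, float]
    association_prob: dict[tuple[str, str], float] = field(default_factory=dict)
    grooming_rate: dict[tuple[str, str], float] = field(default_factory=dict)

    def mothers_of_juveniles(self, roster: list[Individual]) -> dict[str, str]:
        juv = {i.id for i in roster if i.age_class == "juvenile"}
        return {o: m for o, m in self.pedigree.items() if o in juv}


def _class_key(ind: Individual) -> str:
    return f"{ind.age_class}_{'female' if ind.sex == 'F' else 'male'}"


# ---------------------------------------------------------------------------
# Pedigree and genotypes
# ---------------------------------------------------------------------------

def _draw_locus_frequencies(scenario: SyntheticScenario, rng: np.random.Generator):
    """Per-locus allele labels and founder frequencies (Dirichlet-drawn)."""
    loci = {}
    for l in range(scenario.n_loci):
        k = int(rng.integers(scenario.alleles_min, scenario.alleles_max + 1))
        freqs = rng.dirichlet(np.full(k, scenario.founder_concentration))
        loci[f"L{l + 1:02d}"] = {f"a{i + 1}": float(p) for i, p in enumerate(freqs)}
    return loci


def _gamete(freqs: dict[str, float], rng: np.random.Generator) -> str:
    alleles = list(freqs)
    return alleles[rng.choice(len(alleles), p=np.array(list(freqs.values())))]


def _founder_genotype(locus_freqs, rng) -> dict[str, tuple[str, str]]:
    return {
        locus: tuple(sorted((_gamete(f, rng), _gamete(f, rng))))
        for locus, f in locus_freqs.items()
    }


def _offspring_genotype(mother_geno, locus_freqs, rng) -> dict[str, tuple[str, str]]:
    geno = {}
    for locus, f in locus_freqs.items():
        maternal = mother_geno[locus][int(rng.integers(2))]
        paternal = _gamete(f, rng)
        geno[locus] = tuple(sorted((maternal, paternal)))
    return geno


def _apply_genotyping_error(geno, locus_freqs, rate, rng):
    if rate <= 0:
        return geno
    out = {}
    for locus, (a1, a2) in geno.items():
        pair = [a1, a2]
        for slot in range(2):
            if rng.random() < rate:
                pair[slot] = _gamete(locus_freqs[locus], rng)
        out[locus] = tuple(sorted(pair))
    return out


def simulate_pedigree_and_genotypes(
    scenario: SyntheticScenario,
) -> tuple[list[Individual], dict[str, dict[str, tuple[str, str]]], GroundTruth]:
    """Simulate rosters, pedigree and Mendelian genotypes for every group-year.

    Founder adults draw both alleles from the locus frequencies; each
    juvenile and subadult is assigned a mother uniformly among the group's
    adult females and inherits one maternal allele plus one
    frequency-drawn paternal gamete per locus.
    """
    if (scenario.n_juveniles + scenario.n_subadults) > 0 and scenario.n_adult_females == 0:
        raise InvariantError("offspring configured but no adult females")
    rng = derive_rng(scenario.seed, "pedigree")
    locus_freqs = _draw_locus_frequencies(scenario, rng)
    roster: list[Individual] = []
    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    pedigree: dict[str, str] = {}

    for g in range(scenario.n_groups):
        for year in scenario.years:
            tag = f"G{g + 1}Y{year % 100:02d}"
            females = []
            for f in range(scenario.n_adult_females):
                iid = f"{tag}-AF{f + 1}"
                roster.append(Individual(iid, "F", "adult", f"G{g + 1}", year))
                genotypes[iid] = _founder_genotype(locus_freqs, rng)
                females.append(iid)
            for m in range(scenario.n_adult_males):
                iid = f"{tag}-AM{m + 1}"
                roster.append(Individual(iid, "M", "adult", f"G{g + 1}", year))
                genotypes[iid] = _founder_genotype(locus_freqs, rng)
            for prefix, age, count in (
                ("SA", "subadult", scenario.n_subadults),
                ("JU", "juvenile", scenario.n_juveniles),
            ):
                for k in range(count):
                    iid = f"{tag}-{prefix}{k + 1}"
                    sex = "F" if rng.random() < 0.5 else "M"
                    roster.append(Individual(iid, sex, age, f"G{g + 1}", year))
                    mother = females[int(rng.integers(len(females)))]
                    pedigree[iid] = mother
                    genotypes[iid] = _offspring_genotype(
                        genotypes[mother], locus_freqs, rng
                    )

    if scenario.genotyping_error > 0:
        genotypes = {
            iid: _apply_genotyping_error(
                g, locus_freqs, scenario.genotyping_error, rng
            )
            for iid, g in genotypes.items()
        }

    effects = {
        "mother_offspring_association": scenario.mother_offspring_association,
        "juvenile_homophily_association": scenario.juvenile_homophily_association,
        "mother_offspring_grooming": scenario.mother_offspring_grooming,
        "adult_homophily_grooming": scenario.adult_homophily_grooming,
        "male_grooming_attraction": scenario.male_grooming_attraction,
        "mother_support_weight": scenario.mother_support_weight,
    }
    return roster, genotypes, GroundTruth(pedigree=pedigree, effects=effects)


# ---------------------------------------------------------------------------
# Behavioural streams
# ---------------------------------------------------------------------------

def _group_years(roster: list[Individual]):
    units: dict[tuple[str, int], list[Individual]] = {}
    for ind in roster:
        units.setdefault((ind.group_id, ind.year), []).append(ind)
    return units


def _is_mother_juvenile(a: Individual, b: Individual, pedigree) -> bool:
    return (
        (a.age_class == "juvenile" and pedigree.get(a.id) == b.id)
        or (b.age_class == "juvenile" and pedigree.get(b.id) == a.id)
    )


def simulate_focal_samples(
    scenario: SyntheticScenario, roster: list[Individual], truth: GroundTruth
) -> list[FocalSample]:
    """Focal samples per group-year: a uniform focal, then each groupmate is
    a neighbour independently with probability baseline x multipliers
    (mother–juvenile, juvenile–juvenile), capped at 1 with a logged warning."""
    rng = derive_rng(scenario.seed, "focal-samples")
    samples: list[FocalSample] = []
    for (group, year), members in sorted(_group_years(roster).items()):
        members = sorted(members, key=lambda i: i.id)
        probs = {}
        for a in members:
            for b in members:
                if a.id >= b.id:
                    continue
                p = scenario.baseline_association
                if _is_mother_juvenile(a, b, truth.pedigree):
                    p *= scenario.mother_offspring_association
                if a.age_class == b.age_class == "juvenile":
                    p *= scenario.juvenile_homophily_association
                if p > 1.0:
                    logger.warning(
                        "association probability for (%s, %s) capped at 1 "
                        "(was %.3f)", a.id, b.id, p,
                    )
                    p = 1.0
                probs[(a.id, b.id)] = p
                truth.association_prob[(a.id, b.id)] = p
        for s in range(scenario.n_focal_samples):
            focal = members[int(rng.integers(len(members)))]
            neighbors = set()
            for other in members:
                if other.id == focal.id:
                    continue
                key = tuple(sorted((focal.id, other.id)))
                if rng.random() < probs[key]:
                    neighbors.add(other.id)
            samples.append(
                FocalSample(
                    sample_id=f"{group}-{year}-s{s + 1:05d}",
                    focal_id=focal.id,
                    neighbor_ids=frozenset(neighbors),
                )
            )
    return samples


def simulate_interactions(
    scenario: SyntheticScenario, roster: list[Individual], truth: GroundTruth
) -> list[InteractionEvent]:
    """Grooming and aggression event streams.

    Grooming counts per directed dyad are Poisson with a log-linear rate:
    actor-class base rate x mother-juvenile multiplier x adult-homophily
    multiplier x adult-male-recipient attraction.  The maternal boost
    covers dependent juveniles only (mother-subadult dyads get no kin
    term), matching the mother-offspring predictor's coding.  Aggression counts are
    Poisson with actor-class rates and no kin terms; the actor wins every
    simulated contest, so tie orientation (winner -> loser) coincides with
    actor -> recipient.
    """
    rng = derive_rng(scenario.seed, "interactions")
    events: list[InteractionEvent] = []
    for (group, year), members in sorted(_group_years(roster).items()):
        members = sorted(members, key=lambda i: i.id)
        for actor in members:
            for recipient in members:
                if actor.id == recipient.id:
                    continue
                rate = scenario.grooming_base_rates[_class_key(actor)]
                if _is_mother_juvenile(actor, recipient, truth.pedigree):
                    rate *= scenario.mother_offspring_grooming
                if actor.age_class == recipient.age_class == "adult":
                    rate *= scenario.adult_homophily_grooming
                if recipient.age_class == "adult" and recipient.sex == "M":
                    rate *= scenario.male_grooming_attraction
                truth.grooming_rate[(actor.id, recipient.id)] = rate
                for _ in range(rng.poisson(rate)):
                    events.append(
                        InteractionEvent(actor.id, recipient.id, "groom")
                    )
                agg_rate = scenario.aggression_rates[_class_key(actor)]
                for _ in range(rng.poisson(agg_rate)):
                    events.append(
                        InteractionEvent(
                            actor.id, recipient.id, "aggression",
                            winner_id=actor.id,
                        )
                    )
        if scenario.mutual_groom_rate > 0:
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    for _ in range(rng.poisson(scenario.mutual_groom_rate)):
                        events.append(
                            InteractionEvent(a.id, b.id, "mutual_groom")
                        )
    return events


def simulate_coalitions(
    scenario: SyntheticScenario, roster: list[Individual], truth: GroundTruth
) -> list[CoalitionEvent]:
    """Coalition events per group-year: a uniform juvenile is supported by an
    adult female drawn with weight ``mother_support_weight`` for its mother
    and 1 for every other female, against a uniform third individual.

    With w = mother_support_weight and F adult females, the per-event
    mother-support probability is w / (w + F - 1); w = 1 is the random-
    support null.  ``mother_always_supports`` forces the mother whenever
    she exists (the w -> infinity limit).
    """
    rng = derive_rng(scenario.seed, "coalitions")
    events: list[CoalitionEvent] = []
    for (group, year), members in sorted(_group_years(roster).items()):
        members = sorted(members, key=lambda i: i.id)
        juveniles = [m for m in members if m.age_class == "juvenile"]
        females = [m for m in members if m.age_class == "adult" and m.sex == "F"]
        if not females:
            raise InvariantError(
                f"group-year ({group}, {year}) has no adult females"
            )
        if not juveniles:
            continue
        for _ in range(scenario.n_coalition_events):
            juv = juveniles[int(rng.integers(len(juveniles)))]
            mother = truth.pedigree.get(juv.id)
            if scenario.mother_always_supports and mother is not None:
                supporter = mother
            else:
                weights = np.array(
                    [
                        scenario.mother_support_weight if f.id == mother else 1.0
                        for f in females
                    ]
                )
                supporter = females[
                    int(rng.choice(len(females), p=weights / weights.sum()))
                ].id
            candidates = [
                m.id for m in members if m.id not in (juv.id, supporter)
            ]
            target = candidates[int(rng.integers(len(candidates)))]
            events.append(CoalitionEvent(supporter, juv.id, target))
    return events


def simulate_study(scenario: SyntheticScenario):
    """Generate every input stream for one synthetic study.

    Returns (roster, genotypes, truth, focal_samples, interactions,
    coalitions), all reproducible from ``scenario.seed``.
    """
    roster, genotypes, truth = simulate_pedigree_and_genotypes(scenario)
    samples = simulate_focal_samples(scenario, roster, truth)
    interactions = simulate_interactions(scenario, roster, truth)
    coalitions = simulate_coalitions(scenario, roster, truth)
    return roster, genotypes, truth, samples, interactions, coalitions


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_end_to_end(
    scenario: SyntheticScenario,
    out_dir: str | Path | None = None,
    n_permutations: int = 1000,
    predictors: tuple[str, ...] = (
        "mother_offspring", "relatedness", "sex", "adult", "subadult", "juvenile",
    ),
) -> dict:
    """Simulate a study and run the full analysis pipeline on it.

    Per group-year this builds the association, grooming and aggression
    matrices, estimates relatedness and exclusion maternity from the
    simulated genotypes (never from the ground-truth pedigree), runs the
    three MRQAP regressions, computes centrality tables, and summarises
    coalitionary support.  When ``out_dir`` is given all inputs and result
    tables are written as CSV.
    """
    roster, genotypes, truth, samples, interactions, coalition_events = (
        simulate_study(scenario)
    )
    adults = [i.id for i in roster if i.age_class == "adult"]
    freqs = allele_frequencies(genotypes, adults)

    units = _group_years(roster)
    maternity_all: dict[str, str | None] = {}
    mrqap_results: dict[tuple[str, int], dict[str, MRQAPResult]] = {}
    centrality: dict[tuple[str, int], dict[str, "pd.DataFrame"]] = {}

    for (group, year), members in sorted(units.items()):
        ids = {m.id for m in members}
        gy_samples = [s for s in samples if s.focal_id in ids]
        gy_events = [e for e in interactions if e.actor_id in ids]
        females = [
            m.id for m in members if m.age_class == "adult" and m.sex == "F"
        ]
        offspring = [
            m.id for m in members if m.age_class in ("juvenile", "subadult")
        ]
        maternity = maternity_by_exclusion(genotypes, offspring, females)
        maternity_all.update(maternity.mothers)

        assoc = build_association_matrix(gy_samples, members)
        groom = build_interaction_matrix(gy_events, members, "groom")
        aggr = build_interaction_matrix(gy_events, members, "aggression")
        rel = relatedness_matrix(genotypes, freqs, members)
        mo = mother_offspring_matrix(maternity, members)

        preds_und: dict[str, DyadicMatrix] = {}
        for name in predictors:
            if name == "mother_offspring":
                preds_und[name] = mo
            elif name == "relatedness":
                preds_und[name] = rel
            elif name in ("sex", "adult", "subadult", "juvenile"):
                if name in ("adult", "subadult", "juvenile") and not any(
                    m.age_class == name for m in members
                ):
                    continue  # class absent: predictor would be all-zero
                preds_und[name] = homophily_matrix(members, name)
        preds_dir = {
            k: DyadicMatrix(v.ids, v.values, directed=True, defined=v.defined)
            for k, v in preds_und.items()
        }

        gy_res: dict[str, MRQAPResult] = {}
        gy_res["association"] = mrqap_dsp(
            assoc, preds_und, n_permutations=n_permutations, seed=scenario.seed
        )
        gy_res["grooming"] = mrqap_dsp(
            groom, preds_dir, n_permutations=n_permutations, seed=scenario.seed
        )
        gy_res["aggression"] = mrqap_dsp(
            aggr, preds_dir, n_permutations=n_permutations, seed=scenario.seed
        )
        mrqap_results[(group, year)] = gy_res
        centrality[(group, year)] = {
            "grooming": centrality_table(groom),
            "aggression": centrality_table(aggr),
        }

    rel_all = relatedness_matrix(genotypes, freqs, roster)
    coalition_summary = nonmother_support_fraction(coalition_events, maternity_all)
    expected = expected_mother_support(coalition_events, maternity_all, roster)
    supporter_test = supporter_relatedness_test(
        coalition_events, rel_all, roster,
        n_permutations=n_permutations, seed=scenario.seed,
    )

    bundle = {
        "scenario": scenario,
        "roster": roster,
        "genotypes": genotypes,
        "truth": truth,
        "focal_samples": samples,
        "interactions": interactions,
        "coalition_events": coalition_events,
        "allele_frequencies": freqs,
        "maternity": maternity_all,
        "relatedness": rel_all,
        "mrqap": mrqap_results,
        "centrality": centrality,
        "coalition_summary": coalition_summary,
        "expected_mother_support": expected,
        "supporter_relatedness": supporter_test,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    import pandas as pd

    out.mkdir(parents=True, exist_ok=True)
    write_roster(bundle["roster"], out / "roster.csv")
    write_genotypes(bundle["genotypes"], out / "genotypes.csv")
    write_events(bundle["focal_samples"], "focal", out / "focal_samples.csv")
    write_events(bundle["interactions"], "interaction", out / "interactions.csv")
    write_events(bundle["coalition_events"], "coalition", out / "coalitions.csv")
    write_matrix(bundle["relatedness"], out / "relatedness_matrix.csv")
    pd.DataFrame(
        sorted(bundle["truth"].pedigree.items()), columns=["offspring", "mother"]
    ).to_csv(out / "truth_pedigree.csv", index=False)
    pd.DataFrame(
        sorted(bundle["maternity"].items()), columns=["offspring", "mother"]
    ).to_csv(out / "maternity.csv", index=False)

    rows = []
    for (group, year), by_dep in bundle["mrqap"].items():
        for dep_name, res in by_dep.items():
            for p in res.predictors:
                rows.append(
                    {"group_id": group, "year": year, "network": dep_name,
                     "predictor": p.name, "slope": p.slope,
                     "slope_std": p.slope_standardized, "P": p.p_value}
                )
    pd.DataFrame(rows).to_csv(out / "mrqap_results.csv", index=False)

    for (group, year), tables in bundle["centrality"].items():
        for net, tbl in tables.items():
            tbl.to_csv(out / f"centrality_{net}_{group}_{year}.csv")

    cs = bundle["coalition_summary"]
    st = bundle["supporter_relatedness"]
    pd.DataFrame(
        [
            {"n_events": cs.n_events,
             "n_mother_support": cs.n_mother_support,
             "expected_mother_support": bundle["expected_mother_support"],
             "nonmother_percent": cs.nonmother_percent,
             "supporter_mean_r": st.mean_supporter_r,
             "group_mean_r": st.mean_group_r,
             "F": st.f_statistic,
             "p_parametric": st.p_parametric,
             "p_permutation": st.p_permutation}
        ]
    ).to_csv(out / "coalition_summary.csv", index=False)
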