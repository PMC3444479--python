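"""Synthetic mtDNA case-control cohorts with matrilineal structure.

The generator produces everything the pipeline consumes -- per-subject
variant tables, a pedigree, a phenotype/covariate table -- plus a truth
record, so that network construction, scanning, familial risk and
imputation are all testable without any external data.

Model: a neutral Kingman coalescent genealogy over one tip per matriline
(msprime), with infinite-sites mutations (Poisson on branches, each at a
unique position of a toy circular reference). Matrilines receive geometric
sizes; each matriline is a small maternal pedigree (founder grandmother,
non-cohort mothers, cohort-member children in sibling groups), exactly one
cohort member per matriline is "sequenced" and the rest are imputable. Case
status follows a logistic model on age, sex and APOE dosages with the
intercept calibrated to a target case rate, plus an optional planted
log-odds effect ``beta`` for carriers of a chosen genealogical clade
(``beta = -inf`` = fully protective, zero cases among carriers).

Defaults mirror the cohort structure this analysis is designed for: 1007
subjects in 274 matrilines, ~250 distinct haplotypes, ~900 segregating
sites, 43.9% male, age 75.6 (7.5) truncated at 65, 27.2% missing phenotype,
13.8% cases among phenotyped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import msprime
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .pedigree import FEMALE, MALE, Individual, Pedigree, write_pedigree
from .reference import ReferenceSequence, toy_reference
from .variants import SNV, Variant, write_variant_table

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Cohort generator parameters (defaults = study-structure conditions)."""

    H: int = 274  # genealogy tips (one per matriline; identical tips merge)
    theta: float = 1125.0  # scaled mutation rate; ~900 segregating sites with growth
    growth_rate: float = 200.0  # exponential growth (star-like genealogy)
    n_subjects: int = 1007
    n_matrilines: int = 274
    male_fraction: float = 442 / 1007
    age_mean: float = 75.64
    age_sd: float = 7.50
    age_min: float = 65.0
    apoe4_freq: float = 0.15
    apoe2_freq: float = 0.06
    baseline_case_rate: float = 101 / 733
    missing_phenotype_rate: float = 274 / 1007
    effect_clade: Optional[tuple[str, ...]] = None  # explicit tip ids
    effect_clade_size: Optional[int] = None  # target phenotyped carriers (auto-pick)
    beta: float = 0.0  # planted clade log-odds; -inf = full protection
    beta_age: float = 0.10  # per year
    beta_male: float = -0.20
    beta_apoe4: float = 1.20  # per epsilon-4 allele
    beta_apoe2: float = -0.50  # per epsilon-2 allele
    het_rate: float = 0.01
    ref_length: int = 2000
    sib_geom_p: float = 0.55  # sibling-group size ~ geometric(p)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("male_fraction", "apoe4_freq", "apoe2_freq",
                     "baseline_case_rate", "missing_phenotype_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_matrilines > self.n_subjects:
            raise ValueError("n_matrilines cannot exceed n_subjects")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if self.H < 1 or self.theta < 0:
            raise ValueError("need H >= 1 and theta >= 0")


@dataclass
class Genealogy:
    """Coalescent tree over haplotype tips with per-tip variant sets."""

    tips: list[str]
    variant_sets: dict[str, frozenset[Variant]]
    clades: list[frozenset[str]]  # tip sets below each internal node
    n_sites: int
    newick: str


@dataclass
class SyntheticCohort:
    params: SimParams
    reference: ReferenceSequence
    genealogy: Genealogy
    subjects: pd.DataFrame  # subject_id, matriline, tip, genotyped, carrier, ad_status, age, male, apoe4, apoe2
    pedigree: Pedigree
    variant_tables: dict[str, set[Variant]]  # genotyped subjects only
    het_fractions: dict[tuple[str, Variant], float]
    truth: dict

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Emit pipeline input files (variant TSV, PED, covariate TSV, truth JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": outdir / "variants.tsv",
            "pedigree": outdir / "pedigree.ped",
            "flags": outdir / "flags.tsv",
            "phenotypes": outdir / "phenotypes.tsv",
            "truth": outdir / "truth.json",
        }
        write_variant_table(paths["variants"], self.variant_tables, self.het_fractions)
        write_pedigree(self.pedigree, paths["pedigree"])
        with open(paths["flags"], "w") as fh:
            fh.write("subject_id\tcohort_member\taffected\n")
            for ind in self.pedigree.members.values():
                aff = "" if ind.affected is None else int(ind.affected)
                fh.write(f"{ind.id}\t{int(ind.cohort_member)}\t{aff}\n")
        pheno = self.subjects[
            ["subject_id", "ad_status", "age", "male", "apoe4", "apoe2"]
        ].copy()
        pheno.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6f")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def simulate_haplotypes(
    H: int,
    theta: float,
    seed: int,
    reference: ReferenceSequence,
    growth_rate: float = 0.0,
) -> Genealogy:
    """Neutral coalescent genealogy with infinite-sites mutations.

    A Kingman tree over ``H`` haploid tips; mutations are Poisson with total
    rate theta/2 per lineage per coalescent time unit, each at a unique
    position of the reference. At growth_rate 0 the expected number of
    segregating sites is theta * sum_{i<H} 1/i (Watterson's formula); a
    positive exponential growth rate makes the genealogy star-like, shifting
    variation onto terminal branches as in expanding human mtDNA
    populations. Deterministic in seed.
    """
    ms_seed = int(seed) % (2**31 - 2) + 1
    demography = msprime.Demography()
    demography.add_population(initial_size=1.0, growth_rate=growth_rate)
    ts = msprime.sim_ancestry(
        samples=H, ploidy=1, demography=demography,
        sequence_length=1.0, random_seed=ms_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=theta / 2.0, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=ms_seed + 1,
    )
    tips = [f"T{k:03d}" for k in range(H)]
    if mts.num_sites > reference.length:
        raise ValueError(
            f"{mts.num_sites} mutations exceed reference length {reference.length}; "
            "increase ref_length or lower theta"
        )
    # unique integer positions: floor-scale the float positions, then bump collisions
    taken: set[int] = set()
    site_variant: list[Variant] = []
    for site in mts.sites():
        pos = int(site.position * reference.length) + 1
        while pos in taken:
            pos = pos % reference.length + 1
        taken.add(pos)
        ref_base = reference.base_at(pos)
        alt_base = _BASES[(_BASES.index(ref_base) + 1) % 4]
        site_variant.append(Variant(pos, SNV, ref_base, alt_base))
    variant_sets: dict[str, set[Variant]] = {t: set() for t in tips}
    for var, v in zip(mts.variants(), site_variant):
        for k in np.flatnonzero(var.genotypes):
            variant_sets[tips[k]].add(v)
    tree = mts.first()
    clades = []
    for node in tree.nodes():
        if tree.is_leaf(node):
            continue
        below = frozenset(tips[s] for s in tree.samples(node))
        if 0 < len(below) < H:
            clades.append(below)
    clades = sorted(set(clades), key=lambda c: (len(c), sorted(c)))
    return Genealogy(
        tips=tips,
        variant_sets={t: frozenset(s) for t, s in variant_sets.items()},
        clades=clades,
        n_sites=mts.num_sites,
        newick=tree.as_newick(),
    )


def _matriline_sizes(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Geometric matriline sizes adjusted to sum exactly to n_subjects."""
    p = params.n_matrilines / params.n_subjects
    sizes = rng.geometric(min(max(p, 1e-6), 1.0), size=params.n_matrilines)
    total = int(sizes.sum())
    while total > params.n_subjects:
        i = int(rng.integers(params.n_matrilines))
        if sizes[i] > 1:
            sizes[i] -= 1
            total -= 1
    while total < params.n_subjects:
        i = int(rng.integers(params.n_matrilines))
        sizes[i] += 1
        total += 1
    return sizes


def _build_pedigrees(
    params: SimParams, sizes: np.ndarray, rng: np.random.Generator
) -> tuple[list[Individual], list[tuple[str, str]]]:
    """Per-matriline maternal pedigrees.

    Returns (individuals, [(subject_id, matriline_founder_id)]). Cohort
    members are the third-generation children, grouped into sibling clusters
    under non-cohort mothers who are full sisters (so within a matriline the
    cohort holds sib groups, r = 1/2, and first cousins, r = 1/8).
    """
    individuals: list[Individual] = []
    subject_rows: list[tuple[str, str]] = []
    counter = 0
    for m in range(params.n_matrilines):
        fam = f"F{m:03d}"
        founder_mother = f"{fam}.GM"
        founder_father = f"{fam}.GF"
        individuals.append(Individual(founder_mother, fam, FEMALE, None, None))
        individuals.append(Individual(founder_father, fam, MALE, None, None))
        remaining = int(sizes[m])
        mother_idx = 0
        while remaining > 0:
            mother = f"{fam}.M{mother_idx}"
            husband = f"{fam}.H{mother_idx}"
            individuals.append(
                Individual(mother, fam, FEMALE, founder_father, founder_mother)
            )
            individuals.append(Individual(husband, fam, MALE, None, None))
            group = min(int(rng.geometric(params.sib_geom_p)), remaining)
            for _ in range(group):
                sid = f"S{counter:04d}"
                counter += 1
                individuals.append(
                    Individual(sid, fam, MALE, husband, mother, cohort_member=True)
                )
                subject_rows.append((sid, founder_mother))
            remaining -= group
            mother_idx += 1
    return individuals, subject_rows


def choose_effect_clade(
    genealogy: Genealogy,
    subject_tips: pd.Series,
    target_phenotyped: int,
    missing_rate: float,
) -> tuple[str, ...]:
    """Pick the clade whose expected phenotyped carrier count is closest to target.

    Candidate clades are the genealogy's internal-node tip sets covering at
    most half the cohort; the expected phenotyped carriers of a clade are its
    carrier count times (1 - missing_rate). Clades are required to be
    haplotype-closed: no tip outside the clade may carry a variant set
    identical to a clade tip's (identical tips collapse to one haplotype, so
    an unclosed clade would not correspond to any network branch).
    """
    n = len(subject_tips)
    tip_counts = subject_tips.value_counts()
    best: tuple[float, int, tuple[str, ...]] = (math.inf, 0, ())
    for clade in genealogy.clades:
        carriers = int(tip_counts.reindex(sorted(clade)).fillna(0).sum())
        if carriers == 0 or carriers > n // 2:
            continue
        inside = {genealogy.variant_sets[t] for t in clade}
        if any(genealogy.variant_sets[t] in inside for t in genealogy.tips if t not in clade):
            continue
        # the clade must have a defining variant (>=1 mutation on its stem
        # branch), i.e. a variant shared by all clade tips and absent
        # outside; otherwise no network branch can separate it
        shared = frozenset.intersection(*(genealogy.variant_sets[t] for t in clade))
        outside = set().union(*(genealogy.variant_sets[t]
                                for t in genealogy.tips if t not in clade)) if len(clade) < len(genealogy.tips) else set()
        if not (shared - outside):
            continue
        gap = abs(carriers * (1.0 - missing_rate) - target_phenotyped)
        key = (gap, carriers, tuple(sorted(clade)))
        if key < best:
            best = key
    if not best[2]:
        raise ValueError("no candidate clade matches the requested size")
    return best[2]


def _calibrate_intercept(lp: np.ndarray, rate: float) -> float:
    """Intercept b0 with mean(expit(b0 + lp)) = rate."""
    return float(brentq(lambda b0: expit(b0 + lp).mean() - rate, -30.0, 30.0))


def simulate_cohort(params: SimParams) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic in params.seed)."""
    rng = np.random.default_rng(params.seed)
    reference = toy_reference(length=params.ref_length, seed=7)
    genealogy = simulate_haplotypes(
        params.H, params.theta, params.seed, reference, growth_rate=params.growth_rate
    )

    sizes = _matriline_sizes(params, rng)
    individuals, subject_rows = _build_pedigrees(params, sizes, rng)
    n = len(subject_rows)
    assert n == params.n_subjects

    # matriline m -> genealogy tip (one per matriline; extras recycle randomly)
    matriline_tip: dict[str, str] = {}
    for m in range(params.n_matrilines):
        founder = f"F{m:03d}.GM"
        tip = genealogy.tips[m] if m < params.H else genealogy.tips[int(rng.integers(params.H))]
        matriline_tip[founder] = tip

    subjects = pd.DataFrame(subject_rows, columns=["subject_id", "matriline"])
    subjects["tip"] = subjects["matriline"].map(matriline_tip)

    # covariates: exact male count, truncated-normal age, APOE allele dosages
    male = np.zeros(n, dtype=int)
    male[rng.permutation(n)[: round(params.male_fraction * n)]] = 1
    age = params.age_mean + params.age_sd * rng.standard_normal(n)
    for _ in range(1000):
        low = age < params.age_min
        if not low.any():
            break
        age[low] = params.age_mean + params.age_sd * rng.standard_normal(int(low.sum()))
    age = np.maximum(age, params.age_min)
    probs = [params.apoe2_freq, 1.0 - params.apoe2_freq - params.apoe4_freq, params.apoe4_freq]
    alleles = rng.choice(3, size=(n, 2), p=probs)  # 0 = e2, 1 = e3, 2 = e4
    apoe4 = (alleles == 2).sum(axis=1)
    apoe2 = (alleles == 0).sum(axis=1)

    # planted clade
    if params.effect_clade is not None:
        clade = tuple(sorted(params.effect_clade))
    elif params.effect_clade_size is not None:
        clade = choose_effect_clade(
            genealogy, subjects["tip"], params.effect_clade_size,
            params.missing_phenotype_rate,
        )
    else:
        clade = ()
    carrier = subjects["tip"].isin(clade).to_numpy()

    # phenotype model
    lp = (
        params.beta_age * (age - params.age_mean)
        + params.beta_male * male
        + params.beta_apoe4 * apoe4
        + params.beta_apoe2 * apoe2
    )
    b0 = _calibrate_intercept(lp, params.baseline_case_rate)
    prob = expit(b0 + lp + np.where(carrier, params.beta, 0.0))
    if np.isneginf(params.beta):
        prob = np.where(carrier, 0.0, expit(b0 + lp))
    case = (rng.random(n) < prob).astype(float)
    n_missing = round(params.missing_phenotype_rate * n)
    missing_idx = rng.permutation(n)[:n_missing]
    ad_status = case.copy()
    ad_status[missing_idx] = np.nan

    subjects["genotyped"] = False
    subjects["carrier"] = carrier
    subjects["ad_status"] = ad_status
    subjects["age"] = np.round(age, 6)
    subjects["male"] = male
    subjects["apoe4"] = apoe4
    subjects["apoe2"] = apoe2

    # one sequenced representative per matriline
    genotyped_ids = (
        subjects.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1)))
        .groupby("matriline", sort=True)["subject_id"]
        .first()
        .tolist()
    )
    subjects.loc[subjects["subject_id"].isin(genotyped_ids), "genotyped"] = True

    # pedigree flags: cohort membership set during construction; diagnoses
    ped = Pedigree(individuals)
    status_by_id = dict(zip(subjects["subject_id"], ad_status))
    for sid, st in status_by_id.items():
        ped.members[sid].affected = None if math.isnan(st) else bool(st)
    sex_by_id = dict(zip(subjects["subject_id"], male))
    for sid, is_male in sex_by_id.items():
        ped.members[sid].sex = MALE if is_male else FEMALE

    variant_tables = {
        row.subject_id: set(genealogy.variant_sets[row.tip])
        for row in subjects.itertuples(index=False)
        if row.genotyped
    }
    het_fractions = inject_heteroplasmy(
        variant_tables, params.het_rate, int(rng.integers(2**31 - 1))
    )

    truth = {
        "seed": params.seed,
        "beta": "-inf" if np.isneginf(params.beta) else params.beta,
        "intercept": b0,
        "effect_clade_tips": list(clade),
        "carrier_subjects": subjects.loc[carrier, "subject_id"].tolist(),
        "n_carriers_phenotyped": int((carrier & ~np.isnan(ad_status)).sum()),
        "n_segregating_sites": genealogy.n_sites,
        "n_distinct_haplotypes": int(
            subjects["tip"].map(lambda t: genealogy.variant_sets[t]).nunique()
        ),
        "subject_tip": dict(zip(subjects["subject_id"], subjects["tip"])),
    }
    return SyntheticCohort(
        params=params,
        reference=reference,
        genealogy=genealogy,
        subjects=subjects,
        pedigree=ped,
        variant_tables=variant_tables,
        het_fractions=het_fractions,
        truth=truth,
    )


def inject_heteroplasmy(
    variant_tables: dict[str, set[Variant]], het_rate: float, seed: int
) -> dict[tuple[str, Variant], float]:
    """Mark random variants heteroplasmic with a minor-allele fraction < 0.5.

    Mutates ``variant_tables`` in place (flagging chosen variants) and
    returns {(subject, variant): alt-allele fraction} for the flagged ones;
    the alt allele stays the majority (fraction > 0.5), so downstream
    majority-rule resolution recovers the original haplotypes exactly.
    """
    if not 0.0 <= het_rate <= 1.0:
        raise ValueError("het_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    fractions: dict[tuple[str, Variant], float] = {}
    for subject in sorted(variant_tables):
        new_set = set()
        for v in sorted(variant_tables[subject], key=lambda v: (v.position, v.alt_allele)):
            if het_rate > 0 and rng.random() < het_rate:
                minor = 0.05 + 0.40 * rng.random()
                hv = Variant(v.position, v.kind, v.ref_allele, v.alt_allele, True)
                new_set.add(hv)
                fractions[(subject, hv)] = round(1.0 - minor, 4)
            else:
                new_set.add(v)
        variant_tables[subject] = new_set
    return fractions
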