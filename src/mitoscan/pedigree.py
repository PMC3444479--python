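"""Pedigrees, kinship, familial risk, matrilines, and haplotype imputation.

The familial-risk covariate follows the epidemiological construction used in
extended-pedigree cohort studies: for each subject, the coefficient-of-
relationship-weighted sum of affected relatives divided by the weighted sum
of relatives in the at-risk cohort. The coefficient of relationship is twice
the kinship coefficient.

Matrilines (maximal sets sharing an unbroken maternal line to one female
founder) carry a single mtDNA haplotype barring mutation, which justifies
imputing the haplotype observed in one sequenced member to the rest of the
matriline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Union

import pandas as pd

MALE, FEMALE = 1, 2


@dataclass
class Individual:
    id: str
    family: str
    sex: int  # 1 = male, 2 = female (PED convention)
    father: Optional[str]
    mother: Optional[str]
    cohort_member: bool = False  # member of the at-risk cohort
    affected: Optional[bool] = None  # diagnosis where known


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, sex/role conflicts, duplicates)."""


class Pedigree:
    """Validated pedigree with memoized kinship computation."""

    def __init__(self, individuals: list[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        for ind in individuals:
            for parent, role, want in ((ind.father, "father", MALE), (ind.mother, "mother", FEMALE)):
                if parent is None:
                    continue
                if parent not in self.members:
                    raise PedigreeError(f"{ind.id}: unknown {role} {parent!r}")
                if self.members[parent].sex != want:
                    raise PedigreeError(f"{ind.id}: {role} {parent!r} has wrong sex")
        self._depth = self._compute_depths()  # also detects cycles
        self._kin_cache: dict[tuple[str, str], float] = {}

    def _compute_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        state: dict[str, int] = {}  # 1 = in progress, 2 = done

        def visit(i: str) -> int:
            if state.get(i) == 2:
                return depth[i]
            if state.get(i) == 1:
                raise PedigreeError(f"pedigree cycle involving {i!r}")
            state[i] = 1
            ind = self.members[i]
            d = 0
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    d = max(d, visit(parent) + 1)
            depth[i] = d
            state[i] = 2
            return d

        for i in self.members:
            visit(i)
        return depth

    def __contains__(self, i: str) -> bool:
        return i in self.members

    def __len__(self) -> int:
        return len(self.members)

    def parents(self, i: str) -> tuple[Optional[str], Optional[str]]:
        ind = self.members[i]
        return ind.father, ind.mother

    def kinship(self, i: str, j: str) -> float:
        """Kinship coefficient phi via the standard recursive algorithm.

        phi(i,i) = 1/2 + 1/2 phi(father_i, mother_i); for i != j recurse on
        the parents of the later-generation individual (which is never an
        ancestor of the other), phi(i,j) = 1/2 [phi(f_i, j) + phi(m_i, j)];
        founders are unrelated.
        """
        for x in (i, j):
            if x not in self.members:
                raise KeyError(f"unknown individual {x!r}")
        return self._kin(i, j)

    def _kin(self, i: str, j: str) -> float:
        if self._depth[i] < self._depth[j] or (self._depth[i] == self._depth[j] and i > j):
            i, j = j, i
        key = (i, j)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        f, m = self.parents(i)
        if i == j:
            phi = 0.5
            if f is not None and m is not None:
                phi += 0.5 * self._kin(f, m)
        else:
            phi = 0.0
            if f is not None:
                phi += 0.5 * self._kin(f, j)
            if m is not None:
                phi += 0.5 * self._kin(m, j)
        self._kin_cache[key] = phi
        return phi

    def relationship(self, i: str, j: str) -> float:
        """Coefficient of relationship r = 2 phi."""
        return 2.0 * self.kinship(i, j)

    def family_of(self, i: str) -> str:
        return self.members[i].family


def read_pedigree(
    path: Union[str, Path],
    flags: Union[str, Path, pd.DataFrame, None] = None,
) -> Pedigree:
    """Read a PED file (family, id, father, mother, sex, phenotype; 0 = missing).

    The PED phenotype column uses 2 = affected, 1 = unaffected, 0/-9 =
    unknown. ``flags`` is an optional companion table (TSV or DataFrame with
    columns subject_id, cohort_member and optionally affected) that sets the
    at-risk-cohort flag and overrides diagnoses.
    """
    ped = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str, comment="#",
        names=["family", "id", "father", "mother", "sex", "phenotype"],
    )
    individuals = []
    for row in ped.itertuples(index=False):
        pheno = str(row.phenotype)
        affected = {"2": True, "1": False}.get(pheno)
        individuals.append(
            Individual(
                id=row.id,
                family=row.family,
                sex=int(row.sex),
                father=None if row.father in ("0", None) else row.father,
                mother=None if row.mother in ("0", None) else row.mother,
                affected=affected,
            )
        )
    pedigree = Pedigree(individuals)
    if flags is not None:
        df = flags if isinstance(flags, pd.DataFrame) else pd.read_csv(flags, sep="\t", dtype={"subject_id": str})
        for row in df.itertuples(index=False):
            ind = pedigree.members.get(str(row.subject_id))
            if ind is None:
                continue
            ind.cohort_member = bool(int(row.cohort_member))
            if hasattr(row, "affected") and not pd.isna(row.affected):
                ind.affected = bool(int(row.affected))
    return pedigree


def write_pedigree(pedigree: Pedigree, path: Union[str, Path]) -> None:
    """Write PED format (phenotype 2/1/0 for affected/unaffected/unknown)."""
    with open(path, "w") as fh:
        for ind in pedigree.members.values():
            pheno = "0" if ind.affected is None else ("2" if ind.affected else "1")
            fh.write(
                f"{ind.family}\t{ind.id}\t{ind.father or 0}\t{ind.mother or 0}\t"
                f"{ind.sex}\t{pheno}\n"
            )


def kinship_coefficient(i: str, j: str, pedigree: Pedigree) -> float:
    """Kinship coefficient phi(i, j); see :meth:`Pedigree.kinship`."""
    return pedigree.kinship(i, j)


def relationship_coefficient(i: str, j: str, pedigree: Pedigree) -> float:
    """Coefficient of relationship r = 2 phi(i, j)."""
    return pedigree.relationship(i, j)


@dataclass(frozen=True)
class FamilialRisk:
    subject_id: str
    numerator: float
    denominator: float
    score: float
    degenerate: bool  # no at-risk relatives: score forced to 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.numerator <= self.denominator + 1e-12):
            raise ValueError("familial risk numerator outside [0, denominator]")


def familial_risk(
    subject: str,
    pedigree: Pedigree,
    min_relationship: float = 0.0,
) -> FamilialRisk:
    """Relationship-weighted familial risk score for one subject.

    numerator = sum of r(subject, k) over relatives k that are at-risk cohort
    members *and* affected; denominator = the same sum over all at-risk
    cohort relatives. Relatives are pedigree members (same family) with
    r > max(0, min_relationship); the subject is excluded from both sums.
    A subject with no at-risk relatives scores 0 and is flagged degenerate.
    """
    if subject not in pedigree:
        raise KeyError(f"unknown subject {subject!r}")
    fam = pedigree.family_of(subject)
    num = den = 0.0
    for k, ind in pedigree.members.items():
        if k == subject or ind.family != fam or not ind.cohort_member:
            continue
        r = pedigree.relationship(subject, k)
        if r <= 0.0 or r < min_relationship:
            continue
        den += r
        if ind.affected:
            num += r
    if den == 0.0:
        return FamilialRisk(subject, 0.0, 0.0, 0.0, True)
    return FamilialRisk(subject, num, den, num / den, False)


def familial_risk_table(pedigree: Pedigree, subjects: list[str],
                        min_relationship: float = 0.0) -> pd.DataFrame:
    """Familial-risk scores for many subjects as a DataFrame."""
    rows = []
    for s in subjects:
        fr = familial_risk(s, pedigree, min_relationship)
        rows.append((s, fr.numerator, fr.denominator, fr.score, int(fr.degenerate)))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "numerator", "denominator", "familial_risk", "familial_risk_missing"],
    )


def matriline_of(subject: str, pedigree: Pedigree) -> str:
    """Maternal founder id: follow mother links to the matriline founder."""
    if subject not in pedigree:
        raise KeyError(f"unknown subject {subject!r}")
    cur = subject
    while True:
        mother = pedigree.members[cur].mother
        if mother is None:
            return cur
        cur = mother


ConflictPolicy = Literal["abort", "majority", "leave_missing"]


def impute_haplotypes(
    assignments: Mapping[str, str],
    pedigree: Pedigree,
    conflict: ConflictPolicy = "abort",
) -> tuple[dict[str, str], dict[str, bool], list[str]]:
    """Extend genotyped subject -> haplotype assignments along matrilines.

    Every ungenotyped matriline member whose matriline carries exactly one
    observed haplotype receives it; matrilines without a genotyped member
    stay missing. Observed assignments are never overwritten. Matrilines
    whose genotyped members disagree are handled per ``conflict``: abort
    (raise), majority (most common haplotype, ties alphabetical; existing
    observed assignments kept as-is), or leave_missing (only genotyped
    members keep assignments). Returns (extended assignment, imputed flag per
    subject, log messages).
    """
    log: list[str] = []
    by_matriline: dict[str, list[str]] = {}
    for s in pedigree.members:
        by_matriline.setdefault(matriline_of(s, pedigree), []).append(s)
    extended: dict[str, str] = {}
    imputed: dict[str, bool] = {}
    for s, hap in assignments.items():
        if s not in pedigree:
            raise KeyError(f"genotyped subject {s!r} not in pedigree")
        extended[s] = hap
        imputed[s] = False
    for founder, members in sorted(by_matriline.items()):
        observed = sorted({assignments[s] for s in members if s in assignments})
        if not observed:
            continue
        if len(observed) > 1:
            msg = (f"matriline {founder}: discordant haplotypes {observed} "
                   f"among genotyped members")
            if conflict == "abort":
                raise ValueError(msg)
            log.append(msg + f" (policy={conflict})")
            if conflict == "leave_missing":
                continue
            counts: dict[str, int] = {}
            for s in members:
                if s in assignments:
                    counts[assignments[s]] = counts.get(assignments[s], 0) + 1
            hap = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        else:
            hap = observed[0]
        for s in members:
            if s not in extended:
                extended[s] = hap
                imputed[s] = True
    return extended, imputed, log
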