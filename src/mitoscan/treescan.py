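"""Branch-partition association scanning with permutation correction.

Each branch of the haplotype network pools haplotypes into two allelic
classes; being haploid there are exactly two genotypes per branch. Eligible
branches (>= ``min_class_size`` phenotyped subjects in each class) are tested
by a likelihood-ratio statistic for the branch allele in a logistic model of
case status on allele + covariates (Firth-penalized by default, so a clade
with zero cases still yields a finite, rankable statistic).

Inference is by permutation: the subject-to-haplotype assignment is shuffled
across all subjects (phenotypes and covariates stay attached to subjects),
all eligible branch statistics are recomputed per permutation, and nominal
p-values use the add-one convention (b+1)/(B+1). Family-wise correction is
step-down minP (the permutation analogue of the step-down Bonferroni
method), which honours the strong correlation among branches of one network
and permits more than one significant branch. Conditional second-round scans
add a significant branch's allele as a fixed covariate to ask whether other
branches carry the same or a different signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _glm
from .network import BranchPartition, HaplotypeNetwork, enumerate_partitions
from .variants import Variant

#: absolute slack when comparing permuted to observed statistics (covers
#: solver tolerance; distinct contingency configurations differ by far more)
_TIE_EPS = 1e-7

FIRTH_LRT = "firth_lrt"
LRT = "lrt"


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    B: number of permutations. alpha: family-wise significance threshold for
    corrected p-values. min_class_size: minimum phenotyped subjects per
    allelic class for a branch to enter the test family. covariates: column
    names in the subject table entering every model. flavor: ``firth_lrt``
    (default) or plain ``lrt``. exhaustive: enumerate all assignment
    permutations instead of sampling B (only feasible for tiny cohorts);
    p-values are then exact (#{stat >= observed}/n!, identity included).
    """

    B: int = 10000
    alpha: float = 0.05
    min_class_size: int = 5
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "male", "apoe4", "apoe2")
    flavor: str = FIRTH_LRT
    exhaustive: bool = False
    max_iter: int = 25
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.flavor not in (FIRTH_LRT, LRT):
            raise ValueError(f"unknown statistic flavor {self.flavor!r}")


@dataclass(frozen=True)
class ScanResult:
    """Outcome of one branch test in one scan round."""

    branch_id: str
    resolution_id: int
    n_resolutions: int
    round: int
    nominal_p: float
    corrected_p: float
    statistic: float
    beta: float  # log-odds of case status for the clade (side_b) allele
    n_case_a: int
    n_ctrl_a: int
    n_case_b: int
    n_ctrl_b: int
    defining_variants: tuple[Variant, ...]
    degenerate: bool = False
    note: str = ""

    @property
    def direction(self) -> str:
        return "protective" if self.beta < 0 else "risk"


def branch_genotypes(
    partition: BranchPartition,
    assignment: Mapping[str, Optional[str]],
    subjects: Sequence[str],
) -> pd.Series:
    """Per-subject haploid allele for one branch: 0 = side_a, 1 = side_b.

    Subjects without a haplotype assignment, or whose haplotype lies in a
    different network component, get a missing (NaN) genotype. A haplotype id
    that is neither side of the partition's component raises only if the
    caller validates against the network; here unknown ids are treated as
    out-of-component.
    """
    values = np.full(len(subjects), np.nan)
    side_a, side_b = partition.side_a, partition.side_b
    for i, s in enumerate(subjects):
        hap = assignment.get(s)
        if hap is None or (isinstance(hap, float) and math.isnan(hap)):
            continue
        if hap in side_b:
            values[i] = 1.0
        elif hap in side_a:
            values[i] = 0.0
    return pd.Series(values, index=list(subjects), name=partition.branch_id)


def is_eligible(
    genotypes: pd.Series, phenotypes: pd.Series, min_class_size: int
) -> bool:
    """True iff both allelic classes hold >= min_class_size phenotyped subjects."""
    ok = genotypes.notna() & phenotypes.notna()
    n1 = int((genotypes[ok] == 1).sum())
    n0 = int((genotypes[ok] == 0).sum())
    return n0 >= min_class_size and n1 >= min_class_size


def branch_statistic(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    flavor: str = FIRTH_LRT,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Likelihood-ratio statistic and asymptotic chi2(1) p for one branch.

    Rows with any missing value are dropped listwise. Raises on a genotype
    that is constant after deletion (the branch is ineligible).
    """
    genotype = np.asarray(genotype, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    cols = [np.ones_like(genotype)]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != genotype.shape[0]:
            covariates = covariates.T
        cols.extend(covariates.T)
    cols.append(genotype)
    X = np.column_stack(cols)
    keep = ~np.isnan(X).any(axis=1) & ~np.isnan(phenotype)
    X, y = X[keep], phenotype[keep]
    g = X[:, -1]
    if g.min() == g.max():
        raise ValueError("genotype constant after listwise deletion (ineligible branch)")
    stat, _, converged = _glm.lrt_last_column(X, y, firth=(flavor == FIRTH_LRT),
                                              max_iter=max_iter, tol=tol)
    if not converged or not np.isfinite(stat):
        raise RuntimeError("branch statistic did not converge within the iteration cap")
    return float(stat), float(sps.chi2.sf(stat, df=1))


def _count_ge(sorted_col: np.ndarray, values: np.ndarray) -> np.ndarray:
    """#{entries of sorted_col >= v - eps} for each v."""
    n = sorted_col.shape[0]
    return n - np.searchsorted(sorted_col, np.asarray(values) - _TIE_EPS, side="left")


def _pvalues_minp(
    S: np.ndarray, s_obs: np.ndarray, add_one: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nominal and step-down-minP corrected p-values.

    S: (B, K) permuted statistics; s_obs: (K,) observed statistics. With
    ``add_one`` the sampled-permutation convention (b+1)/(B+1) applies;
    without it (exhaustive enumeration, identity permutation included in S)
    p = b/B exactly. Corrected p-values are computed by comparing each
    ordered nominal p to the permutation distribution of the minimum
    per-permutation p-value over the not-yet-rejected branches, then
    monotonized along the rejection order.
    """
    B, K = S.shape
    denom = B + 1 if add_one else B
    plus = 1 if add_one else 0
    sorted_cols = np.sort(S, axis=0)
    nominal = np.empty(K)
    Q = np.empty((B, K))  # per-permutation p-value of each branch statistic:
    # each permuted value is ranked within its own column, where its
    # self-count plays the role the add-one plays for the observed value, so
    # observed and permuted p-values share one scale (min attainable 1/denom)
    for k in range(K):
        nominal[k] = (plus + _count_ge(sorted_cols[:, k], s_obs[k : k + 1])[0]) / denom
        Q[:, k] = _count_ge(sorted_cols[:, k], S[:, k]) / denom
    order = np.lexsort((np.arange(K), -s_obs, nominal))
    # step-down: walking branches from most to least significant, each is
    # compared to the min-p envelope over the not-yet-rejected suffix, so
    # accumulate the envelope backwards and keep only the counts.
    counts = np.empty(K, dtype=np.int64)
    acc = np.full(B, np.inf)
    for j in range(K - 1, -1, -1):
        acc = np.minimum(acc, Q[:, order[j]])
        counts[j] = int((acc <= nominal[order[j]] + 1e-12).sum())
    corrected = np.empty(K)
    prev = 0.0
    for j, k in enumerate(order):
        c = max((plus + counts[j]) / denom, prev)
        corrected[k] = min(c, 1.0)
        prev = corrected[k]
    return nominal, corrected, order


def _subject_arrays(
    subjects: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(idx, y, C) for subjects with phenotype and complete covariates."""
    pheno = subjects["ad_status"].to_numpy(dtype=float)
    C_all = np.column_stack(
        [np.ones(len(subjects))]
        + [subjects[c].to_numpy(dtype=float) for c in covariates]
    )
    keep = ~np.isnan(pheno) & ~np.isnan(C_all).any(axis=1)
    idx = np.flatnonzero(keep).astype(np.int64)
    return idx, pheno[keep], C_all[keep]


def _genotype_matrix(
    partitions: Sequence[BranchPartition],
    assignment: Mapping[str, Optional[str]],
    subject_ids: Sequence[str],
) -> np.ndarray:
    """(K, N) int8 genotype matrix over all subjects, -1 = missing."""
    side_maps = []
    for p in partitions:
        m: dict[str, int] = {}
        for h in p.side_a:
            m[h] = 0
        for h in p.side_b:
            m[h] = 1
        side_maps.append(m)
    G = np.full((len(partitions), len(subject_ids)), -1, dtype=np.int8)
    for j, s in enumerate(subject_ids):
        hap = assignment.get(s)
        if hap is None or (isinstance(hap, float) and math.isnan(hap)):
            continue
        for k, m in enumerate(side_maps):
            G[k, j] = m.get(hap, -1)
    return G


def _make_permutations(
    n: int, config: ScanConfig, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Permutation matrix and whether p-values are exact (exhaustive)."""
    if config.exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration only supported for n <= 8 subjects")
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
        return perms, True
    perms = np.empty((config.B, n), dtype=np.int64)
    for b in range(config.B):
        perms[b] = rng.permutation(n)
    return perms, False


def permutation_scan(
    network: HaplotypeNetwork,
    subjects: pd.DataFrame,
    config: ScanConfig,
    partitions: Optional[Sequence[BranchPartition]] = None,
    conditioning: Optional[np.ndarray] = None,
    round_index: int = 1,
) -> list[ScanResult]:
    """Scan every eligible branch of the network.

    ``subjects`` must hold columns ``subject_id``, ``haplotype`` (nullable)
    and ``ad_status`` (1 = case, 0 = control, NaN = missing), plus the
    configured covariate columns. ``conditioning`` (internal; used by
    conditional rounds) is a per-subject 0/1/NaN allele vector appended to
    the covariates and *not* permuted.
    """
    if partitions is None:
        partitions = enumerate_partitions(network)
    subject_ids = subjects["subject_id"].tolist()
    assignment = dict(zip(subject_ids, subjects["haplotype"].tolist()))
    pheno = subjects["ad_status"].to_numpy(dtype=float)

    work = subjects
    cov_names = list(config.covariates)
    if conditioning is not None:
        work = subjects.copy()
        work["_conditioning"] = conditioning
        cov_names = cov_names + ["_conditioning"]
    idx, y, C = _subject_arrays(work, cov_names)

    G_all = _genotype_matrix(partitions, assignment, subject_ids)

    eligible: list[int] = []
    degenerate: list[tuple[BranchPartition, str]] = []
    for k, part in enumerate(partitions):
        g = G_all[k, idx].astype(float)
        g[G_all[k, idx] < 0] = np.nan
        ok = ~np.isnan(g)
        n1 = int(np.nansum(g[ok]))
        n0 = int(ok.sum()) - n1
        if n0 < config.min_class_size or n1 < config.min_class_size:
            continue
        if conditioning is not None:
            cond = conditioning[idx][ok]
            gg = g[ok]
            if np.all(gg == cond) or np.all(gg == 1 - cond):
                degenerate.append((part, "collinear with conditioning allele"))
                continue
        eligible.append(k)

    results: list[ScanResult] = []
    for part, note in degenerate:
        results.append(
            ScanResult(
                branch_id=part.branch_id,
                resolution_id=part.resolution_id,
                n_resolutions=part.n_resolutions,
                round=round_index,
                nominal_p=float("nan"),
                corrected_p=float("nan"),
                statistic=float("nan"),
                beta=float("nan"),
                n_case_a=0, n_ctrl_a=0, n_case_b=0, n_ctrl_b=0,
                defining_variants=part.defining_variants,
                degenerate=True,
                note=note,
            )
        )
    if not eligible:
        if degenerate:
            return results
        raise ValueError("no eligible branches to test")

    G = np.ascontiguousarray(G_all[eligible])
    firth = config.flavor == FIRTH_LRT
    beta_red, ll_red, conv = _glm._fit_logistic(
        C.copy(), y, firth, np.zeros(C.shape[1]), config.max_iter, config.tol
    )
    if not conv:
        raise RuntimeError("covariate-only model did not converge")

    rng = np.random.default_rng(config.seed)
    perms, exact = _make_permutations(len(subject_ids), config, rng)
    identity = np.arange(len(subject_ids), dtype=np.int64)[None, :]

    s_obs = _glm._scan_kernel(
        G, identity, idx, y, C, firth, beta_red, ll_red, config.max_iter, config.tol
    )[0]
    S = _glm._scan_kernel(
        G, perms, idx, y, C, firth, beta_red, ll_red, config.max_iter, config.tol
    )
    nominal, corrected, _ = _pvalues_minp(S, s_obs, add_one=not exact)

    for j, k in enumerate(eligible):
        part = partitions[k]
        g = G_all[k, idx].astype(float)
        g[G_all[k, idx] < 0] = np.nan
        ok = ~np.isnan(g)
        yv, gv = y[ok], g[ok]
        n_case_b = int(((yv == 1) & (gv == 1)).sum())
        n_ctrl_b = int(((yv == 0) & (gv == 1)).sum())
        n_case_a = int(((yv == 1) & (gv == 0)).sum())
        n_ctrl_a = int(((yv == 0) & (gv == 0)).sum())
        X = np.column_stack([C[ok], gv])
        beta_hat, _, _ = _glm._fit_logistic(
            X, yv, firth, np.append(beta_red, 0.0), config.max_iter, config.tol
        )
        results.append(
            ScanResult(
                branch_id=part.branch_id,
                resolution_id=part.resolution_id,
                n_resolutions=part.n_resolutions,
                round=round_index,
                nominal_p=float(nominal[j]),
                corrected_p=float(corrected[j]),
                statistic=float(s_obs[j]),
                beta=float(beta_hat[-1]),
                n_case_a=n_case_a,
                n_ctrl_a=n_ctrl_a,
                n_case_b=n_case_b,
                n_ctrl_b=n_ctrl_b,
                defining_variants=part.defining_variants,
            )
        )
    results.sort(key=lambda r: (r.degenerate, r.nominal_p if not math.isnan(r.nominal_p) else 2.0,
                                r.branch_id))
    return results


def conditional_scan(
    prior: ScanResult,
    network: HaplotypeNetwork,
    subjects: pd.DataFrame,
    config: ScanConfig,
    partitions: Optional[Sequence[BranchPartition]] = None,
) -> list[ScanResult]:
    """Second-round scan conditioning on a significant prior branch.

    The prior branch's allele (computed from the *observed* assignment) is
    added as a fixed subject-level covariate; branch genotypes still permute.
    Branches collinear with the conditioning allele are reported degenerate.
    """
    if not (prior.corrected_p < config.alpha):
        raise ValueError("conditioning branch is not significant at config.alpha")
    if partitions is None:
        partitions = enumerate_partitions(network)
    part_by_id = {p.branch_id: p for p in partitions}
    if prior.branch_id not in part_by_id:
        raise KeyError(f"unknown branch {prior.branch_id}")
    subject_ids = subjects["subject_id"].tolist()
    assignment = dict(zip(subject_ids, subjects["haplotype"].tolist()))
    cond = branch_genotypes(part_by_id[prior.branch_id], assignment, subject_ids).to_numpy()
    if np.nanmin(cond) == np.nanmax(cond):
        raise ValueError("conditioning allele is constant")
    return permutation_scan(
        network,
        subjects,
        config,
        partitions=partitions,
        conditioning=cond,
        round_index=prior.round + 1,
    )


def scan_rounds(
    network: HaplotypeNetwork,
    subjects: pd.DataFrame,
    config: ScanConfig,
    partitions: Optional[Sequence[BranchPartition]] = None,
    max_rounds: int = 5,
) -> list[ScanResult]:
    """Round-1 scan plus conditional rounds until no new significant branch.

    Each round conditions on the most significant branch of the previous
    round (ties broken by statistic). Returns the concatenated results of
    all rounds, tagged by their ``round`` field.
    """
    if partitions is None:
        partitions = enumerate_partitions(network)
    all_results = permutation_scan(network, subjects, config, partitions=partitions)
    prior_ids: set[str] = set()
    current = all_results
    for _ in range(max_rounds - 1):
        hits = [r for r in current if not r.degenerate and r.corrected_p < config.alpha
                and r.branch_id not in prior_ids]
        if not hits:
            break
        top = min(hits, key=lambda r: (r.nominal_p, -r.statistic, r.branch_id))
        prior_ids.add(top.branch_id)
        current = conditional_scan(top, network, subjects, config, partitions=partitions)
        all_results.extend(current)
    return all_results
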