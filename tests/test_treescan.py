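"""Branch genotypes, eligibility, statistics, and permutation inference."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mitoscan.network import build_network, enumerate_partitions
from mitoscan.treescan import (
    ScanConfig,
    branch_genotypes,
    branch_statistic,
    conditional_scan,
    is_eligible,
    permutation_scan,
    scan_rounds,
)
from mitoscan.variants import SNV, Variant

from conftest import make_haplotypes, tiny_subjects


def v(pos):
    return Variant(pos, SNV, "A", "G")


@pytest.fixture(scope="module")
def path_network():
    haps = make_haplotypes(
        {"A": frozenset(), "B": frozenset({v(1)}), "C": frozenset({v(1), v(2)})},
        counts={"A": 3, "B": 2, "C": 2},
    )
    net = build_network(haps)
    return net, enumerate_partitions(net)


class TestBranchGenotypes:
    def test_all_side_a_is_zero_vector(self, path_network):
        net, parts = path_network
        part = next(p for p in parts if p.side_b == frozenset({"C"}))
        g = branch_genotypes(part, {"s1": "A", "s2": "B"}, ["s1", "s2"])
        assert list(g) == [0.0, 0.0]

    def test_unassigned_subject_missing(self, path_network):
        net, parts = path_network
        part = parts[0]
        g = branch_genotypes(part, {"s1": "A", "s2": None}, ["s1", "s2"])
        assert math.isnan(g["s2"])

    def test_split_counts(self, path_network):
        net, parts = path_network
        part = next(p for p in parts if p.side_b == frozenset({"C"}))
        assignment = {f"a{i}": "A" for i in range(10)} | {f"c{i}": "C" for i in range(28)}
        g = branch_genotypes(part, assignment, sorted(assignment))
        assert int(g.sum()) == 28 and len(g) == 38


class TestEligibility:
    @pytest.mark.parametrize(
        "n0,n1,expected", [(4, 100, False), (5, 5, True), (0, 10, False), (100, 4, False)]
    )
    def test_class_size_rule(self, n0, n1, expected):
        g = pd.Series([0.0] * n0 + [1.0] * n1)
        y = pd.Series([0.0] * (n0 + n1))
        assert is_eligible(g, y, 5) is expected

    def test_only_phenotyped_subjects_count(self):
        g = pd.Series([0.0] * 5 + [1.0] * 5)
        y = pd.Series([0.0] * 5 + [np.nan] * 5)
        assert is_eligible(g, y, 5) is False


def g_statistic(n00, n01, n10, n11):
    """Closed-form 2x2 likelihood-ratio G (independent oracle)."""
    total = n00 + n01 + n10 + n11
    g = 0.0
    for (obs, row, col) in [
        (n00, n00 + n01, n00 + n10), (n01, n00 + n01, n01 + n11),
        (n10, n10 + n11, n00 + n10), (n11, n10 + n11, n01 + n11),
    ]:
        if obs > 0:
            g += 2.0 * obs * math.log(obs * total / (row * col))
    return g


class TestBranchStatistic:
    def test_identical_class_proportions_give_zero(self):
        g = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([1.0] * 5 + [0.0] * 5 + [1.0] * 5 + [0.0] * 5)
        stat, p = branch_statistic(g, y, flavor="lrt")
        assert stat == pytest.approx(0.0, abs=1e-6)

    def test_lrt_equals_contingency_G(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = rng.integers(1, 40, size=4)  # n00, n01, n10, n11
            g = np.repeat([0.0, 0.0, 1.0, 1.0], counts)
            y = np.repeat([0.0, 1.0, 0.0, 1.0], counts)
            stat, _ = branch_statistic(g, y, flavor="lrt")
            assert stat == pytest.approx(g_statistic(*counts), abs=1e-6)

    def test_lrt_with_covariates_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 150
        age = rng.normal(size=n)
        g = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.5 * age + 0.7 * g)))).astype(float)
        stat, _ = branch_statistic(g, y, covariates=age[:, None], flavor="lrt")
        X_full = np.column_stack([np.ones(n), age, g])
        ll_full = sm.Logit(y, X_full).fit(disp=0).llf
        ll_red = sm.Logit(y, X_full[:, :2]).fit(disp=0).llf
        assert stat == pytest.approx(2 * (ll_full - ll_red), abs=1e-6)

    def test_firth_finite_under_complete_separation(self):
        g = np.array([1.0] * 20 + [0.0] * 80)
        y = np.array([0.0] * 20 + [1.0] * 30 + [0.0] * 50)  # all carriers controls
        stat, p = branch_statistic(g, y, flavor="firth_lrt")
        assert np.isfinite(stat) and stat > 0

    def test_constant_genotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            branch_statistic(np.zeros(10), np.ones(10))


def exhaustive_oracle(haps_of, phenotype, sides, min_class=2):
    """Exact enumeration over all assignment permutations (independent code).

    Returns (nominal, corrected) per branch using the G statistic, the exact
    p convention (#{stat >= observed}/n!, identity included), and step-down
    minP with monotonicity.
    """
    subjects = sorted(haps_of)
    labels = [haps_of[s] for s in subjects]
    y = np.array([phenotype[s] for s in subjects])

    def stats_for(perm):
        out = []
        for side_b in sides:
            g = np.array([1.0 if labels[i] in side_b else 0.0 for i in perm])
            n11 = int(((g == 1) & (y == 1)).sum()); n10 = int(((g == 1) & (y == 0)).sum())
            n01 = int(((g == 0) & (y == 1)).sum()); n00 = int(((g == 0) & (y == 0)).sum())
            if min(n00 + n01, n10 + n11) == 0:
                out.append(0.0)
            else:
                out.append(g_statistic(n00, n01, n10, n11))
        return out

    perms = list(itertools.permutations(range(len(subjects))))
    S = np.array([stats_for(p) for p in perms])
    obs = np.array(stats_for(tuple(range(len(subjects)))))
    N = len(perms)
    eps = 1e-9
    nominal = np.array([(S[:, k] >= obs[k] - eps).sum() / N for k in range(len(sides))])
    Q = np.stack([
        np.array([(S[:, k] >= S[b, k] - eps).sum() / N for b in range(N)])
        for k in range(len(sides))
    ], axis=1)
    order = np.lexsort((np.arange(len(sides)), -obs, nominal))
    corrected = np.empty(len(sides))
    prev = 0.0
    for j, k in enumerate(order):
        rest = order[j:]
        c = (Q[:, rest].min(axis=1) <= nominal[k] + 1e-12).sum() / N
        corrected[k] = max(prev, c)
        prev = corrected[k]
    return nominal, corrected


class TestExhaustivePermutation:
    def test_matches_enumeration_oracle_n7(self, path_network):
        """Nominal and corrected p equal exact enumeration over all 7! assignments."""
        net, parts = path_network
        assignment = {"s1": "A", "s2": "A", "s3": "A", "s4": "B", "s5": "B",
                      "s6": "C", "s7": "C"}
        phenotype = {"s1": 1, "s2": 0, "s3": 1, "s4": 0, "s5": 0, "s6": 1, "s7": 0}
        subjects = tiny_subjects(assignment, phenotype)
        cfg = ScanConfig(B=1, exhaustive=True, min_class_size=2, covariates=(),
                         flavor="lrt", seed=0)
        results = permutation_scan(net, subjects, cfg, partitions=parts)
        sides, keep = [], []
        for p in parts:
            g = branch_genotypes(p, assignment, sorted(assignment))
            if is_eligible(g, pd.Series([phenotype[s] for s in sorted(assignment)],
                                        index=sorted(assignment), dtype=float), 2):
                sides.append(p.side_b)
                keep.append(p.branch_id)
        nominal, corrected = exhaustive_oracle(assignment, phenotype, sides)
        by_id = {r.branch_id: r for r in results}
        for bid, nom, corr in zip(keep, nominal, corrected):
            assert by_id[bid].nominal_p == pytest.approx(nom, abs=1e-12)
            assert by_id[bid].corrected_p == pytest.approx(corr, abs=1e-12)

    def test_weak_branch_has_p_one(self, path_network):
        net, parts = path_network
        # near-constant phenotype: p-values stay in (0, 1] and dominance holds
        assignment = {f"s{i}": h for i, h in enumerate(["A", "A", "B", "B", "C", "C"])}
        phenotype = {s: 0 for s in assignment}
        phenotype["s0"] = 1
        subjects = tiny_subjects(assignment, phenotype)
        cfg = ScanConfig(B=1, exhaustive=True, min_class_size=2, covariates=(),
                         flavor="lrt", seed=0)
        results = permutation_scan(net, subjects, cfg, partitions=parts)
        top = min(r.nominal_p for r in results)
        assert all(r.corrected_p >= r.nominal_p for r in results)
        assert max(r.corrected_p for r in results) <= 1.0


@pytest.fixture(scope="module")
def small_cohort():
    rng = np.random.default_rng(3)
    haps = make_haplotypes(
        {"A": frozenset(), "B": frozenset({v(1)}), "C": frozenset({v(1), v(2)}),
         "D": frozenset({v(3)})},
        counts={"A": 30, "B": 25, "C": 25, "D": 20},
    )
    net = build_network(haps)
    parts = enumerate_partitions(net)
    labels = ["A"] * 30 + ["B"] * 25 + ["C"] * 25 + ["D"] * 20
    assignment = {f"s{i:03d}": h for i, h in enumerate(labels)}
    phenotype = {s: int(rng.random() < 0.3) for s in assignment}
    age = {s: float(70 + 8 * rng.standard_normal()) for s in assignment}
    subjects = tiny_subjects(assignment, phenotype, age=age)
    return net, parts, subjects


class TestSampledPermutation:
    def test_corrected_dominates_nominal(self, small_cohort):
        net, parts, subjects = small_cohort
        cfg = ScanConfig(B=300, seed=9, covariates=("age",))
        results = permutation_scan(net, subjects, cfg, partitions=parts)
        assert results
        for r in results:
            assert r.corrected_p >= r.nominal_p - 1e-12
            assert 0 < r.nominal_p <= 1

    def test_deterministic_given_seed(self, small_cohort):
        net, parts, subjects = small_cohort
        cfg = ScanConfig(B=100, seed=4, covariates=("age",))
        r1 = permutation_scan(net, subjects, cfg, partitions=parts)
        r2 = permutation_scan(net, subjects, cfg, partitions=parts)
        assert [(x.nominal_p, x.corrected_p) for x in r1] == [
            (x.nominal_p, x.corrected_p) for x in r2
        ]

    def test_class_counts_reported(self, small_cohort):
        net, parts, subjects = small_cohort
        cfg = ScanConfig(B=50, seed=1, covariates=("age",))
        for r in permutation_scan(net, subjects, cfg, partitions=parts):
            total = r.n_case_a + r.n_ctrl_a + r.n_case_b + r.n_ctrl_b
            assert total == int(subjects["ad_status"].notna().sum())


@pytest.fixture(scope="module")
def planted():
    """Detectable configuration: small branch family, large zero-case clade."""
    import logging

    logging.disable(logging.INFO)
    from mitoscan.simulate import SimParams, simulate_cohort
    from mitoscan.variants import collapse_haplotypes

    params = SimParams(
        n_subjects=400, n_matrilines=110, H=40, theta=250, growth_rate=200,
        ref_length=2000, effect_clade_size=90, beta=-np.inf, seed=21,
    )
    cohort = simulate_cohort(params)
    subj = cohort.subjects.copy()
    sv = {r.subject_id: set(cohort.genealogy.variant_sets[r.tip])
          for r in subj.itertuples()}
    haps, assign = collapse_haplotypes(sv)
    subj["haplotype"] = subj["subject_id"].map(assign)
    net = build_network(haps)
    parts = enumerate_partitions(net)
    carrier_haps = frozenset(assign[s] for s in subj[subj.carrier]["subject_id"])
    planted_ids = {p.branch_id for p in parts
                   if p.side_b == carrier_haps or p.side_a == carrier_haps}
    cfg = ScanConfig(B=2000, seed=5)
    results = permutation_scan(net, subj, cfg, partitions=parts)
    return net, parts, subj, cfg, results, planted_ids, carrier_haps


class TestConditionalScan:
    def test_planted_branch_significant_in_round_one(self, planted):
        net, parts, subj, cfg, results, planted_ids, _ = planted
        hit = [r for r in results if r.branch_id in planted_ids]
        assert hit and hit[0].corrected_p < cfg.alpha
        assert hit[0].direction == "protective"

    def test_conditioning_marks_identical_branch_degenerate(self, planted):
        net, parts, subj, cfg, results, planted_ids, _ = planted
        prior = next(r for r in results if r.branch_id in planted_ids)
        round2 = conditional_scan(prior, net, subj, cfg, partitions=parts)
        r2 = {r.branch_id: r for r in round2}
        assert r2[prior.branch_id].degenerate

    def test_nested_branch_loses_significance_when_conditioned(self, planted):
        net, parts, subj, cfg, results, planted_ids, carrier_haps = planted
        prior = next(r for r in results if r.branch_id in planted_ids)
        nested_hits = [
            r for r in results
            if r.branch_id not in planted_ids and r.corrected_p < cfg.alpha
            and any(p.branch_id == r.branch_id and
                    (p.side_b < carrier_haps or p.side_a < carrier_haps)
                    for p in parts)
        ]
        round2 = conditional_scan(prior, net, subj, cfg, partitions=parts)
        r2 = {r.branch_id: r for r in round2}
        for r in nested_hits:
            follow = r2.get(r.branch_id)
            assert follow is None or follow.degenerate or follow.corrected_p >= cfg.alpha

    def test_conditioning_on_orthogonal_branch_keeps_planted_significant(self, planted):
        net, parts, subj, cfg, results, planted_ids, carrier_haps = planted
        part_by_id = {p.branch_id: p for p in parts}
        orth = next(
            r for r in sorted(results, key=lambda x: x.branch_id)
            if not r.degenerate and r.branch_id not in planted_ids
            and not (part_by_id[r.branch_id].side_b & carrier_haps)
        )
        cond = branch_genotypes(
            part_by_id[orth.branch_id],
            dict(zip(subj["subject_id"], subj["haplotype"])),
            subj["subject_id"].tolist(),
        ).to_numpy()
        round2 = permutation_scan(net, subj, cfg, partitions=parts,
                                  conditioning=cond, round_index=2)
        r2 = {r.branch_id: r for r in round2}
        planted_r2 = next(r2[b] for b in planted_ids if b in r2)
        assert planted_r2.corrected_p < 0.05

    def test_scan_rounds_tags_rounds(self, planted):
        net, parts, subj, cfg, results, planted_ids, _ = planted
        allr = scan_rounds(net, subj, cfg, partitions=parts, max_rounds=2)
        assert {r.round for r in allr} == {1, 2}
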