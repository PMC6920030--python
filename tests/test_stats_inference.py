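"""Statistical stage: exhaustive-enumeration oracles for the exact tests,
placement-value and bootstrap oracles for DeLong, mixed-model limits."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from liverdwi.stats_inference import (
    ContingencyTable2x2,
    clopper_pearson_interval,
    delong_ci,
    delong_paired_test,
    fisher_exact_2x2,
    lmm_group_comparison,
    logistic_combined_auc,
    mann_whitney_u_exact,
    roc_with_youden,
)


# --------------------------------------------------------------------------
# independent oracles

def mw_enumeration_oracle(x, y):
    """Two-sided Mann-Whitney p by brute force over all label assignments,
    computing U by direct pair counting (ties half-weighted) — a different
    route than the implementation's rank-sum enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def u_stat(first_idx):
        first = pooled[list(first_idx)]
        rest = pooled[[i for i in range(n) if i not in first_idx]]
        gt = (first[:, None] > rest[None, :]).sum()
        eq = (first[:, None] == rest[None, :]).sum()
        return gt + 0.5 * eq

    mean_u = n1 * (n - n1) / 2
    obs = abs(u_stat(tuple(range(n1))) - mean_u)
    assignments = list(itertools.combinations(range(n), n1))
    count = sum(abs(u_stat(a) - mean_u) >= obs - 1e-9 for a in assignments)
    return count / len(assignments)


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = stats.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def auc_pair_count_oracle(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# Mann-Whitney / Fisher

class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u_exact([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_case(self):
        # only the 2 extreme assignments out of C(5,2)=10 are as extreme
        _, p = mann_whitney_u_exact([1, 2], [3, 4, 5])
        assert p == pytest.approx(0.2)

    def test_matches_enumeration_oracle_small_n(self, rng):
        for trial in range(25):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 5))
            # integer draws force ties regularly
            x = rng.integers(0, 5, n1).astype(float)
            y = rng.integers(0, 5, n2).astype(float)
            _, p = mann_whitney_u_exact(x, y)
            assert p == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12), \
                (x, y)

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 30)
        _, p = mann_whitney_u_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(float(ref), rel=1e-12)


class TestFisherExact:
    def test_study_sex_table(self):
        p = fisher_exact_2x2(ContingencyTable2x2(4, 8, 4, 1))
        assert p == pytest.approx(0.131, abs=5e-4)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            a, b, c, d = (int(v) for v in rng.integers(0, 8, 4))
            if a + b == 0 or c + d == 0:
                continue
            tab = ContingencyTable2x2(a, b, c, d)
            assert fisher_exact_2x2(tab) == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), abs=1e-9)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


# --------------------------------------------------------------------------
# Clopper-Pearson

class TestClopperPearson:
    @pytest.mark.parametrize("k, n, lo, hi", [
        (5, 5, 47.8, 100.0),
        (9, 12, 42.8, 94.5),
        (10, 10, 69.2, 100.0),
        (20, 24, 62.6, 95.3),
        (23, 24, 78.9, 99.9),
        (8, 10, 44.4, 97.5),
        (19, 24, 57.8, 92.9),
        (16, 24, 44.7, 84.4),
    ])
    def test_published_interval_endpoints(self, k, n, lo, hi):
        got_lo, got_hi = clopper_pearson_interval(k, n)
        assert got_lo == pytest.approx(lo, abs=0.05)
        assert got_hi == pytest.approx(hi, abs=0.05)

    def test_boundary_counts(self):
        assert clopper_pearson_interval(0, 7)[0] == 0.0
        assert clopper_pearson_interval(7, 7)[1] == 100.0

    def test_invalid_counts_rejected(self):
        for k, n in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(ValueError):
                clopper_pearson_interval(k, n)

    def test_coverage_at_least_nominal(self, rng):
        """Exact binomial intervals are conservative: simulated coverage
        >= 95% at every (p, n) combination."""
        for p in (0.1, 0.5, 0.9):
            for n in (5, 10, 24):
                ks = rng.binomial(n, p, 10_000)
                uniq, counts = np.unique(ks, return_counts=True)
                covered = 0
                for k, c in zip(uniq, counts):
                    lo, hi = clopper_pearson_interval(int(k), n)
                    if lo <= 100 * p <= hi:
                        covered += c
                assert covered / 10_000 >= 0.95 - 0.006  # MC slack


# --------------------------------------------------------------------------
# mixed model

def _measurement_frame(ba_means, non_means, noise_sd, rng, replicates=2):
    rows = []
    for g, means in (("BA", ba_means), ("non-BA", non_means)):
        for i, mu in enumerate(means):
            pid = f"{g}{i}"
            for _ in range(replicates):
                rows.append({"patient_id": pid, "group": g,
                             "value": mu + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestLinearMixedModel:
    def test_zero_replicate_variance_equals_patient_mean_t_test(self, rng):
        """With identical within-patient replicates the model reduces to a
        two-sample comparison of patient means."""
        ba = rng.normal(1.0, 0.2, 8)
        non = rng.normal(1.4, 0.2, 5)
        df = _measurement_frame(ba, non, noise_sd=0.0, rng=rng)
        res = lmm_group_comparison(df, "value")
        t_p = stats.ttest_ind(ba, non, equal_var=True).pvalue
        assert res.p_value == pytest.approx(float(t_p), abs=0.02)
        assert res.estimates["BA"][0] == pytest.approx(ba.mean(), rel=1e-6)
        assert res.estimates["non-BA"][0] == pytest.approx(non.mean(), rel=1e-6)

    def test_null_p_values_roughly_uniform(self, rng):
        """With no group effect the p-value distribution is ~uniform: the
        5%-level rejection rate over replicates stays near 5%."""
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            means = rng.normal(1.0, 0.3, 16)
            df = _measurement_frame(means[:8], means[8:], noise_sd=0.15, rng=rng)
            res = lmm_group_comparison(df, "value")
            rejections += res.p_value < 0.05
        # binomial(120, 0.05): 3 sigma ~ 0.06
        assert rejections / n_rep < 0.13

    def test_recovers_simulated_group_effect(self, rng):
        ba = rng.normal(1.0, 0.2, 200)
        non = rng.normal(1.35, 0.2, 200)
        df = _measurement_frame(ba, non, noise_sd=0.1, rng=rng)
        res = lmm_group_comparison(df, "value")
        delta = res.estimates["non-BA"][0] - res.estimates["BA"][0]
        se = (res.estimates["non-BA"][2] - res.estimates["non-BA"][1]) / (2 * 1.96)
        assert abs(delta - 0.35) < 2 * se * math.sqrt(2)
        assert res.p_value < 1e-6

    def test_requires_two_groups_and_two_patients(self):
        df = pd.DataFrame({"patient_id": ["a", "a"], "group": ["BA", "BA"],
                           "value": [1.0, 1.1]})
        with pytest.raises(ValueError):
            lmm_group_comparison(df, "value")


# --------------------------------------------------------------------------
# ROC / Youden / DeLong

class TestROC:
    def test_perfect_separation(self):
        res = roc_with_youden([3, 4, 5, 1, 2], [1, 1, 1, 0, 0], "higher")
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_lower_orientation_criterion(self):
        res = roc_with_youden([0.9, 1.0, 1.4, 1.5], [1, 1, 0, 0], "lower")
        assert res.auc == 1.0
        assert res.criterion.startswith("<=")
        assert res.cutoff == pytest.approx(1.0)

    def test_null_scores_auc_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = np.arange(2000) < 1000
        res = roc_with_youden(scores, labels, "higher")
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_pair_count_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 11))
            scores = rng.integers(0, 6, n).astype(float)  # with ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_with_youden(scores, labels, "higher")
            assert res.auc == pytest.approx(
                auc_pair_count_oracle(scores, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        base = roc_with_youden(scores, labels, "higher").auc
        for fn in (np.exp, lambda s: s ** 3, lambda s: 1 / (1 + np.exp(-s))):
            assert roc_with_youden(fn(scores), labels, "higher").auc == \
                pytest.approx(base, abs=1e-12)

    def test_youden_tie_break_prefers_specificity(self):
        # cutoffs 2 and 3 both give Youden = 0.5; 3 has higher specificity
        scores = np.array([1, 2, 3, 4, 3, 4, 5, 6], dtype=float)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        res = roc_with_youden(scores, labels, "higher")
        sens = 100 * (scores[labels] > res.cutoff).mean()
        spec = 100 * (scores[~labels] <= res.cutoff).mean()
        assert sens + spec == pytest.approx(res.sensitivity + res.specificity)
        assert res.specificity == 100.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_youden([1, 2, 3], [1, 1, 1], "higher")


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=20)
        labels = np.arange(20) < 8
        out = delong_paired_test(s, s, labels)
        assert out["p"] == 1.0
        assert "degenerate_variance" in out["flags"]

    def test_variance_matches_enumerated_placement_values(self, rng):
        """DeLong CI variance against hand-enumerated placement values on
        random small instances."""
        for _ in range(15):
            n = int(rng.integers(6, 13))
            scores = rng.normal(size=n)
            labels = np.zeros(n, bool)
            labels[:int(rng.integers(2, n - 1))] = True
            pos, neg = scores[labels], scores[~labels]
            v10 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                     for q in neg]) for p in pos])
            v01 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                     for p in pos]) for q in neg])
            var = (np.var(v10, ddof=1) / len(pos)
                   + np.var(v01, ddof=1) / len(neg))
            auc, lo, hi = delong_ci(scores, labels)
            assert auc == pytest.approx(v10.mean(), abs=1e-12)
            if var > 0:
                half = stats.norm.ppf(0.975) * math.sqrt(var)
                assert lo == pytest.approx(max(0.0, auc - half), abs=1e-12)
                assert hi == pytest.approx(min(1.0, auc + half), abs=1e-12)

    def test_p_close_to_paired_bootstrap(self, rng):
        """Paired DeLong p within 0.05 of a 2000-resample paired bootstrap
        on correlated simulated markers."""
        n_pos, n_neg = 30, 30
        base = np.concatenate([rng.normal(0.8, 1, n_pos), rng.normal(0, 1, n_neg)])
        a = base + rng.normal(0, 0.4, n_pos + n_neg)
        b = 0.8 * base + rng.normal(0, 0.6, n_pos + n_neg)
        labels = np.arange(n_pos + n_neg) < n_pos
        out = delong_paired_test(a, b, labels)

        def auc(scores, lab):
            pos, neg = scores[lab], scores[~lab]
            return (pos[:, None] > neg[None, :]).mean() + \
                0.5 * (pos[:, None] == neg[None, :]).mean()

        deltas = []
        idx_pos, idx_neg = np.where(labels)[0], np.where(~labels)[0]
        for _ in range(2000):
            rp = rng.choice(idx_pos, n_pos)
            rn = rng.choice(idx_neg, n_neg)
            take = np.concatenate([rp, rn])
            lab = np.arange(n_pos + n_neg) < n_pos
            deltas.append(auc(a[take], lab) - auc(b[take], lab))
        deltas = np.asarray(deltas)
        se_boot = deltas.std(ddof=1)
        z = out["delta"] / se_boot
        p_boot = 2 * stats.norm.sf(abs(z))
        assert out["p"] == pytest.approx(p_boot, abs=0.05)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2, 3], [True, False, True])


# --------------------------------------------------------------------------
# logistic combination

class TestLogisticCombination:
    def test_constant_second_marker_reduces_to_single(self, rng):
        adc2 = np.concatenate([rng.normal(1.0, 0.1, 12), rng.normal(1.35, 0.1, 5)])
        labels = np.arange(17) < 12
        ggt = np.full(17, 200.0)
        combined = logistic_combined_auc(adc2, ggt, labels)
        single = roc_with_youden(-adc2, labels, "higher")
        assert combined.auc == pytest.approx(single.auc, abs=1e-9)

    def test_separating_pair_flagged(self, rng):
        adc2 = np.concatenate([np.full(6, 0.9), np.full(4, 1.4)])
        ggt = np.concatenate([np.full(6, 400.0), np.full(4, 90.0)])
        labels = np.arange(10) < 6
        res = logistic_combined_auc(adc2, ggt, labels)
        assert res.auc == 1.0
        assert "complete_separation" in res.flags

    def test_combination_not_worse_than_best_single(self, rng):
        """On cohorts with the published group separation the combined AUC
        beats max(single AUCs) - 0.02 in >= 90% of replicates."""
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            n_ba, n_non = 12, 5
            labels = np.arange(n_ba + n_non) < n_ba
            adc2 = np.concatenate([rng.lognormal(np.log(0.987), 0.13, n_ba),
                                   rng.lognormal(np.log(1.335), 0.13, n_non)])
            ggt = np.concatenate([rng.lognormal(np.log(368), 0.8, n_ba),
                                  rng.lognormal(np.log(93.5), 0.35, n_non)])
            combined = logistic_combined_auc(adc2, ggt, labels).auc
            best = max(roc_with_youden(-adc2, labels, "higher").auc,
                       roc_with_youden(ggt, labels, "higher").auc)
            wins += combined >= best - 0.02
        assert wins / n_rep >= 0.90

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            logistic_combined_auc([1, 2, 3], [1, 2, 3], [True, False, False])
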