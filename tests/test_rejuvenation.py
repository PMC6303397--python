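"""Overlap enrichment, SASP scoring, tilt regression, and anti-correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senokit.errors import DataValidationError
from senokit.expression import FoldChangeTable, fold_change_table, log_expression, size_factors
from senokit.rejuvenation import (
    anti_correlation,
    compare_sasp_scores,
    overlap_enrichment,
    parse_report,
    read_gmt,
    rejuvenation_report,
    sasp_enrichment,
    sasp_score,
    serialize_report,
    tilt_regression,
    write_gmt,
)


def hypergeom_tail_by_enumeration(N, K, n, k):
    """P(overlap >= k) by summing the exact pmf C(K,i) C(N-K,n-i) / C(N,n)."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


class TestOverlap:
    def test_hand_enumerated_example(self):
        universe = [f"g{i}" for i in range(10)]
        res = overlap_enrichment(universe[:5], universe[1:5], universe)
        assert res.n_overlap == 4
        assert res.p_value == pytest.approx(5 / 210)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = overlap_enrichment(universe[:3], universe[3:6], universe)
        assert res.n_overlap == 0
        assert res.p_value == 1.0

    def test_set_a_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        res = overlap_enrichment(universe, universe[:3], universe)
        assert res.n_overlap == 3
        assert res.p_value == pytest.approx(1.0)

    def test_overlap_fraction_uses_set_b_denominator(self):
        universe = [f"g{i}" for i in range(20)]
        res = overlap_enrichment(universe[:10], universe[6:14], universe)
        assert res.overlap_fraction_of_b == pytest.approx(4 / 8)

    def test_non_subset_rejected_naming_genes(self):
        with pytest.raises(DataValidationError, match="stray"):
            overlap_enrichment(["stray"], ["a"], ["a", "b"])

    def test_matches_enumeration_on_small_universes(self):
        universe = [f"g{i}" for i in range(9)]
        for K, n, k in [(4, 3, 2), (5, 5, 3), (2, 7, 1), (9, 4, 4)]:
            set_a = universe[:K]
            set_b = universe[K - k : K - k + n]
            res = overlap_enrichment(set_a, set_b, universe)
            assert res.n_overlap == k
            assert res.p_value == pytest.approx(hypergeom_tail_by_enumeration(9, K, n, k))


class TestSaspEnrichment:
    def test_all_sasp_affected_is_extreme(self):
        universe = [f"g{i}" for i in range(12)]
        sasp = universe[:4]
        res = sasp_enrichment(affected=universe[:4], sasp=sasp, universe=universe)
        assert res.p_value == pytest.approx(hypergeom_tail_by_enumeration(12, 4, 4, 4))
        assert res.p_value == pytest.approx(1 / math.comb(12, 4))

    def test_disjoint_sets_give_p_one(self):
        universe = [f"g{i}" for i in range(12)]
        res = sasp_enrichment(affected=universe[6:], sasp=universe[:4], universe=universe)
        assert res.p_value == 1.0

    def test_sasp_restricted_to_universe(self):
        universe = [f"g{i}" for i in range(10)]
        res = sasp_enrichment(affected=universe[:3], sasp=universe[:4] + ["offpanel"],
                              universe=universe)
        assert res.n_set_a == 4


def _fct_from(table: pd.DataFrame) -> FoldChangeTable:
    return FoldChangeTable(table=table, tissue="t", detection_threshold=1.0)


class TestSaspScore:
    def test_hand_mean(self):
        table = pd.DataFrame(
            {"lfc_age": [1.0, 2.0, 3.0, 9.9], "lfc_treat_vs_young": [0.5, 0.5, 0.5, 9.9],
             "lfc_treat": 0.0, "detected": [True, True, True, False]},
            index=["s1", "s2", "s3", "s4"],
        )
        score = sasp_score(_fct_from(table), ["s1", "s2", "s3", "s4"], "vehicle_vs_young")
        assert score.score == pytest.approx(2.0)
        assert score.n_detected == 3
        assert score.defined

    def test_undefined_when_nothing_detected(self):
        table = pd.DataFrame(
            {"lfc_age": [1.0], "lfc_treat_vs_young": [1.0], "lfc_treat": [0.0],
             "detected": [False]}, index=["s1"],
        )
        score = sasp_score(_fct_from(table), ["s1"], "treated_vs_young")
        assert not score.defined
        assert math.isnan(score.score)

    def test_linearity_in_ratios(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=8)
        table = pd.DataFrame(
            {"lfc_age": vals, "lfc_treat_vs_young": vals, "lfc_treat": 0.0, "detected": True},
            index=[f"s{i}" for i in range(8)],
        )
        s1 = sasp_score(_fct_from(table), table.index, "vehicle_vs_young").score
        table2 = table.assign(lfc_age=table["lfc_age"] * 3.0)
        s2 = sasp_score(_fct_from(table2), table.index, "vehicle_vs_young").score
        assert s2 == pytest.approx(3.0 * s1)

    def test_vehicle_two_fold_elevation_scores_one(self, tiny_counts):
        # large, zero-free counts make the pseudocount negligible
        counts = (tiny_counts.counts + 1) * 1000
        counts[["liver_old_vehicle_r1", "liver_old_vehicle_r2"]] = (
            counts[["liver_young_r1", "liver_young_r2"]].to_numpy() * 2
        )
        lm = log_expression(counts, pd.Series(1.0, index=counts.columns))
        fct = fold_change_table(lm, tiny_counts.metadata, "liver")
        score = sasp_score(fct, ["gA", "gB", "gC"], "vehicle_vs_young")
        assert score.score == pytest.approx(1.0, abs=1e-3)


def signed_rank_p_by_enumeration(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = (ranks * np.array(signs)).sum()
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / 2**n


class TestCompareSaspScores:
    def test_identical_ratios_give_p_one(self):
        v = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        assert compare_sasp_scores(v, v.copy()) == 1.0

    def test_constant_shift_attains_minimal_p(self):
        idx = [f"g{i}" for i in range(10)]
        v = pd.Series(np.linspace(0.5, 2.0, 10), index=idx)
        t = v - 1.0
        assert compare_sasp_scores(v, t) == pytest.approx(2 / 2**10)

    def test_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            idx = [f"g{i}" for i in range(9)]
            v = pd.Series(rng.normal(1.0, 0.5, 9), index=idx)
            t = pd.Series(v.to_numpy() - rng.normal(0.4, 0.5, 9), index=idx)
            p = compare_sasp_scores(v, t)
            assert p == pytest.approx(signed_rank_p_by_enumeration((t - v).to_numpy()))

    def test_no_pairs_rejected(self):
        with pytest.raises(DataValidationError, match="no paired"):
            compare_sasp_scores(pd.Series(dtype=float), pd.Series(dtype=float))


class TestTiltRegression:
    def test_identity_fit_p_one(self):
        x = np.arange(10.0)
        res = tilt_regression(x, x)
        assert res.tilt == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_exact_half_slope_p_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = tilt_regression(x, 0.5 * x)
        assert res.tilt == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.0)
        assert res.p_value == 0.0

    def test_recovers_true_tilt_from_noise_free_effects(self):
        rng = np.random.default_rng(5)
        beta = rng.normal(0, 1, 50)
        for kappa in (0.0, 0.25, 1.0):
            res = tilt_regression(beta, (1 - kappa) * beta)
            assert res.tilt == pytest.approx(1 - kappa, abs=1e-12)

    def test_matches_statsmodels_inference(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(0, 0.3, size=40)
        res = tilt_regression(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.tilt == pytest.approx(fit.params[1])
        assert res.slope_se == pytest.approx(fit.bse[1])
        # two-sided p against slope = 1
        t = (fit.params[1] - 1) / fit.bse[1]
        assert res.t_statistic == pytest.approx(t)
        lo, hi = fit.conf_int(alpha=0.05)[1]
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    def test_too_few_or_degenerate_inputs_rejected(self):
        with pytest.raises(DataValidationError, match=">= 3"):
            tilt_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DataValidationError, match="no aging signal"):
            tilt_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_estimation_bias_shrinks_with_replicates(self):
        """Count-estimated tilts carry a finite-replicate bias that shrinks with n.

        Both axes share the young-group mean, so the x-noise attenuation and
        the shared-noise covariance combine into a bias proportional to
        (2*kappa - 1) times the per-gene noise variance.  At kappa = 1 the
        true tilt is 0 and the estimate is biased upward; more replicates
        shrink the noise and the bias monotonically.
        """
        from senokit.simulate import ExpressionSimConfig, simulate_counts

        tilts = []
        for reps in (3, 5, 10):
            per_seed = []
            for seed in range(5):
                cfg = ExpressionSimConfig(
                    n_genes=4000, n_replicates_per_group=reps, tissues=("kidney",),
                    baseline_mean_log2=(5.0, 1.5), dispersion=0.1, age_effect_sd=1.0,
                    frac_age_affected=0.5, rejuvenation_kappa=1.0,
                    treatment_noise_sd=0.0, seed=400 + seed,
                )
                cm, truth = simulate_counts(cfg)
                lm = log_expression(cm.counts, size_factors(cm.counts))
                fct = fold_change_table(lm, cm.metadata, "kidney")
                t = truth.tissue_truth("kidney")
                genes = t.index[t["affected_by_age"]]
                per_seed.append(tilt_regression(fct, genes=genes).tilt)
            tilts.append(np.mean(per_seed))
        assert tilts[0] > tilts[1] > tilts[2] > 0.0
        assert tilts[2] < 0.1


def spearman_p_by_enumeration_no_ties(x, y):
    """Exact two-sided p from the d^2 closed form over all n! permutations."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        rho = 1 - 6 * np.sum((rx - np.array(perm)) ** 2) / (n * (n**2 - 1))
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


class TestAntiCorrelation:
    def test_perfect_monotone_relations(self):
        res = anti_correlation([1, 2, 3], [3, 2, 1])
        assert res.rho == pytest.approx(-1.0)
        res = anti_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.rho == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=7)
        y = -0.7 * x + rng.normal(0, 0.5, size=7)
        res = anti_correlation(x, y)
        assert res.method == "exact_permutation"
        assert res.p_value == pytest.approx(spearman_p_by_enumeration_no_ties(x, y))

    def test_exact_p_with_ties_matches_scipy_per_permutation(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 0.5])
        res = anti_correlation(x, y)
        rho_obs = stats.spearmanr(x, y).statistic
        count = total = 0
        for perm in itertools.permutations(y):
            rho = stats.spearmanr(x, perm).statistic
            count += abs(rho) >= abs(rho_obs) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total)

    def test_large_n_uses_asymptotic_method(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        res = anti_correlation(x, y)
        assert res.method == "asymptotic_t"
        assert res.p_value == pytest.approx(stats.spearmanr(x, y).pvalue)

    def test_invariance_under_monotone_transforms(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = anti_correlation(x, y)
        transformed = anti_correlation(np.exp(x), y**3)
        assert transformed.rho == pytest.approx(base.rho)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataValidationError, match="constant"):
            anti_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestReport:
    def test_report_structure_and_round_trip(self, small_sim, tmp_path):
        _, cm, truth = small_sim
        report = rejuvenation_report(cm, truth.sasp_gene_ids)
        text = serialize_report(report)
        assert parse_report(text) == parse_report(serialize_report(parse_report(text)))
        for tissue in ("kidney", "liver"):
            entry = report["tissues"][tissue]
            assert entry["n_detected_genes"] > 0
            assert 0 <= entry["overlap"]["p_value"] <= 1
        assert set(report["combined"]["euler"]) == {"age_only", "treatment_only", "both"}

    def test_strong_rejuvenation_signals(self, small_sim):
        """kappa = 0.6 simulation: tilt near 0.4, negative rho, enriched SASP."""
        _, cm, truth = small_sim
        report = rejuvenation_report(cm, truth.sasp_gene_ids)
        for tissue in ("kidney", "liver"):
            entry = report["tissues"][tissue]
            tilt = entry["tilt"]
            assert tilt["tilt"] < 0.7  # attenuation keeps it near, below 1
            assert tilt["p_value"] < 1e-6
            assert entry["anti_correlation"]["rho"] < -0.5
            assert entry["sasp_enrichment"]["p_value"] < 0.05

    def test_gmt_round_trip(self, tmp_path):
        sets = {"sasp_standin": [f"g{i:05d}" for i in range(10)]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path, description="synthetic")
        assert read_gmt(path) == sets
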