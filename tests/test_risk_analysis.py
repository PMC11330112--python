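import numpy as np
import pytest

from deeprisk.pipeline import PipelineConfig
from deeprisk.risk_analysis import (
    auc,
    cross_validate,
    odds_ratio,
    percentile_prevalence,
    proportion_at_fold_risk,
    risk_snp_counts,
    risk_snp_subgroup_auc,
    snp_removal_robustness,
    stratified_fold_indices,
    stratify,
)
from deeprisk.simulator import (
    ArchitectureSpec,
    SimConfig,
    run_discovery_gwas,
    simulate_genotypes,
    simulate_phenotype,
)
from deeprisk.snp_selection import SelectionParams


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestOddsRatio:
    def test_table_substitution(self):
        # top 20% of 500: TD=10 TE=90; remainder RD=10 RE=390
        scores = np.concatenate([np.linspace(2, 1, 100), np.linspace(0.9, 0, 400)])
        labels = np.zeros(500, int)
        labels[:10] = 1      # 10 cases in the top group
        labels[100:110] = 1  # 10 cases in the remainder
        orv, summary = odds_ratio(scores, labels, 0.2)
        assert orv == pytest.approx(4.3333, abs=1e-4)
        assert (summary.TD, summary.TE, summary.RD, summary.RE) == (10, 90, 10, 390)

    def test_equal_prevalence_gives_unity(self):
        scores = np.linspace(1, 0, 100)
        labels = np.tile([1, 0, 0, 0], 25)  # 25% prevalence in every quartile
        orv, _ = odds_ratio(scores, labels, 0.2)
        assert orv == pytest.approx(1.0)

    def test_exact_match_with_direct_2x2_over_random_draws(self, rng):
        for _ in range(1000):
            n = int(rng.integers(20, 200))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            frac = float(rng.uniform(0.05, 0.95))
            orv, s = odds_ratio(scores, labels, frac)
            k = int(np.ceil(frac * n))
            top = np.argsort(-scores, kind="stable")[:k]
            mask = np.zeros(n, bool)
            mask[top] = True
            td, te = labels[mask].sum(), k - labels[mask].sum()
            rd, re = labels[~mask].sum(), (n - k) - labels[~mask].sum()
            expected = float("inf") if (te == 0 or rd == 0) else (td * re) / (te * rd)
            assert orv == expected

    def test_null_scores_or_near_one(self):
        rng = np.random.default_rng(0)
        ors = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            scores = r.normal(size=10_000)
            labels = (r.random(10_000) < 0.1).astype(int)
            orv, _ = odds_ratio(scores, labels, 0.2)
            ors.append(orv)
        assert 0.8 < np.mean(ors) < 1.25

    def test_zero_cell_reports_infinity(self):
        scores = np.array([3.0, 2.0, 1.0, 0.5])
        labels = np.array([1, 1, 0, 0])
        orv, _ = odds_ratio(scores, labels, 0.5)  # top half all cases -> RD=0
        assert orv == float("inf")


class TestProportionAtFoldRisk:
    def test_perfect_separation_has_positive_fraction(self):
        scores = np.concatenate([np.linspace(2, 1.5, 50), np.linspace(1, 0, 50)])
        labels = np.concatenate([np.ones(50, int), np.zeros(50, int)])
        assert proportion_at_fold_risk(scores, labels, 3.0) > 0

    def test_constant_scores_give_zero(self):
        # ties broken by stable sample order, so keep cases off the prefix
        labels = np.tile([0, 0, 0, 0, 1], 40)
        assert proportion_at_fold_risk(np.ones(200), labels, 3.0) == 0.0

    def test_matches_brute_force_sweep(self, rng):
        for _ in range(30):
            n = int(rng.integers(30, 150))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            fold = float(rng.uniform(1.0, 4.0))
            best = 0.0
            for k in range(1, n):
                orv, _ = odds_ratio(scores, labels, k / n)
                if orv >= fold:
                    best = max(best, k / n)
            assert proportion_at_fold_risk(scores, labels, fold) == pytest.approx(best)


class TestPercentilePrevalence:
    def test_conservation_weighted_mean_equals_overall(self, rng):
        for _ in range(20):
            n = int(rng.integers(100, 500))
            scores = rng.normal(size=n)
            scores[rng.random(n) < 0.3] = 0.0  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            prev, _, _ = percentile_prevalence(scores, labels)
            from scipy.stats import rankdata

            pct = rankdata(scores, method="average") / n * 100
            bins = np.clip(np.ceil(pct).astype(int) - 1, 0, 99)
            weights = np.bincount(bins, minlength=100) / n
            assert np.dot(weights, prev) == pytest.approx(labels.mean(), abs=1e-12)

    def test_null_scores_show_no_trend(self):
        from scipy.stats import spearmanr

        r = np.random.default_rng(2)
        scores = r.normal(size=10_000)
        labels = (r.random(10_000) < 0.2).astype(int)
        prev, med_case, med_ctrl = percentile_prevalence(scores, labels)
        rho = spearmanr(np.arange(100), prev).statistic
        assert abs(rho) < 0.3
        assert abs(med_case - med_ctrl) < 5

    def test_predictive_scores_enrich_top_bin(self):
        r = np.random.default_rng(3)
        liab = r.normal(size=5000)
        labels = (liab > np.quantile(liab, 0.8)).astype(int)
        scores = liab + 0.5 * r.normal(size=5000)
        prev, med_case, med_ctrl = percentile_prevalence(scores, labels)
        assert prev[99] > prev[0]
        assert med_case > med_ctrl

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            percentile_prevalence(np.arange(50.0), np.tile([0, 1], 25))


class TestAUC:
    def test_perfect_and_reversed(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc(scores, labels) == 1.0
        assert auc(scores, 1 - labels) == 0.0

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        base = auc(scores, labels)
        for f in (np.exp, np.tanh, lambda x: 3 * x - 7):
            assert auc(f(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.arange(5.0), np.ones(5, int))


class TestStratifyReport:
    def test_report_shapes(self, rng):
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        rep = stratify(scores, labels)
        assert len(rep.prevalence_bins) == 100
        assert np.all((rep.prevalence_bins >= 0) & (rep.prevalence_bins <= 1))
        assert set(rep.proportion_at_fold) == {3.0, 4.0, 5.0}


class TestCrossValidation:
    def test_folds_partition_and_stratify(self):
        y = np.array([1] * 30 + [0] * 70)
        folds = stratified_fold_indices(y, 10, seed=0)
        allidx = np.concatenate(folds)
        assert len(allidx) == 100 and len(np.unique(allidx)) == 100
        for f in folds:
            assert y[f].sum() == 3  # exactly 3 cases per fold

    def test_null_phenotype_mean_auc_near_half(self):
        """P+T pipeline on a label-free-signal cohort: mean CV AUC ~ 0.5."""
        cfg = SimConfig(n_snps=50, n_genes=10, n_chromosomes=2, ld_block_size=5,
                        missing_rate=0.0, seed=17)
        geno = simulate_genotypes(cfg, 4000, seed=17)
        simulate_phenotype(geno, ArchitectureSpec(prevalence=0.3), seed=18)
        panel = simulate_genotypes(cfg, 300, seed=19)
        disc = simulate_genotypes(cfg, 1000, seed=20)
        simulate_phenotype(disc, ArchitectureSpec(prevalence=0.3), seed=21)
        stats = run_discovery_gwas(disc)
        pcfg = PipelineConfig(method="pt", selection=SelectionParams(0.9, None))
        _, mean_auc = cross_validate(geno, stats, panel, pcfg, k=10, seed=0)
        assert 0.45 < mean_auc < 0.55

    def test_full_pipeline_cv_detects_epistatic_signal(self):
        """10-fold CV of the complete deep pipeline on the epistatic benchmark."""
        from deeprisk.benchmarks import (
            BENCH_MODEL_CFG,
            BENCH_SELECTION,
            epistatic_benchmark,
        )

        bench = epistatic_benchmark(seed=0)
        pcfg = PipelineConfig(method="deeprisk", selection=BENCH_SELECTION,
                              genes=bench.genes, model_cfg=BENCH_MODEL_CFG)
        fold_aucs, mean_auc = cross_validate(
            bench.cohort, bench.stats, bench.panel, pcfg, k=10, seed=0
        )
        se = np.std(fold_aucs, ddof=1) / np.sqrt(len(fold_aucs))
        assert mean_auc > 0.5 + 3 * se

    def test_too_few_cases_rejected(self, small_panel):
        geno = small_panel.subset_samples(np.arange(30))
        geno.phenotype = np.array([1] * 5 + [0] * 25, dtype=np.int8)
        with pytest.raises(ValueError, match="at least"):
            cross_validate(geno, None, None, None, k=10, seed=0)


class TestRiskSnpSubgroups:
    @pytest.fixture()
    def cohort_with_stats(self, labelled_cohort):
        stats = run_discovery_gwas(labelled_cohort)
        return labelled_cohort, stats

    def test_counts_match_brute_force(self, cohort_with_stats):
        from deeprisk.data_io import MISSING

        geno, stats = cohort_with_stats
        counts = risk_snp_counts(geno, stats)
        tab = stats.table
        risk_ids = set(tab.index[(tab["p_value"] < 5e-8) & (tab["beta"] > 0)])
        idx = geno.variant_index()
        for i in range(0, geno.n_samples, 37):
            manual = sum(
                1 for vid in risk_ids
                if geno.alt_counts[i, idx[vid]] != MISSING and geno.alt_counts[i, idx[vid]] >= 1
            )
            assert counts[i] == manual

    def test_zero_alt_alleles_zero_count(self, cohort_with_stats):
        geno, stats = cohort_with_stats
        ds = geno.subset_samples(np.arange(5))
        ds.alt_counts[:] = 0
        assert np.all(risk_snp_counts(ds, stats) == 0)

    def test_max_cutoff_recovers_whole_cohort_auc(self, cohort_with_stats, rng):
        geno, stats = cohort_with_stats
        scores = rng.normal(size=geno.n_samples)
        counts = risk_snp_counts(geno, stats)
        aucs, one_pct = risk_snp_subgroup_auc(
            scores, geno.phenotype, geno, stats, [int(counts.max())]
        )
        assert aucs[int(counts.max())] == pytest.approx(auc(scores, geno.phenotype))
        assert 0 <= one_pct <= counts.max()


class TestRemovalRobustness:
    def test_zero_removal_is_noop_and_error_on_excess(self, labelled_cohort, small_panel):
        stats = run_discovery_gwas(labelled_cohort)
        pcfg = PipelineConfig(method="pt", selection=SelectionParams(0.5, None))
        res = snp_removal_robustness(labelled_cohort, stats, small_panel, pcfg,
                                     removals=(2,), seed=0)
        base = snp_removal_robustness(labelled_cohort, stats, small_panel, pcfg,
                                      removals=(), seed=0)
        assert res[0] == base[0]
        with pytest.raises(ValueError, match="cannot remove"):
            snp_removal_robustness(labelled_cohort, stats, small_panel, pcfg,
                                   removals=(10_000,), seed=0)

    def test_concentrated_signal_collapses_to_chance(self):
        """All signal in the top GWAS SNPs: removal drives AUC toward 0.5."""
        cfg = SimConfig(n_snps=30, n_genes=6, n_chromosomes=2, ld_block_size=1,
                        within_block_rho=0.0, missing_rate=0.0, seed=23)
        arch = ArchitectureSpec(
            n_causal_additive=5, additive_indices=[0, 6, 12, 18, 24],
            additive_betas=[0.8] * 5, heritability_like_scale=0.6, prevalence=0.3,
        )
        geno = simulate_genotypes(cfg, 3000, seed=23)
        simulate_phenotype(geno, arch, seed=24)
        disc = simulate_genotypes(cfg, 3000, seed=25)
        simulate_phenotype(disc, arch, seed=26)
        stats = run_discovery_gwas(disc)
        panel = simulate_genotypes(cfg, 300, seed=27)
        pcfg = PipelineConfig(method="pt", selection=SelectionParams(0.5, None))
        res = snp_removal_robustness(geno, stats, panel, pcfg, removals=(5,), seed=0)
        assert res[0] > 0.65
        assert abs(res[5] - 0.5) < 0.08
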