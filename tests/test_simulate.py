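import numpy as np
import pytest

from survscan import (
    CATEGORIES,
    CohortSimConfig,
    classify_table,
    scan_cohort,
    simulate_cohort,
    simulate_pan_cancer,
)
from survscan.simulate import enhanced_margin_cap


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        cfg = CohortSimConfig(n_samples=40, n_null_genes=5, n_prognostic_genes=3, seed=13)
        e1, c1, t1 = simulate_cohort(cfg)
        e2, c2, t2 = simulate_cohort(cfg)
        np.testing.assert_array_equal(e1.values, e2.values)
        np.testing.assert_array_equal(c1.time, c2.time)
        np.testing.assert_array_equal(c1.event, c2.event)
        assert t1 == t2

    def test_truth_covers_every_gene_exactly_once(self):
        cfg = CohortSimConfig(n_samples=30, n_null_genes=7, n_prognostic_genes=4, seed=0)
        expr, _, truth = simulate_cohort(cfg)
        assert set(truth.genes) == set(expr.gene_ids)
        assert sum(g.is_prognostic for g in truth.genes.values()) == 4

    def test_true_cutoff_reproduces_risk_partition(self):
        cfg = CohortSimConfig(
            n_samples=50, n_null_genes=0, n_prognostic_genes=5,
            true_cutoff_pct=60.0, seed=21,
        )
        expr, _, truth = simulate_cohort(cfg)
        partitions = [
            frozenset(np.flatnonzero(expr.values[i] > truth.genes[g].true_cutoff))
            for i, g in enumerate(expr.gene_ids)
        ]
        # every planted gene dichotomizes into the same latent risk group
        assert len(set(partitions)) == 1
        assert len(partitions[0]) == round(50 * 0.4)

    @pytest.mark.parametrize("target", [0.15, 0.30, 0.50])
    def test_censoring_fraction_calibrated_across_seeds(self, target):
        for seed in range(17):
            cfg = CohortSimConfig(
                n_samples=349, n_null_genes=1, n_prognostic_genes=0, log_hr=0.0,
                censoring_fraction_target=target, seed=seed,
            )
            _, clin, _ = simulate_cohort(cfg)
            realized = 1.0 - clin.event.mean()
            assert abs(realized - target) <= 0.05

    def test_zero_censoring_target_gives_all_events(self):
        cfg = CohortSimConfig(
            n_samples=30, n_null_genes=1, censoring_fraction_target=0.0, seed=2
        )
        _, clin, _ = simulate_cohort(cfg)
        assert clin.event.sum() == 30

    def test_marginal_distribution_of_planted_genes_is_lognormal_sample(self):
        # planting permutes order statistics, so planted and null rows have
        # identical marginal moments up to sampling noise
        cfg = CohortSimConfig(
            n_samples=349, n_null_genes=200, n_prognostic_genes=200, seed=5
        )
        expr, _, _ = simulate_cohort(cfg)
        logv = np.log(expr.values)
        prog_mean = logv[:200].mean()
        null_mean = logv[200:].mean()
        assert prog_mean == pytest.approx(null_mean, abs=0.02)

    def test_planted_positive_log_hr_recovered_as_unfavorable(self):
        cfg = CohortSimConfig(
            n_samples=160, n_null_genes=0, n_prognostic_genes=40, seed=3
        )
        expr, clin, _ = simulate_cohort(cfg)
        res = scan_cohort(expr, clin)
        recovered = [r for r in res if r.prognostic]
        assert len(recovered) >= 30
        unfav = sum(r.direction == "unfavorable" for r in recovered)
        assert unfav / len(recovered) >= 0.95

    def test_negative_log_hr_marks_favorable_truth(self):
        cfg = CohortSimConfig(
            n_samples=30, n_null_genes=0, n_prognostic_genes=2,
            log_hr=-1.0, seed=4,
        )
        _, _, truth = simulate_cohort(cfg)
        assert all(g.true_direction == "favorable" for g in truth.genes.values())

    def test_weibull_shape_still_calibrates_censoring(self):
        cfg = CohortSimConfig(
            n_samples=200, n_null_genes=1, weibull_shape=1.7,
            censoring_fraction_target=0.30, seed=6,
        )
        _, clin, _ = simulate_cohort(cfg)
        assert abs((1 - clin.event.mean()) - 0.30) <= 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 5},
            {"censoring_fraction_target": 1.0},
            {"true_cutoff_pct": 0.0},
            {"n_null_genes": 0, "n_prognostic_genes": 0},
            {"baseline_hazard": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(n_samples=30, n_null_genes=5, seed=0)
        with pytest.raises(ValueError):
            CohortSimConfig(**{**base, **kwargs})


class TestSimulatePanCancer:
    def test_planted_categories_recovered_at_eight_cancers(self):
        table, truth = simulate_pan_cancer(
            {c: 10 for c in CATEGORIES}, n_cancers=8, margin=1.2, seed=31
        )
        calls = classify_table(table)
        assert all(c.category == truth.categories[c.gene_id] for c in calls)

    def test_planted_categories_recovered_at_seventeen_cancers(self):
        table, truth = simulate_pan_cancer(
            {c: 10 for c in CATEGORIES}, n_cancers=17, margin=1.5, seed=32
        )
        calls = classify_table(table)
        assert all(c.category == truth.categories[c.gene_id] for c in calls)

    def test_empty_request_gives_empty_table(self):
        table, truth = simulate_pan_cancer({}, n_cancers=8, margin=1.5, seed=0)
        assert table.gene_ids == () and truth.categories == {}

    def test_group_enriched_needs_three_cancers(self):
        with pytest.raises(ValueError, match="GroupEnriched"):
            simulate_pan_cancer({"GroupEnriched": 1}, n_cancers=2, margin=1.2, seed=0)

    def test_enhanced_margin_cap_enforced(self):
        cap = enhanced_margin_cap(8)
        assert cap < 1.5
        with pytest.raises(ValueError, match="Enhanced"):
            simulate_pan_cancer({"Enhanced": 1}, n_cancers=8, margin=1.5, seed=0)
        # a wider table admits the same margin
        table, _ = simulate_pan_cancer({"Enhanced": 5}, n_cancers=17, margin=1.5, seed=0)
        assert len(table.gene_ids) == 5

    def test_margin_below_floor_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            simulate_pan_cancer({"Mixed": 1}, n_cancers=8, margin=1.0, seed=0)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate_pan_cancer({"Sparse": 1}, n_cancers=8, margin=1.2, seed=0)

    def test_same_seed_bit_identical(self):
        a, _ = simulate_pan_cancer({"Mixed": 5}, n_cancers=8, margin=1.2, seed=9)
        b, _ = simulate_pan_cancer({"Mixed": 5}, n_cancers=8, margin=1.2, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
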