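import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from survscan import (
    ClinicalTable,
    ExpressionMatrix,
    ScanConfig,
    candidate_cutoffs,
    logrank_test,
    read_scan_results,
    scan_cohort,
    scan_gene,
    write_scan_results,
)


class TestCandidateCutoffs:
    def test_integer_grid_window_matches_percentile_rule(self):
        values = np.arange(1, 101, dtype=float)
        cand = candidate_cutoffs(values, ScanConfig())
        # linear-interpolation percentiles of 1..100: P20=20.8, P80=80.2,
        # so the observed values inside the window are the integers 21..80
        np.testing.assert_array_equal(cand, np.arange(21, 81, dtype=float))

    def test_constant_vector_has_no_candidates(self):
        assert candidate_cutoffs(np.full(20, 3.0), ScanConfig()).size == 0

    def test_split_rule_drops_empty_high_group(self):
        cfg = ScanConfig(lower_pct=0, upper_pct=100, min_group_size=1)
        cand = candidate_cutoffs([1.0, 2.0], cfg)
        # cutoff 2 leaves the strictly-greater high group empty
        np.testing.assert_array_equal(cand, [1.0])

    @given(st.integers(0, 10_000))
    def test_candidates_inside_window_and_splits_legal(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.lognormal(0, 1, int(rng.integers(5, 40)))
        cfg = ScanConfig()
        cand = candidate_cutoffs(v, cfg)
        lo, hi = np.percentile(v, [cfg.lower_pct, cfg.upper_pct])
        assert np.all((cand >= lo) & (cand <= hi))
        for c in cand:
            n_high = int((v > c).sum())
            assert n_high >= cfg.min_group_size
            assert v.size - n_high >= cfg.min_group_size


def _clin(time, event):
    return ClinicalTable(
        tuple(f"S{i}" for i in range(len(time))),
        np.asarray(time, float),
        np.asarray(event, int),
    )


class TestScanGene:
    def test_low_median_gene_excluded_without_testing(self, small_cohort):
        row = np.full(10, 0.4)
        r = scan_gene(row, small_cohort)
        assert r.excluded and r.exclude_reason == "low_expression"
        assert r.n_cutoffs_scanned == 0 and not r.prognostic

    def test_constant_expressed_gene_excluded_as_degenerate(self, small_cohort):
        r = scan_gene(np.full(10, 5.0), small_cohort)
        assert r.excluded and r.exclude_reason == "degenerate"

    def test_perfect_separation_recovers_planted_partition(self):
        # high-expression half dies strictly earlier; no censoring
        rng = np.random.default_rng(1)
        n = 60
        expr = np.empty(n)
        expr[:30] = rng.uniform(6, 10, 30)   # early deaths
        expr[30:] = rng.uniform(1, 5, 30)
        time = np.concatenate([rng.uniform(1, 10, 30), rng.uniform(20, 30, 30)])
        clin = _clin(time, np.ones(n, int))
        r = scan_gene(expr, clin)
        assert not r.excluded and r.prognostic
        assert r.direction == "unfavorable"
        # the chosen cutoff reproduces the planted partition to within one
        # sample: at extreme separation, neighbouring splits have log-rank
        # p-values of the same order and the minimum may land one step off
        chosen = set(np.flatnonzero(expr > r.best_cutoff))
        assert len(chosen ^ set(range(30))) <= 1

    def test_min_p_dominates_median_cutoff(self):
        rng = np.random.default_rng(9)
        n = 61  # odd so the median is an observed value
        expr = rng.lognormal(1, 1, n)
        time = rng.exponential(10, n)
        clin = _clin(time, np.ones(n, dtype=int))
        r = scan_gene(expr, clin)
        med = float(np.median(expr))
        assert med in set(candidate_cutoffs(expr, ScanConfig()))
        at_median = logrank_test(clin.time, clin.event, (expr > med).astype(int))
        assert r.best_p <= at_median.p_value + 1e-15

    def test_observed_plus_expected_consistency(self, small_cohort):
        rng = np.random.default_rng(2)
        r = scan_gene(rng.lognormal(1, 1, 10), small_cohort)
        assert not r.excluded
        assert r.n_high + r.n_low == 10
        total_events = int(small_cohort.event.sum())
        assert 0 <= r.observed_high <= total_events
        assert 0 <= r.expected_high <= total_events


class TestScanCohort:
    def _cohort(self, rows, clin):
        return ExpressionMatrix(
            tuple(f"G{i}" for i in range(len(rows))),
            clin.sample_ids,
            np.asarray(rows, float),
        )

    def test_constant_gene_flagged_others_scanned(self, small_cohort):
        rng = np.random.default_rng(4)
        rows = [
            rng.lognormal(1, 1, 10),
            np.full(10, 2.0),
            rng.lognormal(1, 1, 10),
        ]
        res = scan_cohort(self._cohort(rows, small_cohort), small_cohort)
        assert [r.excluded for r in res] == [False, True, False]
        assert res[1].exclude_reason == "degenerate"

    def test_duplicate_gene_rows_give_identical_results(self, small_cohort):
        rng = np.random.default_rng(6)
        row = rng.lognormal(1, 1, 10)
        res = scan_cohort(self._cohort([row, row], small_cohort), small_cohort)
        a, b = res
        assert dataclasses.asdict(a) | {"gene_id": ""} == dataclasses.asdict(b) | {"gene_id": ""}

    def test_scan_is_deterministic(self, small_cohort):
        rng = np.random.default_rng(8)
        rows = rng.lognormal(1, 1, (5, 10))
        expr = self._cohort(rows, small_cohort)
        r1 = scan_cohort(expr, small_cohort)
        r2 = scan_cohort(expr, small_cohort)
        assert r1 == r2  # bit-identical dataclasses

    def test_misaligned_cohort_rejected(self, small_cohort):
        expr = ExpressionMatrix(
            ("G0",), tuple(f"X{i}" for i in range(10)), np.ones((1, 10))
        )
        with pytest.raises(ValueError, match="align"):
            scan_cohort(expr, small_cohort)

    def test_results_roundtrip_through_tsv(self, small_cohort, tmp_path):
        rng = np.random.default_rng(10)
        rows = [rng.lognormal(1, 1, 10), np.full(10, 0.2)]
        res = scan_cohort(self._cohort(rows, small_cohort), small_cohort)
        p = tmp_path / "scan.tsv"
        write_scan_results(res, p)
        back = read_scan_results(p)
        import pandas as pd

        from survscan.scan import results_to_frame

        pd.testing.assert_frame_equal(results_to_frame(back), results_to_frame(res))
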