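"""Batch labeling, PCA scores, metric-PC correlations, batch R2, prevalence."""

import datetime

import numpy as np
import pandas as pd
import pytest

import hookqc as hq
from hookqc.batch import (BatchLabeling, batch_r2, derive_batch_labels,
                          expression_matrix_from_estimates,
                          metric_pc_correlations, pc_scores, prevalence_table)
from hookqc.errors import ValidationError

from test_metrics import estimates_from_r


def meta(sample_id, exp, date):
    return hq.SampleMetadata(sample_id, exp, date)


class TestBatchLabels:
    def test_label_is_experiment_and_month(self):
        lab = derive_batch_labels(
            [meta("s1", "E1", datetime.date(2004, 3, 15))])
        assert lab.labels == ["E1·2004-03"]

    def test_same_experiment_different_months_split(self):
        lab = derive_batch_labels([
            meta("s1", "E1", datetime.date(2004, 3, 1)),
            meta("s2", "E1", datetime.date(2004, 4, 1)),
        ])
        assert lab.n_batches == 2

    def test_identical_labels_collapse(self):
        lab = derive_batch_labels([
            meta(f"s{i}", "E1", datetime.date(2004, 3, i + 1))
            for i in range(5)])
        assert lab.n_batches == 1


class TestExpressionMatrix:
    def test_values_are_log_r_plus_one(self):
        est = estimates_from_r([9.0, 9.0])
        m = expression_matrix_from_estimates([("a", est), ("b", est)])
        np.testing.assert_allclose(m.values, 1.0)
        assert m.sample_ids == ["a", "b"]

    def test_single_sample_column(self):
        m = expression_matrix_from_estimates([("a", estimates_from_r([1.0]))])
        assert m.values.shape == (1, 1)

    def test_mismatched_universe_rejected(self):
        a = estimates_from_r([1.0, 2.0])
        b = estimates_from_r([1.0, 2.0])
        b.probeset_ids = np.array(["x0", "x1"], dtype=object)
        with pytest.raises(ValidationError, match="universe"):
            expression_matrix_from_estimates([("a", a), ("b", b)])


class TestPCScores:
    def _rank1_matrix(self, n_feat=30, n_samp=10):
        u = np.linspace(-1, 1, n_feat)
        v = np.arange(1.0, n_samp + 1)
        return hq.ExpressionMatrix(
            feature_ids=[f"g{i}" for i in range(n_feat)],
            sample_ids=[f"s{j}" for j in range(n_samp)],
            values=np.outer(u, v))

    def test_rank_one_matrix_dominated_by_pc1(self):
        scores = pc_scores(self._rank1_matrix(), n_components=3)
        var = scores.var(axis=0)
        assert var["PC1"] / var.sum() > 0.999

    def test_sign_convention_invariant_to_sample_order(self):
        m = self._rank1_matrix()
        rng = np.random.default_rng(0)
        m.values += rng.normal(0, 0.01, m.values.shape)
        scores = pc_scores(m, n_components=2)
        perm = list(reversed(range(len(m.sample_ids))))
        m2 = hq.ExpressionMatrix(
            feature_ids=m.feature_ids,
            sample_ids=[m.sample_ids[i] for i in perm],
            values=m.values[:, perm])
        scores2 = pc_scores(m2, n_components=2)
        np.testing.assert_allclose(
            scores2.loc[scores.index].to_numpy(), scores.to_numpy(),
            atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            pc_scores(self._rank1_matrix(n_samp=4), n_components=5)


class TestMetricPCCorrelations:
    def _scores(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 5)),
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            columns=[f"PC{j + 1}" for j in range(5)]), rng

    def test_metric_equal_to_pc1_correlates_perfectly(self):
        scores, _ = self._scores()
        table = pd.DataFrame({"m": scores["PC1"]})
        corr = metric_pc_correlations(table, scores)
        assert corr.loc["m", "r_PC1"] == pytest.approx(1.0)
        assert corr.loc["m", "best_pc"] == 1

    def test_independent_metric_uncorrelated(self):
        ok = 0
        for seed in range(20):
            scores, rng = self._scores(seed=seed)
            table = pd.DataFrame({"m": rng.normal(size=200)},
                                 index=scores.index)
            corr = metric_pc_correlations(table, scores)
            r = corr.loc["m", [f"r_PC{j}" for j in range(1, 6)]].astype(float)
            ok += (r.abs() < 0.2).all()
        assert ok >= 19

    def test_constant_metric_reported_undefined(self):
        scores, _ = self._scores(n=10)
        table = pd.DataFrame({"m": np.ones(10)}, index=scores.index)
        corr = metric_pc_correlations(table, scores)
        assert np.isnan(corr.loc["m", "r_PC1"])
        assert np.isnan(corr.loc["m", "best_pc"])


class TestBatchR2:
    def test_perfect_batch_separation(self):
        lab = BatchLabeling(sample_ids=[f"s{i}" for i in range(6)],
                            labels=["A"] * 3 + ["B"] * 3)
        r2 = batch_r2([1.0, 1.0, 1.0, 2.0, 2.0, 2.0], lab)
        assert r2 == pytest.approx(1.0)

    def test_iid_noise_near_zero(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = [f"b{i // 20}" for i in range(200)]
            lab = BatchLabeling(sample_ids=[f"s{i}" for i in range(200)],
                                labels=labels)
            r2 = batch_r2(rng.normal(size=200), lab)
            ok += -0.1 < r2 < 0.1
        assert ok >= 19

    def test_variance_decomposition_oracle(self):
        """Two batches with between-batch variance = 2x within variance:
        R2 -> 2/3 at large n (random-effects variance decomposition)."""
        rng = np.random.default_rng(1)
        n = 400
        offsets = np.array([-1.0, 1.0]) * np.sqrt(2.0) / np.sqrt(2.0)
        # between-variance of +-1 offsets is 1; within sd chosen so
        # sigma_b^2 = 2 sigma_w^2  ->  offsets +-1, within sd = 1/sqrt(2)
        y = np.concatenate([
            offsets[0] + rng.normal(0, np.sqrt(0.5), n // 2),
            offsets[1] + rng.normal(0, np.sqrt(0.5), n // 2)])
        lab = BatchLabeling(sample_ids=[f"s{i}" for i in range(n)],
                            labels=["A"] * (n // 2) + ["B"] * (n // 2))
        assert batch_r2(y, lab) == pytest.approx(2.0 / 3.0, abs=0.05)

    def test_single_batch_rejected(self):
        lab = BatchLabeling(sample_ids=["a", "b"], labels=["A", "A"])
        with pytest.raises(ValidationError):
            batch_r2([1.0, 2.0], lab)


class TestPrevalence:
    def _metrics(self, sample_id, d=0.9, flags=()):
        return hq.QualityMetrics(
            sample_id=sample_id, d_index=d, lambda_=1.2, beta=2.2,
            log_kdiff=4.0, d_ggg=0.05, n_expressed=100,
            decay_slope_gamma=0.0, flags=tuple(flags))

    def test_ten_percent_flagged(self):
        metrics = [self._metrics(f"s{i}") for i in range(9)]
        metrics.append(self._metrics("s9", d=0.3, flags=("LOW_RNA_QUALITY",)))
        table = prevalence_table(metrics)
        assert table.loc["LOW_RNA_QUALITY", "prevalence_all"] == 0.1
        assert table.loc["LOW_SPECIFIC_LEVEL", "prevalence_all"] == 0.0

    def test_qc_label_strata(self):
        metadata = [
            hq.SampleMetadata("s0", "E", datetime.date(2004, 1, 1),
                              "included"),
            hq.SampleMetadata("s1", "E", datetime.date(2004, 1, 1),
                              "excluded"),
        ]
        metrics = [self._metrics("s0"),
                   self._metrics("s1", d=0.2, flags=("LOW_RNA_QUALITY",))]
        table = prevalence_table(metrics, metadata=metadata)
        assert table.loc["LOW_RNA_QUALITY", "prevalence_included"] == 0.0
        assert table.loc["LOW_RNA_QUALITY", "prevalence_excluded"] == 1.0

    def test_undefined_counted_separately(self):
        metrics = [hq.QualityMetrics(
            sample_id=f"s{i}", d_index=None, lambda_=None, beta=None,
            log_kdiff=None, d_ggg=None, n_expressed=None,
            decay_slope_gamma=None, flags=()) for i in range(4)]
        table = prevalence_table(metrics)
        assert (table["prevalence_all"] == 0).all()
        assert (table["undefined_all"] == 4).all()
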