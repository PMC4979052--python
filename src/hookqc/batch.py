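"""Batch-impact analysis: how strongly the quality metrics covary with
technical batches and with the dominant axes of an expression space.

Batches are surrogate technical groups: experiment id combined with the
hybridization month.  Three analyses quantify a metric's impact:

* Pearson correlation with each of the first five principal components of an
  expression matrix (the PC with the largest |r| is reported, Table-style);
* adjusted R-squared of a one-way fixed-effects fit of the metric on the
  batch factor (how much metric variance the batch structure explains);
* threshold prevalence: the fraction of samples flagged, overall and per
  qc-label stratum.

A metric that both exceeds its threshold in a sizable fraction of samples
and correlates with leading principal components is a candidate driver of
batch effects.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .errors import ValidationError
from .hook import ProbeSetEstimates
from .io import ExpressionMatrix, SampleMetadata
from .metrics import ALL_FLAGS, FLAG_METRIC, QualityMetrics, ThresholdConfig

METRIC_COLUMNS = ("d_index", "lambda", "beta", "log_kdiff", "d_ggg")


@dataclasses.dataclass
class BatchLabeling:
    """Per-sample technical batch labels (experiment id + scan month)."""

    sample_ids: list[str]
    labels: list[str]

    @property
    def n_batches(self) -> int:
        return len(set(self.labels))


def derive_batch_labels(metadata: Sequence[SampleMetadata]) -> BatchLabeling:
    """label = experiment_id + "·" + YYYY-MM of the scan date."""
    sample_ids = [m.sample_id for m in metadata]
    labels = [f"{m.experiment_id}·{m.scan_date.strftime('%Y-%m')}"
              for m in metadata]
    return BatchLabeling(sample_ids=sample_ids, labels=labels)


def expression_matrix_from_estimates(
        samples: Sequence[tuple[str, ProbeSetEstimates]]) -> ExpressionMatrix:
    """Internal expression measure: value(p, sample) = log10(R_p + 1).

    All samples must be decomposed over the same probe-set universe.
    """
    if not samples:
        raise ValidationError("no samples")
    first_ids = samples[0][1].probeset_ids
    columns = []
    sample_ids = []
    for sid, est in samples:
        if est.probeset_ids.shape != first_ids.shape or \
                not (est.probeset_ids == first_ids).all():
            raise ValidationError(
                f"sample {sid!r}: probe-set universe differs from "
                f"{samples[0][0]!r}")
        columns.append(np.log10(est.r_set + 1.0))
        sample_ids.append(sid)
    return ExpressionMatrix(
        feature_ids=[str(f) for f in first_ids],
        sample_ids=sample_ids,
        values=np.column_stack(columns),
    )


def pc_scores(matrix: ExpressionMatrix, n_components: int = 5) -> pd.DataFrame:
    """Per-sample scores on the first principal components of the expression
    space (features centered across samples).

    Deterministic sign convention: each component's feature loading vector is
    oriented so its largest-magnitude entry is positive, which makes scores
    reproducible across runs and sample orderings.
    """
    n_samples = len(matrix.sample_ids)
    if n_samples <= n_components:
        raise ValidationError(
            f"PCA needs more samples ({n_samples}) than components "
            f"({n_components})")
    x = matrix.values.T  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for j in range(n_components):
        loading = pca.components_[j]
        top = np.argmax(np.abs(loading))
        if loading[top] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=[f"PC{j + 1}" for j in range(n_components)])


def metric_pc_correlations(metric_table: pd.DataFrame,
                           scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of every metric column against every PC score column.

    Undefined metric values are pairwise-deleted; a metric with fewer than 3
    defined samples or zero variance gets NaN correlations.  The returned
    frame has one row per metric with columns ``r_PC1..r_PCk``, ``best_pc``
    (index of max |r|) and ``best_r`` (the signed value there).
    """
    joined = metric_table.join(scores, how="inner")
    if joined.shape[0] < 3:
        raise ValidationError(
            "need >= 3 overlapping samples for correlations")
    rows = []
    for metric in metric_table.columns:
        r_values = {}
        for pc in scores.columns:
            pair = joined[[metric, pc]].dropna()
            m = pair[metric].to_numpy(dtype=float)
            p = pair[pc].to_numpy(dtype=float)
            if m.shape[0] < 3 or np.std(m) == 0 or np.std(p) == 0:
                r_values[f"r_{pc}"] = np.nan
            else:
                r_values[f"r_{pc}"] = scipy.stats.pearsonr(m, p).statistic
        r_arr = np.array(list(r_values.values()))
        if np.isnan(r_arr).all():
            best_pc, best_r = np.nan, np.nan
        else:
            best = int(np.nanargmax(np.abs(r_arr)))
            best_pc, best_r = best + 1, r_arr[best]
        rows.append({"metric": metric, **r_values,
                     "best_pc": best_pc, "best_r": best_r})
    return pd.DataFrame(rows).set_index("metric")


def batch_r2(values: Sequence[float] | np.ndarray,
             labeling: BatchLabeling) -> float:
    """Adjusted R-squared of a one-way fixed-effects fit of the metric on the
    batch factor: R2_adj = 1 - (1 - R2)(n - 1)/(n - g)."""
    y = np.asarray(values, dtype=float)
    labels = np.asarray(labeling.labels, dtype=object)
    if y.shape[0] != labels.shape[0]:
        raise ValidationError("metric vector and batch labels differ in length")
    keep = np.isfinite(y)
    y = y[keep]
    labels = labels[keep]
    groups = pd.unique(labels)
    g = groups.shape[0]
    if g < 2:
        raise ValidationError("batch R2 needs >= 2 batches")
    if y.shape[0] <= g:
        raise ValidationError(
            f"batch R2 needs more samples ({y.shape[0]}) than batches ({g})")
    if np.var(y) == 0:
        # a constant metric shows no batch covariation (R2 is 0/0 here)
        return 0.0
    dummies = pd.get_dummies(pd.Series(labels), drop_first=True, dtype=float)
    design = sm.add_constant(dummies.to_numpy())
    fit = sm.OLS(y, design).fit()
    return float(fit.rsquared_adj)


def prevalence_table(metrics: Sequence[QualityMetrics],
                     thresholds: ThresholdConfig | None = None,
                     metadata: Sequence[SampleMetadata] | None = None
                     ) -> pd.DataFrame:
    """Per-flag prevalence: fraction flagged overall and per qc-label
    stratum, with samples whose backing metric is undefined counted in a
    separate tally (never as flagged).

    ``thresholds`` is accepted for interface symmetry; flags stored on the
    metrics are authoritative (they were assigned from the thresholds at
    QC time).
    """
    if not metrics:
        raise ValidationError("no metrics")
    qc_by_sample = {}
    if metadata is not None:
        qc_by_sample = {m.sample_id: m.qc_label for m in metadata}
    strata: dict[str, list[QualityMetrics]] = {"all": list(metrics)}
    for m in metrics:
        label = qc_by_sample.get(m.sample_id)
        if label:
            strata.setdefault(label, []).append(m)
    metric_attr = {"d_index": "d_index", "lambda": "lambda_", "beta": "beta",
                   "log_kdiff": "log_kdiff", "d_ggg": "d_ggg"}
    rows = []
    for flag in ALL_FLAGS:
        attr = metric_attr[FLAG_METRIC[flag]]
        row: dict[str, object] = {"flag": flag, "metric": FLAG_METRIC[flag]}
        for name, group in strata.items():
            n = len(group)
            flagged = sum(flag in m.flags for m in group)
            undefined = sum(getattr(m, attr) is None for m in group)
            row[f"prevalence_{name}"] = flagged / n
            row[f"n_{name}"] = n
            row[f"undefined_{name}"] = undefined
        rows.append(row)
    return pd.DataFrame(rows).set_index("flag")


def impact_report(metric_table: pd.DataFrame,
                  labeling: BatchLabeling,
                  scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-metric impact summary: PC correlations (when scores are given)
    and adjusted batch R2."""
    label_by_sample = dict(zip(labeling.sample_ids, labeling.labels))
    missing = [s for s in metric_table.index if s not in label_by_sample]
    if missing:
        raise ValidationError(
            f"samples missing from metadata: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
    sub_labeling = BatchLabeling(
        sample_ids=list(metric_table.index),
        labels=[label_by_sample[s] for s in metric_table.index])
    if scores is not None:
        report = metric_pc_correlations(metric_table, scores)
    else:
        report = pd.DataFrame(index=pd.Index(metric_table.columns,
                                             name="metric"))
    r2 = []
    for metric in report.index:
        try:
            r2.append(batch_r2(metric_table[metric].to_numpy(dtype=float),
                               sub_labeling))
        except ValidationError:
            r2.append(np.nan)
    report["batch_r2_adj"] = r2
    return report


def metrics_to_table(metrics: Sequence[QualityMetrics]) -> pd.DataFrame:
    """Samples x metrics DataFrame (NaN for undefined), indexed by sample."""
    rows = []
    for m in metrics:
        rows.append({
            "sample_id": m.sample_id,
            "d_index": np.nan if m.d_index is None else m.d_index,
            "lambda": np.nan if m.lambda_ is None else m.lambda_,
            "beta": np.nan if m.beta is None else m.beta,
            "log_kdiff": np.nan if m.log_kdiff is None else m.log_kdiff,
            "d_ggg": np.nan if m.d_ggg is None else m.d_ggg,
        })
    return pd.DataFrame(rows).set_index("sample_id")
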