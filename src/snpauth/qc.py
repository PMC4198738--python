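"""Array-level quality control before authentication.

Two lines of defence: (1) heterozygous (H) and no-call (N) rate outliers
among reference samples, flagged by the 1.5 x IQR rule; (2) the two-sample
Kolmogorov–Smirnov statistic D between each sample's sum-intensity
distribution (I = X + Y per marker) and a pooled reference distribution.
D outliers split into genotyping failures (whole distribution shifted left)
and samples from a non-target species (normal median but a spike of markers
with I near zero, where probes fail to hybridise).

QC is asymmetric by design: reference samples outside the fences are
excluded, cell lines only warned about, because expected H/N rates for cell
lines cannot be established a priori.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datastore import Database

VERDICTS = ("pass", "fail_call_rate", "fail_left_shift", "spike_non_target_species")


@dataclass
class QcThresholds:
    iqr_k: float = 1.5
    #: fraction of markers with I below the reference 1st percentile that
    #: constitutes a "spike at I ~ 0"
    spike_fraction: float = 0.05
    spike_reference_percentile: float = 1.0
    #: a left shift requires the sample median to fall below this multiple of
    #: the reference median (a near-zero spike alone also lowers the median,
    #: but only marginally)
    left_shift_median_ratio: float = 0.9


@dataclass
class QcReport:
    sample_id: str
    h_rate: float
    n_rate: float
    ks_d: float  # NaN when no intensities are available
    verdict: str
    warn_only: bool = False  # cell lines are warned, never auto-excluded


def call_rate_stats(db: Database) -> dict[str, tuple[float, float]]:
    """Per-sample (h_rate, n_rate).

    h_rate is the heterozygous fraction among *called* markers; n_rate the
    no-call fraction of all markers. An all-NA sample gets h_rate 0.
    """
    calls = db.genotypes.calls
    called = np.isfinite(calls)
    n_called = called.sum(axis=1)
    n_het = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        h = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    n = 1.0 - n_called / calls.shape[1]
    return {s: (float(h[i]), float(n[i])) for i, s in enumerate(db.genotypes.samples)}


def iqr_outlier_flags(values, k: float = 1.5) -> np.ndarray:
    """Tukey fences: flag v outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use numpy's linear interpolation convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for IQR outlier detection")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def ks_intensity_statistic(sample_sum_intensities, reference_sum_intensities) -> float:
    """Two-sample KS statistic D = sup |ECDF_sample - ECDF_reference|."""
    s = np.asarray(sample_sum_intensities, dtype=float)
    r = np.asarray(reference_sum_intensities, dtype=float)
    if s.size == 0 or r.size == 0:
        raise ValueError("both intensity lists must be non-empty")
    return float(stats.ks_2samp(s, r, method="asymp").statistic)


def classify_qc(
    *,
    call_rate_outlier: bool,
    ks_outlier: bool = False,
    sample_median_I: float = np.nan,
    reference_median_I: float = np.nan,
    near_zero_fraction: float = 0.0,
    thresholds: QcThresholds | None = None,
) -> str:
    """Combine the QC signals into a verdict.

    D outliers with a depressed median sum intensity are genotyping failures
    (left shift); D outliers with a normal median but excess mass near I = 0
    indicate a non-target species. Call-rate outliers fail on their own.
    """
    thresholds = thresholds or QcThresholds()
    if ks_outlier and np.isfinite(sample_median_I) and np.isfinite(reference_median_I):
        if sample_median_I < thresholds.left_shift_median_ratio * reference_median_I:
            return "fail_left_shift"
        if near_zero_fraction > thresholds.spike_fraction:
            return "spike_non_target_species"
    if call_rate_outlier:
        return "fail_call_rate"
    return "pass"


def qc_report(db: Database, thresholds: QcThresholds | None = None) -> list[QcReport]:
    """Run the full QC battery over a database.

    H/N fences are computed from reference samples (grouped over the whole
    reference set; finer grouping by taxon is the caller's responsibility via
    subsetting). The KS reference distribution pools the sum intensities of
    all reference samples.
    """
    thresholds = thresholds or QcThresholds()
    stats_by_sample = call_rate_stats(db)
    refs = db.reference_ids()

    h_ref = np.array([stats_by_sample[s][0] for s in refs])
    n_ref = np.array([stats_by_sample[s][1] for s in refs])
    if len(refs) >= 4:
        h_fences = np.percentile(h_ref, [25, 75])
        n_fences = np.percentile(n_ref, [25, 75])
        h_lo = h_fences[0] - thresholds.iqr_k * (h_fences[1] - h_fences[0])
        h_hi = h_fences[1] + thresholds.iqr_k * (h_fences[1] - h_fences[0])
        n_lo = n_fences[0] - thresholds.iqr_k * (n_fences[1] - n_fences[0])
        n_hi = n_fences[1] + thresholds.iqr_k * (n_fences[1] - n_fences[0])
    else:
        h_lo = n_lo = -np.inf
        h_hi = n_hi = np.inf

    frame = db.intensities
    ks_by_sample: dict[str, float] = {}
    median_I: dict[str, float] = {}
    near_zero: dict[str, float] = {}
    ref_median = np.nan
    ks_outliers: set[str] = set()
    if frame is not None:
        I = frame.sum_intensity()
        ref_in_frame = [s for s in refs if s in frame.samples]
        # iterate to convergence: D outliers found against the reference pool
        # are dropped from the pool and all statistics recomputed, so a
        # corrupted reference cannot mask itself (or others) by widening the
        # pool or dragging its near-zero cutoff down
        excluded: set[str] = set()
        for _ in range(5):
            rows = [frame.sample_position(s) for s in ref_in_frame if s not in excluded]
            pooled = I[rows].ravel()
            pooled = pooled[np.isfinite(pooled)]
            ref_median = float(np.median(pooled))
            cutoff = np.percentile(pooled, thresholds.spike_reference_percentile)
            for s in frame.samples:
                row = I[frame.sample_position(s)]
                row = row[np.isfinite(row)]
                ks_by_sample[s] = ks_intensity_statistic(row, pooled)
                median_I[s] = float(np.median(row))
                near_zero[s] = float(np.mean(row < cutoff))
            ds = np.array([ks_by_sample[s] for s in frame.samples])
            if ds.size >= 4:
                flags = iqr_outlier_flags(ds, thresholds.iqr_k)
                ks_outliers = {s for s, f in zip(frame.samples, flags) if f}
            if ks_outliers == excluded:
                break
            excluded = set(ks_outliers)

    reports = []
    for s in db.genotypes.samples:
        h, n = stats_by_sample[s]
        all_na = n >= 1.0
        cr_outlier = all_na or not (h_lo <= h <= h_hi and n_lo <= n <= n_hi)
        verdict = classify_qc(
            call_rate_outlier=cr_outlier,
            ks_outlier=s in ks_outliers,
            sample_median_I=median_I.get(s, np.nan),
            reference_median_I=ref_median,
            near_zero_fraction=near_zero.get(s, 0.0),
            thresholds=thresholds,
        )
        warn_only = db.samples[s].sample_type == "cell_line" and verdict == "fail_call_rate"
        reports.append(
            QcReport(s, h, n, ks_by_sample.get(s, np.nan), verdict, warn_only=warn_only)
        )
    return reports
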