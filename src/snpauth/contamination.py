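"""Cross-contamination from B-allele-frequency deviations.

An uncontaminated diploid sample has BAFs concentrated at 0, 0.5 and 1.
DNA from a second genetic background shifts the allelic ratio at every
marker where the contaminant's genotype differs from the host's, pushing
BAFs out of their normal ranges. With thresholds T_hom and T_het bounding
those ranges (folded BAF below T_hom for homozygous calls, above T_het for
heterozygous calls), each marker's BAF is transformed to its distance
outside the normal range, and the sample's deviation statistic D is the sum
of the transformed values over the number of assessed markers M.

D increases monotonically with the contaminant fraction, so a dilution
series of known mixtures calibrates a linear model through the origin
(after subtracting the uncontaminated baseline) whose inverse estimates the
contamination fraction of an unknown sample. Significance is declared
against the upper tail of D under the uncontaminated null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Thresholds derived from reference intercross samples on the original
#: platform; used whenever no calibration data are available.
DEFAULT_T_HOM = 0.02
DEFAULT_T_HET = 0.46


@dataclass(frozen=True)
class BafThresholds:
    """Bounds of the normal folded-BAF range for hom and het calls."""

    t_hom: float = DEFAULT_T_HOM
    t_het: float = DEFAULT_T_HET

    def __post_init__(self) -> None:
        if not (0 < self.t_hom < self.t_het < 0.5 + 1e-12):
            raise ValueError("need 0 < T_hom < T_het <= 0.5")


@dataclass
class DeviationResult:
    D_baf: float
    M: int
    n_deviating: int


@dataclass
class DilutionModel:
    """Linear-through-origin calibration of deviation vs contaminant fraction."""

    slope: float
    baseline_D0: float
    calibration_points: list[tuple[float, float]] = field(default_factory=list)
    fit_r: float = float("nan")
    model_type: str = "linear_through_origin"

    def predict_fraction(self, D: float) -> float:
        return float(np.clip((D - self.baseline_D0) / self.slope, 0.0, 1.0))


def fold(baf) -> np.ndarray:
    """Folded BAF min(b, 1-b): distance from the nearer homozygous pole."""
    b = np.asarray(baf, dtype=float)
    return np.minimum(b, 1.0 - b)


def calibrate_baf_thresholds(
    bafs,
    calls,
    hom_quantile: float = 0.995,
    het_quantile: float = 0.005,
) -> BafThresholds:
    """Derive (T_hom, T_het) from reference BAFs and their genotype calls.

    T_hom is an upper quantile of the folded BAF among homozygous calls,
    T_het a lower quantile among heterozygous calls. Either side falls back
    to the platform default (with a warning) when no calls of that class
    exist.
    """
    b = fold(bafs).ravel()
    c = np.asarray(calls, dtype=float).ravel()
    valid = np.isfinite(b) & np.isfinite(c)
    hom = b[valid & np.isin(c, (0.0, 2.0))]
    het = b[valid & (c == 1.0)]
    if hom.size:
        t_hom = float(np.quantile(hom, hom_quantile))
    else:
        warnings.warn("no homozygous reference calls; using default T_hom")
        t_hom = DEFAULT_T_HOM
    if het.size:
        t_het = float(np.quantile(het, het_quantile))
    else:
        warnings.warn("no heterozygous reference calls; using default T_het")
        t_het = DEFAULT_T_HET
    if not t_hom < t_het:
        raise ValueError(f"calibration degenerate: T_hom {t_hom:.3f} >= T_het {t_het:.3f}")
    return BafThresholds(t_hom=max(t_hom, 1e-9), t_het=min(t_het, 0.5))


def baf_deviation(bafs, calls, thr: BafThresholds | None = None) -> DeviationResult:
    """Mean transformed BAF deviation of one sample.

    Per marker with a call and a BAF: homozygous calls contribute
    max(0, folded - T_hom), heterozygous calls max(0, T_het - folded) — zero
    inside the normal range, the excursion beyond it otherwise. Markers with
    no call or no BAF are excluded from both the numerator and M.
    """
    thr = thr or BafThresholds()
    b = fold(bafs).ravel()
    c = np.asarray(calls, dtype=float).ravel()
    if b.shape != c.shape:
        raise ValueError("bafs and calls must be aligned")
    valid = np.isfinite(b) & np.isfinite(c)
    if not valid.any():
        raise ValueError("no markers with both a call and a BAF")
    hom = valid & np.isin(c, (0.0, 2.0))
    het = valid & (c == 1.0)
    d = np.zeros_like(b)
    d[hom] = np.maximum(0.0, b[hom] - thr.t_hom)
    d[het] = np.maximum(0.0, thr.t_het - b[het])
    m = int(valid.sum())
    return DeviationResult(D_baf=float(d[valid].sum() / m), M=m, n_deviating=int((d > 0).sum()))


def fit_dilution_model(series: list[tuple[float, float]]) -> DilutionModel:
    """Fit the calibration model to (fraction, deviation) points.

    The baseline D0 is the mean deviation at fraction 0; the slope is the
    least-squares line through the origin on (f, D - D0). Requires at least
    three points including f = 0 and a positive slope.
    """
    pts = [(float(f), float(d)) for f, d in series]
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration points")
    f = np.array([p[0] for p in pts])
    d = np.array([p[1] for p in pts])
    at_zero = f == 0.0
    if not at_zero.any():
        raise ValueError("calibration series must include fraction 0")
    d0 = float(d[at_zero].mean())
    denom = float((f**2).sum())
    slope = float((f * (d - d0)).sum() / denom)
    if slope <= 0:
        raise ValueError("calibration slope is non-positive; series invalid")
    r = float(stats.pearsonr(f, d).statistic) if np.ptp(f) > 0 and np.ptp(d) > 0 else float("nan")
    return DilutionModel(slope=slope, baseline_D0=d0, calibration_points=pts, fit_r=r)


def estimate_contamination_fraction(
    deviation: DeviationResult | float,
    model: DilutionModel,
    null_D,
    null_quantile: float = 0.99,
) -> tuple[float, bool]:
    """Invert the dilution model and test against the uncontaminated null.

    Returns (f_hat clipped to [0, 1], significant), where significance means
    the observed deviation exceeds the ``null_quantile`` of ``null_D`` — the
    deviation distribution of uncontaminated replicates (simulated or
    empirical).
    """
    D = deviation.D_baf if isinstance(deviation, DeviationResult) else float(deviation)
    null_D = np.asarray(null_D, dtype=float)
    f_hat = model.predict_fraction(D)
    significant = bool(D > np.quantile(null_D, null_quantile))
    return f_hat, significant
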