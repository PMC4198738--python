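"""Two-channel intensity handling: BAF/LRR, dye-bias and GC-wave correction.

Each marker's two allele probes yield intensities X (A channel) and
Y (B channel). In polar coordinates theta = (2/pi)·arctan(Y/X) and
R = X + Y, per-marker genotype cluster centroids estimated from reference
samples anchor two derived quantities:

* BAF (B-allele frequency): the sample's theta interpolated piecewise
  linearly between the AA, AB and BB centroids (0, 0.5, 1 at the centroids,
  saturating outside).
* LRR (log R ratio): log2 of observed R over the R expected at the sample's
  theta (interpolated between centroid Rs); 0 at copy number 2.

Two normalisation steps precede this: thresholded quantile normalisation of
the X/Y channels against a reference distribution (dye-bias correction, with
the per-value adjustment capped), and a per-sample linear regression of LRR
on local GC content that removes "genomic waves".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats


class IntensityFrame:
    """Per-sample, per-marker X/Y intensities with derived BAF and LRR.

    ``X``/``Y`` are (n_samples, n_markers) arrays; ``baf``/``lrr`` are filled
    by :func:`compute_baf_lrr` (or directly by a simulator). ``calls`` is an
    optional aligned coded-call matrix when the source file carried calls.
    """

    def __init__(
        self,
        samples: Sequence[str],
        markers: Sequence[str],
        X: np.ndarray,
        Y: np.ndarray,
        baf: np.ndarray | None = None,
        lrr: np.ndarray | None = None,
        calls: np.ndarray | None = None,
        flags: list[str] | None = None,
    ):
        self.samples = list(samples)
        self.markers = list(markers)
        shape = (len(self.samples), len(self.markers))
        self.X = np.asarray(X, dtype=float).reshape(shape)
        self.Y = np.asarray(Y, dtype=float).reshape(shape)
        self.baf = None if baf is None else np.asarray(baf, dtype=float).reshape(shape)
        self.lrr = None if lrr is None else np.asarray(lrr, dtype=float).reshape(shape)
        self.calls = None if calls is None else np.asarray(calls, dtype=np.float32).reshape(shape)
        self.flags = list(flags or [])
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._marker_index = {m: i for i, m in enumerate(self.markers)}

    def sample_position(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def marker_position(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def sum_intensity(self) -> np.ndarray:
        """I = X + Y per sample per marker."""
        return self.X + self.Y

    def theta(self) -> np.ndarray:
        """(2/pi)·arctan(Y/X); NaN where X = Y = 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (2.0 / np.pi) * np.arctan2(self.Y, self.X)
        t[(self.X == 0) & (self.Y == 0)] = np.nan
        return t

    # -- persistence helpers used by the datastore -------------------------

    def to_records(self):
        nan = float("nan")
        baf = self.baf if self.baf is not None else np.full_like(self.X, nan)
        lrr = self.lrr if self.lrr is not None else np.full_like(self.X, nan)
        return [
            (s, m, float(self.X[i, j]), float(self.Y[i, j]), float(baf[i, j]), float(lrr[i, j]))
            for i, s in enumerate(self.samples)
            for j, m in enumerate(self.markers)
        ]

    @classmethod
    def from_records(cls, rows, sample_order, marker_order) -> "IntensityFrame":
        present_s = list(dict.fromkeys(r[0] for r in rows))
        present_m = list(dict.fromkeys(r[1] for r in rows))
        samples = [s for s in sample_order if s in set(present_s)] or present_s
        markers = [m for m in marker_order if m in set(present_m)] or present_m
        si = {s: i for i, s in enumerate(samples)}
        mi = {m: i for i, m in enumerate(markers)}
        shape = (len(samples), len(markers))
        X = np.full(shape, np.nan)
        Y = np.full(shape, np.nan)
        baf = np.full(shape, np.nan)
        lrr = np.full(shape, np.nan)
        for s, m, x, y, b, l in rows:
            X[si[s], mi[m]], Y[si[s], mi[m]] = x, y
            baf[si[s], mi[m]], lrr[si[s], mi[m]] = b, l
        has_baf = np.isfinite(baf).any()
        has_lrr = np.isfinite(lrr).any()
        return cls(samples, markers, X, Y, baf if has_baf else None, lrr if has_lrr else None)


def read_final_report(path: str | Path) -> IntensityFrame:
    """Read an Illumina final-report-style TSV (sample, marker, X, Y[, call])."""
    table = pd.read_csv(path, sep="\t")
    table.columns = [c.strip().lower() for c in table.columns]
    samples = list(dict.fromkeys(table["sample"]))
    markers = list(dict.fromkeys(table["marker"]))
    si = {s: i for i, s in enumerate(samples)}
    mi = {m: i for i, m in enumerate(markers)}
    shape = (len(samples), len(markers))
    X = np.full(shape, np.nan)
    Y = np.full(shape, np.nan)
    for row in table.itertuples(index=False):
        X[si[row.sample], mi[row.marker]] = row.x
        Y[si[row.sample], mi[row.marker]] = row.y
    return IntensityFrame(samples, markers, X, Y)


def write_baf_lrr(frame: IntensityFrame, out_dir: str | Path) -> None:
    """One TSV per sample with marker, BAF, LRR columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(frame.samples):
        pd.DataFrame(
            {
                "marker_id": frame.markers,
                "baf": frame.baf[i] if frame.baf is not None else np.nan,
                "lrr": frame.lrr[i] if frame.lrr is not None else np.nan,
            }
        ).to_csv(out_dir / f"{s}.baf_lrr.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker cluster model


@dataclass
class MarkerClusterModel:
    """Per-marker genotype cluster centroids in (theta, R) space.

    Arrays are (n_markers, 3) for clusters AA, AB, BB. ``imputed`` flags
    centroids filled in by reflection/midpoint when a genotype class was
    never observed among the references; ``usable`` is False for markers with
    no reference observations at all (excluded from intensity analyses).
    """

    markers: list[str]
    theta: np.ndarray
    R: np.ndarray
    counts: np.ndarray
    imputed: np.ndarray
    usable: np.ndarray
    marker_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.marker_index:
            self.marker_index = {m: i for i, m in enumerate(self.markers)}


def estimate_marker_clusters(
    frame: IntensityFrame, calls: np.ndarray, reference_rows: Sequence[int] | None = None
) -> MarkerClusterModel:
    """Estimate (theta, R) centroids per marker per genotype from references.

    Centroids are medians for robustness. A missing AB centroid is imputed at
    the midpoint of AA and BB; a missing homozygous centroid is imputed by
    reflecting the opposite one (theta_AA = 1 - theta_BB). Imputed Rs copy
    the nearest observed cluster.
    """
    calls = np.asarray(calls, dtype=float)
    rows = np.arange(len(frame.samples)) if reference_rows is None else np.asarray(reference_rows)
    theta_all = frame.theta()[rows]
    r_all = frame.sum_intensity()[rows]
    g = calls[rows]

    n_markers = len(frame.markers)
    theta_c = np.full((n_markers, 3), np.nan)
    r_c = np.full((n_markers, 3), np.nan)
    counts = np.zeros((n_markers, 3), dtype=int)
    for code in (0, 1, 2):
        mask = (g == code) & np.isfinite(theta_all)
        counts[:, code] = mask.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            theta_c[:, code] = np.nanmedian(np.where(mask, theta_all, np.nan), axis=0)
            r_c[:, code] = np.nanmedian(np.where(mask, r_all, np.nan), axis=0)

    imputed = ~np.isfinite(theta_c)
    usable = np.isfinite(theta_c).any(axis=1)

    has = np.isfinite(theta_c)
    aa, ab, bb = theta_c[:, 0], theta_c[:, 1], theta_c[:, 2]
    # reflect a missing homozygous centroid through the symmetric scale
    fill_aa = ~has[:, 0] & has[:, 2]
    theta_c[fill_aa, 0] = 1.0 - bb[fill_aa]
    fill_bb = ~has[:, 2] & has[:, 0]
    theta_c[fill_bb, 2] = 1.0 - aa[fill_bb]
    fill_ab = ~has[:, 1] & np.isfinite(theta_c[:, 0]) & np.isfinite(theta_c[:, 2])
    theta_c[fill_ab, 1] = 0.5 * (theta_c[fill_ab, 0] + theta_c[fill_ab, 2])
    # lone observed cluster: spread the canonical centroids around it
    lone = usable & ~np.isfinite(theta_c).all(axis=1)
    for j in np.where(lone)[0]:
        ref = {0: 0.0, 1: 0.5, 2: 1.0}
        obs = int(np.where(has[j])[0][0])
        shift = theta_c[j, obs] - ref[obs]
        for code in (0, 1, 2):
            if not has[j, code]:
                theta_c[j, code] = np.clip(ref[code] + shift, 0.0, 1.0)
    # copy R of the nearest observed cluster
    for j in np.where(usable)[0]:
        obs_codes = np.where(has[j])[0]
        for code in (0, 1, 2):
            if not has[j, code]:
                nearest = obs_codes[np.argmin(np.abs(obs_codes - code))]
                r_c[j, code] = r_c[j, nearest]
    return MarkerClusterModel(list(frame.markers), theta_c, r_c, counts, imputed, usable)


def compute_baf_lrr(frame: IntensityFrame, model: MarkerClusterModel) -> IntensityFrame:
    """Derive BAF and LRR from raw X/Y via the cluster model.

    BAF interpolates theta piecewise-linearly through the centroids (0 at or
    below theta_AA, 0.5 at theta_AB, 1 at or beyond theta_BB); the expected R
    interpolates the centroid Rs at the sample's theta, and
    LRR = log2(R_observed / R_expected). Markers with X = Y = 0 or without a
    usable cluster model get NaN.
    """
    idx = np.array([model.marker_index[m] for m in frame.markers], dtype=np.intp)
    t_aa, t_ab, t_bb = (model.theta[idx, c] for c in (0, 1, 2))
    r_aa, r_ab, r_bb = (model.R[idx, c] for c in (0, 1, 2))
    usable = model.usable[idx]

    theta = frame.theta()
    R = frame.sum_intensity()
    baf = np.full_like(theta, np.nan)
    r_exp = np.full_like(theta, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        lo = theta <= t_aa
        hi = theta >= t_bb
        mid_l = (theta > t_aa) & (theta < t_ab)
        mid_r = (theta >= t_ab) & (theta < t_bb)
        baf[lo] = 0.0
        baf[hi] = 1.0
        frac_l = (theta - t_aa) / (t_ab - t_aa)
        frac_r = (theta - t_ab) / (t_bb - t_ab)
        baf = np.where(mid_l, 0.5 * frac_l, baf)
        baf = np.where(mid_r, 0.5 + 0.5 * frac_r, baf)
        r_exp[lo] = np.broadcast_to(r_aa, theta.shape)[lo]
        r_exp[hi] = np.broadcast_to(r_bb, theta.shape)[hi]
        r_exp = np.where(mid_l, r_aa + frac_l * (r_ab - r_aa), r_exp)
        r_exp = np.where(mid_r, r_ab + frac_r * (r_bb - r_ab), r_exp)
        lrr = np.log2(R / r_exp)

    bad = ~np.isfinite(theta) | ~usable[np.newaxis, :]
    baf[bad] = np.nan
    lrr[bad] = np.nan
    baf = np.clip(baf, 0.0, 1.0)
    return IntensityFrame(
        frame.samples, frame.markers, frame.X, frame.Y, baf, lrr, frame.calls,
        flags=frame.flags + ["baf_lrr"],
    )


# ---------------------------------------------------------------------------
# Normalisation


def reference_channel_quantiles(frame: IntensityFrame, reference_rows: Sequence[int]) -> np.ndarray:
    """Pooled sorted X+Y channel values of the reference samples.

    Pooling both channels into one target distribution is what removes the
    relative dye bias between them.
    """
    rows = np.asarray(reference_rows)
    pooled = np.concatenate([frame.X[rows].ravel(), frame.Y[rows].ravel()])
    pooled = pooled[np.isfinite(pooled)]
    return np.sort(pooled)


def tqn_normalize(
    frame: IntensityFrame, reference_quantiles: np.ndarray, threshold: float = 1.5
) -> IntensityFrame:
    """Thresholded quantile normalisation of the X and Y channels.

    Each channel of each sample is quantile-mapped onto the reference
    distribution; the per-value correction is capped so that the
    normalised/original ratio stays within [1/threshold, threshold]. Rank
    order within a channel is preserved.
    """
    ref = np.sort(np.asarray(reference_quantiles, dtype=float))
    ref_q = (np.arange(ref.size) + 0.5) / ref.size

    def map_channel(values: np.ndarray) -> np.ndarray:
        out = values.copy()
        finite = np.isfinite(values)
        v = values[finite]
        if v.size == 0:
            return out
        q = (stats.rankdata(v, method="average") - 0.5) / v.size
        mapped = np.interp(q, ref_q, ref)
        capped = np.clip(mapped, v / threshold, v * threshold)
        out[finite] = capped
        return out

    X = np.vstack([map_channel(frame.X[i]) for i in range(len(frame.samples))])
    Y = np.vstack([map_channel(frame.Y[i]) for i in range(len(frame.samples))])
    return IntensityFrame(
        frame.samples, frame.markers, X, Y, frame.baf, frame.lrr, frame.calls,
        flags=frame.flags + ["tqn"],
    )


def gc_wave_adjust(lrr: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Remove the GC-covarying component of one sample's LRR.

    Ordinary least squares of LRR on GC fraction; only the centred fitted
    component is subtracted, so the sample's mean LRR is preserved. Markers
    without a GC annotation pass through unchanged.
    """
    lrr = np.asarray(lrr, dtype=float)
    gc = np.asarray(gc, dtype=float)
    have = np.isfinite(gc) & np.isfinite(lrr)
    if have.sum() < max(2, 0.5 * np.isfinite(lrr).sum()):
        if not np.isfinite(gc).any():
            return lrr.copy()
        raise ValueError("GC fraction available for fewer than 50% of markers")
    g = gc[have]
    if np.ptp(g) == 0:
        warnings.warn("GC fraction is constant; wave adjustment is a no-op")
        return lrr.copy()
    fit = stats.linregress(g, lrr[have])
    out = lrr.copy()
    out[have] = lrr[have] - fit.slope * (g - g.mean())
    return out
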