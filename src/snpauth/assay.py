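"""Assay design: select the reliable, informative marker subset.

Markers are retained when they are (1) autosomal, (2) well-called
(call rate > 80% across reference samples), (3) polymorphic (minor allele
frequency > 0), (4) fully consistent within every replicate group of inbred
references, and (5) not redundant — a marker is dropped when it is in
linkage disequilibrium (r^2 >= 0.25) with the physically preceding retained
marker on the same chromosome *and* carries the same strain distribution
pattern (SDP), since such a pair contributes no extra discriminating
information.

Outbred stocks are handled separately: their within-line inconsistency is a
biological fact, not a genotyping failure, so instead of discarding markers
the assay keeps a second, smaller list of markers that are consistent within
every outbred line; that list is substituted whenever an outbred sample is
on either side of a comparison.

The in-silico F1 machinery imputes intercross genotypes from pairs of
(predominantly homozygous) reference parents, letting the reference panel
cover every pairwise hybrid background without genotyping one.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datastore import (
    DEFAULT_CHROMOSOMES,
    Database,
    GenotypeMatrix,
    SampleAnnotation,
)

#: Default per-marker genotype error rate: one minus the mean replicate
#: reproducibility observed on the lower-quality of the two array
#: generations; deliberately conservative.
DEFAULT_ERROR_RATE = 0.032


@dataclass
class AssayParams:
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES
    call_rate_min: float = 0.80  # exclusive: call rate must exceed this
    maf_min: float = 0.0  # exclusive: MAF must exceed this
    r2_max: float = 0.25  # pairs at or above are "in LD"
    #: optional Hardy-Weinberg filter (chi-squared p-value floor); disabled by
    #: default — the assay's final criteria list does not use it
    hwe_p_min: float | None = None
    #: None -> the conservative default; pass replicate_error_rate(db) to use
    #: the measured replicate discordance instead
    error_rate: float | None = None


@dataclass
class AssayDefinition:
    """The designed assay: marker lists plus the calibrated error rate."""

    informative_markers: list[str]
    outbred_consistent_markers: list[str]
    error_rate_E: float
    filter_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not (0 < self.error_rate_E < 1):
            raise ValueError("error_rate_E must be in (0, 1)")

    def markers_for(self, *outbred_flags: bool) -> list[str]:
        """Marker list for a comparison: the outbred-consistent subset when any
        side is outbred, the full informative set otherwise."""
        return self.outbred_consistent_markers if any(outbred_flags) else self.informative_markers

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "informative_markers": self.informative_markers,
                    "outbred_consistent_markers": self.outbred_consistent_markers,
                    "error_rate_E": self.error_rate_E,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AssayDefinition":
        d = json.loads(Path(path).read_text())
        return cls(
            informative_markers=d["informative_markers"],
            outbred_consistent_markers=d["outbred_consistent_markers"],
            error_rate_E=d["error_rate_E"],
        )


# ---------------------------------------------------------------------------
# Per-marker statistics


def minor_allele_frequency(calls) -> float:
    """MAF from coded calls: min(p, 1-p) with p = mean(dosage)/2 over calls."""
    calls = np.asarray(calls, dtype=float)
    called = calls[np.isfinite(calls)]
    if called.size == 0:
        raise ValueError("all calls are NA")
    p = called.mean() / 2.0
    return float(min(p, 1.0 - p))


def replicate_consistency(calls: np.ndarray, groups) -> np.ndarray:
    """Per-marker consistency across replicate groups.

    ``calls`` is samples x markers; ``groups`` assigns each sample a
    replicate-group label (None/NaN = ungrouped, ignored). A marker is
    consistent iff within every group all non-NA calls are identical; NA
    never breaks consistency. With no groups every marker is vacuously
    consistent.
    """
    calls = np.asarray(calls, dtype=float)
    ok = np.ones(calls.shape[1], dtype=bool)
    labels = pd.Series(list(groups))
    for _, idx in labels.groupby(labels, dropna=True).groups.items():
        sub = calls[np.asarray(idx, dtype=int)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            spread = np.nanmax(sub, axis=0) - np.nanmin(sub, axis=0)
        ok &= ~(spread > 0)
    return ok


def pairwise_r2(calls_a, calls_b) -> float:
    """Squared Pearson correlation of dosages over jointly called samples.

    NaN when fewer than two joint calls or either marker is monomorphic on
    the joint subset (the caller treats NaN as "not in LD").
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    both = np.isfinite(a) & np.isfinite(b)
    a, b = a[both], b[both]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Strain distribution patterns


def strain_sdp(db: Database, marker_id: str, strains: list[str] | None = None) -> np.ndarray:
    """SDP of a marker: consensus coded call per reference strain.

    Within a strain the consensus is the majority non-NA call; a strain with
    no calls (or a tie) contributes NA.
    """
    strains = strains if strains is not None else reference_strains(db)
    col = db.genotypes.column(marker_id)
    out = np.full(len(strains), np.nan)
    by_strain: dict[str, list[float]] = {s: [] for s in strains}
    for sid in db.reference_ids():
        ann = db.samples[sid]
        if ann.outbred or not ann.strain_label or ann.strain_label not in by_strain:
            continue
        v = col[db.genotypes.sample_position(sid)]
        if np.isfinite(v):
            by_strain[ann.strain_label].append(float(v))
    for i, s in enumerate(strains):
        vals = by_strain[s]
        if vals:
            codes, counts = np.unique(vals, return_counts=True)
            best = counts.max()
            if (counts == best).sum() == 1:
                out[i] = codes[counts.argmax()]
    return out


def reference_strains(db: Database) -> list[str]:
    seen: dict[str, None] = {}
    for sid in db.reference_ids():
        ann = db.samples[sid]
        if not ann.outbred and ann.strain_label:
            seen.setdefault(ann.strain_label)
    return list(seen)


def sdp_equal(sdp_a, sdp_b) -> bool:
    """SDP identity, up to allele relabelling.

    A-vs-B labelling is an array convention, so a pattern and its dosage
    complement (x -> 2 - x) carry the same information and compare equal.
    Patterns with different sets of missing strains are never equal.
    """
    a = np.asarray(sdp_a, dtype=float)
    b = np.asarray(sdp_b, dtype=float)
    if a.shape != b.shape:
        return False
    na_a, na_b = ~np.isfinite(a), ~np.isfinite(b)
    if not np.array_equal(na_a, na_b):
        return False
    a, b = a[~na_a], b[~na_b]
    return bool(np.array_equal(a, b) or np.array_equal(a, 2.0 - b))


# ---------------------------------------------------------------------------
# Marker selection


def _hwe_pvalue(calls: np.ndarray) -> float:
    """Chi-squared HWE test on genotype counts (1 df)."""
    from scipy.stats import chi2

    called = calls[np.isfinite(calls)]
    n = called.size
    if n < 2:
        return 1.0
    n_aa, n_ab, n_bb = (called == 0).sum(), (called == 1).sum(), (called == 2).sum()
    p = (2 * n_bb + n_ab) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_aa, n_ab, n_bb])
    mask = exp > 0
    stat = float((((obs - exp) ** 2)[mask] / exp[mask]).sum())
    return float(chi2.sf(stat, df=1))


def select_assay_markers(db: Database, params: AssayParams | None = None) -> AssayDefinition:
    """Apply the five selection criteria and assemble the assay definition.

    Criteria 1-4 are per-marker filters computed on reference samples
    (consistency on non-outbred replicate groups only). Criterion 5 walks
    each chromosome left to right over the survivors and removes the later
    marker of any adjacent pair that is both in LD (r^2 >= ``r2_max``) and
    SDP-identical. The filter log records the first failed criterion per
    excluded marker.
    """
    params = params or AssayParams()
    refs = db.reference_ids()
    if not refs:
        raise ValueError("no reference samples in database")
    ref_rows = np.array([db.genotypes.sample_position(s) for s in refs])
    ref_calls = db.genotypes.calls[ref_rows].astype(float)
    non_outbred = [i for i, s in enumerate(refs) if not db.samples[s].outbred]
    rep_groups = [db.samples[refs[i]].replicate_group for i in non_outbred]
    consistent = replicate_consistency(ref_calls[non_outbred], rep_groups)

    strains = reference_strains(db)
    reasons: dict[str, str] = {}
    survivors: list[str] = []
    for m in db.markers_sorted():
        j = db.genotypes.marker_position(m)
        col = ref_calls[:, j]
        if db.markers[m].chromosome not in params.chromosomes:
            reasons[m] = "not_autosomal"
            continue
        called = np.isfinite(col)
        if called.mean() <= params.call_rate_min:
            reasons[m] = "low_call_rate"
            continue
        if minor_allele_frequency(col) <= params.maf_min:
            reasons[m] = "monomorphic"
            continue
        if not consistent[j]:
            reasons[m] = "replicate_inconsistent"
            continue
        if params.hwe_p_min is not None and _hwe_pvalue(col) < params.hwe_p_min:
            reasons[m] = "hwe_violation"
            continue
        survivors.append(m)

    # criterion 5: greedy left-to-right scan of physically adjacent survivors
    retained: list[str] = []
    sdp_cache: dict[str, np.ndarray] = {}

    def sdp(m: str) -> np.ndarray:
        if m not in sdp_cache:
            sdp_cache[m] = strain_sdp(db, m, strains)
        return sdp_cache[m]

    last_by_chrom: dict[str, str] = {}
    for m in survivors:
        chrom = db.markers[m].chromosome
        prev = last_by_chrom.get(chrom)
        if prev is not None:
            r2 = pairwise_r2(
                ref_calls[:, db.genotypes.marker_position(prev)],
                ref_calls[:, db.genotypes.marker_position(m)],
            )
            if np.isfinite(r2) and r2 >= params.r2_max and sdp_equal(sdp(prev), sdp(m)):
                reasons[m] = "ld_redundant"
                continue
        retained.append(m)
        last_by_chrom[chrom] = m

    error_rate = params.error_rate if params.error_rate is not None else DEFAULT_ERROR_RATE
    outbred_subset = outbred_consistent_subset(db, retained)
    log = pd.DataFrame(
        sorted(reasons.items()), columns=["marker_id", "exclusion_reason"]
    )
    return AssayDefinition(
        informative_markers=retained,
        outbred_consistent_markers=outbred_subset,
        error_rate_E=error_rate,
        filter_log=log,
    )


def replicate_error_rate(db: Database) -> float:
    """Per-marker error rate from replicate discordance.

    One minus the mean (over replicate groups with >= 2 samples) of the
    fraction of markers fully consistent within the group. Falls back to the
    conservative default when no usable replicate groups exist.
    """
    groups: dict[str, list[int]] = {}
    for sid in db.reference_ids():
        ann = db.samples[sid]
        if ann.replicate_group and not ann.outbred:
            groups.setdefault(ann.replicate_group, []).append(db.genotypes.sample_position(sid))
    reproducibilities = []
    for rows in groups.values():
        if len(rows) < 2:
            continue
        sub = db.genotypes.calls[rows].astype(float)
        enough = np.isfinite(sub).sum(axis=0) >= 2
        if not enough.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            spread = np.nanmax(sub[:, enough], axis=0) - np.nanmin(sub[:, enough], axis=0)
        reproducibilities.append(float((spread == 0).mean()))
    if not reproducibilities:
        return DEFAULT_ERROR_RATE
    e = 1.0 - float(np.mean(reproducibilities))
    return max(e, 1e-6)


def outbred_consistent_subset(db: Database, candidate_markers: list[str]) -> list[str]:
    """Candidates at which all non-NA calls agree within every outbred line.

    With no outbred samples the subset equals the candidate set.
    """
    lines = db.outbred_lines()
    if not lines:
        return list(candidate_markers)
    keep = np.ones(len(candidate_markers), dtype=bool)
    cols = np.array([db.genotypes.marker_position(m) for m in candidate_markers])
    for sample_ids in lines.values():
        rows = [db.genotypes.sample_position(s) for s in sample_ids]
        sub = db.genotypes.calls[np.ix_(rows, cols)].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            spread = np.nanmax(sub, axis=0) - np.nanmin(sub, axis=0)
        keep &= ~(spread > 0)
    return [m for m, k in zip(candidate_markers, keep) if k]


# ---------------------------------------------------------------------------
# In-silico F1 panel


def impute_f1(parent1_calls, parent2_calls) -> np.ndarray:
    """Impute F1 genotypes from two parents.

    Homozygous-concordant parents pass their code through, opposite
    homozygotes yield a heterozygote, and any heterozygous or missing parent
    yields NA (parents are unphased, so no guess is made).
    """
    p1 = np.asarray(parent1_calls, dtype=float)
    p2 = np.asarray(parent2_calls, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("parent call vectors must have equal length")
    hom = np.isin(p1, (0.0, 2.0)) & np.isin(p2, (0.0, 2.0))
    out = np.where(hom, (p1 + p2) / 2.0, np.nan)
    return out.astype(np.float32)


def generate_insilico_f1_panel(db: Database, parent_sample_ids: list[str]) -> Database:
    """Add one imputed F1 reference sample per unordered parent pair.

    n parents yield C(n, 2) F1 samples labelled "parent1 x parent2"; label
    collisions get a numeric suffix and a provenance entry.
    """
    for p in parent_sample_ids:
        if db.samples[p].sample_type != "reference":
            raise ValueError(f"F1 parent {p!r} is not a reference sample")

    g = db.genotypes
    parent_rows = np.array([g.sample_position(p) for p in parent_sample_ids])
    parents = g.calls[parent_rows].astype(np.float32)
    pairs = list(itertools.combinations(range(len(parent_sample_ids)), 2))
    i_idx = np.array([i for i, _ in pairs], dtype=np.intp)
    j_idx = np.array([j for _, j in pairs], dtype=np.intp)
    p1, p2 = parents[i_idx], parents[j_idx]
    hom = np.isin(p1, (0.0, 2.0)) & np.isin(p2, (0.0, 2.0))
    f1_calls = np.where(hom, (p1 + p2) / 2.0, np.nan).astype(np.float32)

    new_samples = dict(db.samples)
    new_ids = list(g.samples)
    log = list(db.provenance)
    labels = []
    for i, j in pairs:
        base = f"{parent_sample_ids[i]} x {parent_sample_ids[j]}"
        label, k = base, 2
        while label in new_samples or label in labels:
            label = f"{base}_{k}"
            k += 1
        if label != base:
            log.append(f"F1 label collision: {base!r} stored as {label!r}")
        labels.append(label)
        parent_ann = db.samples[parent_sample_ids[i]]
        new_samples[label] = SampleAnnotation(
            sample_id=label,
            sample_type="reference",
            strain_label=label,
            taxon_label=parent_ann.taxon_label,
        )
    new_ids.extend(labels)
    calls = np.vstack([g.calls, f1_calls])
    out = Database(
        genotypes=GenotypeMatrix(new_ids, list(g.markers), calls),
        markers=db.markers,
        samples=new_samples,
        intensities=db.intensities,
        provenance=log,
    )
    out.log(f"added {len(pairs)} in-silico F1 samples from {len(parent_sample_ids)} parents")
    return out
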