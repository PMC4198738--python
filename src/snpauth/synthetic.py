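"""Seeded generators with the statistical structure the method assumes.

The generators emulate the study conditions end to end — an inbred
reference panel (fully homozygous strains, substrain pairs separated by a
handful of drift differences, outbred stocks with within-line variation),
F1 hybrids, array intensity noise, host/contaminant mixtures, dilution
series and whole-chromosome aneuploidy — so every analysis module is
testable without any array download. Every generator is a pure function of
its seed.

What these fixtures do NOT model: batch effects, probe-specific bias,
wave artefacts beyond a linear GC term, or linkage disequilibrium between
markers (strain alleles are drawn independently per marker).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .datastore import Database, GenotypeMatrix, MarkerAnnotation, SampleAnnotation
from .intensity import IntensityFrame

#: Mouse autosome lengths (bp, GRCm38 scale); panel positions are drawn
#: uniformly within these and markers allotted proportionally.
MOUSE_AUTOSOME_BP: dict[str, int] = {
    "1": 195_471_971, "2": 182_113_224, "3": 160_039_680, "4": 156_508_116,
    "5": 151_834_684, "6": 149_736_546, "7": 145_441_459, "8": 129_401_213,
    "9": 124_595_110, "10": 130_694_993, "11": 122_082_543, "12": 120_129_022,
    "13": 120_421_639, "14": 124_902_244, "15": 104_043_685, "16": 98_207_768,
    "17": 94_987_271, "18": 90_702_639, "19": 61_431_566,
}


@dataclass
class PanelSpec:
    """Reference-panel geometry and composition."""

    n_strains: int = 20
    n_markers: int = 3552
    n_chromosomes: int = 19
    maf_low: float = 0.1  # strain-level B-allele frequency ~ U(maf_low, maf_high)
    maf_high: float = 0.5
    substrain_pairs: list[tuple[str, int]] = field(default_factory=list)
    n_outbred_lines: int = 0
    samples_per_outbred: int = 0
    n_replicates: int = 1  # genotyped copies per inbred strain
    seed: int = 0


@dataclass
class NoiseSpec:
    """Array noise magnitudes.

    BAF noise is genotype-class specific (homozygous clusters are tighter
    than heterozygous ones); LRR noise is marker-independent Gaussian.
    """

    hom_baf_sd: float = 0.015
    het_baf_sd: float = 0.03
    lrr_sd: float = 0.15
    call_error: float = 0.01
    no_call_rate: float = 0.02
    r0: float = 2.0  # baseline total intensity at copy number 2
    seed: int = 0

    def zero_noise(self) -> "NoiseSpec":
        return replace(self, hom_baf_sd=0.0, het_baf_sd=0.0, lrr_sd=0.0,
                       call_error=0.0, no_call_rate=0.0)


# ---------------------------------------------------------------------------
# Reference panel


def _strain_names(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def make_reference_panel(spec: PanelSpec) -> Database:
    """Generate a seeded inbred reference panel.

    Inbred strains are fully homozygous with per-marker B-allele frequency
    drawn from U(maf_low, maf_high); substrains copy a parent strain and
    flip exactly ``n_private_differences`` homozygous calls; outbred
    individuals draw genotypes with heterozygosity 2p(1-p) independently
    per sample (so outbred replicates legitimately disagree).
    """
    rng = np.random.default_rng(spec.seed)
    chroms = list(MOUSE_AUTOSOME_BP)[: spec.n_chromosomes]
    lengths = np.array([MOUSE_AUTOSOME_BP[c] for c in chroms], dtype=float)
    counts = np.maximum(1, np.round(spec.n_markers * lengths / lengths.sum()).astype(int))
    while counts.sum() != spec.n_markers:
        counts[int(np.argmax(counts))] += int(np.sign(spec.n_markers - counts.sum()))

    markers: dict[str, MarkerAnnotation] = {}
    marker_ids: list[str] = []
    bases = np.array(list("ACGT"))
    for c, k in zip(chroms, counts):
        pos = np.sort(rng.choice(int(MOUSE_AUTOSOME_BP[c]) - 1, size=k, replace=False) + 1)
        for p in pos:
            mid = f"m{len(marker_ids) + 1:06d}"
            pair = rng.choice(4, size=2, replace=False)
            markers[mid] = MarkerAnnotation(
                marker_id=mid,
                chromosome=c,
                position_bp=int(p),
                alleles=(str(bases[pair[0]]), str(bases[pair[1]])),
                gc_fraction=float(rng.uniform(0.3, 0.6)),
            )
            marker_ids.append(mid)

    freqs = rng.uniform(spec.maf_low, spec.maf_high, size=spec.n_markers)
    strains = _strain_names(spec.n_strains)
    strain_calls = {
        s: (rng.random(spec.n_markers) < freqs).astype(np.float32) * 2.0 for s in strains
    }
    for parent, n_diff in spec.substrain_pairs:
        if parent not in strain_calls:
            raise ValueError(f"unknown parent strain {parent!r}")
        if n_diff > spec.n_markers:
            raise ValueError("n_private_differences exceeds the marker count")
        if n_diff < 1:
            raise ValueError("n_private_differences must be >= 1")
        sub = strain_calls[parent].copy()
        flip = rng.choice(spec.n_markers, size=n_diff, replace=False)
        sub[flip] = 2.0 - sub[flip]
        strain_calls[f"{parent}sub"] = sub

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    anns: dict[str, SampleAnnotation] = {}
    for strain, calls in strain_calls.items():
        for r in range(spec.n_replicates):
            sid = strain if spec.n_replicates == 1 else f"{strain}_r{r + 1}"
            sample_ids.append(sid)
            rows.append(calls)
            anns[sid] = SampleAnnotation(
                sample_id=sid, sample_type="reference", strain_label=strain,
                replicate_group=strain if spec.n_replicates > 1 else None,
                taxon_label="M. musculus",
            )
    letters = string.ascii_uppercase
    for o in range(spec.n_outbred_lines):
        line = f"OUT{letters[o % 26]}"
        for k in range(spec.samples_per_outbred):
            sid = f"{line}_{k + 1}"
            dosage = rng.binomial(2, freqs).astype(np.float32)
            sample_ids.append(sid)
            rows.append(dosage)
            anns[sid] = SampleAnnotation(
                sample_id=sid, sample_type="reference", strain_label=line,
                outbred=True, taxon_label="M. musculus",
            )

    db = Database(
        genotypes=GenotypeMatrix(sample_ids, marker_ids, np.vstack(rows)),
        markers=markers,
        samples=anns,
    )
    db.log(
        f"synthetic panel: {len(strain_calls)} strains x {spec.n_replicates} replicates, "
        f"{spec.n_outbred_lines} outbred lines, {spec.n_markers} markers, seed {spec.seed}"
    )
    return db


def add_cell_line(
    db: Database, source_sample_id: str, cell_line_id: str, reported_strain: str | None = None
) -> Database:
    """Clone a panel sample's genotypes as a cell-line sample."""
    g = db.genotypes
    calls = np.vstack([g.calls, g.row(source_sample_id)[np.newaxis, :]])
    samples = dict(db.samples)
    samples[cell_line_id] = SampleAnnotation(
        sample_id=cell_line_id,
        sample_type="cell_line",
        strain_label=reported_strain or db.samples[source_sample_id].strain_label,
    )
    return Database(
        genotypes=GenotypeMatrix(list(g.samples) + [cell_line_id], list(g.markers), calls),
        markers=db.markers,
        samples=samples,
        intensities=db.intensities,
        provenance=list(db.provenance) + [f"cell line {cell_line_id} cloned from {source_sample_id}"],
    )


def perturb_calls(calls: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply genotype call noise: random flips and dropped calls."""
    rng = np.random.default_rng(noise.seed)
    out = np.asarray(calls, dtype=np.float32).copy()
    finite = np.isfinite(out)
    if noise.call_error > 0:
        flip = finite & (rng.random(out.shape) < noise.call_error)
        shift = rng.integers(1, 3, size=out.shape).astype(np.float32)
        out[flip] = np.mod(out[flip] + shift[flip], 3.0)
    if noise.no_call_rate > 0:
        out[finite & (rng.random(out.shape) < noise.no_call_rate)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Intensities


def _baf_noise_sd(calls: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    return np.where(calls == 1.0, noise.het_baf_sd, noise.hom_baf_sd)


def simulate_intensities(db: Database, noise: NoiseSpec) -> IntensityFrame:
    """Simulate X/Y intensities consistent with the database's genotypes.

    BAF = dosage/2 plus class-specific Gaussian noise (clipped to [0, 1]);
    LRR is zero-mean Gaussian; the two channels are back-computed as
    X = I·(1 - BAF), Y = I·BAF with I = r0·2^LRR. Markers with no call get
    missing intensities.
    """
    rng = np.random.default_rng(noise.seed)
    g = db.genotypes.calls.astype(float)
    baf = g / 2.0 + rng.normal(0.0, 1.0, g.shape) * _baf_noise_sd(g, noise)
    baf = np.clip(baf, 0.0, 1.0)
    lrr = rng.normal(0.0, noise.lrr_sd, g.shape) if noise.lrr_sd > 0 else np.zeros(g.shape)
    missing = ~np.isfinite(g)
    baf[missing] = np.nan
    lrr[missing] = np.nan
    I = noise.r0 * np.exp2(lrr)
    X = I * (1.0 - baf)
    Y = I * baf
    return IntensityFrame(
        db.genotypes.samples, db.genotypes.markers, X, Y, baf, lrr,
        calls=db.genotypes.calls, flags=["simulated"],
    )


def simulate_mixture(
    host_calls, contaminant_calls, f: float, noise: NoiseSpec
) -> IntensityFrame:
    """One contaminated sample: host DNA fraction 1-f, contaminant f.

    The noiseless mixture BAF is ((1-f)·g_host + f·g_cont)/2; the reported
    genotype call is the majority component's call (the host's for f < 0.5).
    Noise class follows the called genotype.
    """
    h = np.asarray(host_calls, dtype=float)
    c = np.asarray(contaminant_calls, dtype=float)
    if h.shape != c.shape:
        raise ValueError("host and contaminant call vectors must be aligned")
    rng = np.random.default_rng(noise.seed)
    called = np.where(f < 0.5, h, c)
    both = np.isfinite(h) & np.isfinite(c)
    mix = np.where(both, ((1.0 - f) * h + f * c) / 2.0, called / 2.0)
    z = rng.normal(0.0, 1.0, h.shape)
    baf = np.clip(mix + z * _baf_noise_sd(called, noise), 0.0, 1.0)
    lrr = rng.normal(0.0, noise.lrr_sd, h.shape) if noise.lrr_sd > 0 else np.zeros(h.shape)
    missing = ~np.isfinite(called)
    baf[missing] = np.nan
    lrr[missing] = np.nan
    I = noise.r0 * np.exp2(lrr)
    sample = f"mix_{f:g}"
    return IntensityFrame(
        [sample], [f"m{j}" for j in range(h.size)] , (I * (1 - baf))[np.newaxis, :],
        (I * baf)[np.newaxis, :], baf[np.newaxis, :], lrr[np.newaxis, :],
        calls=called[np.newaxis, :].astype(np.float32), flags=["simulated", "mixture"],
    )


def make_dilution_series(
    host_calls, contaminant_calls, fractions, noise: NoiseSpec
) -> list[IntensityFrame]:
    """One frame per contaminant fraction, with a shared noise stream.

    Reusing one noise draw across fractions makes the deviation statistic
    exactly monotone in f for a fixed seed, mirroring a dilution series run
    on the same DNA preparations.
    """
    h = np.asarray(host_calls, dtype=float)
    c = np.asarray(contaminant_calls, dtype=float)
    rng = np.random.default_rng(noise.seed)
    z_baf = rng.normal(0.0, 1.0, h.shape)
    z_lrr = rng.normal(0.0, 1.0, h.shape)
    frames = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        called = np.where(f < 0.5, h, c)
        both = np.isfinite(h) & np.isfinite(c)
        mix = np.where(both, ((1.0 - f) * h + f * c) / 2.0, called / 2.0)
        baf = np.clip(mix + z_baf * _baf_noise_sd(called, noise), 0.0, 1.0)
        lrr = z_lrr * noise.lrr_sd
        missing = ~np.isfinite(called)
        baf = baf.copy()
        lrr = lrr.copy()
        baf[missing] = np.nan
        lrr[missing] = np.nan
        I = noise.r0 * np.exp2(lrr)
        frames.append(
            IntensityFrame(
                [f"mix_{f:g}"], [f"m{j}" for j in range(h.size)],
                (I * (1 - baf))[np.newaxis, :], (I * baf)[np.newaxis, :],
                baf[np.newaxis, :], lrr[np.newaxis, :],
                calls=called[np.newaxis, :].astype(np.float32),
                flags=["simulated", "dilution"],
            )
        )
    return frames


def genotypes_from_baf(baf, het_band: tuple[float, float] = (0.25, 0.75)) -> np.ndarray:
    """Re-call genotypes from BAF by nearest cluster.

    Mimics an array caller re-genotyping a mixed DNA preparation: BAFs pushed
    past the midpoints between clusters change the reported call, which is
    why alignment scores against the pure host decay as contamination rises.
    """
    b = np.asarray(baf, dtype=float)
    lo, hi = het_band
    out = np.where(b < lo, 0.0, np.where(b > hi, 2.0, 1.0))
    out[~np.isfinite(b)] = np.nan
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# Aneuploidy


def simulate_aneuploidy(
    db: Database,
    sample_id: str,
    chromosome: str,
    target_cn: int,
    cell_fraction: float,
    noise: NoiseSpec,
) -> IntensityFrame:
    """Intensities for one sample carrying a whole-chromosome event.

    On the target chromosome a fraction ``cell_fraction`` of cells carries
    ``target_cn`` copies (one homologue duplicated or deleted, chosen per
    marker at random for heterozygous genotypes): effective copy number
    e = 2(1-c) + t·c, LRR centred at log2(e/2), and BAFs at the allelic
    proportions of the cell mixture (full trisomy puts heterozygous markers
    at 1/3 and 2/3; full monosomy drives them to 0 or 1).
    """
    if target_cn not in (0, 1, 3, 4):
        raise ValueError("target_cn must be one of 0, 1, 3, 4")
    if not 0.0 < cell_fraction <= 1.0:
        raise ValueError("cell_fraction must be in (0, 1]")
    rng = np.random.default_rng(noise.seed)
    g_all = db.genotypes.calls.astype(float)
    row = db.genotypes.sample_position(sample_id)
    g = g_all[row]
    n = g.size
    t, c = target_cn, cell_fraction
    e = 2.0 * (1.0 - c) + t * c

    on_target = np.array(
        [db.markers[m].chromosome == chromosome for m in db.genotypes.markers]
    )

    b_copies = np.where(g == 0.0, 0.0, np.where(g == 2.0, float(t), np.nan))
    het = g == 1.0
    if t == 0:
        b_copies[het] = 0.0
    elif t == 1:
        b_copies[het] = rng.integers(0, 2, size=int(het.sum())).astype(float)
    else:
        b_copies[het] = rng.integers(1, t, size=int(het.sum())).astype(float)

    centers = g / 2.0
    if e > 0:
        centers = np.where(on_target, ((1.0 - c) * g + c * b_copies) / e, centers)
    else:
        centers = np.where(on_target, 0.5, centers)
    lrr_center = np.where(on_target, np.log2(max(e, 1e-6) / 2.0), 0.0)

    baf = np.clip(centers + rng.normal(0.0, 1.0, n) * _baf_noise_sd(g, noise), 0.0, 1.0)
    lrr = lrr_center + rng.normal(0.0, noise.lrr_sd, n)
    missing = ~np.isfinite(g)
    baf[missing] = np.nan
    lrr[missing] = np.nan
    I = noise.r0 * np.exp2(lrr)
    return IntensityFrame(
        [sample_id], db.genotypes.markers, (I * (1 - baf))[np.newaxis, :],
        (I * baf)[np.newaxis, :], baf[np.newaxis, :], lrr[np.newaxis, :],
        calls=db.genotypes.calls[row][np.newaxis, :],
        flags=["simulated", f"aneuploidy:{chromosome}:cn{t}:c{c:g}"],
    )
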