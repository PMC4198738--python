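# Methods

This note documents the statistical models, the parameters that matter,
the numerical choices, and what the synthetic fixtures do and do not show.

## Genotype coding and the database

Calls are coded as B-allele dosage (0 = AA, 1 = AB, 2 = BB, NaN = no-call),
which makes two things closed-form: the expected B-allele frequency of a
genotype is `code / 2`, and an F1 genotype is the mean of two homozygous
parental codes. Heterozygous letter order in source files is ignored
("GT" ≡ "TG") because array exports are inconsistent about it. Coordinates
are 1-based; the default chromosome set is the 19 mouse autosomes (the
assay is autosomal by design — sex chromosomes confound dosage with sex).
On disk a database is one SQLite file with long-format tables, so a
database is a file you can mail; merging unions samples and, by default,
intersects markers (the safe choice when two array generations share only
part of their content). A duplicate sample id with conflicting calls is
kept under a suffixed name rather than silently overwritten.

## Quality control

Two screens run before authentication. Heterozygous/no-call rates are
checked against Tukey fences (1.5 × IQR, linear-interpolation quartiles)
computed from reference samples; cell lines are only *warned* about, never
auto-excluded, because no prior H/N expectation exists for them. The
two-sample Kolmogorov–Smirnov statistic D compares each sample's
sum-intensity distribution (I = X + Y) to a pooled reference distribution.
D outliers split into genotyping failures (median I well below the
reference: the whole distribution is left-shifted) and samples of a
non-target species (normal median but a spike of markers with I ≈ 0, where
probes fail to hybridise). Two operationalisations are ours because no
cutoffs exist in the field's descriptions: the spike is "more than 5% of
markers below the reference 1st percentile", and a left shift requires the
sample median below 0.9 × the reference median (a spike alone also drags
the median, but only by a few percent). The pooled reference is iterated
to convergence with D outliers removed, so a corrupted reference sample
cannot widen its own fence or drag the near-zero cutoff down.

## Assay design

Markers are retained when (1) autosomal, (2) call rate > 0.80 across
reference samples, (3) minor allele frequency > 0, (4) fully consistent
within every replicate group of non-outbred references (NA never breaks
consistency — missingness is already penalised by the call-rate filter),
and (5) not redundant. Redundancy means: in linkage disequilibrium
(genotype-dosage r² ≥ 0.25) with the physically preceding retained marker
on the same chromosome *and* carrying the same strain distribution pattern
(SDP). Adjacency is checked greedily left-to-right over the survivors of
filters 1–4; a pair in LD with *different* SDPs is kept, since it still
separates strains. SDPs compare equal up to dosage complement (A/B
labelling is an array convention carrying no information), and patterns
with different missing-strain sets are never equal. r² undefined on a
monomorphic joint subset is treated as "not in LD".

Outbred stocks are excluded from the consistency filter — within-line
variation is biology, not error — and instead define a second marker list
(consistent within every outbred line) that is substituted automatically
whenever either side of a comparison is outbred.

The default per-marker error rate E = 0.032 is one minus a conservative
replicate reproducibility; `replicate_error_rate` recomputes it from the
replicate groups of a given panel when preferred. A Hardy–Weinberg filter
hook exists (`AssayParams.hwe_p_min`, chi-squared with 1 df) but is off by
default: for panels dominated by inbred homozygotes HWE is violated by
construction.

## Matching statistics

For two samples, `H` counts jointly called, unequal markers and the
alignment score is `(compared − H) / compared`. The best match minimises
H; ties are surfaced as an `ambiguous` verdict with all tied references
listed, never broken silently. PIA = E^H is computed against the *closest
non-best* reference — the probability that every genotype separating the
sample from its strongest competitor is an error, i.e. the worst-case
misassignment probability. Score thresholds (identity ≥ 0.96, secondary
background ≥ 0.90, both configurable) follow the published practice for
SNP-based cell-line identity. Comparisons with fewer than `min_overlap`
(default 100) jointly called markers are flagged unreliable.

When the primary score is low, a secondary background is sought using only
the markers discordant with the primary match (at least 30 required). The
introgression-vs-contamination call uses a permutation test: the statistic
is the mean genome-wide marker-rank spacing between consecutive discordant
markers; the null redraws the discordant set uniformly over the assay
markers; p = (1 + #{null ≤ observed}) / (n_perm + 1). Clustered
discordance (small p, default α = 0.05) indicates chromosomal segments
from a second background fixed before derivation; scattered discordance
suggests contamination. The statistic and test are this package's design —
the phenomenon (non-random discordance under introgression) is
field-standard, a specific test is not.

## Intensities

Genotype cluster centroids per marker are medians of reference samples in
(theta, R) space, theta = (2/π)·arctan(Y/X), R = X + Y. Missing clusters
are imputed (AB at the homozygote midpoint, a missing homozygote by
reflection theta → 1 − theta; R copied from the nearest observed cluster)
and flagged. BAF interpolates theta piecewise-linearly through the
centroids (saturating at 0/1 outside); LRR = log2(R / R_expected) with
R_expected interpolated the same way. Because theta is an arctan of the
channel ratio, the BAF recovered from back-computed X/Y is exact at the
three cluster centers and within ≈ 0.046 (the analytic maximum of the
arctan map's deviation from linearity) in between; this bound, not machine
precision, is the round-trip contract.

Dye bias is corrected by thresholded quantile normalisation: each channel
is quantile-mapped onto a pooled reference distribution (pooling both
channels of the reference samples is what equalises them), with the
per-value correction capped to a factor `t` (default 1.5) so extreme
markers are not dragged arbitrarily. Genomic waves are removed per sample
by ordinary least squares of LRR on marker GC fraction; only the centred
fitted component is subtracted, so the sample's mean LRR is invariant.
Both are deliberately simplified re-implementations of the published
procedures (full tQN and the multi-window wave model); functional
equivalence on synthetic data is the contract, not script parity.

## Contamination

With contaminant fraction f, the expected BAF at a marker is
`((1−f)·g_host + f·g_cont)/2`. The deviation transform is a hinge on the
folded BAF `min(b, 1−b)`: homozygous calls contribute
`max(0, folded − T_hom)`, heterozygous calls `max(0, T_het − folded)`;
D is the mean over markers that have both a call and a BAF. Defaults
T_hom = 0.02 and T_het = 0.46 correspond to the ~99.5% normal ranges of
reference clusters (hom noise sd ≈ 0.008, het ≈ 0.015) and can be
recalibrated from any reference set by `calibrate_baf_thresholds`.

The dilution model is linear through the origin on (f, D − D₀), D₀ being
the deviation of the uncontaminated end point; this form is invertible and
matches the near-linear response of D to f. Note the hinge introduces a
dead zone of width ≈ T_hom: a fraction f shifts discordant-marker BAFs by
f but only f − T_hom of that survives the transform, so inverted estimates
are biased low by up to ~0.02 at small f — visible in the README example
(8% recovered as 6.4%) and the reason the recovery tolerance is stated as
median error < 0.02. Significance uses the 99th percentile of D over
uncontaminated replicates (simulated or empirical); no parametric null is
assumed.

## Copy number

Cultured populations are often heterogeneous, so an aberration present in
cell fraction c with copy number t produces effective DNA content
e = 2(1−c) + t·c, LRR centred at log2(e/2), and heterozygous BAFs at the
allelic proportions of the mixture. The HMM's state space is therefore the
grid (t, c) for t ∈ {0, 1, 3, 4} at each configured cell fraction, plus
the diploid state, with all emissions derived from e:

* LRR ~ Normal(log2(max(e, 0.5)/2), lrr_sd) — the 0.5 floor avoids log 0
  for the zero-copy state;
* BAF ~ equal-weight Normal mixture over the state's allowed B-allele
  proportions (e.g. 0, 1/3, 2/3, 1 for clonal trisomy) plus a uniform
  error mass `geno_error`, which plays the role of the genotyping error
  rate;
* missing LRR or BAF contributes a flat factor; where nothing
  discriminates, the flat prior over states has mean effective copy number
  exactly 2 — the diploid default for uninformative intervals.

Transitions decay with distance: P(state change) = ρ·(1 − exp(−d /
dist_threshold_bp)), ρ = 0.1, so adjacent markers are coupled and distant
ones decouple. Presets: dist_threshold 750 kb / geno_error 0.03 for a
7.8k-marker array, 100 kb / 0.01 for a 78k one. Noise scales default to
robust per-sample estimates (1.4826 × MAD of LRR; folded-BAF MAD of
heterozygous-range markers), estimated genome-wide so a single aberrant
chromosome cannot inflate them.

The per-marker posterior mean of e, averaged over the chromosome, is the
mean predicted copy number; thresholds classify < 1.5 as loss, > 2.1 as
gain, < 1.25 / > 2.75 as complete events. The default cell-fraction grid
is (2/3, 1): two fractions span clonal and majority-subclonal events, and
neither grid point's effective copy number lands on a classification
threshold (a state at exactly e = 1.5 would make a 50%-cellularity loss an
unresolvable coin flip between "loss" and "normal"). A 50% loss thus snaps
to the (1, 2/3) state (e = 1.33 < 1.5) and is called reliably, while a 30%
trisomy splits posterior mass between diploid and (3, 2/3), landing the
chromosome mean near 2.2–2.3 — an intermediate value that correctly reads
as a subclonal gain. This mixture-state design replaces an earlier
pure-integer state space, which provably cannot detect 50%-cellularity
losses (LRR −0.415 is closer to the diploid mean than to the monosomy mean
for any emission sd, and BAF 1/3 actively resembles trisomy).

Sub-chromosome events are reported as segments (runs of constant MAP
state), but significance testing of segmental events and sex chromosomes
are out of scope.

## Synthetic data: what it shows and what it does not

All generators are pure functions of their seed. The panel generator draws
strain-level B-allele frequencies from U(0.1, 0.5) per marker, giving
unrelated inbreds an expected pairwise identity of 1 − 2·E[p(1−p)] ≈ 0.61;
substrains differ from their parent at an exact, known number of markers;
outbred individuals are drawn per sample with heterozygosity 2p(1−p), so
outbred replicates legitimately disagree. Marker counts per chromosome are
proportional to real mouse autosome lengths (median spacing ≈ 500 kb at
3,552 markers). Intensity noise defaults: hom BAF sd 0.015, het 0.03, LRR
sd 0.15, call error 0.01, no-call 0.02. Mixtures report the majority
component's genotype as the call; a dilution series reuses one noise draw
across fractions, which makes D exactly monotone in f for a fixed seed.
`genotypes_from_baf` re-calls genotypes by nearest cluster for analyses
where the caller's degradation under mixing matters (e.g. alignment-score
decay along a dilution series).

Deliberately not modelled: linkage disequilibrium between markers (strain
alleles are independent per marker, so LD-pruning exercises rely on
hand-built fixtures), batch and plate effects, probe-specific bias, wave
artefacts beyond the linear GC term, and bead-level noise. Passing tests
on these fixtures therefore demonstrates correctness of the statistical
machinery under its stated model, not robustness to every artefact of real
array data.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at the scales the method targets:
3,552-marker assays for combinatorial and matching checks, 78,000 markers
for contamination sensitivity/recovery and the end-to-end pipeline run,
~3,900 markers per chromosome for copy-number recovery (20 seeded
replicates per event class), and 111 parents for the full C(111,2) = 6,105
in-silico F1 panel.
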