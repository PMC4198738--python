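"""Chromosome-level copy-number aberrations from LRR + BAF.

A hidden Markov model over copy-number states scans each chromosome's
position-sorted markers. Because cultured cell populations are frequently
heterogeneous, an aberration present in only part of the culture produces
attenuated signals: at cell fraction c, an aberrant copy number t yields an
effective DNA content e = 2(1-c) + t·c, an LRR centred at log2(e/2), and
het-marker BAFs at the allelic proportions of the mixture. The state space
is therefore the grid of (copy number, cell fraction) pairs — copy numbers
{0, 1, 3, 4} at each configured cell fraction, plus the diploid state — and
every state's emissions derive from its effective copy number:

* LRR ~ Normal(log2(max(e, 0.5)/2), lrr_sd)  (floored to avoid log 0);
* BAF ~ a mixture of Normals at the B-allele proportions the state allows
  (e.g. full trisomy: 0, 1/3, 2/3, 1) plus a uniform error mass geno_error.

Transitions decay with physical distance: the probability that the state
changes between adjacent markers is rho·(1 - exp(-d / dist_threshold_bp)),
so nearby markers are strongly coupled and distant ones decouple.

The per-marker posterior mean of e is the predicted copy number; its
unweighted chromosome average is compared with fixed thresholds: below 1.5
is a loss and above 2.1 a gain, with below 1.25 / above 2.75 marking
complete (near-clonal) deletion or gain.

The default cell-fraction grid (2/3, 1) spans clonal and majority-subclonal
events while keeping every state's effective copy number away from the
classification thresholds (no state sits at exactly 1.5 or 2.1), so a
detected event always lands on a definite side of the decision boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class CnaParams:
    """HMM and classification parameters.

    ``dist_threshold_bp``/``geno_error`` defaults suit a high-density array
    (~78k markers); use :func:`platform_params` for the low-density preset.
    ``lrr_sd``/``baf_sd`` of None are estimated robustly from the data
    (1.4826·MAD of LRR; folded-BAF MAD of heterozygous-range markers).
    """

    dist_threshold_bp: int = 100_000
    geno_error: float = 0.01
    states: tuple[int, ...] = (0, 1, 2, 3, 4)
    cell_fractions: tuple[float, ...] = (2.0 / 3.0, 1.0)
    rho: float = 0.1
    lrr_sd: float | None = None
    baf_sd: float | None = None
    loss_threshold: float = 1.5
    gain_threshold: float = 2.1
    complete_loss: float = 1.25
    complete_gain: float = 2.75

    def __post_init__(self) -> None:
        if not (self.complete_loss < self.loss_threshold < 2 < self.gain_threshold < self.complete_gain):
            raise ValueError("classification thresholds out of order")


def platform_params(platform: str) -> CnaParams:
    """Presets for the two array generations (low / high marker density)."""
    if platform == "muga":
        return CnaParams(dist_threshold_bp=750_000, geno_error=0.03)
    if platform == "megamuga":
        return CnaParams(dist_threshold_bp=100_000, geno_error=0.01)
    raise ValueError(f"unknown platform {platform!r}; use platform='custom' via CnaParams")


@dataclass
class CnaState:
    copy_number: int
    cell_fraction: float
    effective_cn: float
    baf_centers: np.ndarray
    lrr_mean: float


@dataclass
class CnaCall:
    chromosome: str
    mean_cn: float
    classification: str
    segments: list[tuple[int, int, int, float]] = field(default_factory=list)
    # segments: (start_bp, end_bp, most-probable copy number, posterior mean CN)


@dataclass
class CnaFit:
    states: list[CnaState]
    posteriors: np.ndarray  # (n_markers, n_states), rows sum to 1
    posterior_mean_cn: np.ndarray  # per-marker posterior mean of effective CN
    map_state: np.ndarray  # per-marker index of the most probable state


# ---------------------------------------------------------------------------
# State construction


def _allowed_b_copies(host_dosage: int, t: int) -> list[int]:
    """B-allele copies the aberrant clone can carry, by host genotype.

    Whole-homologue events: a homozygous host stays homozygous (0 -> 0,
    2 -> t B copies); a heterozygous host loses or duplicates either
    homologue.
    """
    if host_dosage == 0:
        return [0]
    if host_dosage == 2:
        return [t]
    if t == 0:
        return [0]
    if t == 1:
        return [0, 1]
    return list(range(1, t))  # t=3 -> {1,2}; t=4 -> {1,2,3}


def build_states(params: CnaParams) -> list[CnaState]:
    states: list[CnaState] = []
    specs = [(2, 1.0)] + [
        (t, c) for t in params.states if t != 2 for c in params.cell_fractions
    ]
    for t, c in specs:
        e = 2.0 * (1.0 - c) + t * c
        centers = set()
        if e > 0:
            for k in (0, 1, 2):
                for j in _allowed_b_copies(k, t):
                    centers.add(round(((1.0 - c) * k + c * j) / e, 9))
        lrr_mean = float(np.log2(max(e, 0.5) / 2.0))
        states.append(CnaState(t, c, e, np.array(sorted(centers)), lrr_mean))
    return states


# ---------------------------------------------------------------------------
# Emissions and forward-backward


def _robust_sds(lrr: np.ndarray, baf: np.ndarray) -> tuple[float, float]:
    l = lrr[np.isfinite(lrr)]
    lrr_sd = 1.4826 * float(np.median(np.abs(l - np.median(l)))) if l.size else 0.2
    folded = np.minimum(baf, 1.0 - baf)
    het = folded[np.isfinite(folded) & (folded > 0.25)]
    baf_sd = 1.4826 * float(np.median(np.abs(het - 0.5))) if het.size else 0.03
    return max(lrr_sd, 1e-3), max(baf_sd, 1e-3)


def _emission_loglik(
    lrr: np.ndarray, baf: np.ndarray, states: list[CnaState], params: CnaParams,
    lrr_sd: float, baf_sd: float,
) -> np.ndarray:
    n, S = lrr.size, len(states)
    ll = np.zeros((n, S))
    lrr_ok = np.isfinite(lrr)
    baf_ok = np.isfinite(baf)
    lrr_f = np.where(lrr_ok, lrr, 0.0)
    baf_f = np.where(baf_ok, baf, 0.5)
    for s, st in enumerate(states):
        lrr_term = -0.5 * ((lrr_f - st.lrr_mean) / lrr_sd) ** 2 - np.log(lrr_sd * SQRT_2PI)
        ll[:, s] += np.where(lrr_ok, lrr_term, 0.0)
        if st.baf_centers.size:
            diffs = (baf_f[:, None] - st.baf_centers[None, :]) / baf_sd
            comp = np.exp(-0.5 * diffs**2) / (baf_sd * SQRT_2PI)
            dens = (1.0 - params.geno_error) * comp.mean(axis=1) + params.geno_error
            baf_term = np.log(np.maximum(dens, 1e-300))
        else:  # state with no DNA: BAF is pure noise
            baf_term = np.zeros(n)
        ll[:, s] += np.where(baf_ok, baf_term, 0.0)
    return ll


def transition_change_prob(distance_bp: np.ndarray, params: CnaParams) -> np.ndarray:
    """P(state changes between adjacent markers), increasing with distance
    and capped at rho."""
    return params.rho * (1.0 - np.exp(-np.asarray(distance_bp, dtype=float) / params.dist_threshold_bp))


def cn_hmm_fit(lrr, baf, positions, params: CnaParams | None = None) -> CnaFit:
    """Forward-backward copy-number posteriors for one chromosome.

    Markers must be position-sorted. Missing LRR or BAF values contribute a
    flat emission for the affected term; where no data discriminate the
    states, the flat prior keeps the posterior mean near 2 (the diploid
    assumption for uninformative intervals).
    """
    params = params or CnaParams()
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = lrr.size
    if n < 10:
        raise ValueError("need at least 10 markers per chromosome")
    if not np.isfinite(lrr).any():
        raise ValueError("all LRR values missing")
    if np.any(np.diff(positions) < 0):
        raise ValueError("markers must be position-sorted")

    lrr_sd = params.lrr_sd
    baf_sd = params.baf_sd
    if lrr_sd is None or baf_sd is None:
        est_l, est_b = _robust_sds(lrr, baf)
        lrr_sd = lrr_sd if lrr_sd is not None else est_l
        baf_sd = baf_sd if baf_sd is not None else est_b

    states = build_states(params)
    S = len(states)
    log_e = _emission_loglik(lrr, baf, states, params, lrr_sd, baf_sd)
    # scale emissions per marker for numerical stability
    e = np.exp(log_e - log_e.max(axis=1, keepdims=True))

    pc = transition_change_prob(np.diff(positions), params)

    # forward pass with per-step normalisation
    alpha = np.empty((n, S))
    scale = np.empty(n)
    prior = np.full(S, 1.0 / S)
    a = prior * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for i in range(1, n):
        p = pc[i - 1]
        stay, move = 1.0 - p, p / (S - 1)
        pred = alpha[i - 1] * (stay - move) + move  # row-stochastic kernel applied
        a = pred * e[i]
        scale[i] = a.sum()
        alpha[i] = a / scale[i]

    beta = np.empty((n, S))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        p = pc[i]
        stay, move = 1.0 - p, p / (S - 1)
        v = beta[i + 1] * e[i + 1]
        beta[i] = (v * (stay - move) + move * v.sum()) / scale[i + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    eff = np.array([st.effective_cn for st in states])
    return CnaFit(
        states=states,
        posteriors=gamma,
        posterior_mean_cn=gamma @ eff,
        map_state=gamma.argmax(axis=1),
    )


# ---------------------------------------------------------------------------
# Chromosome-level summaries


def chromosome_mean_cn(fit: CnaFit) -> float:
    """Unweighted mean of per-marker posterior-mean copy number."""
    return float(fit.posterior_mean_cn.mean())


def classify_chromosome(mean_cn: float, params: CnaParams | None = None) -> str:
    params = params or CnaParams()
    if mean_cn < 0:
        raise ValueError("mean copy number must be non-negative")
    if mean_cn < params.complete_loss:
        return "complete_loss"
    if mean_cn < params.loss_threshold:
        return "loss"
    if mean_cn > params.complete_gain:
        return "complete_gain"
    if mean_cn > params.gain_threshold:
        return "gain"
    return "normal"


def segments_from_fit(fit: CnaFit, positions) -> list[tuple[int, int, int, float]]:
    """Runs of constant most-probable state, tiling the chromosome's span."""
    positions = np.asarray(positions)
    segs = []
    start = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or fit.map_state[i] != fit.map_state[start]:
            st = fit.states[fit.map_state[start]]
            segs.append(
                (
                    int(positions[start]),
                    int(positions[i - 1]),
                    st.copy_number,
                    float(fit.posterior_mean_cn[start:i].mean()),
                )
            )
            start = i
    return segs


def call_chromosome(lrr, baf, positions, chromosome: str, params: CnaParams | None = None) -> CnaCall:
    params = params or CnaParams()
    fit = cn_hmm_fit(lrr, baf, positions, params)
    mean_cn = chromosome_mean_cn(fit)
    return CnaCall(
        chromosome=chromosome,
        mean_cn=mean_cn,
        classification=classify_chromosome(mean_cn, params),
        segments=segments_from_fit(fit, positions),
    )


def detect_cna(db, frame, sample_id: str, params: CnaParams | None = None) -> list[CnaCall]:
    """Per-chromosome copy-number calls for one sample of an IntensityFrame.

    Noise scales are estimated once from the sample's genome-wide LRR/BAF
    (robust to a minority of aberrant chromosomes) and shared across
    chromosomes.
    """
    from dataclasses import replace as _replace

    params = params or CnaParams()
    row = frame.sample_position(sample_id)
    lrr_all = frame.lrr[row]
    baf_all = frame.baf[row]
    if params.lrr_sd is None or params.baf_sd is None:
        est_l, est_b = _robust_sds(lrr_all, baf_all)
        params = _replace(
            params,
            lrr_sd=params.lrr_sd if params.lrr_sd is not None else est_l,
            baf_sd=params.baf_sd if params.baf_sd is not None else est_b,
        )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, m in enumerate(frame.markers):
        ann = db.markers[m]
        by_chrom.setdefault(ann.chromosome, []).append((ann.position_bp, j))
    calls = []
    for chrom in sorted(by_chrom, key=lambda c: (0, int(c)) if c.isdigit() else (1, 0)):
        pairs = sorted(by_chrom[chrom])
        pos = np.array([p for p, _ in pairs])
        idx = np.array([j for _, j in pairs])
        if idx.size < 10:
            continue
        calls.append(call_chromosome(lrr_all[idx], baf_all[idx], pos, chrom, params))
    return calls
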