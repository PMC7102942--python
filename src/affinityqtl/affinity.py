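"""Biophysical TF-binding affinity and its allelic variation.

The raw affinity of a TF for a sequence follows the TRAP occupancy
model: every W-mer placement ``i`` on either strand contributes an
occupancy probability

    p_i = R0 * exp(-E_i) / (1 + R0 * exp(-E_i)),

where the mismatch energy ``E_i = sum_j (1/lambda) * ln(c_max,j / c_b(i,j),j)``
compares the placed base ``b(i, j)`` with the most frequent base of PWM
column ``j``.  The affinity is the sum of ``p_i`` over all placements on
both strands, which naturally accumulates multiple low-affinity sites.
Defaults are ``lambda = 0.7`` and ``ln R0 = 0.584 * W - 5.66``.  No
pseudocount is added: a zero PWM frequency under a placed base forces
``p_i = 0``.

Raw affinities are not comparable between motifs, so they are converted
to exceedance probabilities ``A`` under a generalized extreme value
(GEV) law fitted to affinities of length-matched background sequences
(CRMs not bound by the TF, cut or extended to a standard length).  Lower
``A`` means higher affinity.  Allelic variation is summarized per CRM
haplotype as the base-10 log fold change in ``A`` relative to the
reference individual's highest-affinity allele, median-pooled across a
TF's motifs.

Sign convention: the atlas stores the *canonical* score
``s = log10(A_ref_best) - log10(A_alt)``, i.e. affinity-reducing
haplotypes score negative.  ``printed`` convention (the plain
``log10(A_alt) - log10(A_ref_best)`` ratio) is the same number negated;
:func:`build_affinity_atlas` takes a ``sign_convention`` switch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import genextreme

from .crm import CRM, HaplotypeSet
from .pwm import PWM

logger = logging.getLogger(__name__)

#: Standard background lengths (bp) spanning the CRM length distribution.
STANDARD_LENGTHS = (40, 100, 200, 250, 300, 400, 500, 800, 1000, 2000, 3000)

TRAP_LAMBDA = 0.7
#: ln R0 = LNR0_SLOPE * W + LNR0_INTERCEPT
LNR0_SLOPE = 0.584
LNR0_INTERCEPT = -5.66

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "STANDARD_LENGTHS",
    "TRAP_LAMBDA",
    "GEVBackground",
    "AffinityVariant",
    "trap_affinity",
    "trap_affinity_naive",
    "resize_sequence",
    "fit_gev_scores",
    "fit_gev_background",
    "nearest_standard_length",
    "normalize_affinity",
    "log_fca",
    "pool_tf_logfca",
    "build_affinity_atlas",
]


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to 0..3 (A, C, G, T); anything else to 4."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in zip(b"ACGT", range(4)):
        out[arr == base] = code
    return out


def _energy_matrix(pwm: PWM, lam: float) -> np.ndarray:
    """(W, 5) mismatch energies; column 4 (ambiguous base) is +inf."""
    freqs = pwm.freqs  # (4, W)
    cmax = freqs.max(axis=0)  # (W,)
    with np.errstate(divide="ignore"):
        e = (np.log(cmax[None, :]) - np.log(freqs)) / lam  # (4, W), inf at zeros
    e5 = np.full((pwm.width, 5), np.inf)
    e5[:, :4] = e.T
    return e5


def trap_affinity(
    sequence: str,
    pwm: PWM,
    lam: float = TRAP_LAMBDA,
    ln_r0: float | None = None,
) -> float:
    """TRAP occupancy affinity of ``pwm`` for ``sequence`` (both strands).

    Sequences shorter than the motif score 0 by convention.  Non-ACGT
    characters void every placement covering them (their count is logged
    at debug level).
    """
    W = pwm.width
    if len(sequence) < W:
        return 0.0
    if ln_r0 is None:
        ln_r0 = LNR0_SLOPE * W + LNR0_INTERCEPT
    idx_fwd = _encode(sequence)
    n_ambig = int((idx_fwd == 4).sum())
    if n_ambig:
        logger.debug(
            "%d ambiguous base(s) in sequence; covering placements contribute 0",
            n_ambig,
        )
    e5 = _energy_matrix(pwm, lam)
    total = 0.0
    rev = sequence.upper().translate(_COMPLEMENT)[::-1]
    for idx in (idx_fwd, _encode(rev)):
        windows = np.lib.stride_tricks.sliding_window_view(idx, W)
        energies = e5[np.arange(W)[None, :], windows].sum(axis=1)
        # p = R0 e^-E / (1 + R0 e^-E) = 1 / (1 + e^(E - ln R0)); E = inf -> p = 0
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(energies - ln_r0))
        p[np.isinf(energies)] = 0.0
        total += float(p.sum())
    return total


def trap_affinity_naive(
    sequence: str,
    pwm: PWM,
    lam: float = TRAP_LAMBDA,
    ln_r0: float | None = None,
) -> float:
    """Reference double-loop TRAP implementation (slow; used as an oracle)."""
    from .pwm import BASE_INDEX

    W = pwm.width
    if len(sequence) < W:
        return 0.0
    if ln_r0 is None:
        ln_r0 = LNR0_SLOPE * W + LNR0_INTERCEPT
    r0 = math.exp(ln_r0)
    cmax = pwm.freqs.max(axis=0)
    total = 0.0
    for seq in (sequence.upper(), sequence.upper().translate(_COMPLEMENT)[::-1]):
        for i in range(len(seq) - W + 1):
            energy = 0.0
            ok = True
            for j in range(W):
                base = seq[i + j]
                if base not in BASE_INDEX:
                    ok = False
                    break
                freq = pwm.freqs[BASE_INDEX[base], j]
                if freq == 0.0:
                    ok = False
                    break
                energy += math.log(cmax[j] / freq) / lam
            if ok:
                boltz = r0 * math.exp(-energy)
                total += boltz / (1.0 + boltz)
    return total


# ---------------------------------------------------------------------------
# background normalization


@dataclass(frozen=True)
class GEVBackground:
    """Per-standard-length GEV fits of a motif's background affinities.

    The law is fitted to the *natural-log* affinities, whose distribution
    over background sequences is well described by a generalized extreme
    value family (raw occupancy sums span orders of magnitude and are
    extremely right-skewed).  ``params`` maps length -> (shape, loc,
    scale) on the log scale, in scipy's ``genextreme`` parameterization
    (shape ``c = -xi``).
    """

    motif_id: str
    params: dict = field(repr=False)

    def __post_init__(self) -> None:
        for length, (c, loc, scale) in self.params.items():
            if not (scale > 0 and np.isfinite([c, loc, scale]).all()):
                raise ValueError(
                    f"invalid GEV parameters for motif {self.motif_id} "
                    f"at length {length}"
                )

    @property
    def lengths(self) -> list[int]:
        return sorted(self.params)


def resize_sequence(genome: str, start: int, end: int, target: int) -> str:
    """Cut centrally or extend symmetrically from flanks to ``target`` bp."""
    mid = (start + end) // 2
    s = mid - target // 2
    e = s + target
    if s < 0:
        s, e = 0, min(target, len(genome))
    if e > len(genome):
        e = len(genome)
        s = max(0, e - target)
    return genome[s:e]


def fit_gev_scores(scores: np.ndarray, censor_fraction: float = 0.85):
    """Maximum-likelihood GEV fit of log-affinity scores, tail-weighted.

    Two numerical choices matter here.  First, the likelihood is
    censored: observations below the ``censor_fraction`` empirical
    quantile enter only through their total mass below that point.
    Normalized affinities are read off the fitted *upper* tail, so
    trading bulk fit for tail fit is what calibrates the exceedance
    probabilities.  Second, the shape is constrained to the
    range ``-0.5 <= c <= 0`` (scipy sign convention; Gumbel up to
    moderately Frechet): an occupancy sum has no finite upper bound, so
    a Weibull-type fit (``c > 0``) on a modest background sample can
    place a finite endpoint *below* the scores of strong binding sites,
    collapsing their exceedance probabilities to an uninformative exact
    zero, while an extremely heavy log-scale tail (``c < -0.5``) is
    small-sample noise that washes out genuinely strong sites.
    Returns (shape, loc, scale) in scipy's parameterization.
    """
    from scipy.optimize import minimize

    x = np.asarray(scores, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate scores: all values identical")
    if not (0 <= censor_fraction < 1):
        raise ValueError("censor_fraction must lie in [0, 1)")
    c0, l0, s0 = genextreme.fit(x)
    c0 = float(np.clip(c0, -0.499, -1e-6))
    t0 = float(np.quantile(x, censor_fraction))
    tail = x[x > t0]
    n_cens = x.size - tail.size

    def to_shape(u):
        # logistic reparameterization keeps c in (-0.5, 0)
        return -0.5 / (1.0 + np.exp(-np.clip(u, -60, 60)))

    def from_shape(c):
        frac = np.clip(-c / 0.5, 1e-6, 1 - 1e-6)
        return float(np.log(frac / (1 - frac)))

    def nll(p):
        u, loc, log_scale = p
        c = to_shape(u)
        scale = np.exp(log_scale)
        lp = genextreme.logpdf(tail, c, loc=loc, scale=scale)
        if not np.isfinite(lp).all():
            return 1e10
        lc = genextreme.logcdf(t0, c, loc=loc, scale=scale) if n_cens else 0.0
        return -(lp.sum() + n_cens * lc)

    res = minimize(
        nll,
        [from_shape(c0), l0, np.log(s0)],
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8},
    )
    fit = (float(to_shape(res.x[0])), float(res.x[1]), float(np.exp(res.x[2])))
    if not (np.isfinite(fit).all() and fit[2] > 0):
        raise RuntimeError("GEV fit did not converge")
    return fit


def fit_gev_background(
    pwm: PWM,
    background_crms,
    genome: str,
    lengths=STANDARD_LENGTHS,
    min_sequences: int = 50,
    censor_fraction: float = 0.7,
) -> GEVBackground:
    """Fit a GEV law to background affinities at each standard length.

    ``background_crms`` must be CRMs not bound by the PWM's TF (or
    equivalent unbound intervals); each is cut/extended to every length
    in ``lengths``, scored with :func:`trap_affinity`, and the log scores
    are fitted with :func:`fit_gev_scores`.  Sequences with zero affinity
    (every placement voided) carry no tail information and are dropped
    before fitting.
    """
    crms = list(background_crms)
    if len(crms) < min_sequences:
        raise ValueError(
            f"need >= {min_sequences} background sequences, got {len(crms)}"
        )
    params = {}
    for length in lengths:
        seqs = [
            resize_sequence(genome, c.interval.start, c.interval.end, length)
            for c in crms
        ]
        raw = np.array([trap_affinity(s, pwm) for s in seqs])
        scores = np.log(raw[raw > 0])
        if scores.size < min_sequences // 2:
            raise ValueError(
                f"too few scoreable background sequences for motif "
                f"{pwm.motif_id} at length {length}"
            )
        try:
            params[length] = fit_gev_scores(scores, censor_fraction)
        except (ValueError, RuntimeError) as err:
            raise type(err)(
                f"GEV background fit for motif {pwm.motif_id} at length "
                f"{length}: {err}"
            ) from err
    return GEVBackground(motif_id=pwm.motif_id, params=params)


def nearest_standard_length(crm_length: int, lengths) -> int:
    """Standard length closest to ``crm_length``; ties break toward smaller."""
    return min(lengths, key=lambda L: (abs(L - crm_length), L))


def normalize_affinity(raw: float, crm_length: int, background: GEVBackground) -> float:
    """Exceedance probability A of ``raw`` under the length-matched GEV fit.

    A is the probability of observing the given or higher affinity in
    background sequence; lower A therefore reflects higher affinity.  A
    zero raw affinity maps to A = 1 (nothing binds weaker).
    """
    length = nearest_standard_length(crm_length, background.lengths)
    c, loc, scale = background.params[length]
    if raw <= 0:
        return 1.0
    sf = genextreme.sf(np.log(raw), c, loc=loc, scale=scale)
    return float(np.clip(sf, 0.0, 1.0))


# ---------------------------------------------------------------------------
# log fold change in affinity


def log_fca(a_alt: float, a_ref_best: float, floor_a: float) -> float:
    """Printed-convention log10 fold change in normalized affinity.

    ``floor_a`` must be the lowest non-zero A observed for the motif
    across all CRMs; exact zeros in either argument are replaced by it
    so the ratio stays finite.
    """
    if floor_a <= 0:
        raise ValueError("floor_a must be positive (no non-zero A for motif)")
    a_alt = a_alt if a_alt > 0 else floor_a
    a_ref_best = a_ref_best if a_ref_best > 0 else floor_a
    return math.log10(a_alt) - math.log10(a_ref_best)


def pool_tf_logfca(per_pwm_logfca: dict) -> float:
    """Median of per-motif log FCA values for one TF."""
    if not per_pwm_logfca:
        raise ValueError("no per-motif log FCA values to pool")
    return float(np.median(list(per_pwm_logfca.values())))


@dataclass(frozen=True)
class AffinityVariant:
    """Per-haplotype pooled affinity change for one (CRM, TF) pair.

    ``log_fca`` is indexed like the CRM's haplotype set and stored in the
    requested sign convention (canonical by default: affinity-reducing
    haplotypes negative).  ``ref_best_haplotype`` is the reference
    individual's highest-affinity haplotype, whose score is 0 whenever
    the TF has a single motif (and by construction per motif otherwise).
    """

    crm_id: str
    tf: str
    log_fca: tuple
    ref_best_a: float
    ref_best_haplotype: int
    invariant: bool
    sign_convention: str = "canonical"
    driver_snp: str | None = None

    @property
    def max_abs_logfca(self) -> float:
        return max(abs(v) for v in self.log_fca)


def _haplotype_a_values(hapset: HaplotypeSet, crm_length, pwms, backgrounds):
    """A[motif_id][hap index] for every motif of the TF set supplied."""
    a_vals = {}
    for pwm in pwms:
        bg = backgrounds[pwm.motif_id]
        a_vals[pwm.motif_id] = np.array(
            [
                normalize_affinity(trap_affinity(h.sequence, pwm), crm_length, bg)
                for h in hapset.haplotypes
            ]
        )
    return a_vals


def compute_motif_floors(a_values_by_crm: dict) -> dict:
    """Lowest non-zero A per motif across the full atlas (two-pass rule)."""
    floors: dict[str, float] = {}
    for per_motif in a_values_by_crm.values():
        for motif_id, arr in per_motif.items():
            nz = arr[arr > 0]
            if nz.size:
                lo = float(nz.min())
                if motif_id not in floors or lo < floors[motif_id]:
                    floors[motif_id] = lo
    return floors


def build_affinity_atlas(
    crms,
    haplotype_sets: dict,
    pwms_by_tf: dict,
    backgrounds: dict,
    reference_individual: int = 0,
    a_max_ref: float = 0.1,
    sign_convention: str = "canonical",
    return_floors: bool = False,
):
    """Build the atlas of per-haplotype affinity changes.

    For each CRM and each bound TF with at least one motif, normalized
    affinities are computed for every haplotype and motif.  The (CRM, TF)
    pair is retained only if the reference individual's highest-affinity
    allele has ``A < a_max_ref`` for at least one motif.  Per-motif log
    fold changes relative to that allele (with the per-motif non-zero
    floor substituted for exact zeros, computed atlas-wide first) are
    median-pooled across motifs.
    """
    if sign_convention not in ("canonical", "printed"):
        raise ValueError("sign_convention must be 'canonical' or 'printed'")
    ref_chroms = (2 * reference_individual, 2 * reference_individual + 1)

    # pass 1: all A values
    a_by_crm: dict[tuple, dict] = {}
    missing_pwm_tfs = set()
    for crm in crms:
        hapset = haplotype_sets[crm.id]
        for tf in sorted(crm.bound_tfs):
            pwms = pwms_by_tf.get(tf)
            if not pwms:
                missing_pwm_tfs.add(tf)
                continue
            a_by_crm[(crm.id, tf)] = _haplotype_a_values(
                hapset, len(crm.interval), pwms, backgrounds
            )
    if missing_pwm_tfs:
        logger.info(
            "%d bound TF(s) lack motifs and were skipped: %s",
            len(missing_pwm_tfs),
            ", ".join(sorted(missing_pwm_tfs)),
        )

    # per-motif floors over the whole atlas
    floors = compute_motif_floors(a_by_crm)

    # pass 2: filter on the reference allele and emit pooled log FCA
    atlas: list[AffinityVariant] = []
    for (crm_id, tf), per_motif in sorted(a_by_crm.items()):
        hapset = haplotype_sets[crm_id]
        hap_of_chrom = hapset.haplotype_of_chromosome()
        ref_haps = sorted({int(hap_of_chrom[c]) for c in ref_chroms})
        ref_a_by_motif = {m: arr[ref_haps].min() for m, arr in per_motif.items()}
        if min(ref_a_by_motif.values()) >= a_max_ref:
            continue
        n_haps = len(hapset.haplotypes)
        pooled = []
        for h in range(n_haps):
            per_pwm = {
                m: log_fca(per_motif[m][h], ref_a_by_motif[m], floors[m])
                for m in per_motif
            }
            pooled.append(pool_tf_logfca(per_pwm))
        # reference individual's highest-affinity allele under pooling
        ref_best_hap = min(ref_haps, key=lambda h: (pooled[h], h))
        scores = tuple(
            -v if sign_convention == "canonical" else v for v in pooled
        )
        atlas.append(
            AffinityVariant(
                crm_id=crm_id,
                tf=tf,
                log_fca=scores,
                ref_best_a=float(min(ref_a_by_motif.values())),
                ref_best_haplotype=int(ref_best_hap),
                invariant=n_haps == 1,
                sign_convention=sign_convention,
            )
        )
    if return_floors:
        return atlas, floors
    return atlas
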