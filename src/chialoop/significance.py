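"""Binomial significance tests, missing-mass correction, and calibration.

The significance of occupancy in a region is Pr(Y > Z) for two independent
binomials over the same number of draws: Y follows the uniform background
(success probability = region width / mappable genome size, or the product
of marginal masses in the joint case) and Z follows the estimated
occupancy.  Small p-values mean the background would rarely out-draw the
estimate.

Sequencing undersamples the joint occupancy space, so anchored conditional
masses t_i are deflated by an estimated missing mass τ_i before testing.
The τ_i are pinned to the marginal occupancy: at the fixed point the
corrected masses (t_i + τ_i) are proportional to the anchor marginals m_i.
The overall scale c (which fixes τ at the heaviest anchor) is calibrated
so that a target fraction of the significant regions are supported by a
single read pair — enough correction to distrust singletons, not so much
that real signal drowns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ChialoopError
from .deconvolution import OccupancyTrack
from .genome import GenomeModel
from .joint import ConditionalJointField

log = logging.getLogger(__name__)

EXACT_BINOMIAL_LIMIT = 10_000


# ----------------------------------------------------------------------
# core binomial comparison
# ----------------------------------------------------------------------

def pr_y_gt_z(n1, p1, n2, p2, exact_limit=EXACT_BINOMIAL_LIMIT) -> float:
    """Pr(Y > Z) for independent Y ~ Binomial(n1, p1), Z ~ Binomial(n2, p2).

    Exact convolution up to ``exact_limit`` trials; beyond that a normal
    approximation with continuity correction.  Monotone nondecreasing in p1
    and nonincreasing in p2.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0 or not np.isfinite(p):
            raise ChialoopError(f"invalid probability {p}")
    n1, n2 = int(n1), int(n2)
    if n1 < 0 or n2 < 0:
        raise ChialoopError("negative trial count")
    if n1 == 0 or p1 == 0.0:
        return 0.0
    if max(n1, n2) <= exact_limit:
        k = np.arange(1, n1 + 1)
        pmf_y = stats.binom.pmf(k, n1, p1)
        cdf_z = stats.binom.cdf(k - 1.0, n2, p2)
        return float(np.clip(np.dot(pmf_y, cdf_z), 0.0, 1.0))
    mu = n1 * p1 - n2 * p2
    var = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
    if var <= 0:
        return float(mu >= 1)
    return float(stats.norm.sf((0.5 - mu) / math.sqrt(var)))


def marginal_region_pvalue(region, occ: OccupancyTrack, n_self,
                           genome: GenomeModel) -> float:
    """Significance of marginal occupancy in a region against the uniform
    background w/M."""
    w = region.width
    M = genome.mappable_size
    if w >= M:
        raise ChialoopError(f"region width {w} >= mappable genome {M}")
    if n_self <= 0:
        raise ChialoopError("n_self must be positive")
    p = occ.mass_between(region.chrom, region.start, region.end)
    n = int(round(n_self))
    return pr_y_gt_z(n, w / M, n, min(1.0, p))


def joint_region_pvalue(p_joint, p_a, p_b, n_inter) -> float:
    """Significance of joint occupancy of two regions: estimated joint mass
    against the product of the marginal masses."""
    n = int(round(n_inter))
    return pr_y_gt_z(n, min(1.0, p_a * p_b), n, min(1.0, p_joint))


def rpkm(width_bp, reads_in_region, total_reads) -> float:
    """Reads per kilobase of region per million mapped reads."""
    width_bp = getattr(width_bp, "width", width_bp)
    if width_bp <= 0:
        raise ChialoopError("region width must be positive")
    if total_reads <= 0:
        raise ChialoopError("dataset size must be positive")
    return reads_in_region / ((width_bp / 1000.0) * (total_reads / 1e6))


def enrichment_pvalue(width_bp, reads_in_region, total_reads,
                      genome: GenomeModel) -> float:
    """Read-count enrichment of a region against the uniform w/M background,
    using the observed read proportion as the alternative rate."""
    width_bp = getattr(width_bp, "width", width_bp)
    n = int(total_reads)
    return pr_y_gt_z(n, width_bp / genome.mappable_size, n, reads_in_region / n)


# ----------------------------------------------------------------------
# candidate regions
# ----------------------------------------------------------------------

@dataclass
class Region:
    """A candidate interacting region for one anchor."""

    chrom: str
    start: int
    end: int
    anchor: int
    field_mass: float
    occ_mass: float
    support: int
    bins: tuple = ()  # (k0, k1) on the occupancy bin grid

    @property
    def width(self) -> int:
        return self.end - self.start


def candidate_regions(fieldest: ConditionalJointField, i, f, occ: OccupancyTrack):
    """Maximal runs of consecutive bins with conditional density > f.

    Each run becomes one region carrying its conditional mass, marginal
    occupancy mass, and the number of distinct supporting inter pairs.
    """
    if f < 0:
        raise ChialoopError("threshold f must be >= 0")
    b = fieldest.bin_size
    out = []
    for chrom, (k0, vals) in fieldest.profiles[i].items():
        above = vals > f
        if not np.any(above):
            continue
        padded = np.concatenate([[False], above, [False]])
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0]  # exclusive
        for a, e in zip(starts, ends):
            ka, ke = k0 + a, k0 + e - 1
            support = {
                c.pair for c in fieldest.contributions[i]
                if c.chrom == chrom and c.k0 <= ke and c.k1 >= ka
            }
            start_bp, end_bp = ka * b, (ke + 1) * b
            out.append(Region(
                chrom=chrom, start=start_bp, end=end_bp, anchor=i,
                field_mass=float(vals[a:e].sum()),
                occ_mass=occ.mass_between(chrom, start_bp, end_bp),
                support=len(support), bins=(ka, ke),
            ))
    return out


def estimate_eloc(region: Region, fieldest: ConditionalJointField, i) -> int:
    """Most likely jointly occupied point in a region: the midpoint of its
    maximal-density bin (leftmost on ties)."""
    bins, vals = fieldest.profile_values(i, region.chrom)
    ka, ke = region.bins
    sel = (bins >= ka) & (bins <= ke)
    if not np.any(sel) or vals[sel].sum() <= 0:
        raise ChialoopError("region has no conditional mass")
    vv = vals[sel]
    bb = bins[sel]
    k = bb[int(np.argmax(vv))]
    b = fieldest.bin_size
    return int(k * b + b // 2)


# ----------------------------------------------------------------------
# missing-mass fixed point
# ----------------------------------------------------------------------

@dataclass
class TauState:
    """Converged missing-mass corrections for one setting of c."""

    t: np.ndarray
    m: np.ndarray
    tau: np.ndarray
    i_max: int
    c: float
    sweeps: int

    def constraint_residual(self) -> float:
        """Max deviation of (t+τ)/Σ(t+τ) from m/Σm over free coordinates.

        Floored coordinates (τ = 0) and the pinned coordinate i_max are
        constrained, not free: the proportionality can only be enforced on
        the rest.  When no floor binds, the identity automatically extends
        to i_max as well.
        """
        free = self.tau > 0
        free[self.i_max] = False
        if not np.any(free) or self.m.sum() <= 0:
            return 0.0
        tot = self.t + self.tau
        lhs = tot / tot.sum()
        rhs = self.m / self.m.sum()
        return float(np.max(np.abs(lhs[free] - rhs[free])))


def solve_tau(t, m, c, tol=1e-10, max_sweeps=10_000) -> TauState:
    """Cyclic fixed-point iteration for the missing masses τ_i.

    τ at the heaviest anchor is pinned to (c − 1)·t_max; the others are
    updated in turn to satisfy (t_i + τ_i)/Σ(t_j + τ_j) = m_i/Σm_j, each
    update floored at zero.
    """
    t = np.asarray(t, dtype=float)
    m = np.asarray(m, dtype=float)
    if c <= 1:
        raise ChialoopError(f"c must exceed 1, got {c}")
    if np.any((t > 0) & (m <= 0)):
        raise ChialoopError("anchor with conditional mass but zero marginal occupancy")
    i_max = int(np.argmax(t))  # argmax takes the lowest index on ties
    tau = np.zeros_like(t)
    tau[i_max] = (c - 1.0) * t[i_max]
    others = [i for i in range(len(t)) if i != i_max]
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        delta = 0.0
        for i in others:
            tot_others = t.sum() + tau.sum() - t[i] - tau[i]
            m_others = m.sum() - m[i]
            if m_others <= 0:
                new = 0.0
            else:
                new = max(0.0, m[i] * tot_others / m_others - t[i])
            delta = max(delta, abs(new - tau[i]))
            tau[i] = new
        if delta < tol:
            return TauState(t=t, m=m, tau=tau, i_max=i_max, c=float(c), sweeps=sweeps)
    state = TauState(t=t, m=m, tau=tau, i_max=i_max, c=float(c), sweeps=sweeps)
    raise ChialoopError(
        f"τ fixed point did not converge after {max_sweeps} sweeps "
        f"(constraint residual {state.constraint_residual():.3g})"
    )


def corrected_joint_pvalue(region: Region, fieldest: ConditionalJointField, i,
                           tau: TauState, n_inter) -> float:
    """Undersampling-corrected significance of an anchored region.

    The region's conditional mass is deflated by the anchor's corrected
    total t_i + τ_i and compared with the marginal occupancy mass.
    """
    denom = tau.t[i] + tau.tau[i]
    if denom <= 0:
        return 1.0
    p = min(1.0, region.field_mass / denom)
    p_prime = min(1.0, region.occ_mass)
    n = int(round(n_inter))
    score = pr_y_gt_z(n, p_prime, n, p)
    if p <= p_prime:
        # no enrichment to call: when both rates are far below 1/n the raw
        # Pr(Y > Z) score is small merely because Y is almost surely zero,
        # not because the estimate beats the background
        return max(score, 0.5)
    return score


# ----------------------------------------------------------------------
# calibration of c and interaction calling
# ----------------------------------------------------------------------

@dataclass
class SignificanceConfig:
    """Knobs for candidate extraction, testing, and c calibration."""

    f: float = 0.0                      # conditional-density cutoff (> f)
    pvalue_cutoff: float = 0.05
    target_single_fraction: float = 0.1
    single_fraction_slack: float = 0.05  # lower edge of the acceptance band
    c_init: float = 2.0
    c_min: float = 1.01
    c_max: float = 1e4
    max_search_iters: int = 30
    tau_tol: float = 1e-10
    bh_correction: bool = False          # off by default


@dataclass
class InteractionCall:
    """A significant anchored interaction."""

    anchor_index: int
    anchor_chrom: str
    anchor_pos: int
    anchor_name: str
    region: Region
    pvalue: float
    support: int
    eloc: int
    t: float
    tau: float


@dataclass
class CalibrationResult:
    c: float
    tau: TauState
    calls: list
    regions: list
    pvalues: np.ndarray
    single_fraction: float
    n_significant: int
    history: list = field(default_factory=list)


def _bh_adjust(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return adj


def calibrate_c(fieldest: ConditionalJointField, occ: OccupancyTrack, n_inter,
                config: SignificanceConfig | None = None) -> CalibrationResult:
    """Search for the missing-mass scale c by the single-pair-fraction rule.

    At each candidate c the τ fixed point is solved, every candidate region
    is scored, and the fraction of significant regions supported by exactly
    one read pair is measured.  Too many singletons → c grows (more
    correction); too few → c shrinks.  The search brackets multiplicatively
    and then bisects on log c.
    """
    cfg = config or SignificanceConfig()
    anchors_with_mass = np.nonzero(fieldest.t > 0)[0]
    regions = []
    for i in range(len(fieldest.anchors)):
        regions.extend(candidate_regions(fieldest, i, cfg.f, occ))

    def evaluate(c):
        tau = solve_tau(fieldest.t, fieldest.m, c, tol=cfg.tau_tol)
        pvals = np.array([
            corrected_joint_pvalue(r, fieldest, r.anchor, tau, n_inter)
            for r in regions
        ])
        shown = _bh_adjust(pvals) if cfg.bh_correction and len(pvals) else pvals
        sig = shown < cfg.pvalue_cutoff
        n_sig = int(sig.sum())
        n_single = int(np.sum(sig & (np.array([r.support for r in regions]) == 1))) if n_sig else 0
        frac = n_single / n_sig if n_sig else 0.0
        return tau, pvals, sig, n_sig, frac

    if not regions or len(anchors_with_mass) == 0:
        log.warning("calibration: no candidate regions; nothing to call")
        tau = solve_tau(np.maximum(fieldest.t, 0), np.maximum(fieldest.m, 1e-12),
                        cfg.c_min + 1e-9) if len(fieldest.t) else None
        return CalibrationResult(c=cfg.c_min, tau=tau, calls=[], regions=[],
                                 pvalues=np.array([]), single_fraction=0.0,
                                 n_significant=0)

    lo_edge = max(0.0, cfg.target_single_fraction - cfg.single_fraction_slack)
    c = cfg.c_init
    lo = None   # largest c seen with too many singletons
    hi = None   # smallest c seen with too few
    history = []
    evaluations = []
    best = None
    for _ in range(cfg.max_search_iters):
        tau, pvals, sig, n_sig, frac = evaluate(c)
        history.append((c, n_sig, frac))
        evaluations.append((c, tau, pvals, sig, n_sig, frac))
        if n_sig > 0 and lo_edge <= frac <= cfg.target_single_fraction:
            best = evaluations[-1]
            break
        if frac > cfg.target_single_fraction:
            lo = c if lo is None else max(lo, c)
            if c >= cfg.c_max:
                break
            c = math.sqrt(c * hi) if hi is not None else min(cfg.c_max, c * 2.0)
        else:  # too few singleton significants (includes n_sig == 0)
            hi = c if hi is None else min(hi, c)
            if c <= cfg.c_min:
                break
            c = math.sqrt(c * lo) if lo is not None else max(cfg.c_min, c / 2.0)
        if lo is not None and hi is not None and hi / lo < 1.001:
            break

    if best is None:
        # the target band was never hit (e.g. the singleton fraction jumps
        # across it): return the conservative side — the smallest c whose
        # singleton fraction does not exceed the target; if every c has too
        # many singletons, the most-corrected state
        acceptable = [e for e in evaluations if e[5] <= cfg.target_single_fraction]
        best = min(acceptable, key=lambda e: e[0]) if acceptable \
            else max(evaluations, key=lambda e: e[0])

    c, tau, pvals, sig, n_sig, frac = best
    if n_sig == 0:
        log.warning("calibration: no significant regions at any searched c "
                    "(final c=%.3g)", c)
    calls = []
    for r, p, s in zip(regions, pvals, sig):
        if not s:
            continue
        i = r.anchor
        calls.append(InteractionCall(
            anchor_index=i,
            anchor_chrom=fieldest.anchors.chroms[i],
            anchor_pos=int(fieldest.anchors.positions[i]),
            anchor_name=fieldest.anchors.names[i],
            region=r, pvalue=float(p), support=r.support,
            eloc=estimate_eloc(r, fieldest, i),
            t=float(fieldest.t[i]), tau=float(tau.tau[i]),
        ))
    return CalibrationResult(c=float(c), tau=tau, calls=calls, regions=regions,
                             pvalues=pvals, single_fraction=float(frac),
                             n_significant=n_sig, history=history)
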