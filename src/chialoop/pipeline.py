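"""End-to-end orchestration: marginal occupancy estimation and anchored
interaction calling.

`estimate_marginal` runs the full marginal path: orientation split and
mixture weighting, LSCV bandwidths, blind RL deconvolution of a training
window to learn the read spread function and its peak λ, then the fast
diagonal-slice occupancy genome-wide.  `call_interactions` feeds the
resulting occupancy and RSF marginals into the anchored conditional field
and calibrated significance testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ChialoopError
from .genome import GenomeModel
from .readpairs import ReadPairSet
from .selfligation import (classify_self_ligation, lscv_bandwidth_2d,
                           weighted_kde_2d, SelfLigationWeights)
from .deconvolution import (RLSchedule, RSFMarginals, blind_deconvolve,
                            band_from_density, fast_marginal_occupancy)
from .joint import AnchorSet, conditional_field
from .significance import SignificanceConfig, calibrate_c

log = logging.getLogger(__name__)


@dataclass
class MarginalParams:
    """Tunable parameters of the marginal path."""

    distance_cap: int = 50_000
    lscv_subsample: int = 1000
    bandwidth_grid: tuple | None = None
    rsf_half_width: int = 2000
    grid_step: int = 10
    bin_size: int = 10
    training_window_bp: int = 5_000_000
    schedule: RLSchedule = field(default_factory=RLSchedule)
    truncate: float = 4.0
    seed: int = 0


@dataclass
class MarginalResult:
    weights: SelfLigationWeights
    h_self: float
    rsf: object
    marginals: RSFMarginals
    lam: float
    occupancy: object
    training_window: tuple
    report: dict


def select_training_window(weights: SelfLigationWeights, genome: GenomeModel,
                           window_bp) -> tuple:
    """The window of the requested size holding the most self-ligation weight.

    Scans pair midpoints per chromosome with a two-pointer sweep; the
    deconvolution only needs a representative region, not a special one.
    """
    mp = weights.minus_plus
    w = weights.weights
    best = None
    for ci, chrom in enumerate(genome.names):
        sel = np.nonzero((mp.chrom1 == ci) & (w > 0))[0]
        if len(sel) == 0:
            continue
        mids = (mp.pos1[sel] + mp.pos2[sel]) / 2.0
        order = np.argsort(mids)
        mids = mids[order]
        ws = w[sel][order]
        cw = np.concatenate([[0.0], np.cumsum(ws)])
        j = np.searchsorted(mids, mids + window_bp, side="right")
        gains = cw[j] - cw[:-1]
        k = int(np.argmax(gains))
        if best is None or gains[k] > best[0]:
            start = int(mids[k])
            best = (float(gains[k]), chrom, start)
    if best is None:
        raise ChialoopError("no weighted self-ligation pairs anywhere")
    _, chrom, start = best
    length = genome.length(chrom)
    start = max(0, min(start, length - window_bp)) if length > window_bp else 0
    end = min(length, start + window_bp)
    return chrom, start, end


def estimate_marginal(pairs: ReadPairSet, genome: GenomeModel,
                      params: MarginalParams | None = None) -> MarginalResult:
    p = params or MarginalParams()
    weights = classify_self_ligation(
        pairs, distance_cap=p.distance_cap, candidates=p.bandwidth_grid,
        lscv_subsample=p.lscv_subsample, seed=p.seed)

    mp = weights.minus_plus
    pos = np.nonzero(weights.weights > 0)[0]
    if len(pos) < 2:
        raise ChialoopError("no self-ligation signal (fewer than 2 weighted -+ pairs)")
    rng = np.random.default_rng(p.seed + 1)
    sub = pos if len(pos) <= p.lscv_subsample else rng.choice(pos, p.lscv_subsample, replace=False)
    h_self = lscv_bandwidth_2d(mp.pos1[sub].astype(float), mp.pos2[sub].astype(float),
                               weights.weights[sub], p.bandwidth_grid)

    window = select_training_window(weights, genome, p.training_window_bp)
    chrom, start, end = window
    ci = genome.index(chrom)
    pad = p.rsf_half_width + int(6 * h_self)
    in_win = ((mp.chrom1 == ci)
              & (mp.pos1 >= start - pad) & (mp.pos2 <= end + pad)
              & (weights.weights > 0))
    if int(in_win.sum()) < 2:
        raise ChialoopError("no self-ligation signal in the training window")
    density = weighted_kde_2d(
        (mp.pos1[in_win].astype(float), mp.pos2[in_win].astype(float)),
        weights.weights[in_win], h_self, window, step=p.grid_step)
    band = band_from_density(density, max_span=2 * p.rsf_half_width,
                             truncate=p.truncate)
    deconv = blind_deconvolve(band, schedule=p.schedule,
                              rsf_half_width=p.rsf_half_width)
    lam = deconv.rsf.peak()
    occupancy = fast_marginal_occupancy(weights, h_self, lam, genome,
                                        bin_size=p.bin_size, truncate=p.truncate)
    report = {
        "n_pairs": len(pairs),
        "n_minus_plus": len(mp),
        "inter_fraction": weights.inter_fraction,
        "n_self": weights.n_self,
        "n_inter": weights.n_inter,
        "h_minus_plus": weights.h_minus_plus,
        "h_non_minus_plus": weights.h_non_minus_plus,
        "h_self": h_self,
        "lambda": lam,
        "training_window": list(window),
        "rl_converged": deconv.converged,
        "rl_rounds": deconv.rounds,
        "bin_size": p.bin_size,
    }
    return MarginalResult(weights=weights, h_self=h_self, rsf=deconv.rsf,
                          marginals=RSFMarginals.from_rsf(deconv.rsf), lam=lam,
                          occupancy=occupancy, training_window=window, report=report)


@dataclass
class AnchoredCallResult:
    field: object
    calibration: object
    inter_pairs: ReadPairSet
    n_inter: int
    report: dict


def select_inter_pairs(pairs: ReadPairSet, weights: SelfLigationWeights) -> ReadPairSet:
    """Pairs treated as inter-ligation for the joint step: every non--+
    pair plus -+ pairs whose self-ligation posterior is below 1/2."""
    from .readpairs import split_by_orientation

    mp, non = split_by_orientation(pairs)
    low = weights.weights < 0.5
    if np.any(low):
        keep = mp.subset(low)
        return ReadPairSet(
            pairs.genome,
            np.concatenate([non.chrom1, keep.chrom1]),
            np.concatenate([non.pos1, keep.pos1]),
            np.concatenate([non.strand1, keep.strand1]),
            np.concatenate([non.chrom2, keep.chrom2]),
            np.concatenate([non.pos2, keep.pos2]),
            np.concatenate([non.strand2, keep.strand2]),
        )
    return non


def call_interactions(pairs: ReadPairSet, genome: GenomeModel, anchors: AnchorSet,
                      marginal: MarginalResult,
                      sig_config: SignificanceConfig | None = None) -> AnchoredCallResult:
    inter = select_inter_pairs(pairs, marginal.weights)
    if len(inter) == 0:
        raise ChialoopError("no inter-ligation pairs to analyze")
    fieldest = conditional_field(inter, marginal.occupancy, marginal.marginals, anchors)
    n_inter = max(1, int(round(marginal.weights.n_inter)))
    calib = calibrate_c(fieldest, marginal.occupancy, n_inter, sig_config)
    report = {
        "n_anchors": len(anchors),
        "n_inter_pairs_used": len(inter),
        "n_inter_binomial": n_inter,
        "c": calib.c,
        "single_pair_fraction": calib.single_fraction,
        "n_candidate_regions": len(calib.regions),
        "n_significant": calib.n_significant,
    }
    return AnchoredCallResult(field=fieldest, calibration=calib, inter_pairs=inter,
                       n_inter=n_inter, report=report)
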