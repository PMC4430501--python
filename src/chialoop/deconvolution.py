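"""Blind Richardson-Lucy deconvolution of the self-ligation density.

The 2D self-ligation read-pair density is modeled as the convolution of a
1D occupancy distribution placed on the diagonal with a 2D *read spread
function* (RSF) — the distribution of mate-pair offsets around an occupied
location induced by sonication, the sequencing analogue of an imaging
point spread function.  Alternating multiplicative Richardson-Lucy updates
recover both factors from the observed density.

Because both the data and the forward model live within a narrow band
around the plane's diagonal (a pair's span cannot exceed the RSF support),
all 2D objects are stored in *banded* form indexed by (span δ = y − x,
lower coordinate x).  For a fixed span the forward model is an ordinary 1D
convolution of the occupancy with the RSF's δ-slice, so one batched FFT
convolution per update covers the whole band.

The RSF peak sits at offsets ⟨−λ, λ⟩ where λ is roughly half the modal
fragment length; with a sharply peaked RSF the genome-wide occupancy can be
read directly off the self-ligation density along the shifted diagonal
(the "fast path"), avoiding genome-scale deconvolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import ChialoopError
from .genome import GenomeModel
from .selfligation import SelfLigationWeights, SelfPairDensity2D

log = logging.getLogger(__name__)

_FLOOR = 1e-300


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

class ReadSpreadFunction:
    """2D distribution of self-ligation mate offsets (dx, dy) from an
    occupied location, on a square grid with half-width W and step s.

    Support is restricted to dy >= dx: the ordered lower mate can never sit
    above the upper mate.  Values are normalized to sum to 1.
    """

    def __init__(self, offsets, values, step):
        offsets = np.asarray(offsets, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(offsets), len(offsets)):
            raise ChialoopError("RSF values must be square over the offset grid")
        if np.any(values < 0):
            raise ChialoopError("negative RSF value")
        total = values.sum()
        if total <= 0:
            raise ChialoopError("RSF has no mass")
        self.offsets = offsets
        self.values = values / total
        self.step = int(step)

    @property
    def half_width(self) -> float:
        return float(self.offsets[-1])

    # -- band form -----------------------------------------------------
    def band(self) -> np.ndarray:
        """Banded form kb[d, i] = RSF(off_i, off_i + d*step)."""
        K = len(self.offsets)
        kb = np.zeros((2 * K - 1, K))
        for d in range(2 * K - 1):
            i = np.arange(0, K - d)
            kb[d, i] = self.values[i, i + d]
        return kb

    @classmethod
    def from_band(cls, kb, offsets, step) -> "ReadSpreadFunction":
        K = len(offsets)
        sq = np.zeros((K, K))
        for d in range(kb.shape[0]):
            i = np.arange(0, max(0, K - d))
            sq[i, i + d] = kb[d, i]
        return cls(offsets, sq, step)

    # -- summaries -----------------------------------------------------
    def peak(self) -> float:
        return rsf_peak(self)

    def marginal(self, strand):
        return marginalize_rsf(self, strand)


def rsf_peak(rsf: ReadSpreadFunction) -> float:
    """λ of the RSF peak ⟨−λ, λ⟩: the global maximum projected onto the
    anti-diagonal, ties broken toward smaller λ."""
    v = rsf.values
    if v.size == 0:
        raise ChialoopError("empty RSF")
    vmax = v.max()
    triangle = np.triu(np.ones_like(v, dtype=bool))  # representable support
    if triangle.sum() > 1 and np.all(v[triangle] == v[triangle][0]) \
            and np.all(v[~triangle] == 0):
        raise ChialoopError("no peak: RSF is flat")
    ii, jj = np.nonzero(v == vmax)
    lams = (rsf.offsets[jj] - rsf.offsets[ii]) / 2.0
    return float(lams.min())


def marginalize_rsf(rsf: ReadSpreadFunction, strand):
    """Single-end read spread for one strand.

    Minus-strand mates are the lower coordinate of a self-ligation pair, so
    their spread is the RSF marginal over dx (sum over dy); plus-strand
    mates marginalize over dx leaving a distribution over dy.  Returns
    ``(offsets, values)`` with values normalized to 1.
    """
    if strand in ("-", 1):
        vals = rsf.values.sum(axis=1)
    elif strand in ("+", 0):
        vals = rsf.values.sum(axis=0)
    else:
        raise ChialoopError(f"bad strand {strand!r}")
    total = vals.sum()
    if total > 0:
        vals = vals / total
    return rsf.offsets.copy(), vals


@dataclass
class RSFMarginals:
    """Per-strand 1D read spreads obtained by marginalizing the RSF."""

    offsets: np.ndarray
    step: int
    minus: np.ndarray
    plus: np.ndarray

    @classmethod
    def from_rsf(cls, rsf: ReadSpreadFunction, support_floor=1e-9) -> "RSFMarginals":
        """Marginalize an RSF; values below ``support_floor`` of the marginal
        maximum are treated as exactly zero.  Multiplicative RL drives
        unsupported cells toward zero without ever reaching it, and those
        underflow-scale tails must not count as read support downstream."""
        _, mi = marginalize_rsf(rsf, "-")
        _, pl = marginalize_rsf(rsf, "+")
        out = []
        for v in (mi, pl):
            v = np.where(v >= support_floor * v.max(), v, 0.0)
            out.append(v / v.sum())
        return cls(offsets=rsf.offsets.copy(), step=rsf.step, minus=out[0], plus=out[1])

    @property
    def support(self) -> float:
        """Half-width of the offset grid in bp."""
        return float(self.offsets[-1])

    def __call__(self, strand, offset):
        """Strand-appropriate spread evaluated at integer offsets (0 outside)."""
        vals = self.minus if strand in ("-", 1) else self.plus
        offset = np.asarray(offset, dtype=float)
        idx = np.rint((offset - self.offsets[0]) / self.step).astype(int)
        ok = (idx >= 0) & (idx < len(vals))
        out = np.zeros(offset.shape)
        out[ok] = vals[idx[ok]]
        return out


class OccupancyTrack:
    """Binned marginal occupancy Pr(q = u): per-chromosome mass arrays.

    ``data`` maps chromosome -> (start_bp, values); values are per-bin
    masses and the track normalizes to total 1 over its domain.
    """

    def __init__(self, bin_size, data, normalize=True):
        self.bin_size = int(bin_size)
        self.data = {c: (int(s), np.asarray(v, dtype=float)) for c, (s, v) in data.items()}
        for c, (_, v) in self.data.items():
            if np.any(v < 0):
                raise ChialoopError(f"negative occupancy on {c}")
        if normalize:
            self.normalize()

    def total(self) -> float:
        return float(sum(v.sum() for _, v in self.data.values()))

    def normalize(self):
        t = self.total()
        if t <= 0:
            raise ChialoopError("occupancy track has no mass")
        for c in self.data:
            s, v = self.data[c]
            self.data[c] = (s, v / t)
        return self

    def value_at(self, chrom, pos) -> float:
        """Mass of the bin containing ``pos`` (0 outside the track)."""
        if chrom not in self.data:
            return 0.0
        start, v = self.data[chrom]
        k = (int(pos) - start) // self.bin_size
        if 0 <= k < len(v):
            return float(v[k])
        return 0.0

    def mass_between(self, chrom, start, end) -> float:
        """Total mass of bins overlapping [start, end)."""
        if chrom not in self.data or end <= start:
            return 0.0
        s0, v = self.data[chrom]
        k0 = max(0, (int(start) - s0) // self.bin_size)
        k1 = min(len(v), -(-(int(end) - s0) // self.bin_size))
        return float(v[k0:k1].sum()) if k1 > k0 else 0.0

    def argmax(self):
        """(chrom, bin_start_bp) of the maximal bin."""
        best = None
        for c, (s, v) in self.data.items():
            k = int(np.argmax(v))
            if best is None or v[k] > best[2]:
                best = (c, s + k * self.bin_size, v[k])
        return best[0], best[1]


@dataclass
class BandedSelfDensity:
    """Self-ligation density on a diagonal band.

    ``values[d, k]`` is the density at (x, y) = (start + k*step,
    start + (k + d)*step); rows index the pair span δ = d*step >= 0.
    """

    chrom: str
    start: int
    step: int
    values: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    @property
    def n_spans(self) -> int:
        return self.values.shape[0]


def band_from_density(density: SelfPairDensity2D, max_span, truncate=4.0) -> BandedSelfDensity:
    """Evaluate a 2D pair KDE on the diagonal band δ in [0, max_span].

    Each kernel is separable in (x, y), so a pair deposits an outer-product
    patch remapped into band coordinates; contributions beyond ``truncate``
    bandwidths are dropped.
    """
    s = density.step
    start = density.start
    n = density.n_positions
    nd = int(max_span) // s + 1
    B = np.zeros((nd, n))
    h = density.bandwidth
    r = truncate * h
    norm = 1.0 / (2.0 * math.pi * h * h)
    pos0 = float(start)
    for a, b, w in zip(density.x, density.y, density.weights):
        if w <= 0:
            continue
        kx0 = max(0, int(math.ceil((a - r - pos0) / s)))
        kx1 = min(n - 1, int(math.floor((a + r - pos0) / s)))
        ky0 = max(0, int(math.ceil((b - r - pos0) / s)))
        ky1 = min(n - 1, int(math.floor((b + r - pos0) / s)))
        if kx1 < kx0 or ky1 < ky0:
            continue
        ix = np.arange(kx0, kx1 + 1)
        iy = np.arange(ky0, ky1 + 1)
        fx = np.exp(-((pos0 + ix * s - a) ** 2) / (2.0 * h * h))
        fy = np.exp(-((pos0 + iy * s - b) ** 2) / (2.0 * h * h))
        D = iy[:, None] - ix[None, :]
        X = np.broadcast_to(ix[None, :], D.shape)
        patch = (w * norm) * fy[:, None] * fx[None, :]
        m = (D >= 0) & (D < nd)
        np.add.at(B, (D[m], X[m]), patch[m])
    return BandedSelfDensity(chrom=density.chrom, start=start, step=s, values=B)


# ----------------------------------------------------------------------
# Richardson-Lucy core (banded arrays)
# ----------------------------------------------------------------------

def _forward_band(occ, kb):
    """F[d] = occ ⊛ kb[d] for every span row (batched FFT convolution)."""
    n = len(occ)
    K = kb.shape[1]
    c = (K - 1) // 2
    full = fftconvolve(kb, occ[None, :], axes=1)
    return np.clip(full[:, c:c + n], 0.0, None)


def _ratio(D, F):
    G = np.where(F > _FLOOR, D / np.maximum(F, _FLOOR), 0.0)
    dropped = D[F <= _FLOOR].sum()
    if dropped > 1e-6 * D.sum():
        d, k = np.argwhere((F <= _FLOOR) & (D > 0))[0]
        raise ChialoopError(
            f"re-blurred estimate is zero where data mass exists "
            f"(band row {d}, column {k}; dropped mass {dropped:.3g})"
        )
    return G


def _occ_sensitivity(kb, n):
    """Per-position kernel mass falling inside the observed band — the
    flat-field denominator that removes boundary bias (and makes the
    noiseless fixed point exact)."""
    K = kb.shape[1]
    c = (K - 1) // 2
    ones = np.ones((kb.shape[0], n))
    return fftconvolve(kb[:, ::-1], ones, axes=1)[:, K - 1 - c:K - 1 - c + n].sum(axis=0)


def _occ_step(occ, kb, D, sens=None):
    """One multiplicative RL occupancy update; renormalized to input sum."""
    n = len(occ)
    K = kb.shape[1]
    c = (K - 1) // 2
    if sens is None:
        sens = _occ_sensitivity(kb, n)
    F = _forward_band(occ, kb)
    G = _ratio(D, F)
    corr = fftconvolve(kb[:, ::-1], G, axes=1)[:, K - 1 - c:K - 1 - c + n].sum(axis=0)
    mult = np.where(sens > _FLOOR, corr / np.maximum(sens, _FLOOR), 0.0)
    new = np.clip(occ * mult, 0.0, None)
    t = new.sum()
    if t <= 0:
        raise ChialoopError("occupancy update annihilated all mass")
    return new * (occ.sum() / t)


def _rsf_sensitivity(occ, shape):
    """Per-cell occupancy mass visible from the band for the RSF update."""
    n = len(occ)
    K = shape[1]
    c = (K - 1) // 2
    cum = np.concatenate([[0.0], np.cumsum(occ)])
    i = np.arange(K)
    lo = np.clip(c - i, 0, n)
    hi = np.clip(n + c - i, 0, n)
    row = cum[hi] - cum[lo]
    return np.broadcast_to(row, shape)


def _rsf_step(kb, occ, D, sens=None):
    """One multiplicative RL update of the banded RSF; sum preserved."""
    n = len(occ)
    K = kb.shape[1]
    c = (K - 1) // 2
    if n - 1 - c < 0:
        raise ChialoopError("window shorter than RSF half-width")
    if sens is None:
        sens = _rsf_sensitivity(occ, kb.shape)
    F = _forward_band(occ, kb)
    G = _ratio(D, F)
    corr = fftconvolve(G, occ[::-1][None, :], axes=1)[:, n - 1 - c:n - 1 - c + K]
    mult = np.where(sens > _FLOOR, corr / np.maximum(sens, _FLOOR), 0.0)
    new = np.clip(kb * mult, 0.0, None)
    t = new.sum()
    if t <= 0:
        raise ChialoopError("RSF update annihilated all mass")
    return new * (kb.sum() / t)


def _check_grids(occ_values, rsf: ReadSpreadFunction, data: BandedSelfDensity):
    if rsf.step != data.step:
        raise ChialoopError("RSF and data grids have different steps")
    if data.n_positions != len(occ_values):
        raise ChialoopError("occupancy and data windows disagree")


def rl_update_occupancy(occ: OccupancyTrack, rsf: ReadSpreadFunction,
                        selfdist: BandedSelfDensity) -> OccupancyTrack:
    """One RL occupancy update on a window track (non-negativity and total
    mass of the input are preserved)."""
    start, values = occ.data[selfdist.chrom]
    _check_grids(values, rsf, selfdist)
    new = _occ_step(values, rsf.band(), selfdist.values)
    return OccupancyTrack(occ.bin_size, {selfdist.chrom: (start, new)}, normalize=False)


def rl_update_rsf(rsf: ReadSpreadFunction, occ: OccupancyTrack,
                  selfdist: BandedSelfDensity) -> ReadSpreadFunction:
    """One RL update of the RSF with the occupancy held fixed."""
    start, values = occ.data[selfdist.chrom]
    _check_grids(values, rsf, selfdist)
    kb = _rsf_step(rsf.band(), values, selfdist.values)
    return ReadSpreadFunction.from_band(kb, rsf.offsets, rsf.step)


@dataclass
class RLSchedule:
    """Alternation schedule for blind deconvolution."""

    occ_iters: int = 10
    rsf_iters: int = 10
    rounds: int = 5
    tol: float = 1e-6


@dataclass
class BlindDeconvolution:
    occupancy: OccupancyTrack
    rsf: ReadSpreadFunction
    converged: bool
    rounds: int
    delta: float


def blind_deconvolve(selfdist, schedule: RLSchedule | None = None,
                     rsf_half_width: int = 2000) -> BlindDeconvolution:
    """Alternating blind RL deconvolution of a windowed self-ligation density.

    ``selfdist`` is a :class:`SelfPairDensity2D` (converted to band form
    internally) or an already-banded density.  Both estimates start uniform:
    the occupancy over the window, the RSF over its dy >= dx support.
    Rounds of occupancy updates then RSF updates run until the combined L1
    change per round falls below ``schedule.tol``; on non-convergence the
    current state is returned with a warning.
    """
    sched = schedule or RLSchedule()
    if isinstance(selfdist, SelfPairDensity2D):
        band = band_from_density(selfdist, max_span=2 * rsf_half_width)
    else:
        band = selfdist
    s = band.step
    half = (rsf_half_width // s) * s
    K = 2 * (half // s) + 1
    offsets = (np.arange(K) - (K - 1) // 2) * float(s)
    n = band.n_positions
    if n <= K:
        raise ChialoopError("training window must exceed the RSF grid")

    D = band.values[: 2 * K - 1].copy()
    if D.shape[0] < 2 * K - 1:
        D = np.vstack([D, np.zeros((2 * K - 1 - D.shape[0], n))])
    total = D.sum()
    if total <= 0:
        raise ChialoopError("self-ligation density has no mass in the window")
    D = D / total

    # only span rows where the data carries mass can hold RSF mass at the
    # optimum; restricting the updates to them is exact and much faster
    row_mass = D.sum(axis=1)
    nz = np.nonzero(row_mass > 0)[0]
    d_lo, d_hi = max(0, nz[0] - 1), min(2 * K - 2, nz[-1] + 1)
    Dr = D[d_lo:d_hi + 1]
    Dr = Dr / Dr.sum()

    # occupancy starts uniform; the RSF starts with a mild taper centered on
    # the anti-diagonal (offset -delta/2 within each span row).  A perfectly
    # flat RSF start is a degenerate fixed point of the multiplicative
    # updates: the diagonal-shift ambiguity of blind deconvolution leaves the
    # update multiplier exactly flat along each row, so nothing ever
    # concentrates.  The taper breaks the tie toward the symmetric solution
    # (it does not bias the peak span, hence not lambda).
    occ = np.full(n, 1.0 / n)
    kbr = np.zeros((d_hi - d_lo + 1, K))
    c = (K - 1) // 2
    sigma_c = max(1.0, half / (2.0 * s))
    for row, d in enumerate(range(d_lo, d_hi + 1)):
        m = max(0, K - d)
        i = np.arange(m)
        centered = i - c + d / 2.0  # distance from the symmetric offset
        kbr[row, :m] = np.exp(-0.5 * (centered / sigma_c) ** 2)
    if kbr.sum() <= 0:
        raise ChialoopError("RSF grid cannot represent the observed spans")
    kbr /= kbr.sum()

    converged = False
    delta = math.inf
    r = 0
    for r in range(1, sched.rounds + 1):
        occ_prev, kb_prev = occ, kbr
        sens = _occ_sensitivity(kbr, n)
        for _ in range(sched.occ_iters):
            occ = _occ_step(occ, kbr, Dr, sens=sens)
        sens = _rsf_sensitivity(occ, kbr.shape)
        for _ in range(sched.rsf_iters):
            kbr = _rsf_step(kbr, occ, Dr, sens=sens)
        delta = np.abs(occ - occ_prev).sum() + np.abs(kbr - kb_prev).sum()
        if delta < sched.tol:
            converged = True
            break
    if not converged:
        log.warning("blind deconvolution: L1 change %.3g after %d rounds "
                    "(tolerance %.3g); returning current state", delta, r, sched.tol)

    # gauge fixing: a diagonal shift of the RSF compensated by the opposite
    # occupancy shift leaves the forward model unchanged, so report the
    # canonical representative with the peak on the anti-diagonal
    pk_row, pk_col = np.unravel_index(np.argmax(kbr), kbr.shape)
    d_pk = d_lo + pk_row
    center_off = (pk_col - c) + d_pk / 2.0  # (dx + dy) / (2 s) of the peak cell
    t = int(round(center_off))
    if t != 0:
        shifted = np.zeros_like(kbr)
        if t > 0:
            shifted[:, :K - t] = kbr[:, t:]
        else:
            shifted[:, -t:] = kbr[:, :K + t]
        if shifted.sum() > 0.5 * kbr.sum():  # keep the shift only if lossless-ish
            kbr = shifted / shifted.sum() * kbr.sum()
            occ_s = np.zeros_like(occ)
            if t > 0:
                occ_s[t:] = occ[:n - t]
            else:
                occ_s[:n + t] = occ[-t:]
            if occ_s.sum() > 0:
                occ = occ_s / occ_s.sum() * occ.sum()

    kb = np.zeros((2 * K - 1, K))
    kb[d_lo:d_hi + 1] = kbr
    track = OccupancyTrack(s, {band.chrom: (band.start, occ)}, normalize=False)
    rsf = ReadSpreadFunction.from_band(kb, offsets, s)
    return BlindDeconvolution(occupancy=track, rsf=rsf, converged=converged,
                              rounds=r, delta=float(delta))


# ----------------------------------------------------------------------
# fast genome-wide occupancy (diagonal-slice approximation)
# ----------------------------------------------------------------------

def fast_marginal_occupancy(weights: SelfLigationWeights, bandwidth, lam,
                            genome: GenomeModel, bin_size=10,
                            truncate=4.0) -> OccupancyTrack:
    """Genome-wide occupancy via the sharply-peaked-RSF approximation.

    The occupancy at u is proportional to the weighted pair KDE evaluated at
    the single point ⟨u − λ, u + λ⟩.  For the isotropic Gaussian kernel this
    collapses to a 1D weighted KDE over pair midpoints with a per-pair factor
    penalizing half-spans away from λ.  Bins farther than ``truncate``
    bandwidths from every weighted midpoint are exactly zero.
    """
    if lam < 0:
        raise ChialoopError(f"negative λ ({lam})")
    mp = weights.minus_plus
    w = weights.weights
    if not np.any(w > 0):
        raise ChialoopError("no positive self-ligation weights")
    h = float(bandwidth)
    wsum = w.sum()
    data = {}
    names = genome.names
    for ci, chrom in enumerate(names):
        nbins = -(-genome.length(chrom) // bin_size)
        vals = np.zeros(nbins)
        sel = (mp.chrom1 == ci) & (w > 0)
        if np.any(sel):
            mids = (mp.pos1[sel] + mp.pos2[sel]) / 2.0
            halfs = (mp.pos2[sel] - mp.pos1[sel]) / 2.0
            wf = (w[sel] / wsum) * np.exp(-((lam - halfs) ** 2) / (h * h))
            order = np.argsort(mids)
            r = truncate * h
            for mid, f in zip(mids[order], wf[order]):
                if f <= 0:
                    continue
                k0 = max(0, int((mid - r) // bin_size))
                k1 = min(nbins - 1, int((mid + r) // bin_size))
                centers = (np.arange(k0, k1 + 1) + 0.5) * bin_size
                vals[k0:k1 + 1] += f * np.exp(-((centers - mid) ** 2) / (h * h))
        data[chrom] = (0, vals / (2.0 * math.pi * h * h))
    track = OccupancyTrack(bin_size, data, normalize=False)
    if track.total() <= 0:
        raise ChialoopError("fast occupancy track has no mass")
    return track.normalize()


def diagonal_slice_profile(density: SelfPairDensity2D, lam, positions) -> np.ndarray:
    """Exact diagonal-slice evaluation: density at ⟨u − λ, u + λ⟩."""
    u = np.asarray(positions, dtype=float)
    return density.evaluate(u - lam, u + lam)
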