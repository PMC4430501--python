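"""Self-ligation mixture model and kernel density machinery.

The distance distribution of intra-chromosomal ``-+`` read pairs is a
mixture: self-ligation pairs whose span is bounded by the sonication
fragment length, and inter-ligation pairs whose span is unconstrained.
Because the three other orientations (``++``, ``+-``, ``--``) can only be
produced by inter-ligation, they identify both the inter-ligation distance
density and (by orientation symmetry of ligation) the expected number of
``-+`` pairs that are really inter-ligation.  Each ``-+`` pair then gets a
posterior probability of being self-ligation given its span, and those
posteriors weight a 2D kernel density estimate of the self-ligation
read-pair distribution.

Bandwidths for all kernel estimates are chosen by least-squares
cross-validation (LSCV) over a log-spaced candidate grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ChialoopError
from .readpairs import ReadPairSet, split_by_orientation

log = logging.getLogger(__name__)

SQRT2PI = math.sqrt(2.0 * math.pi)
DEFAULT_BANDWIDTH_GRID = tuple(np.geomspace(10.0, 10_000.0, 30))
DEFAULT_DISTANCE_CAP = 50_000


def _phi(u, h):
    """Gaussian kernel density with bandwidth (standard deviation) h."""
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * (u / h) ** 2) / (h * SQRT2PI)


# ----------------------------------------------------------------------
# 1D kernel density estimation
# ----------------------------------------------------------------------

@dataclass
class DistanceDensity:
    """A 1D Gaussian KDE over read-pair distances.

    ``grid``/``values`` give a precomputed evaluation (used for fast
    interpolation in the pipeline); calling the object evaluates the exact
    kernel sum.
    """

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float
    points: np.ndarray
    weights: np.ndarray  # normalized to sum 1

    def __call__(self, x):
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        # chunked exact kernel sum to bound memory
        step = max(1, int(2_000_000 / max(1, len(self.points))))
        for lo in range(0, len(x), step):
            xs = x[lo:lo + step, None]
            out[lo:lo + step] = (_phi(xs - self.points[None, :], self.bandwidth)
                                 * self.weights[None, :]).sum(axis=1)
        return float(out[0]) if scalar else out

    def interp(self, x):
        """Linear interpolation on the precomputed grid (0 outside)."""
        return np.interp(x, self.grid, self.values, left=0.0, right=0.0)


def kde_1d(distances, bandwidth, weights=None, grid=None, grid_points=1024) -> DistanceDensity:
    """Weighted (or unweighted) Gaussian KDE over distances."""
    d = np.asarray(distances, dtype=float)
    if bandwidth is None or bandwidth <= 0:
        raise ChialoopError(f"bandwidth must be positive, got {bandwidth}")
    if len(d) == 0:
        raise ChialoopError("kde_1d needs at least one point")
    if weights is None:
        w = np.full(len(d), 1.0 / len(d))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ChialoopError("weights must be non-negative with positive sum")
        w = w / w.sum()
    if grid is None:
        lo, hi = d.min() - 6 * bandwidth, d.max() + 6 * bandwidth
        grid = np.linspace(lo, hi, grid_points)
    dens = DistanceDensity(grid=np.asarray(grid, float), values=None,
                           bandwidth=float(bandwidth), points=d, weights=w)
    dens.values = dens(dens.grid)
    return dens


def lscv_criterion_1d(distances, h) -> float:
    """Least-squares cross-validation score for an unweighted 1D Gaussian KDE.

    LSCV(h) = ∫ f̂² − (2/n) Σ_i f̂_{−i}(x_i), computed in closed form for the
    Gaussian kernel.
    """
    d = np.asarray(distances, dtype=float)
    n = len(d)
    diff = d[:, None] - d[None, :]
    term1 = _phi(diff, h * math.sqrt(2.0)).sum() / n**2
    m = _phi(diff, h)
    np.fill_diagonal(m, 0.0)
    term2 = 2.0 * m.sum() / (n * (n - 1) * 1.0)
    return float(term1 - term2)


def lscv_bandwidth_1d(distances, candidates=None) -> float:
    """Bandwidth minimizing the LSCV criterion over a candidate grid."""
    d = np.asarray(distances, dtype=float)
    if len(d) < 2:
        raise ChialoopError("LSCV bandwidth selection needs at least 2 points")
    if candidates is None:
        candidates = DEFAULT_BANDWIDTH_GRID
    candidates = np.asarray(candidates, dtype=float)
    diff2 = (d[:, None] - d[None, :]) ** 2
    n = len(d)
    scores = np.empty(len(candidates))
    for k, h in enumerate(candidates):
        e2 = np.exp(-diff2 / (4.0 * h * h))      # kernel at sd h*sqrt(2)
        e1 = np.exp(-diff2 / (2.0 * h * h))      # kernel at sd h
        term1 = e2.sum() / (n**2 * h * math.sqrt(2.0) * SQRT2PI)
        term2 = 2.0 * (e1.sum() - n) / (n * (n - 1) * h * SQRT2PI)
        scores[k] = term1 - term2
    if not np.all(np.isfinite(scores)):
        raise ChialoopError("non-finite LSCV criterion value")
    return float(candidates[int(np.argmin(scores))])


# ----------------------------------------------------------------------
# mixture model
# ----------------------------------------------------------------------

def estimate_inter_fraction(counts) -> float:
    """Fraction of -+ pairs attributable to inter-ligation.

    The average count of the three orientations that can only arise from
    inter-ligation estimates how many -+ pairs are inter-ligation too;
    the ratio is clipped at 1.
    """
    if isinstance(counts, ReadPairSet):
        counts = counts.counts
    n_mp = counts["-+"]
    if n_mp == 0:
        raise ChialoopError("no -+ pairs: cannot estimate inter fraction")
    avg_other = (counts["++"] + counts["+-"] + counts["--"]) / 3.0
    return min(1.0, avg_other / n_mp)


def self_posterior(d, p_d, p_d_inter, inter_fraction):
    """Posterior probability that a -+ pair with span d is self-ligation.

    ``p_d`` and ``p_d_inter`` may be densities (callables) or values
    already evaluated at ``d``.  The implied self-ligation distance density
    (total minus the inter component) is clipped at zero, and the posterior
    is clipped to [0, 1]; both can stray outside their ranges under
    finite-sample density estimates.
    """
    scalar = np.isscalar(d)
    d = np.atleast_1d(np.asarray(d, dtype=float))
    pd = np.atleast_1d(p_d(d) if callable(p_d) else np.asarray(p_d, float))
    pint = np.atleast_1d(p_d_inter(d) if callable(p_d_inter) else np.asarray(p_d_inter, float))
    pi = float(inter_fraction)
    if not 0.0 <= pi <= 1.0:
        raise ChialoopError(f"inter fraction {pi} outside [0, 1]")
    if pi >= 1.0:
        post = np.zeros_like(pd)
    else:
        p_d_self = np.clip(pd - pi * pint, 0.0, None) / (1.0 - pi)
        with np.errstate(divide="ignore", invalid="ignore"):
            post = np.where(pd > 0.0, np.clip(p_d_self * (1.0 - pi) / pd, 0.0, 1.0), 0.0)
    return float(post[0]) if scalar else post


@dataclass
class SelfLigationWeights:
    """Per -+ pair self-ligation posteriors plus mixture bookkeeping."""

    minus_plus: ReadPairSet
    weights: np.ndarray
    inter_fraction: float
    n_total: int          # N over the whole dataset
    h_minus_plus: float
    h_non_minus_plus: float
    density_all: DistanceDensity | None = None
    density_inter: DistanceDensity | None = None

    @property
    def n_self(self) -> float:
        return float(self.weights.sum())

    @property
    def n_inter(self) -> float:
        return float(self.n_total - self.weights.sum())


def classify_self_ligation(pairs: ReadPairSet, *, distance_cap=DEFAULT_DISTANCE_CAP,
                           candidates=None, lscv_subsample=1000, seed=0) -> SelfLigationWeights:
    """Full mixture workflow: split, fit both distance KDEs, weight -+ pairs.

    Distances above ``distance_cap`` are treated as certainly inter-ligation
    (self-ligation spans are bounded by the fragment length); both KDEs are
    fitted on capped distances.  LSCV runs on a deterministic subsample when
    the input is large.
    """
    mp, non = split_by_orientation(pairs)
    if len(mp) == 0:
        raise ChialoopError("no -+ pairs in dataset")
    rng = np.random.default_rng(seed)
    d_mp = mp.distances()
    fit_mp = d_mp[d_mp <= distance_cap]
    if len(fit_mp) < 2:
        raise ChialoopError("fewer than 2 -+ pairs within the distance cap")

    d_non = non.distances()
    fit_non = d_non[np.isfinite(d_non) & (d_non <= distance_cap)]

    def _sub(x):
        if len(x) <= lscv_subsample:
            return x
        return rng.choice(x, size=lscv_subsample, replace=False)

    h_mp = lscv_bandwidth_1d(_sub(fit_mp), candidates)
    dens_mp = kde_1d(fit_mp, h_mp)

    if len(fit_non) >= 2:
        h_non = lscv_bandwidth_1d(_sub(fit_non), candidates)
        dens_non = kde_1d(fit_non, h_non)
        inter_at = dens_non.interp
    else:
        # no usable inter-only distances: fall back to a uniform density
        log.warning("no non--+ intra-chromosomal distances within cap; "
                    "using a uniform inter-ligation distance density")
        h_non = float("nan")
        dens_non = None
        inter_at = lambda x: np.full(np.shape(x), 1.0 / distance_cap)  # noqa: E731

    pi = estimate_inter_fraction(pairs.counts)
    w = self_posterior(d_mp, dens_mp.interp(d_mp), inter_at(d_mp), pi)
    w = np.asarray(w, dtype=float)
    w[d_mp > distance_cap] = 0.0
    return SelfLigationWeights(
        minus_plus=mp, weights=w, inter_fraction=pi, n_total=len(pairs),
        h_minus_plus=h_mp, h_non_minus_plus=h_non,
        density_all=dens_mp, density_inter=dens_non,
    )


# ----------------------------------------------------------------------
# 2D weighted kernel density over read-pair coordinates
# ----------------------------------------------------------------------

@dataclass
class SelfPairDensity2D:
    """Weighted bivariate Gaussian KDE of self-ligation pair coordinates.

    Mass integrates to 1 over the full plane by construction (weights are
    normalized); a dense grid is only materialized for small windows, the
    genome-scale path evaluates the density pointwise or on a diagonal band.
    """

    chrom: str
    start: int
    end: int
    step: int
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray  # normalized
    bandwidth: float
    _grid: np.ndarray = field(default=None, repr=False)

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(self.n_positions) * self.step

    @property
    def n_positions(self) -> int:
        return (self.end - self.start) // self.step + 1

    def evaluate(self, xq, yq):
        """Exact kernel sum at query coordinates (vectorized, chunked)."""
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        yq = np.atleast_1d(np.asarray(yq, dtype=float))
        h = self.bandwidth
        out = np.zeros(len(xq))
        step = max(1, int(2_000_000 / max(1, len(self.x))))
        for lo in range(0, len(xq), step):
            dx = xq[lo:lo + step, None] - self.x[None, :]
            dy = yq[lo:lo + step, None] - self.y[None, :]
            k = np.exp(-(dx * dx + dy * dy) / (2.0 * h * h))
            out[lo:lo + step] = (k * self.weights[None, :]).sum(axis=1)
        return out / (2.0 * math.pi * h * h)

    def grid_values(self) -> np.ndarray:
        """Dense (n, n) evaluation over the window's square grid."""
        n = self.n_positions
        if n > 4000:
            raise ChialoopError(
                f"window too large for a dense grid ({n} positions); "
                "use the banded representation"
            )
        if self._grid is None:
            pos = self.positions.astype(float)
            xs = np.repeat(pos, n)
            ys = np.tile(pos, n)
            self._grid = self.evaluate(xs, ys).reshape(n, n)
        return self._grid


def weighted_kde_2d(pairs, weights, bandwidth, window, step=10) -> SelfPairDensity2D:
    """Self-ligation read-pair density from weighted -+ pairs.

    ``pairs`` is a ReadPairSet (pos1 = lower mate, pos2 = upper mate) or an
    ``(x, y)`` tuple of arrays; ``window`` is ``(chrom, start, end)``.
    """
    if isinstance(pairs, ReadPairSet):
        x, y = pairs.pos1.astype(float), pairs.pos2.astype(float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in pairs)
    w = np.asarray(weights, dtype=float)
    if bandwidth is None or bandwidth <= 0:
        raise ChialoopError(f"bandwidth must be positive, got {bandwidth}")
    chrom, start, end = window
    if end <= start:
        raise ChialoopError("empty window")
    if np.any(w < 0):
        raise ChialoopError("negative self-ligation weight")
    if w.sum() <= 0:
        raise ChialoopError("no self-ligation signal in window")
    return SelfPairDensity2D(
        chrom=chrom, start=int(start), end=int(end), step=int(step),
        x=x, y=y, weights=w / w.sum(), bandwidth=float(bandwidth),
    )


def lscv_criterion_2d(x, y, weights, h) -> float:
    """Weighted least-squares CV score for the 2D self-ligation KDE.

    With normalized weights ω_i the estimate is f̂ = Σ ω_i K_h(· − r_i); the
    score is ∫ f̂² − 2 Σ_i ω_i f̂_{−i}(r_i), with leave-one-out weights
    renormalized over j ≠ i.  With equal weights this reduces to the
    unweighted LSCV criterion.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    s = w.sum()
    wn = w / s
    d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
    k2 = np.exp(-d2 / (4.0 * h * h)) / (2.0 * math.pi * 2.0 * h * h)   # sd h*sqrt(2)
    term1 = float(wn @ k2 @ wn)
    k1 = np.exp(-d2 / (2.0 * h * h)) / (2.0 * math.pi * h * h)
    np.fill_diagonal(k1, 0.0)
    loo = (k1 @ w) / np.maximum(s - w, 1e-300)
    term2 = 2.0 * float(np.dot(wn, loo))
    return term1 - term2


def lscv_bandwidth_2d(x, y, weights, candidates=None) -> float:
    """Bandwidth minimizing the weighted 2D LSCV criterion."""
    w = np.asarray(weights, float)
    if int(np.sum(w > 0)) < 2:
        raise ChialoopError("LSCV needs at least 2 pairs with positive weight")
    if candidates is None:
        candidates = DEFAULT_BANDWIDTH_GRID
    candidates = np.asarray(candidates, dtype=float)
    scores = np.array([lscv_criterion_2d(x, y, w, h) for h in candidates])
    if not np.all(np.isfinite(scores)):
        raise ChialoopError("non-finite LSCV criterion value")
    return float(candidates[int(np.argmin(scores))])
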