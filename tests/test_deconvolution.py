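"""Richardson-Lucy blind deconvolution: banded updates vs dense brute force,
conservation, peak extraction, marginals, and the fast occupancy path."""

import numpy as np
import pytest

from chialoop import (ChialoopError, GenomeModel, OccupancyTrack,
                      ReadSpreadFunction, RLSchedule, Site, SimulationConfig,
                      FragmentModel, blind_deconvolve, classify_self_ligation,
                      fast_marginal_occupancy, lscv_bandwidth_2d,
                      marginalize_rsf, rl_update_occupancy, rl_update_rsf,
                      rsf_peak, simulate_dataset, weighted_kde_2d)
from chialoop.deconvolution import (BandedSelfDensity, RSFMarginals,
                                    _forward_band, _occ_sensitivity, _occ_step,
                                    _rsf_step, band_from_density, diagonal_slice_profile)
from chialoop.selfligation import SelfLigationWeights


# ----------------------------------------------------------------------
# dense brute-force reference for the banded algebra
# ----------------------------------------------------------------------

def random_band_instance(rng, K=7, n=30):
    """Random RSF band, occupancy, and a data band restricted to cells the
    forward model can reach."""
    kb = np.zeros((2 * K - 1, K))
    for d in range(2 * K - 1):
        m = K - d
        if m > 0:
            kb[d, :m] = rng.random(m)
    kb /= kb.sum()
    occ = rng.random(n)
    occ /= occ.sum()
    F = dense_forward(occ, kb, K, n)
    D = rng.random((2 * K - 1, n)) * (F > 0)
    D /= D.sum()
    return kb, occ, D


def dense_forward(occ, kb, K, n):
    c = (K - 1) // 2
    F = np.zeros((kb.shape[0], n))
    for d in range(kb.shape[0]):
        for k in range(n):
            for i in range(K):
                m = k + c - i
                if 0 <= m < n:
                    F[d, k] += kb[d, i] * occ[m]
    return F


class TestBandedUpdatesMatchBruteForce:
    def test_forward_model(self):
        rng = np.random.default_rng(0)
        kb, occ, _ = random_band_instance(rng)
        assert np.allclose(_forward_band(occ, kb), dense_forward(occ, kb, 7, 30),
                           atol=1e-14)

    def test_occupancy_update(self):
        rng = np.random.default_rng(1)
        K, n, c = 7, 30, 3
        kb, occ, D = random_band_instance(rng)
        F = dense_forward(occ, kb, K, n)
        G = np.where(F > 0, D / np.where(F > 0, F, 1.0), 0.0)
        U = np.zeros(n)
        W = np.zeros(n)
        for u in range(n):
            for d in range(2 * K - 1):
                for k in range(n):
                    i = k - u + c
                    if 0 <= i < K:
                        U[u] += G[d, k] * kb[d, i]
                        W[u] += kb[d, i]
        expect = occ * np.where(W > 0, U / np.where(W > 0, W, 1.0), 0.0)
        expect *= occ.sum() / expect.sum()
        assert np.allclose(_occ_step(occ, kb, D), expect, atol=1e-12)

    def test_rsf_update(self):
        rng = np.random.default_rng(2)
        K, n, c = 7, 30, 3
        kb, occ, D = random_band_instance(rng)
        F = dense_forward(occ, kb, K, n)
        G = np.where(F > 0, D / np.where(F > 0, F, 1.0), 0.0)
        M = np.zeros((2 * K - 1, K))
        V = np.zeros((2 * K - 1, K))
        for d in range(2 * K - 1):
            for i in range(K):
                for m in range(n):
                    k = m + i - c
                    if 0 <= k < n:
                        M[d, i] += occ[m] * G[d, k]
                        V[d, i] += occ[m]
        expect = kb * np.where(V > 0, M / np.where(V > 0, V, 1.0), 0.0)
        expect *= kb.sum() / expect.sum()
        assert np.allclose(_rsf_step(kb, occ, D), expect, atol=1e-12)


class TestConservationAndFixedPoints:
    def test_noiseless_fixed_point(self):
        # data equal to the exact forward convolution leaves both factors
        # unchanged by one update
        rng = np.random.default_rng(3)
        kb, occ, _ = random_band_instance(rng)
        D = _forward_band(occ, kb)
        assert np.allclose(_occ_step(occ, kb, D), occ, atol=1e-9)
        assert np.allclose(_rsf_step(kb, occ, D), kb, atol=1e-9)

    def test_delta_rsf_identity(self):
        # point-mass RSF at the origin: the data diagonal IS the occupancy
        K, n, c = 7, 40, 3
        kb = np.zeros((2 * K - 1, K))
        kb[0, c] = 1.0
        rng = np.random.default_rng(4)
        occ = rng.random(n)
        occ /= occ.sum()
        D = np.zeros((2 * K - 1, n))
        D[0] = occ
        assert np.allclose(_occ_step(occ, kb, D), occ, atol=1e-9)

    def test_updates_preserve_positivity_and_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            kb, occ, D = random_band_instance(rng)
            o2 = _occ_step(occ, kb, D)
            k2 = _rsf_step(kb, occ, D)
            assert o2.min() >= 0 and k2.min() >= 0
            assert o2.sum() == pytest.approx(occ.sum(), abs=1e-9)
            assert k2.sum() == pytest.approx(kb.sum(), abs=1e-9)

    def test_symmetric_inputs_keep_rsf_symmetric(self):
        # a data band with exact reflection symmetry (generated by a second
        # symmetric occupancy/RSF pair) and a symmetric current occupancy
        # leave each updated RSF span row symmetric about its own center
        K, n, c = 7, 41, 3

        def sym_band(width):
            kb = np.zeros((2 * K - 1, K))
            for d in range(2 * K - 1):
                m = K - d
                if m <= 0:
                    continue
                i = np.arange(m)
                kb[d, :m] = np.exp(-0.5 * ((i - c + d / 2.0) / width) ** 2)
            return kb / kb.sum()

        def sym_occ(width):
            # compactly supported so window edges cannot break the symmetry
            u = np.arange(n) - n // 2
            o = np.where(np.abs(u) <= 12, np.exp(-0.5 * (u / width) ** 2), 0.0)
            return o / o.sum()

        kb, occ = sym_band(1.0), sym_occ(6.0)
        D = _forward_band(sym_occ(3.0), sym_band(1.7))  # symmetric, not a fixed point
        k2 = _rsf_step(kb, occ, D / D.sum())
        for d in range(2 * K - 1):
            m = K - d
            if m > 1:
                assert np.allclose(k2[d, :m], k2[d, :m][::-1], atol=1e-9)


class TestPublicUpdateWrappers:
    def test_track_roundtrip_conservation(self):
        rng = np.random.default_rng(7)
        kb, occ, D = random_band_instance(rng)
        offsets = (np.arange(7) - 3) * 10.0
        rsf = ReadSpreadFunction.from_band(kb, offsets, 10)
        band = BandedSelfDensity("chr1", 0, 10, D)
        track = OccupancyTrack(10, {"chr1": (0, occ)}, normalize=False)
        t2 = rl_update_occupancy(track, rsf, band)
        assert t2.total() == pytest.approx(track.total(), abs=1e-9)
        r2 = rl_update_rsf(rsf, track, band)
        assert r2.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestRsfPeak:
    def mk(self, cells, K=9, step=10):
        offsets = (np.arange(K) - K // 2) * step
        v = np.zeros((K, K))
        for dx, dy, val in cells:
            i = int(dx / step) + K // 2
            j = int(dy / step) + K // 2
            v[i, j] = val
        return ReadSpreadFunction(offsets, v, step)

    def test_symmetric_peak(self):
        K = 41
        rsf = self.mk([(-150, 150, 1.0), (-140, 140, 0.5)], K=K)
        assert rsf_peak(rsf) == 150.0

    def test_off_diagonal_peak_projects(self):
        rsf = self.mk([(-140, 160, 1.0)], K=41)
        assert rsf_peak(rsf) == 150.0

    def test_tie_breaks_toward_smaller_lambda(self):
        rsf = self.mk([(-100, 100, 1.0), (-200, 200, 1.0)], K=51)
        assert rsf_peak(rsf) == 100.0

    def test_flat_rsf_errors(self):
        K = 9
        offsets = (np.arange(K) - K // 2) * 10.0
        v = np.triu(np.ones((K, K)))
        with pytest.raises(ChialoopError, match="no peak"):
            rsf_peak(ReadSpreadFunction(offsets, v, 10))


class TestMarginals:
    def test_delta_rsf_marginals(self):
        K = 41
        offsets = (np.arange(K) - K // 2) * 10.0
        v = np.zeros((K, K))
        v[K // 2 - 15, K // 2 + 15] = 1.0  # cell (-150, 150)
        rsf = ReadSpreadFunction(offsets, v, 10)
        off, minus = marginalize_rsf(rsf, "-")
        _, plus = marginalize_rsf(rsf, "+")
        assert minus[np.searchsorted(off, -150)] == 1.0
        assert plus[np.searchsorted(off, 150)] == 1.0
        assert minus.sum() == pytest.approx(1.0, abs=1e-9)
        assert plus.sum() == pytest.approx(1.0, abs=1e-9)

    def test_antidiagonal_symmetry_mirrors_marginals(self):
        K = 21
        offsets = (np.arange(K) - K // 2) * 10.0
        rng = np.random.default_rng(8)
        v = np.zeros((K, K))
        for i in range(K):
            for j in range(i, K):
                val = rng.random()
                v[i, j] = val
                v[K - 1 - j, K - 1 - i] = val  # mirror across anti-diagonal
        rsf = ReadSpreadFunction(offsets, v, 10)
        _, minus = marginalize_rsf(rsf, "-")
        _, plus = marginalize_rsf(rsf, "+")
        assert np.allclose(minus, plus[::-1], atol=1e-9)


class TestBlindDeconvolve:
    def test_noiseless_limit_concentrates_rsf(self):
        # pairs exactly at (u-150, u+150): nearly all RSF mass must land in
        # the single cell (-150, +150)
        us = np.array([1000.0, 2000.0, 3000.0])
        x = np.repeat(us - 150, 50)
        y = np.repeat(us + 150, 50)
        dens = weighted_kde_2d((x, y), np.ones_like(x), 2.0, ("c", 0, 4000), step=10)
        band = band_from_density(dens, 800, truncate=12)
        res = blind_deconvolve(band, RLSchedule(5, 5, 15, tol=1e-12),
                               rsf_half_width=400)
        v = res.rsf.values
        i, j = np.unravel_index(np.argmax(v), v.shape)
        assert (res.rsf.offsets[i], res.rsf.offsets[j]) == (-150.0, 150.0)
        assert v[i, j] >= 0.9
        assert res.rsf.peak() == 150.0

    def test_outputs_sum_to_one(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(500, 3500, 300)
        y = x + rng.normal(300, 30, 300)
        dens = weighted_kde_2d((x, y), np.ones_like(x), 20.0, ("c", 0, 4200), step=10)
        res = blind_deconvolve(band_from_density(dens, 800),
                               RLSchedule(3, 3, 2), rsf_half_width=400)
        assert res.occupancy.total() == pytest.approx(1.0, abs=1e-9)
        assert res.rsf.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.occupancy.data["c"][1].min() >= 0

    def test_peak_on_antidiagonal_within_two_steps(self):
        rng = np.random.default_rng(10)
        us = rng.integers(1000, 9000, 5).astype(float)
        idx = rng.integers(0, 5, 2000)
        L = rng.normal(300, 30, 2000)
        beta = rng.uniform(0.3, 0.7, 2000)
        x = us[idx] - L * beta
        y = us[idx] + L * (1 - beta)
        dens = weighted_kde_2d((x, y), np.ones(2000), 15.0, ("c", 0, 10_000), step=10)
        res = blind_deconvolve(band_from_density(dens, 800),
                               RLSchedule(8, 8, 3), rsf_half_width=400)
        v = res.rsf.values
        i, j = np.unravel_index(np.argmax(v), v.shape)
        # peak cell projects onto the anti-diagonal within 2 grid steps
        assert abs(res.rsf.offsets[i] + res.rsf.offsets[j]) <= 20.0
        assert abs(res.rsf.peak() - 150.0) <= 20.0


# ----------------------------------------------------------------------
# fast genome-wide occupancy (diagonal-slice approximation)
# ----------------------------------------------------------------------

def _weights_for(genome, x, y, w):
    from chialoop.readpairs import ReadPairSet

    n = len(x)
    mp = ReadPairSet(genome, np.zeros(n, dtype=np.int32), x, np.ones(n, dtype=np.int8),
                     np.zeros(n, dtype=np.int32), y, np.zeros(n, dtype=np.int8))
    return SelfLigationWeights(minus_plus=mp, weights=np.asarray(w, float),
                               inter_fraction=0.0, n_total=n,
                               h_minus_plus=1.0, h_non_minus_plus=1.0)


class TestFastMarginalOccupancy:
    def test_single_pair_midpoint(self):
        genome = GenomeModel({"chr1": 10_000})
        w = _weights_for(genome, np.array([850]), np.array([1150]), [1.0])
        track = fast_marginal_occupancy(w, bandwidth=30.0, lam=150.0,
                                        genome=genome, bin_size=10)
        chrom, pos = track.argmax()
        # the pair midpoint 1000 is a bin boundary, so either adjacent bin
        assert chrom == "chr1" and abs(pos + 5 - 1000) <= 10

    def test_matches_exact_diagonal_slice(self):
        genome = GenomeModel({"chr1": 6000})
        rng = np.random.default_rng(11)
        x = rng.uniform(1000, 4000, 15)
        y = x + rng.normal(300, 30, 15)
        wts = rng.uniform(0.2, 1.0, 15)
        h, lam = 40.0, 150.0
        w = _weights_for(genome, x.astype(np.int64), y.astype(np.int64), wts)
        track = fast_marginal_occupancy(w, h, lam, genome, bin_size=10, truncate=50.0)
        dens = weighted_kde_2d((w.minus_plus.pos1.astype(float),
                                w.minus_plus.pos2.astype(float)), wts, h,
                               ("chr1", 0, 6000))
        centers = np.arange(len(track.data["chr1"][1])) * 10 + 5.0
        expect = diagonal_slice_profile(dens, lam, centers)
        expect /= expect.sum()
        assert np.allclose(track.data["chr1"][1], expect, atol=1e-12)

    def test_two_sites_recovered_within_one_bin(self):
        genome = GenomeModel({"chr1": 40_000})
        cfg = SimulationConfig(genome=genome,
                               sites=[Site("chr1", 10_000), Site("chr1", 20_000)],
                               loops=[], n_self=1000, n_inter=0, n_noise=0, seed=12)
        pairs, _ = simulate_dataset(cfg)
        wts = classify_self_ligation(pairs)
        track = fast_marginal_occupancy(wts, 25.0, 150.0, genome, bin_size=10)
        vals = track.data["chr1"][1]
        for site in (10_000, 20_000):
            k = site // 10
            local = np.argmax(vals[k - 50:k + 50]) + k - 50
            assert abs(local - k) <= 1

    def test_requires_positive_weights(self):
        genome = GenomeModel({"chr1": 1000})
        w = _weights_for(genome, np.array([100]), np.array([400]), [0.0])
        with pytest.raises(ChialoopError, match="weight"):
            fast_marginal_occupancy(w, 30.0, 150.0, genome)


class TestFastVersusFullDeconvolution:
    def test_tracks_agree_at_positional_uncertainty_scale(self):
        """Diagonal-slice track vs full RL with the generative RSF on 1 Mb.

        Exact RL removes the kernel + fragmentation width that the fast
        track retains, so agreement is assessed on 100 bp mass aggregates
        (the estimator's positional uncertainty), where both reduce to
        'which sites carry how much occupancy'.
        """
        genome = GenomeModel({"chrF": 1_000_000})
        rng = np.random.default_rng(5)
        sites = [Site("chrF", int(p)) for p in rng.integers(20_000, 980_000, 20)]
        cfg = SimulationConfig(genome=genome, sites=sites, loops=[],
                               fragment=FragmentModel(300, 30), n_self=10_000,
                               n_inter=0, n_noise=0, seed=5)
        pairs, _ = simulate_dataset(cfg)
        w = classify_self_ligation(pairs)
        mp = w.minus_plus
        sub = np.random.default_rng(1).choice(np.nonzero(w.weights > 0)[0], 1000,
                                              replace=False)
        h = lscv_bandwidth_2d(mp.pos1[sub].astype(float), mp.pos2[sub].astype(float),
                              w.weights[sub])
        dens = weighted_kde_2d((mp.pos1.astype(float), mp.pos2.astype(float)),
                               w.weights, h, ("chrF", 0, 1_000_000), step=10)
        band = band_from_density(dens, 600)
        nz = np.nonzero(band.values.sum(axis=1) > 0)[0]
        d_lo, d_hi = nz[0], nz[-1]
        K, c, s = 101, 50, 10
        kb = np.zeros((d_hi - d_lo + 1, K))
        for r_i, d in enumerate(range(d_lo, d_hi + 1)):
            span = d * s
            if span <= 0:
                continue
            a = (np.arange(K) - c) * s
            beta = -a / span
            kb[r_i] = np.where((beta >= 0.3) & (beta <= 0.7),
                               np.exp(-0.5 * ((span - 300) / 30) ** 2) / span, 0.0)
        kb /= kb.sum()
        D = band.values[d_lo:d_hi + 1].copy()
        D /= D.sum()
        occ = np.full(band.n_positions, 1.0 / band.n_positions)
        sens = _occ_sensitivity(kb, len(occ))
        for _ in range(30):
            occ = _occ_step(occ, kb, D, sens=sens)
        fast = fast_marginal_occupancy(w, h, 150.0, genome, bin_size=10)
        fv = fast.data["chrF"][1]
        n = (min(len(occ), len(fv)) // 10) * 10
        agg = lambda t: t[:n].reshape(-1, 10).sum(axis=1)  # noqa: E731
        r = np.corrcoef(agg(occ), agg(fv))[0, 1]
        assert r >= 0.9
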