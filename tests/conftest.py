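"""Shared fixtures: small genomes, and session-scoped pipeline runs on the
default synthetic scenario (planted loops + noise) and its noise-only twin."""

from types import SimpleNamespace

import numpy as np
import pytest

from chialoop import (AnchorSet, GenomeModel, MarginalParams, ReadPairSet,
                      RLSchedule, SignificanceConfig, call_interactions,
                      default_scenario, estimate_marginal, simulate_dataset)


@pytest.fixture
def small_genome():
    return GenomeModel({"chr1": 100_000, "chr2": 80_000})


def make_pairs(genome, rows):
    """rows: (chrom1, pos1, strand1, chrom2, pos2, strand2)."""
    c1, p1, s1, c2, p2, s2 = zip(*rows)
    return ReadPairSet.from_mates(genome, list(c1), list(p1), list(s1),
                                  list(c2), list(p2), list(s2))


def fixture_params():
    """Analysis settings used for runs on the default 2 Mb scenario:
    an 800 bp RSF grid (fragment ~300 bp), a 150 kb training window, and a
    short alternation schedule, all chosen for the scenario's scale."""
    return MarginalParams(rsf_half_width=800, training_window_bp=150_000,
                          schedule=RLSchedule(occ_iters=8, rsf_iters=8, rounds=3))


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default scenario: 20 planted loops, 50% of the
    inter-ligation pairs uniform noise."""
    scen = default_scenario(seed=0)
    pairs, truth = simulate_dataset(scen)
    marg = estimate_marginal(pairs, scen.genome, fixture_params())
    anchors = AnchorSet.build(scen.anchor_points, scen.genome)
    gx = call_interactions(pairs, scen.genome, anchors, marg, SignificanceConfig())
    return SimpleNamespace(scenario=scen, pairs=pairs, truth=truth,
                           marginal=marg, anchors=anchors, interactions=gx)


@pytest.fixture(scope="session")
def noise_run():
    """Same layout but all inter-ligation pairs are uniform noise."""
    scen = default_scenario(seed=0, n_inter=0, n_noise=25_000)
    pairs, truth = simulate_dataset(scen)
    marg = estimate_marginal(pairs, scen.genome, fixture_params())
    anchors = AnchorSet.build(scen.anchor_points, scen.genome)
    gx = call_interactions(pairs, scen.genome, anchors, marg, SignificanceConfig())
    return SimpleNamespace(scenario=scen, pairs=pairs, truth=truth,
                           marginal=marg, anchors=anchors, interactions=gx)
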