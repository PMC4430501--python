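"""Synthetic ChIA-PET read-pair generator with known ground truth.

Self-ligation pairs are emitted around occupancy sites: a site location u,
a sonication fragment of length L (modal length ~300 bp), and a breakpoint
jitter β ~ Uniform(0.3, 0.7) place the minus-strand mate at u − Lβ and the
plus-strand mate at u + L(1 − β), so the pair always reads -+ and its span
equals the fragment length.  Inter-ligation pairs sample a planted loop's
two sites and fragment each end independently with uniformly random
strands; noise pairs have both mates uniform over the genome.  The jitter
makes the implied read spread function a ridge rather than a degenerate
line, which is what real sonication produces.

Everything is driven by one seed, so identical configs yield identical
files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ChialoopError
from .genome import GenomeModel
from .readpairs import ReadPairSet

LABEL_SELF = "self"
LABEL_LOOP = "loop"
LABEL_NOISE = "noise"


@dataclass
class Site:
    """An occupancy site: point location, sampling weight, optional width."""

    chrom: str
    position: int
    weight: float = 1.0
    width: int = 0


@dataclass
class Loop:
    """A planted interaction between two genomic points."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    intensity: float = 1.0


@dataclass
class FragmentModel:
    """Sonication fragment length distribution (normal, clipped >= 50 bp)."""

    mean: float = 300.0
    sd: float = 30.0

    def sample(self, rng, n):
        return np.clip(rng.normal(self.mean, self.sd, size=n), 50.0, None)


@dataclass
class SimulationConfig:
    genome: GenomeModel
    sites: list
    loops: list
    fragment: FragmentModel = field(default_factory=FragmentModel)
    n_self: int = 10_000
    n_inter: int = 5_000      # loop-derived inter-ligation pairs
    n_noise: int = 5_000      # uniform background pairs
    beta_range: tuple = (0.3, 0.7)
    read_length: int = 36
    seed: int = 0

    def __post_init__(self):
        if min(self.n_self, self.n_inter, self.n_noise) < 0:
            raise ChialoopError("pair counts must be non-negative")
        if self.fragment.mean <= 0:
            raise ChialoopError("modal fragment length must be positive")
        for s in self.sites:
            if not 0 <= s.position < self.genome.length(s.chrom):
                raise ChialoopError(f"site {s.chrom}:{s.position} outside genome")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated dataset."""

    sites: list
    loops: list
    labels: np.ndarray          # per emitted pair, aligned with the pair set
    lambda_true: float          # half the modal fragment length
    config: SimulationConfig


def _draw_sites(config, rng, n):
    """Sample occupied locations from the configured site mixture."""
    weights = np.array([s.weight for s in config.sites], dtype=float)
    if len(weights) == 0 or weights.sum() <= 0:
        raise ChialoopError("no occupancy sites configured")
    idx = rng.choice(len(config.sites), size=n, p=weights / weights.sum())
    chroms, positions = [], np.empty(n, dtype=np.int64)
    for k, i in enumerate(idx):
        s = config.sites[i]
        pos = s.position
        if s.width > 0:
            pos = pos + rng.integers(-(s.width // 2), s.width // 2 + 1)
        chroms.append(s.chrom)
        positions[k] = pos
    return chroms, positions


def _mate_from_site(config, rng, pos, strand):
    """5' mate location for a tag on one strand of a fragment covering pos."""
    L = float(config.fragment.sample(rng, 1)[0])
    beta = rng.uniform(*config.beta_range)
    if strand == "-":
        return int(round(pos - L * beta))
    return int(round(pos + L * (1.0 - beta)))


def _in_bounds(config, chrom, pos):
    return config.read_length <= pos < config.genome.length(chrom) - config.read_length


def simulate_self_pairs(config: SimulationConfig, rng) -> tuple:
    """Self-ligation pairs: both mates flank one occupied location."""
    if config.n_self <= 0:
        raise ChialoopError("n_self must be positive")
    c1, p1, c2, p2 = [], [], [], []
    while len(p1) < config.n_self:
        chroms, centers = _draw_sites(config, rng, config.n_self - len(p1))
        for chrom, u in zip(chroms, centers):
            L = float(config.fragment.sample(rng, 1)[0])
            beta = rng.uniform(*config.beta_range)
            lo = int(round(u - L * beta))
            hi = int(round(u + L * (1.0 - beta)))
            if not (_in_bounds(config, chrom, lo) and _in_bounds(config, chrom, hi)):
                continue  # resample
            c1.append(chrom)
            p1.append(lo)
            c2.append(chrom)
            p2.append(hi)
    pairs = ReadPairSet.from_mates(
        config.genome, c1, p1, ["-"] * len(p1), c2, p2, ["+"] * len(p2))
    return pairs, np.array([LABEL_SELF] * len(pairs), dtype=object)


def simulate_inter_pairs(config: SimulationConfig, rng) -> tuple:
    """Loop-derived inter-ligation pairs plus uniform background noise."""
    if not config.loops and config.n_noise <= 0:
        raise ChialoopError("need loops or noise to simulate inter pairs")
    c1, p1, s1, c2, p2, s2, labels = [], [], [], [], [], [], []

    if config.n_inter > 0:
        if not config.loops:
            raise ChialoopError("n_inter > 0 but no loops configured")
        inten = np.array([lp.intensity for lp in config.loops], dtype=float)
        probs = inten / inten.sum()
        emitted = 0
        while emitted < config.n_inter:
            li = int(rng.choice(len(config.loops), p=probs))
            lp = config.loops[li]
            sa = "+" if rng.random() < 0.5 else "-"
            sb = "+" if rng.random() < 0.5 else "-"
            ma = _mate_from_site(config, rng, lp.pos_a, sa)
            mb = _mate_from_site(config, rng, lp.pos_b, sb)
            if not (_in_bounds(config, lp.chrom_a, ma) and _in_bounds(config, lp.chrom_b, mb)):
                continue
            c1.append(lp.chrom_a); p1.append(ma); s1.append(sa)
            c2.append(lp.chrom_b); p2.append(mb); s2.append(sb)
            labels.append(f"{LABEL_LOOP}:{li}")
            emitted += 1

    if config.n_noise > 0:
        names = config.genome.names
        lens = np.array([config.genome.length(c) for c in names], dtype=float)
        cprob = lens / lens.sum()
        for _ in range(config.n_noise):
            while True:
                ca = names[int(rng.choice(len(names), p=cprob))]
                cb = names[int(rng.choice(len(names), p=cprob))]
                ma = int(rng.integers(0, config.genome.length(ca)))
                mb = int(rng.integers(0, config.genome.length(cb)))
                if _in_bounds(config, ca, ma) and _in_bounds(config, cb, mb):
                    break
            c1.append(ca); p1.append(ma)
            s1.append("+" if rng.random() < 0.5 else "-")
            c2.append(cb); p2.append(mb)
            s2.append("+" if rng.random() < 0.5 else "-")
            labels.append(LABEL_NOISE)

    pairs = ReadPairSet.from_mates(config.genome, c1, p1, s1, c2, p2, s2)
    return pairs, np.array(labels, dtype=object)


def simulate_dataset(config: SimulationConfig):
    """Full labeled dataset: self + loop + noise pairs, with ground truth."""
    rng = np.random.default_rng(config.seed)
    self_pairs, self_labels = simulate_self_pairs(config, rng)
    if config.n_inter > 0 or config.n_noise > 0:
        inter_pairs, inter_labels = simulate_inter_pairs(config, rng)
        pairs = _concat(self_pairs, inter_pairs)
        labels = np.concatenate([self_labels, inter_labels])
    else:
        pairs, labels = self_pairs, self_labels
    pairs.names = labels.copy()
    truth = SimulationTruth(sites=config.sites, loops=config.loops, labels=labels,
                            lambda_true=config.fragment.mean / 2.0, config=config)
    return pairs, truth


def _concat(a: ReadPairSet, b: ReadPairSet) -> ReadPairSet:
    return ReadPairSet(
        a.genome,
        np.concatenate([a.chrom1, b.chrom1]), np.concatenate([a.pos1, b.pos1]),
        np.concatenate([a.strand1, b.strand1]),
        np.concatenate([a.chrom2, b.chrom2]), np.concatenate([a.pos2, b.pos2]),
        np.concatenate([a.strand2, b.strand2]),
    )


# ----------------------------------------------------------------------
# default scenario used by the test-suite and worked examples
# ----------------------------------------------------------------------

def default_scenario(seed=0, n_self=20_000, n_inter=12_500, n_noise=12_500,
                     n_loops=20, n_extra_anchors=5) -> SimulationConfig:
    """Two 1 Mb chromosomes, 20 planted anchor-distal loops, 50% inter noise.

    Anchors emulate TSSs; each loop connects an anchor to a distal site
    5-300 kb away.  All loop endpoints are also occupancy sites so the
    marginal track covers them.  Layout is drawn deterministically from the
    seed.
    """
    genome = GenomeModel({"chrS1": 1_000_000, "chrS2": 1_000_000})
    rng = np.random.default_rng(seed)
    sites, loops = [], []
    anchors = []
    for li in range(n_loops + n_extra_anchors):
        chrom = "chrS1" if li % 2 == 0 else "chrS2"
        a = int(rng.integers(60_000, 640_000))
        anchors.append((chrom, a))
        sites.append(Site(chrom=chrom, position=a, weight=1.0))
        if li < n_loops:
            d = a + int(rng.integers(5_000, 300_000))
            sites.append(Site(chrom=chrom, position=d, weight=1.0))
            loops.append(Loop(chrom_a=chrom, pos_a=a, chrom_b=chrom, pos_b=d))
    cfg = SimulationConfig(genome=genome, sites=sites, loops=loops,
                           n_self=n_self, n_inter=n_inter, n_noise=n_noise,
                           seed=seed)
    cfg.anchor_points = anchors  # all anchors, looped and not
    return cfg


# ----------------------------------------------------------------------
# emission
# ----------------------------------------------------------------------

def emit(pairs: ReadPairSet, truth: SimulationTruth, outdir):
    """Write BEDPE + truth files; round-trips losslessly through parse_bedpe."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rl = truth.config.read_length
    paths = {
        "bedpe": os.path.join(outdir, "pairs.bedpe"),
        "occupancy": os.path.join(outdir, "true_occupancy.bedgraph"),
        "loops": os.path.join(outdir, "true_loops.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "config": os.path.join(outdir, "sim_config.json"),
    }
    names = pairs.genome.names
    with open(paths["bedpe"], "w") as fh:
        for j in range(len(pairs)):
            rows = []
            for chrom, pos, strand in ((pairs.chrom1[j], pairs.pos1[j], pairs.strand1[j]),
                                       (pairs.chrom2[j], pairs.pos2[j], pairs.strand2[j])):
                if strand == 0:  # +: 5' end is the interval start
                    start, end = int(pos), int(pos) + rl
                else:            # -: 5' end is end - 1
                    start, end = int(pos) - rl + 1, int(pos) + 1
                rows.append((names[chrom], start, end, "+" if strand == 0 else "-"))
            label = truth.labels[j]
            fh.write(f"{rows[0][0]}\t{rows[0][1]}\t{rows[0][2]}"
                     f"\t{rows[1][0]}\t{rows[1][1]}\t{rows[1][2]}"
                     f"\t{label}\t0\t{rows[0][3]}\t{rows[1][3]}\n")
    total_w = sum(s.weight for s in truth.sites)
    with open(paths["occupancy"], "w") as fh:
        for s in sorted(truth.sites, key=lambda s: (pairs.genome.index(s.chrom), s.position)):
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.weight / total_w:.6g}\n")
    with open(paths["loops"], "w") as fh:
        fh.write("chrom_a\tpos_a\tchrom_b\tpos_b\tintensity\n")
        for lp in truth.loops:
            fh.write(f"{lp.chrom_a}\t{lp.pos_a}\t{lp.chrom_b}\t{lp.pos_b}\t{lp.intensity:g}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("index\tlabel\n")
        for j, lab in enumerate(truth.labels):
            fh.write(f"{j}\t{lab}\n")
    cfg = truth.config
    with open(paths["config"], "w") as fh:
        json.dump({
            "chromosomes": cfg.genome.chromosomes,
            "mappable_size": cfg.genome.mappable_size,
            "n_self": cfg.n_self, "n_inter": cfg.n_inter, "n_noise": cfg.n_noise,
            "fragment": asdict(cfg.fragment), "beta_range": list(cfg.beta_range),
            "read_length": cfg.read_length, "seed": cfg.seed,
            "n_sites": len(cfg.sites), "n_loops": len(cfg.loops),
        }, fh, indent=2, sort_keys=True)
    return paths
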