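"""Joint and conditional (anchored) occupancy from inter-ligation pairs.

Each inter-ligation read pair is treated as a noisy sample of two
simultaneously occupied locations.  The likelihood that a mate arose from
occupancy at u is the strand-appropriate 1D marginal of the RSF evaluated
at the mate's offset from u, and the prior over locations is the marginal
occupancy track, with a uniform prior on read alignment.  Summing the
per-pair products over pairs gives an (unnormalized) joint density over
location pairs; one global constant — the total over every pair's full
support — normalizes it, so windowed joint densities and anchored
conditional profiles share a common scale.

The anchored variant evaluates the joint density only on columns fixed at
a set of anchor locations (e.g. annotated TSSs), which is what interaction
calling consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ChialoopError
from .deconvolution import OccupancyTrack, RSFMarginals
from .genome import GenomeModel
from .readpairs import ReadPairSet

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# anchors
# ----------------------------------------------------------------------

@dataclass
class AnchorSet:
    """Ordered, deduplicated point anchors (e.g. transcription start sites)."""

    chroms: list
    positions: np.ndarray
    names: list
    strands: list

    @classmethod
    def build(cls, records, genome: GenomeModel) -> "AnchorSet":
        """records: iterable of (chrom, pos[, name[, strand]])."""
        seen = set()
        rows = []
        for rec in records:
            chrom, pos = rec[0], int(rec[1])
            if chrom not in genome:
                continue
            key = (chrom, pos)
            if key in seen:
                continue
            seen.add(key)
            name = rec[2] if len(rec) > 2 else f"{chrom}:{pos}"
            strand = rec[3] if len(rec) > 3 else "."
            rows.append((genome.index(chrom), pos, chrom, name, strand))
        if not rows:
            raise ChialoopError("empty anchor set")
        rows.sort(key=lambda r: (r[0], r[1]))
        return cls(
            chroms=[r[2] for r in rows],
            positions=np.array([r[1] for r in rows], dtype=np.int64),
            names=[r[3] for r in rows],
            strands=[r[4] for r in rows],
        )

    @classmethod
    def from_bed(cls, path, genome: GenomeModel) -> "AnchorSet":
        """BED with >= 3 columns; the anchor point is the interval midpoint
        (a 1 bp BED record is a point)."""
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ChialoopError(f"{path}: line {lineno}: need >= 3 BED columns")
                start, end = int(fields[1]), int(fields[2])
                pos = (start + end) // 2
                name = fields[3] if len(fields) > 3 else f"{fields[0]}:{pos}"
                strand = fields[5] if len(fields) > 5 else "."
                records.append((fields[0], pos, name, strand))
        return cls.build(records, genome)

    def __len__(self):
        return len(self.positions)


# ----------------------------------------------------------------------
# end likelihood
# ----------------------------------------------------------------------

def end_likelihood(pos, strand, u, marginals: RSFMarginals):
    """Likelihood of a mate at ``pos`` (with strand) given occupancy at u.

    Evaluates the strand-appropriate RSF marginal at offset pos − u;
    exactly 0 outside the RSF support.
    """
    u = np.asarray(u, dtype=float)
    return marginals(strand, np.asarray(pos, dtype=float) - u)


# ----------------------------------------------------------------------
# internal: per-pair support patches
# ----------------------------------------------------------------------

@dataclass
class _Patch:
    chrom: str
    k0: int
    values: np.ndarray  # end-likelihood * occupancy over bins k0..k0+len-1

    @property
    def k1(self):
        return self.k0 + len(self.values) - 1

    @property
    def total(self):
        return float(self.values.sum())


def _pair_patches(pairs: ReadPairSet, occ: OccupancyTrack, marginals: RSFMarginals):
    """For every pair and both ends, the weighted support profile
    A(u)·occ(u) over the occupancy bins within RSF support of the end."""
    b = occ.bin_size
    W = marginals.support
    names = pairs.genome.names
    out1, out2 = [], []
    for which, out in ((1, out1), (2, out2)):
        chroms = pairs.chrom1 if which == 1 else pairs.chrom2
        poss = pairs.pos1 if which == 1 else pairs.pos2
        strands = pairs.strand1 if which == 1 else pairs.strand2
        for j in range(len(pairs)):
            chrom = names[chroms[j]]
            if chrom not in occ.data:
                out.append(None)
                continue
            start, vals = occ.data[chrom]
            pos = float(poss[j])
            k0 = max(0, int((pos - W - start) // b))
            k1 = min(len(vals) - 1, int((pos + W - start) // b))
            if k1 < k0:
                out.append(None)
                continue
            # bins are represented by their start coordinate so that the
            # occupancy grid aligns with the RSF offset grid (b == step)
            centers = start + np.arange(k0, k1 + 1).astype(float) * b
            prof = marginals(int(strands[j]), pos - centers) * vals[k0:k1 + 1]
            if not np.any(prof > 0):
                out.append(None)
                continue
            out.append(_Patch(chrom=chrom, k0=k0, values=prof))
    return out1, out2


def _normalizer(patches1, patches2) -> float:
    z = 0.0
    for p1, p2 in zip(patches1, patches2):
        if p1 is not None and p2 is not None:
            z += p1.total * p2.total
    return z


# ----------------------------------------------------------------------
# windowed joint density
# ----------------------------------------------------------------------

@dataclass
class JointWindow:
    """Dense joint density over (u, v) bins for a pair of windows."""

    chrom_u: str
    chrom_v: str
    u_start_bin: int
    v_start_bin: int
    bin_size: int
    values: np.ndarray


def joint_density(inter: ReadPairSet, occ: OccupancyTrack, marginals: RSFMarginals,
                  window_u, window_v) -> JointWindow:
    """Joint occupancy density on a (u, v) window pair.

    The lower-coordinate mate informs u and the higher-coordinate mate
    informs v; the normalizer is global (all pairs, full support), so
    window totals are comparable across windows and with the anchored
    conditional profiles.
    """
    if len(inter) == 0:
        raise ChialoopError("no inter-ligation pairs")
    b = occ.bin_size
    cu, us, ue = window_u
    cv, vs, ve = window_v
    ku0, ku1 = us // b, -(-ue // b) - 1
    kv0, kv1 = vs // b, -(-ve // b) - 1
    nu, nv = ku1 - ku0 + 1, kv1 - kv0 + 1
    patches1, patches2 = _pair_patches(inter, occ, marginals)
    z = _normalizer(patches1, patches2)
    if z <= 0:
        raise ChialoopError("joint density has no mass (occupancy never overlaps pair support)")
    out = np.zeros((nu, nv))
    for p1, p2 in zip(patches1, patches2):
        if p1 is None or p2 is None:
            continue
        if p1.chrom != cu or p2.chrom != cv:
            continue
        a0, a1 = max(p1.k0, ku0), min(p1.k1, ku1)
        b0, b1 = max(p2.k0, kv0), min(p2.k1, kv1)
        if a1 < a0 or b1 < b0:
            continue
        pu = p1.values[a0 - p1.k0:a1 - p1.k0 + 1]
        pv = p2.values[b0 - p2.k0:b1 - p2.k0 + 1]
        out[a0 - ku0:a1 - ku0 + 1, b0 - kv0:b1 - kv0 + 1] += np.outer(pu, pv)
    return JointWindow(chrom_u=cu, chrom_v=cv, u_start_bin=ku0, v_start_bin=kv0,
                       bin_size=b, values=out / z)


# ----------------------------------------------------------------------
# anchored conditional field
# ----------------------------------------------------------------------

@dataclass
class Contribution:
    """One inter pair's contribution interval to an anchor's profile."""

    pair: int
    chrom: str
    k0: int
    k1: int


@dataclass
class ConditionalJointField:
    """Per-anchor 1D joint-occupancy profiles with masses and support index.

    ``profiles[i]`` maps chromosome -> (k0, values) on the occupancy bin
    grid; ``t[i]`` is the anchor's total conditional mass, ``m[i]`` the
    marginal occupancy at the anchor bin.  ``contributions[i]`` records
    which pairs support which bins, which feeds region support counts.
    """

    anchors: AnchorSet
    bin_size: int
    t: np.ndarray
    m: np.ndarray
    profiles: list
    contributions: list
    normalizer: float
    n_inter: int
    zero_occupancy: np.ndarray = field(default=None)

    def profile_values(self, i, chrom=None):
        """Concatenated (bins, values) arrays for anchor i on one chromosome
        (default: the anchor's own chromosome)."""
        chrom = chrom or self.anchors.chroms[i]
        if chrom not in self.profiles[i]:
            return np.array([], dtype=int), np.array([])
        k0, vals = self.profiles[i][chrom]
        return k0 + np.arange(len(vals)), vals


def conditional_field(inter: ReadPairSet, occ: OccupancyTrack,
                      marginals: RSFMarginals, anchors: AnchorSet) -> ConditionalJointField:
    """Anchored joint-occupancy estimation.

    For each anchor v, every inter pair with one mate inside RSF support of
    v contributes its *other* mate's weighted support profile, scaled by the
    anchor-side likelihood and occupancy.  Both orientations are covered:
    the anchor may be matched by the lower- or the higher-coordinate mate.
    """
    if len(anchors) == 0:
        raise ChialoopError("empty anchor set")
    b = occ.bin_size
    W = marginals.support
    names = inter.genome.names
    patches1, patches2 = _pair_patches(inter, occ, marginals)
    z = _normalizer(patches1, patches2)

    n_anchor = len(anchors)
    t = np.zeros(n_anchor)
    m = np.zeros(n_anchor)
    profiles = [dict() for _ in range(n_anchor)]
    contributions = [[] for _ in range(n_anchor)]
    zero_occ = np.zeros(n_anchor, dtype=bool)

    if z <= 0:
        log.warning("conditional field: no pair support overlaps occupancy; empty field")
        for i in range(n_anchor):
            m[i] = occ.value_at(anchors.chroms[i], int(anchors.positions[i]))
        return ConditionalJointField(anchors=anchors, bin_size=b, t=t, m=m,
                                     profiles=profiles, contributions=contributions,
                                     normalizer=0.0, n_inter=len(inter),
                                     zero_occupancy=zero_occ)

    # sorted per-chromosome end indexes for fast anchor matching
    by_end = {}
    for which, (chroms, poss) in enumerate(((inter.chrom1, inter.pos1),
                                            (inter.chrom2, inter.pos2)), start=1):
        idx = {}
        for ci in np.unique(chroms):
            sel = np.nonzero(chroms == ci)[0]
            order = np.argsort(poss[sel])
            idx[names[ci]] = (poss[sel][order], sel[order])
        by_end[which] = idx

    any_hit = False
    for i in range(n_anchor):
        chrom = anchors.chroms[i]
        v = int(anchors.positions[i])
        if chrom not in occ.data:
            zero_occ[i] = True
            continue
        start, vals = occ.data[chrom]
        kv = (v - start) // b
        u_center = start + float(kv * b)
        occ_v = occ.value_at(chrom, v)
        m[i] = occ_v
        if occ_v <= 0:
            zero_occ[i] = True
        raw = []  # (coef, patch, pair_index)
        for which, anchor_patches, distal_patches in (
                (2, patches2, patches1), (1, patches1, patches2)):
            index = by_end[which].get(chrom)
            if index is None:
                continue
            poss, pair_idx = index
            lo = np.searchsorted(poss, u_center - W - b)
            hi = np.searchsorted(poss, u_center + W + b)
            for j in pair_idx[lo:hi]:
                ap = anchor_patches[j]
                dp = distal_patches[j]
                if ap is None or dp is None:
                    continue
                # anchor-side likelihood * occupancy at the anchor bin
                k = kv - ap.k0
                if not 0 <= k < len(ap.values):
                    continue
                coef = float(ap.values[k]) / z
                if coef <= 0:
                    continue
                raw.append((coef, dp, int(j)))
        if not raw:
            continue
        any_hit = True
        # merge contributions into dense per-chromosome spans
        by_chrom = {}
        for coef, dp, j in raw:
            by_chrom.setdefault(dp.chrom, []).append((coef, dp, j))
            contributions[i].append(Contribution(pair=j, chrom=dp.chrom,
                                                 k0=dp.k0, k1=dp.k1))
        for c, items in by_chrom.items():
            k0 = min(dp.k0 for _, dp, _ in items)
            k1 = max(dp.k1 for _, dp, _ in items)
            acc = np.zeros(k1 - k0 + 1)
            for coef, dp, _ in items:
                acc[dp.k0 - k0:dp.k1 - k0 + 1] += coef * dp.values
            profiles[i][c] = (k0, acc)
        t[i] = float(sum(vals.sum() for _, vals in profiles[i].values()))

    if not any_hit:
        log.warning("conditional field: no inter pair within RSF support of any anchor")
    return ConditionalJointField(anchors=anchors, bin_size=b, t=t, m=m,
                                 profiles=profiles, contributions=contributions,
                                 normalizer=z, n_inter=len(inter),
                                 zero_occupancy=zero_occ)
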