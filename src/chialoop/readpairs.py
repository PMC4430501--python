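"""Read-pair containers: parsing, mate ordering, orientation, classification.

A ChIA-PET read pair is stored as the 5' alignment locations of its two
mates, ordered so that the lower-coordinate mate comes first (for
intra-chromosomal pairs) or the mate on the earlier chromosome in genome
order comes first.  The *orientation* is the pair of strand labels of the
ordered mates; self-ligation products always read ``-+`` because the two
tags point outward from within a single sonication fragment, while
inter-ligation products occur in all four orientations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ChialoopError, ParseError
from .genome import GenomeModel

log = logging.getLogger(__name__)

STRAND_CHARS = ("+", "-")
ORIENTATIONS = ("++", "+-", "-+", "--")


@dataclass(frozen=True)
class ReadPair:
    """A single coordinate-ordered read pair (5' mate locations)."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str

    @property
    def orientation(self) -> str:
        return self.strand1 + self.strand2

    @property
    def intra(self) -> bool:
        return self.chrom1 == self.chrom2


def pair_distance(pair: ReadPair):
    """Distance between the aligned mate locations; None across chromosomes."""
    if pair.chrom1 != pair.chrom2:
        return None
    return abs(pair.pos2 - pair.pos1)


class ReadPairSet:
    """Columnar set of ordered read pairs sharing one genome model.

    Strands are encoded 0 for ``+`` and 1 for ``-``; chromosomes as indices
    into the genome's chromosome order.  Row order is preserved from input,
    which keeps external per-pair annotations (e.g. simulation labels)
    aligned by index.
    """

    def __init__(self, genome: GenomeModel, chrom1, pos1, strand1,
                 chrom2, pos2, strand2, names=None):
        self.genome = genome
        self.chrom1 = np.asarray(chrom1, dtype=np.int32)
        self.pos1 = np.asarray(pos1, dtype=np.int64)
        self.strand1 = np.asarray(strand1, dtype=np.int8)
        self.chrom2 = np.asarray(chrom2, dtype=np.int32)
        self.pos2 = np.asarray(pos2, dtype=np.int64)
        self.strand2 = np.asarray(strand2, dtype=np.int8)
        self.names = None if names is None else np.asarray(names, dtype=object)
        n = len(self.pos1)
        for arr in (self.chrom1, self.strand1, self.chrom2, self.pos2, self.strand2):
            if len(arr) != n:
                raise ChialoopError("read pair columns have mismatched lengths")

    # -- construction --------------------------------------------------
    @classmethod
    def from_mates(cls, genome, chrom1, pos1, strand1, chrom2, pos2, strand2,
                   names=None):
        """Build a set from unordered mates, swapping mates where needed.

        Ordering key is (chromosome index in genome order, position); ties
        keep the input mate order.
        """
        c1 = np.asarray([genome.index(c) for c in chrom1], dtype=np.int32)
        c2 = np.asarray([genome.index(c) for c in chrom2], dtype=np.int32)
        p1 = np.asarray(pos1, dtype=np.int64)
        p2 = np.asarray(pos2, dtype=np.int64)
        s1 = _encode_strands(strand1)
        s2 = _encode_strands(strand2)
        swap = (c1 > c2) | ((c1 == c2) & (p1 > p2))
        out = cls(
            genome,
            np.where(swap, c2, c1), np.where(swap, p2, p1), np.where(swap, s2, s1),
            np.where(swap, c1, c2), np.where(swap, p1, p2), np.where(swap, s1, s2),
            names=names,
        )
        return out

    def subset(self, mask_or_index) -> "ReadPairSet":
        m = mask_or_index
        return ReadPairSet(
            self.genome, self.chrom1[m], self.pos1[m], self.strand1[m],
            self.chrom2[m], self.pos2[m], self.strand2[m],
            names=None if self.names is None else self.names[m],
        )

    # -- container protocol --------------------------------------------
    def __len__(self):
        return len(self.pos1)

    def __getitem__(self, i) -> ReadPair:
        names = self.genome.names
        return ReadPair(
            names[self.chrom1[i]], int(self.pos1[i]), STRAND_CHARS[self.strand1[i]],
            names[self.chrom2[i]], int(self.pos2[i]), STRAND_CHARS[self.strand2[i]],
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    # -- derived columns -----------------------------------------------
    @property
    def intra(self) -> np.ndarray:
        return self.chrom1 == self.chrom2

    @property
    def orientation_code(self) -> np.ndarray:
        """0=++, 1=+-, 2=-+, 3=--."""
        return (2 * self.strand1 + self.strand2).astype(np.int8)

    @property
    def counts(self) -> dict:
        code = self.orientation_code
        out = {o: int(np.sum(code == k)) for k, o in enumerate(ORIENTATIONS)}
        out["N"] = len(self)
        return out

    def distances(self) -> np.ndarray:
        """|pos2 - pos1| as float, NaN for inter-chromosomal pairs."""
        d = (self.pos2 - self.pos1).astype(float)
        d[~self.intra] = np.nan
        return np.abs(d)

    def midpoints(self) -> np.ndarray:
        return (self.pos1 + self.pos2) / 2.0


def _encode_strands(strands) -> np.ndarray:
    out = np.empty(len(strands), dtype=np.int8)
    for i, s in enumerate(strands):
        if s == "+":
            out[i] = 0
        elif s == "-":
            out[i] = 1
        else:
            raise ChialoopError(f"bad strand {s!r}")
    return out


def split_by_orientation(pairs: ReadPairSet):
    """Partition into (intra-chromosomal -+ pairs, everything else).

    Only intra-chromosomal ``-+`` pairs can be self-ligation products (a
    single fragment cannot span chromosomes), so inter-chromosomal ``-+``
    pairs are grouped with the unambiguous inter-ligation orientations.
    """
    mp = (pairs.orientation_code == 2) & pairs.intra
    return pairs.subset(mp), pairs.subset(~mp)


def parse_bedpe(path, genome: GenomeModel, deduplicate: bool = False) -> ReadPairSet:
    """Parse a 10-column BEDPE file into an ordered :class:`ReadPairSet`.

    A mate's aligned location is taken as its 5' end: interval start on the
    ``+`` strand, interval end − 1 on the ``-`` strand.  Records on
    chromosomes absent from the genome model are dropped (count logged and
    stored on the returned set as ``dropped_unknown_chrom``).
    """
    c1, p1, s1, c2, p2, s2, names = [], [], [], [], [], [], []
    dropped = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected 10 BEDPE columns, got {len(fields)}"
                )
            ca, cb = fields[0], fields[3]
            try:
                sa, ea = int(fields[1]), int(fields[2])
                sb, eb = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            ta, tb = fields[8], fields[9]
            if ta not in STRAND_CHARS or tb not in STRAND_CHARS:
                raise ParseError(f"{path}: line {lineno}: bad strand {ta!r}/{tb!r}")
            if ea <= sa or eb <= sb:
                raise ParseError(f"{path}: line {lineno}: empty interval")
            if ca not in genome or cb not in genome:
                dropped += 1
                continue
            c1.append(ca)
            p1.append(sa if ta == "+" else ea - 1)
            s1.append(ta)
            c2.append(cb)
            p2.append(sb if tb == "+" else eb - 1)
            s2.append(tb)
            names.append(fields[6])
    if n_lines == 0:
        raise ParseError(f"{path}: empty BEDPE file")
    if dropped:
        log.info("parse_bedpe: dropped %d records on unknown chromosomes", dropped)
    pairs = ReadPairSet.from_mates(genome, c1, p1, s1, c2, p2, s2, names=np.array(names, dtype=object))
    if deduplicate and len(pairs):
        key = np.stack([pairs.chrom1, pairs.pos1, pairs.strand1,
                        pairs.chrom2, pairs.pos2, pairs.strand2]).T
        _, keep = np.unique(key, axis=0, return_index=True)
        pairs = pairs.subset(np.sort(keep))
    pairs.dropped_unknown_chrom = dropped
    return pairs
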