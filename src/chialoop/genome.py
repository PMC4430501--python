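"""Genome model: ordered chromosome sizes plus the mappable-genome size.

The mappable size ``M`` is the effective number of base pairs a uniformly
distributed read could align to; it is the denominator of the uniform
background null used by the significance tests.  When it is not known it
defaults to a fixed fraction of the assembly length.
"""

from __future__ import annotations

from .errors import ChialoopError, ParseError

DEFAULT_MAPPABLE_FRACTION = 0.8


class GenomeModel:
    """Ordered mapping of chromosome name -> length, plus mappable size M."""

    def __init__(self, chromosomes, mappable_size=None):
        chroms = dict(chromosomes)
        if not chroms:
            raise ChialoopError("genome model needs at least one chromosome")
        for name, length in chroms.items():
            if int(length) <= 0:
                raise ChialoopError(f"chromosome {name!r} has non-positive length {length}")
        self.chromosomes = {name: int(length) for name, length in chroms.items()}
        total = sum(self.chromosomes.values())
        if mappable_size is None:
            mappable_size = int(round(total * DEFAULT_MAPPABLE_FRACTION))
        mappable_size = int(mappable_size)
        if not 0 < mappable_size <= total:
            raise ChialoopError(
                f"mappable size {mappable_size} outside (0, {total}]"
            )
        self.mappable_size = mappable_size
        self._index = {name: i for i, name in enumerate(self.chromosomes)}

    # -- basic queries -------------------------------------------------
    @property
    def names(self):
        return list(self.chromosomes)

    @property
    def total_size(self):
        return sum(self.chromosomes.values())

    def __contains__(self, name):
        return name in self.chromosomes

    def length(self, name):
        return self.chromosomes[name]

    def index(self, name):
        """Position of a chromosome in genome order."""
        return self._index[name]

    def __repr__(self):
        return (
            f"GenomeModel({len(self.chromosomes)} chromosomes, "
            f"total={self.total_size}, mappable={self.mappable_size})"
        )

    # -- IO ------------------------------------------------------------
    @classmethod
    def from_chrom_sizes(cls, path, mappable_size=None):
        """Read a two-column ``name<TAB>length`` chrom.sizes file."""
        chroms = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{path}: line {lineno}: expected 'name<TAB>length'")
                try:
                    length = int(fields[1])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad length {fields[1]!r}") from exc
                chroms[fields[0]] = length
        if not chroms:
            raise ParseError(f"{path}: empty chrom.sizes file")
        return cls(chroms, mappable_size=mappable_size)
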