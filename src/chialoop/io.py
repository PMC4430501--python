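"""Writers for the standard text formats the tool emits.

bedGraph for 1D tracks, gzipped (or plain) tabular dumps for 2D objects,
BEDPE + TSV for interaction calls.  All writers take open paths and are
plain functions so the CLI stays thin.
"""

from __future__ import annotations

import gzip
import json

import numpy as np

from .deconvolution import OccupancyTrack, ReadSpreadFunction, RSFMarginals


def _opener(path):
    return gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")


def write_bedgraph(track: OccupancyTrack, path, skip_zero=True):
    """Occupancy track as bedGraph (merging equal-valued adjacent bins is
    left to downstream tools; bins are written as-is)."""
    b = track.bin_size
    with _opener(path) as fh:
        for chrom, (start, vals) in track.data.items():
            for k, v in enumerate(vals):
                if skip_zero and v == 0.0:
                    continue
                s = start + k * b
                fh.write(f"{chrom}\t{s}\t{s + b}\t{v:.6g}\n")


def read_bedgraph(path, genome, bin_size) -> OccupancyTrack:
    data = {c: (0, np.zeros(-(-genome.length(c) // bin_size))) for c in genome.names}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, _e, v = line.split("\t")[:4]
            if chrom in data:
                data[chrom][1][int(s) // bin_size] += float(v)
    return OccupancyTrack(bin_size, data, normalize=False)


def write_rsf(rsf: ReadSpreadFunction, path):
    """RSF as a three-column (dx, dy, value) table; zero cells omitted."""
    with _opener(path) as fh:
        fh.write("dx\tdy\tvalue\n")
        for i, dx in enumerate(rsf.offsets):
            row = rsf.values[i]
            for j in np.nonzero(row)[0]:
                fh.write(f"{dx:g}\t{rsf.offsets[j]:g}\t{row[j]:.8g}\n")


def write_marginals(marginals: RSFMarginals, path):
    with _opener(path) as fh:
        fh.write("offset\tminus\tplus\n")
        for o, mi, pl in zip(marginals.offsets, marginals.minus, marginals.plus):
            fh.write(f"{o:g}\t{mi:.8g}\t{pl:.8g}\n")


def write_distance_density(density, path):
    """1D distance density as bedGraph over the distance axis (diagnostic)."""
    with _opener(path) as fh:
        grid = density.grid
        for k in range(len(grid) - 1):
            fh.write(f"distance\t{int(grid[k])}\t{int(grid[k + 1])}\t{density.values[k]:.8g}\n")


def write_calls(calls, path_bedpe, path_tsv, c=None):
    """Interaction calls as anchor<->region BEDPE plus a detail TSV."""
    with _opener(path_bedpe) as fh:
        for call in calls:
            r = call.region
            fh.write(f"{call.anchor_chrom}\t{call.anchor_pos}\t{call.anchor_pos + 1}"
                     f"\t{r.chrom}\t{r.start}\t{r.end}"
                     f"\t{call.anchor_name}\t{min(1000, int(-10 * np.log10(max(call.pvalue, 1e-300))))}"
                     f"\t.\t.\n")
    with _opener(path_tsv) as fh:
        fh.write("anchor\tanchor_chrom\tanchor_pos\tregion_chrom\tregion_start"
                 "\tregion_end\teloc\tsupport\tpvalue\tt\ttau\tc\n")
        for call in calls:
            r = call.region
            fh.write(f"{call.anchor_name}\t{call.anchor_chrom}\t{call.anchor_pos}"
                     f"\t{r.chrom}\t{r.start}\t{r.end}\t{call.eloc}\t{call.support}"
                     f"\t{call.pvalue:.6g}\t{call.t:.6g}\t{call.tau:.6g}"
                     f"\t{'' if c is None else format(c, '.6g')}\n")


def write_field_summary(fieldest, path):
    """Per-anchor summary TSV: conditional mass, marginal mass, support."""
    with _opener(path) as fh:
        fh.write("anchor\tchrom\tpos\tt\tm\tn_supporting_pairs\tzero_occupancy\n")
        for i in range(len(fieldest.anchors)):
            n_pairs = len({c.pair for c in fieldest.contributions[i]})
            fh.write(f"{fieldest.anchors.names[i]}\t{fieldest.anchors.chroms[i]}"
                     f"\t{fieldest.anchors.positions[i]}\t{fieldest.t[i]:.6g}"
                     f"\t{fieldest.m[i]:.6g}\t{n_pairs}"
                     f"\t{int(bool(fieldest.zero_occupancy[i]))}\n")


def write_report(report: dict, path):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
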