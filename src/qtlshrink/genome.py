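"""Genetic map: chromosomes, marker positions and the Haldane map function.

Positions are measured in centiMorgans (cM) from the left end of each
chromosome.  A single *global* coordinate (cumulative cM over the
concatenated chromosomes) is used internally by the sampler and the
post-processing profiles; :class:`GenomeMap` converts between the two.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeMap", "haldane", "evenly_spaced_map"]


def haldane(d_cm):
    """Recombination fraction for a map distance ``d_cm`` in cM.

    Haldane's map function, r = (1 - exp(-2d))/2 with d in Morgans,
    assuming no crossover interference.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass
class GenomeMap:
    """Marker map over one or more chromosomes.

    Parameters
    ----------
    lengths : list of float
        Chromosome lengths in cM.
    marker_pos : list of ndarray
        Per chromosome, strictly increasing marker positions in cM.
    n_alleles : list of ndarray
        Per chromosome, number of alleles per marker (each >= 2).
    """

    lengths: list
    marker_pos: list
    n_alleles: list
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not (len(self.lengths) == len(self.marker_pos) == len(self.n_alleles)):
            raise ValueError("lengths, marker_pos and n_alleles must align")
        self.lengths = [float(l) for l in self.lengths]
        self.marker_pos = [np.asarray(p, dtype=float) for p in self.marker_pos]
        self.n_alleles = [np.asarray(a, dtype=int) for a in self.n_alleles]
        for L, pos, na in zip(self.lengths, self.marker_pos, self.n_alleles):
            if L <= 0:
                raise ValueError("chromosome length must be positive")
            if len(pos) != len(na):
                raise ValueError("marker positions and allele counts must align")
            if len(pos) and (np.any(np.diff(pos) <= 0)):
                raise ValueError("marker positions must be strictly increasing")
            if len(pos) and (pos[0] < 0 or pos[-1] > L):
                raise ValueError("marker positions must lie within the chromosome")
            if np.any(na < 2):
                raise ValueError("markers need at least 2 alleles")
        self._offsets = np.concatenate([[0.0], np.cumsum(self.lengths)])

    # ---- coordinates -------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.marker_pos))

    @property
    def total_length(self) -> float:
        return float(self._offsets[-1])

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global cM coordinate of each chromosome's left end."""
        return self._offsets[:-1]

    def to_global(self, chrom: int, pos_cm) -> float:
        return self._offsets[chrom] + np.asarray(pos_cm, dtype=float)

    def to_local(self, gpos):
        """Map global cM position(s) to (chromosome index, local cM)."""
        g = np.asarray(gpos, dtype=float)
        c = np.clip(np.searchsorted(self._offsets, g, side="right") - 1, 0,
                    self.n_chromosomes - 1)
        return c, g - self._offsets[c]

    def to_local_scalar(self, gpos: float):
        """Scalar fast path of :meth:`to_local` (no array overhead)."""
        c = bisect.bisect_right(self._offsets, gpos) - 1
        if c < 0:
            c = 0
        elif c >= self.n_chromosomes:
            c = self.n_chromosomes - 1
        return c, gpos - self._offsets[c]

    def chrom_of(self, gpos) -> int:
        c, _ = self.to_local(gpos)
        return int(c)

    def marker_global_pos(self) -> np.ndarray:
        return np.concatenate([self._offsets[c] + self.marker_pos[c]
                               for c in range(self.n_chromosomes)])

    def marker_slices(self):
        """Per chromosome, slice into the global marker index."""
        out, start = [], 0
        for p in self.marker_pos:
            out.append(slice(start, start + len(p)))
            start += len(p)
        return out


def evenly_spaced_map(length_cm: float, n_markers: int, n_alleles: int = 6,
                      n_chromosomes: int = 1) -> GenomeMap:
    """A genome of identical chromosomes with evenly spaced markers.

    Markers sit at both chromosome ends, e.g. ``length_cm=100, n_markers=11``
    gives a 10-cM grid.
    """
    pos = np.linspace(0.0, length_cm, n_markers)
    return GenomeMap(
        lengths=[length_cm] * n_chromosomes,
        marker_pos=[pos.copy() for _ in range(n_chromosomes)],
        n_alleles=[np.full(n_markers, n_alleles) for _ in range(n_chromosomes)],
    )
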