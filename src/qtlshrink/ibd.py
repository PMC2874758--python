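"""Identity-by-descent inference for full-sib families.

At any chromosomal position the expected pairwise IBD sharing among the
offspring of a full-sib family is computed by conditional expectation given
the marker data of the family, marginalizing over the unknown linkage phases
of the parents:

1. every offspring allele is attributed to a parent (Mendelian attribution);
   a marker is *informative* for an offspring/parent pair when the
   attribution is unambiguous and the parent is heterozygous there;
2. for each parent, phase configurations of the heterozygous markers in a
   window around the evaluation position are enumerated and weighted by the
   probability of the observed offspring inheritance pattern under Haldane
   recombination;
3. per phase, the probability that an offspring inherited a given parental
   haplotype at the position follows from crossover logic on the nearest
   informative flanking markers; pairwise sharing through that parent is
   p_i p_k + (1-p_i)(1-p_k), averaged over phase weights;
4. the IBD proportion is the average of the paternal and the maternal
   sharing; diagonal entries are 1 (non-inbred individuals).

The window is capped at the two flanking markers plus one more on each side;
with multiallelic markers at ~10 cM spacing the flanking markers almost
always resolve phase within a family, so the truncation loses essentially
nothing (the Monte-Carlo gene-dropping oracle in the test-suite bounds the
error).  IBD is on the [0, 1] scale — the expected *proportion* of alleles
shared IBD — so the QTL variance component is the full additive variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse

from .genome import GenomeMap, haldane
from ._kernels import ibd_at_kernel

__all__ = [
    "MendelianError", "IbdEngine", "additive_relationship",
    "infer_phase_weights", "transmission_prob", "ibd_block_at",
]


class MendelianError(ValueError):
    """An offspring allele cannot be attributed to either parent."""

    def __init__(self, family, marker, genotype=None):
        self.family = family
        self.marker = marker
        msg = (f"Mendelian inconsistency in family {family} at marker {marker}")
        if genotype is not None:
            msg += f" (offspring genotype {tuple(genotype)})"
        super().__init__(msg)


# ----------------------------------------------------------------------
# allele attribution
# ----------------------------------------------------------------------
def attribute_alleles(sire, dam, offspring, family_label=0):
    """Attribute offspring alleles to parents for one family.

    Returns ``(info, slot)`` of shape (s, M, 2): for each offspring, marker
    and parent (0 = sire, 1 = dam), whether the transmitted *genotype slot*
    of that parent is determined, and which slot (0 or 1) it is.  A marker is
    uninformative when the parent is homozygous or when both attribution
    orders of a heterozygous offspring genotype are Mendelian-consistent.
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    off = np.asarray(offspring)
    o1, o2 = off[..., 0], off[..., 1]
    in_s = lambda a: (a == sire[None, :, 0]) | (a == sire[None, :, 1])
    in_d = lambda a: (a == dam[None, :, 0]) | (a == dam[None, :, 1])
    c1 = in_s(o1) & in_d(o2)          # o1 paternal, o2 maternal
    c2 = in_s(o2) & in_d(o1)
    bad = ~(c1 | c2)
    if bad.any():
        oi, mi = np.argwhere(bad)[0]
        raise MendelianError(family_label, int(mi), off[oi, mi])
    amb = c1 & c2 & (o1 != o2)
    det = ~amb
    pat = np.where(c1, o1, o2)
    mat = np.where(c1, o2, o1)
    sire_het = sire[:, 0] != sire[:, 1]
    dam_het = dam[:, 0] != dam[:, 1]
    info = np.empty(off.shape[:2] + (2,), dtype=bool)
    slot = np.zeros(off.shape[:2] + (2,), dtype=np.int8)
    info[..., 0] = det & sire_het[None, :]
    info[..., 1] = det & dam_het[None, :]
    slot[..., 0] = (pat != sire[None, :, 0])
    slot[..., 1] = (mat != dam[None, :, 0])
    return info, slot


# ----------------------------------------------------------------------
# reference (small-scale) phase and transmission computations
# ----------------------------------------------------------------------
def infer_phase_weights(sire, dam, offspring, positions, parent=0):
    """Posterior weights over a parent's phase configurations.

    Enumerates all phase classes of the parent's heterozygous markers on one
    chromosome (global haplotype flip is unidentifiable, so configurations
    are canonicalized by fixing the first heterozygous marker) and weights
    each by the probability of the family's observed offspring inheritance
    pattern under Haldane recombination.

    Returns ``(het_markers, phases, weights)``: the heterozygous marker
    indices, a list of 0/1 tuples over them (phase bit b flips which
    haplotype carries slot 0 of marker ``het_markers[b]``), and normalized
    weights.  Exponential in the number of heterozygous markers — intended
    for small inputs and as a reference for the windowed engine.
    """
    positions = np.asarray(positions, dtype=float)
    info, slot = attribute_alleles(sire, dam, offspring, 0)
    gt = np.asarray(sire if parent == 0 else dam)
    het = [m for m in range(gt.shape[0]) if gt[m, 0] != gt[m, 1]]
    if not het:
        return [], [()], np.array([1.0])
    nfree = len(het) - 1
    phases = []
    logw = []
    s = np.asarray(offspring).shape[0]
    for code in range(1 << nfree):
        bits = tuple([0] + [(code >> b) & 1 for b in range(nfree)])
        lw = 0.0
        for o in range(s):
            im = [m for m in het if info[o, m, parent]]
            for mprev, mnext in zip(im[:-1], im[1:]):
                z1 = slot[o, mprev, parent] ^ bits[het.index(mprev)]
                z2 = slot[o, mnext, parent] ^ bits[het.index(mnext)]
                r = haldane(positions[mnext] - positions[mprev])
                lw += np.log1p(-r) if z1 == z2 else np.log(r)
        phases.append(bits)
        logw.append(lw)
    logw = np.asarray(logw)
    w = np.exp(logw - logw.max())
    return het, phases, w / w.sum()


def transmission_prob(sire, dam, offspring, positions, lam, offspring_index,
                      parent=0, phase=None):
    """P(offspring inherited the parent's haplotype-0 allele at ``lam``).

    Haplotype 0 is defined, per phase configuration, as the haplotype
    carrying genotype slot 0 at the first heterozygous marker.  Computed per
    phase by crossover logic on the nearest informative flanking markers and
    averaged over the phase weights (or evaluated at a supplied ``phase``).
    """
    positions = np.asarray(positions, dtype=float)
    info, slot = attribute_alleles(sire, dam, offspring, 0)
    het, phases, weights = infer_phase_weights(sire, dam, offspring,
                                               positions, parent)
    if phase is not None:
        phases, weights = [tuple(phase)], np.array([1.0])
    o = offspring_index
    im = np.array([m for m in range(positions.size) if info[o, m, parent]],
                  dtype=int)
    p = 0.0
    for bits, w in zip(phases, weights):
        left = im[positions[im] <= lam]
        right = im[positions[im] > lam]
        pl = pr = None
        if left.size:
            m = left[np.argmax(positions[left])]
            z = slot[o, m, parent] ^ bits[het.index(m)]
            r = float(haldane(lam - positions[m]))
            pl = (1.0 - r) if z == 0 else r
        if right.size:
            m = right[np.argmin(positions[right])]
            z = slot[o, m, parent] ^ bits[het.index(m)]
            r = float(haldane(positions[m] - lam))
            pr = (1.0 - r) if z == 0 else r
        if pl is not None and pr is not None:
            p += w * (pl * pr) / (pl * pr + (1.0 - pl) * (1.0 - pr))
        elif pl is not None:
            p += w * pl
        elif pr is not None:
            p += w * pr
        else:
            p += w * 0.5
    return float(p)


# ----------------------------------------------------------------------
# fast engine
# ----------------------------------------------------------------------
@dataclass
class _ChromTables:
    """Segment-major lookup tables for one chromosome (see _kernels)."""

    mpos: np.ndarray
    wn: np.ndarray
    wm: np.ndarray
    ph_n: np.ndarray
    ph_w: np.ndarray
    ph_bits: np.ndarray
    bitL: np.ndarray
    wslL: np.ndarray
    slotL: np.ndarray
    bitR: np.ndarray
    wslR: np.ndarray
    slotR: np.ndarray


class IbdEngine:
    """Precomputed conditional-expectation IBD for a whole dataset.

    Builds, per family, parent and marker interval, the phase weights and
    nearest-informative-marker tables, after which
    :meth:`blocks_at` evaluates all family IBD blocks at any position in
    ~O(total offspring) time.
    """

    def __init__(self, dataset, phase_prune: float = 1e-4):
        self.dataset = dataset
        self.genome: GenomeMap = dataset.genome
        self.sizes = dataset.family_sizes
        self.smax = int(self.sizes.max())
        self.block_offsets = np.concatenate(
            [[0], np.cumsum(self.sizes.astype(np.int64) ** 2)])
        self.n_block = int(self.block_offsets[-1])
        self.phase_prune = phase_prune
        self._attr = []
        for fi, fam in enumerate(dataset.families):
            self._attr.append(attribute_alleles(fam.sire, fam.dam,
                                                fam.offspring, fi))
        self._tables = [self._build_chrom(c)
                        for c in range(self.genome.n_chromosomes)]

    # -- construction ---------------------------------------------------
    def _build_chrom(self, c: int) -> _ChromTables:
        genome = self.genome
        sl = genome.marker_slices()[c]
        mpos = np.ascontiguousarray(genome.marker_pos[c])
        Mc = len(mpos)
        S = Mc + 1
        F = len(self.dataset.families)
        smax = self.smax

        # pad attribution to (F, 2, smax, Mc)
        info = np.zeros((F, 2, smax, Mc), dtype=np.uint8)
        slot = np.zeros((F, 2, smax, Mc), dtype=np.uint8)
        het = np.zeros((F, 2, Mc), dtype=np.uint8)
        for f, fam in enumerate(self.dataset.families):
            ai, asl = self._attr[f]
            s = fam.n_offspring
            for par in range(2):
                info[f, par, :s, :] = ai[:, sl, par]
                slot[f, par, :s, :] = asl[:, sl, par]
            het[f, 0] = fam.sire[sl, 0] != fam.sire[sl, 1]
            het[f, 1] = fam.dam[sl, 0] != fam.dam[sl, 1]

        wn = np.zeros(S, dtype=np.int64)
        wm = np.zeros((S, 4), dtype=np.int64)
        ph_n = np.zeros((S, F, 2), dtype=np.int64)
        ph_w = np.zeros((S, F, 2, 8))
        ph_bits = np.zeros((S, F, 2, 8), dtype=np.uint16)
        bitL = np.full((S, F, 2, smax), -1, dtype=np.int8)
        wslL = np.zeros((S, F, 2, smax), dtype=np.int8)
        slotL = np.zeros((S, F, 2, smax), dtype=np.uint8)
        bitR = np.full((S, F, 2, smax), -1, dtype=np.int8)
        wslR = np.zeros((S, F, 2, smax), dtype=np.int8)
        slotR = np.zeros((S, F, 2, smax), dtype=np.uint8)
        from ._kernels import ibd_build_tables
        ibd_build_tables(mpos, self.sizes, info, slot, het,
                         self.phase_prune, wn, wm, ph_n, ph_w, ph_bits,
                         bitL, wslL, slotL, bitR, wslR, slotR)
        return _ChromTables(mpos=mpos, wn=wn, wm=wm, ph_n=ph_n, ph_w=ph_w,
                            ph_bits=ph_bits, bitL=bitL, wslL=wslL,
                            slotL=slotL, bitR=bitR, wslR=wslR, slotR=slotR)

    # -- evaluation -----------------------------------------------------
    def blocks_at(self, gpos: float, out: np.ndarray = None) -> np.ndarray:
        """Flat concatenated per-family IBD blocks at a global position."""
        c, loc = self.genome.to_local_scalar(float(gpos))
        t = self._tables[c]
        seg = int(np.searchsorted(t.mpos, loc, side="left"))
        # a position exactly on the first marker belongs to the first
        # marker interval (gets both flanks in its window)
        if seg == 0 and len(t.mpos) >= 2 and loc == t.mpos[0]:
            seg = 1
        if out is None:
            out = np.empty(self.n_block)
        ibd_at_kernel(float(loc), self.sizes, self.block_offsets,
                      t.mpos, t.wn[seg], t.wm[seg],
                      t.ph_n[seg], t.ph_w[seg], t.ph_bits[seg],
                      t.bitL[seg], t.wslL[seg], t.slotL[seg],
                      t.bitR[seg], t.wslR[seg], t.slotR[seg], out)
        return out

    def block_matrix(self, family_index: int, gpos: float) -> np.ndarray:
        """Dense IBD matrix for one family at a global position."""
        flat = self.blocks_at(gpos)
        s = int(self.sizes[family_index])
        o = int(self.block_offsets[family_index])
        return flat[o:o + s * s].reshape(s, s).copy()


def ibd_block_at(dataset, family_index: int, chrom: int, pos_cm: float,
                 engine: IbdEngine = None) -> np.ndarray:
    """Expected IBD matrix of one family's offspring at (chrom, pos_cm)."""
    if engine is None:
        engine = IbdEngine(dataset)
    return engine.block_matrix(family_index,
                               engine.genome.to_global(chrom, pos_cm))


def additive_relationship(family_sizes) -> scipy.sparse.csr_matrix:
    """Block-diagonal additive relationship matrix for full-sib families.

    1 on the diagonal, 0.5 between full sibs, 0 between families.
    """
    blocks = [np.full((s, s), 0.5) + 0.5 * np.eye(s)
              for s in np.asarray(family_sizes, dtype=int)]
    return scipy.sparse.block_diag(blocks, format="csr")
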