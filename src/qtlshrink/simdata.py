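"""Gene-dropping simulator for outbred full-sib QTL mapping experiments.

Founders are drawn from an outbred population in Hardy-Weinberg and linkage
equilibrium: marker alleles are sampled uniformly and independently across
loci, and every founder carries two *unique* alleles at each QTL (the
infinite-alleles model).  QTL allele effects are i.i.d. N(0, sigma2_q / 2),
so a founder's genotypic value at a QTL (the sum of its two allele effects)
has variance sigma2_q.  Offspring genotypes arise by meiosis under Haldane's
map function (no interference); phenotypes are

    y = mu + sum_j a_j + g + e

with a_j the QTL genotypic values, g a polygenic effect simulated as
midparent average plus a Mendelian-sampling deviation, and e ~ N(0, sigma2_e).
The full decomposition is retained in :class:`SimTruth` so tests can verify
the bookkeeping exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeMap, evenly_spaced_map, haldane

__all__ = [
    "Qtl", "TrueQtlConfig", "Family", "FamilyDataset", "SimTruth",
    "drop_gamete", "simulate_polygenic", "simulate_dataset", "design_report",
    "chromosome_design", "zero_qtl_design", "genome_wide_design",
    "scaled_genome_design",
]


# ----------------------------------------------------------------------
# configuration types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Qtl:
    chrom: int
    pos_cm: float
    variance: float


@dataclass
class TrueQtlConfig:
    """True genetic architecture used by the simulator."""

    qtl: list          # list of Qtl
    sigma2_A: float = 0.0
    sigma2_e: float = 1.0
    mu: float = 0.0

    def __post_init__(self):
        self.qtl = [q if isinstance(q, Qtl) else Qtl(*q) for q in self.qtl]
        for q in self.qtl:
            if q.variance < 0:
                raise ValueError("QTL variance must be non-negative")
        if self.sigma2_A < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def total_variance(self) -> float:
        return sum(q.variance for q in self.qtl) + self.sigma2_A + self.sigma2_e

    def validate_against(self, genome: GenomeMap):
        for q in self.qtl:
            if not (0 <= q.chrom < genome.n_chromosomes):
                raise ValueError(f"QTL chromosome {q.chrom} out of range")
            if not (0.0 <= q.pos_cm <= genome.lengths[q.chrom]):
                raise ValueError(
                    f"QTL position {q.pos_cm} cM outside chromosome {q.chrom}")


# ----------------------------------------------------------------------
# dataset containers
# ----------------------------------------------------------------------
@dataclass
class Family:
    """One full-sib family: genotyped parents, genotyped+phenotyped offspring.

    Genotypes are pairs of allele codes per marker; the column order of the
    pair carries no phase information.
    """

    sire: np.ndarray          # (M, 2) int
    dam: np.ndarray           # (M, 2) int
    offspring: np.ndarray     # (s, M, 2) int
    phenotypes: np.ndarray    # (s,) float

    @property
    def n_offspring(self) -> int:
        return self.offspring.shape[0]


@dataclass
class FamilyDataset:
    families: list
    genome: GenomeMap
    X: np.ndarray = None      # (n, k) covariates; default a column of ones

    def __post_init__(self):
        n = self.n_offspring
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != n:
            raise ValueError("covariate rows must match total offspring count")

    @property
    def n_offspring(self) -> int:
        return int(sum(f.n_offspring for f in self.families))

    @property
    def family_sizes(self) -> np.ndarray:
        return np.array([f.n_offspring for f in self.families], dtype=np.int64)

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([f.phenotypes for f in self.families])


@dataclass
class SimTruth:
    """Simulation bookkeeping: the exact decomposition of every phenotype."""

    config: TrueQtlConfig
    qtl_values: np.ndarray      # (n, nq) genotypic value a_j per offspring
    qtl_alleles: np.ndarray     # (n, nq, 2) founder-allele ids (pat, mat)
    polygenic: np.ndarray       # (n,)
    residual: np.ndarray        # (n,)
    allele_effects: list = field(default_factory=list)  # per QTL: id -> effect

    def phenotype(self) -> np.ndarray:
        return (self.config.mu + self.qtl_values.sum(axis=1)
                + self.polygenic + self.residual)

    def realized_ibd(self, qtl_index: int, sizes: np.ndarray) -> list:
        """Per-family realized IBD matrices at a QTL (from allele identity)."""
        out, start = [], 0
        ids = self.qtl_alleles[:, qtl_index, :]
        for s in sizes:
            blk = np.empty((s, s))
            sub = ids[start:start + s]
            for i in range(s):
                for k in range(s):
                    blk[i, k] = 0.5 * (int(sub[i, 0] == sub[k, 0])
                                       + int(sub[i, 1] == sub[k, 1]))
            np.fill_diagonal(blk, 1.0)
            out.append(blk)
            start += s
        return out


# ----------------------------------------------------------------------
# meiosis
# ----------------------------------------------------------------------
def _meiosis_indicators(positions: np.ndarray, n_gametes: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Haplotype-of-origin indicator (0/1) per locus for ``n_gametes`` gametes.

    Crossovers occur independently between adjacent loci with Haldane
    recombination fraction; no interference.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or positions.size == 0:
        raise ValueError("positions must be a non-empty 1-D array")
    if np.any(np.diff(positions) < 0):
        raise ValueError("loci must be ordered by position")
    r = haldane(np.diff(positions))
    start = rng.integers(0, 2, size=n_gametes)
    if positions.size == 1:
        return start[:, None]
    switch = rng.random((n_gametes, positions.size - 1)) < r
    ind = np.empty((n_gametes, positions.size), dtype=np.int64)
    ind[:, 0] = start
    ind[:, 1:] = (start[:, None] + np.cumsum(switch, axis=1)) % 2
    return ind


def drop_gamete(parent_haplotypes: np.ndarray, positions: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Sample one gamete from a parent's two phased haplotypes.

    Parameters
    ----------
    parent_haplotypes : (2, L) array
        Allele codes of the parent's two haplotypes at ordered loci.
    positions : (L,) array
        Locus positions in cM, non-decreasing.
    """
    hap = np.asarray(parent_haplotypes)
    if hap.shape[0] != 2:
        raise ValueError("parent_haplotypes must have shape (2, L)")
    ind = _meiosis_indicators(positions, 1, rng)[0]
    return hap[ind, np.arange(hap.shape[1])]


# ----------------------------------------------------------------------
# polygenic effect
# ----------------------------------------------------------------------
def simulate_polygenic(family_sizes, sigma2_A: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Additive polygenic values for the offspring of full-sib families.

    Parent values are N(0, sigma2_A); each offspring receives the midparent
    average plus an independent Mendelian-sampling deviation N(0, sigma2_A/2),
    giving offspring variance sigma2_A and full-sib covariance sigma2_A/2.
    """
    if sigma2_A < 0:
        raise ValueError("sigma2_A must be non-negative")
    sizes = np.asarray(family_sizes, dtype=int)
    n = int(sizes.sum())
    if sigma2_A == 0:
        return np.zeros(n)
    parents = rng.normal(0.0, np.sqrt(sigma2_A), size=(len(sizes), 2))
    mid = np.repeat(parents.mean(axis=1), sizes)
    return mid + rng.normal(0.0, np.sqrt(sigma2_A / 2.0), size=n)


# ----------------------------------------------------------------------
# full dataset
# ----------------------------------------------------------------------
def simulate_dataset(genome: GenomeMap, truth: TrueQtlConfig,
                     n_families: int, sibs_per_family: int,
                     rng_seed) -> tuple:
    """Simulate a :class:`FamilyDataset` plus its :class:`SimTruth`.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    if sibs_per_family < 2:
        raise ValueError("need at least two sibs per family")
    truth.validate_against(genome)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    nq = len(truth.qtl)
    s = sibs_per_family
    n = n_families * s
    M = genome.n_markers
    slices = genome.marker_slices()

    # merged locus lists per chromosome: markers + QTL, sorted by position
    chrom_loci = []      # per chrom: (positions, marker_idx_global, qtl_idx)
    for c in range(genome.n_chromosomes):
        mpos = genome.marker_pos[c]
        qidx = [j for j, q in enumerate(truth.qtl) if q.chrom == c]
        qpos = np.array([truth.qtl[j].pos_cm for j in qidx])
        pos = np.concatenate([mpos, qpos])
        kind = np.concatenate([np.arange(len(mpos)),            # marker local index
                               -1 - np.array(qidx, dtype=float)])  # -(j+1) for QTL j
        order = np.argsort(pos, kind="stable")
        chrom_loci.append((pos[order], kind[order].astype(int)))

    # founder genotypes ---------------------------------------------------
    # marker alleles: uniform over each marker's allele set (HWE/LE)
    def founder_markers(n_ind):
        g = np.empty((n_ind, M, 2), dtype=np.int64)
        for c, sl in enumerate(slices):
            na = genome.n_alleles[c]
            g[:, sl, :] = rng.integers(1, na[None, :, None] + 1,
                                       size=(n_ind, sl.stop - sl.start, 2))
        return g

    sires = founder_markers(n_families)
    dams = founder_markers(n_families)

    # unique QTL alleles per founder (infinite-alleles model)
    # allele id for founder parent p (0..2F-1), slot h: 2*p + h
    allele_effects = []
    for q in truth.qtl:
        eff = rng.normal(0.0, np.sqrt(q.variance / 2.0), size=4 * n_families)
        allele_effects.append(eff)

    # meiosis --------------------------------------------------------------
    qtl_alleles = np.zeros((n, nq, 2), dtype=np.int64)
    off_gen = np.empty((n_families, s, M, 2), dtype=np.int64)

    for c in range(genome.n_chromosomes):
        pos, kind = chrom_loci[c]
        L = len(pos)
        if L == 0:
            continue
        sl = slices[c]
        is_marker = kind >= 0
        mk_local = kind[is_marker]
        for par, gen_table, slot in ((0, sires, 0), (1, dams, 1)):
            # haplotypes over merged loci for all parents of this role;
            # at marker loci the haplotype columns are the genotype slots,
            # at QTL loci they are the founder's two unique allele ids
            haps = np.empty((n_families, 2, L), dtype=np.int64)
            haps[:, :, is_marker] = gen_table[:, sl, :][:, mk_local, :].transpose(0, 2, 1)
            for lidx in np.where(~is_marker)[0]:
                haps[:, 0, lidx] = 4 * np.arange(n_families) + 2 * par
                haps[:, 1, lidx] = 4 * np.arange(n_families) + 2 * par + 1
            ind = _meiosis_indicators(pos, n_families * s, rng)
            ind = ind.reshape(n_families, s, L)
            fam_idx = np.arange(n_families)[:, None, None]
            gam = haps[fam_idx, ind, np.arange(L)[None, None, :]]
            off_gen[:, :, sl, slot] = gam[:, :, is_marker]
            for lidx in np.where(~is_marker)[0]:
                j = -kind[lidx] - 1
                qtl_alleles[:, j, slot] = gam[:, :, lidx].reshape(n)

    # genotypic values -----------------------------------------------------
    qtl_values = np.zeros((n, nq))
    for j in range(nq):
        eff = allele_effects[j]
        qtl_values[:, j] = eff[qtl_alleles[:, j, 0]] + eff[qtl_alleles[:, j, 1]]

    g = simulate_polygenic([s] * n_families, truth.sigma2_A, rng)
    e = rng.normal(0.0, np.sqrt(truth.sigma2_e), size=n)
    y = truth.mu + qtl_values.sum(axis=1) + g + e

    families = []
    for f in range(n_families):
        families.append(Family(
            sire=sires[f], dam=dams[f],
            offspring=off_gen[f],
            phenotypes=y[f * s:(f + 1) * s],
        ))
    ds = FamilyDataset(families=families, genome=genome)
    st = SimTruth(config=truth, qtl_values=qtl_values, qtl_alleles=qtl_alleles,
                  polygenic=g, residual=e, allele_effects=allele_effects)
    return ds, st


# ----------------------------------------------------------------------
# study designs
# ----------------------------------------------------------------------
def chromosome_design() -> tuple:
    """One 100-cM chromosome, 11 markers at 10 cM, three QTL.

    QTL additive variances 0.5 / 1.2 / 0.8 at 15 / 45 / 75 cM; polygenic and
    residual variances both 1.0 (per-QTL heritabilities 11.1/26.7/17.8 %).
    """
    genome = evenly_spaced_map(100.0, 11, n_alleles=6)
    truth = TrueQtlConfig(
        qtl=[Qtl(0, 15.0, 0.5), Qtl(0, 45.0, 1.2), Qtl(0, 75.0, 0.8)],
        sigma2_A=1.0, sigma2_e=1.0, mu=0.0)
    return genome, truth


def zero_qtl_design() -> tuple:
    """Same genome as the chromosome design but with no segregating QTL."""
    genome = evenly_spaced_map(100.0, 11, n_alleles=6)
    truth = TrueQtlConfig(qtl=[], sigma2_A=1.0, sigma2_e=1.0, mu=0.0)
    return genome, truth


def genome_wide_design() -> tuple:
    """2,000-cM genome, 201 markers at 10 cM, five QTL, no polygenic term."""
    genome = evenly_spaced_map(2000.0, 201, n_alleles=6)
    truth = TrueQtlConfig(
        qtl=[Qtl(0, 215.0, 0.4), Qtl(0, 422.0, 0.6), Qtl(0, 853.0, 1.1),
             Qtl(0, 1450.0, 0.5), Qtl(0, 1843.0, 0.8)],
        sigma2_A=0.0, sigma2_e=1.5, mu=0.0)
    return genome, truth


def scaled_genome_design() -> tuple:
    """A reduced genome scan: 600 cM, 61 markers, two QTL, no polygenic term."""
    genome = evenly_spaced_map(600.0, 61, n_alleles=6)
    truth = TrueQtlConfig(
        qtl=[Qtl(0, 150.0, 0.8), Qtl(0, 450.0, 1.1)],
        sigma2_A=0.0, sigma2_e=1.5, mu=0.0)
    return genome, truth


def design_report(truth: TrueQtlConfig) -> dict:
    """Analytic variance budget of a design.

    Per-QTL heritability is sigma2_q divided by the total phenotypic variance
    (sum of all QTL, polygenic and residual variances).
    """
    tot = truth.total_variance
    h2 = [q.variance / tot for q in truth.qtl]
    return {
        "total_variance": tot,
        "per_qtl_h2": h2,
        "total_h2": sum(h2) + truth.sigma2_A / tot,
        "qtl_h2_total": sum(h2),
        "max_qtl_h2": max(h2) if h2 else 0.0,
    }
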