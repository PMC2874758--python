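import numpy as np
import pytest

import qtlshrink as qs
from qtlshrink.genome import haldane
from qtlshrink.ibd import (IbdEngine, MendelianError, additive_relationship,
                           attribute_alleles, infer_phase_weights,
                           transmission_prob)
from qtlshrink.simdata import Family, FamilyDataset

# a family in which the maternal attribution is always unambiguous:
# sire het at both markers, dam homozygous for private alleles
SIRE = np.array([[1, 2], [3, 4]])
DAM = np.array([[5, 5], [6, 6]])
POS2 = np.array([0.0, 10.0])


def _coupling_family(n_off=6):
    # all non-recombinant offspring (paternal haplotype 1-3)
    off = np.array([[[1, 5], [3, 6]]] * max(n_off, 1))[:n_off]
    off = off.reshape(n_off, 2, 2)
    return SIRE, DAM, off


class TestPhaseWeights:
    def test_homozygous_parent_single_configuration(self):
        sire = np.array([[1, 1], [2, 2]])
        _, _, off = _coupling_family(0)
        het, phases, w = infer_phase_weights(sire, DAM, off[:0], POS2, 0)
        assert het == [] and phases == [()] and w.tolist() == [1.0]

    def test_no_offspring_symmetric(self):
        sire, dam, off = _coupling_family(0)
        het, phases, w = infer_phase_weights(sire, dam, off, POS2, 0)
        assert len(phases) == 2
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_six_nonrecombinant_offspring(self):
        # weight of the coupling phase = (1-r)^6 / ((1-r)^6 + r^6)
        sire, dam, off = _coupling_family(6)
        het, phases, w = infer_phase_weights(sire, dam, off, POS2, 0)
        r = haldane(10.0)
        expected = (1 - r) ** 6 / ((1 - r) ** 6 + r ** 6)
        assert phases[0] == (0, 0)
        np.testing.assert_allclose(w[0], expected, rtol=1e-12)


class TestTransmissionProb:
    def test_at_informative_marker_phase_known(self):
        sire, dam, off = _coupling_family(6)
        p = transmission_prob(sire, dam, off, POS2, 0.0, 0, parent=0,
                              phase=(0, 0))
        assert p == pytest.approx(1.0)

    def test_uninformative_prior_half(self):
        sire = np.array([[1, 1], [2, 2]])   # homozygous -> no information
        _, dam, off = _coupling_family(2)
        off = np.array([[[1, 5], [2, 6]]] * 2)
        p = transmission_prob(sire, dam, off, POS2, 5.0, 0, parent=0)
        assert p == pytest.approx(0.5)

    def test_midpoint_between_consistent_flanks(self):
        sire, dam, off = _coupling_family(6)
        r = haldane(5.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r ** 2)
        p = transmission_prob(sire, dam, off, POS2, 5.0, 0, parent=0,
                              phase=(0, 0))
        assert p == pytest.approx(expected, rel=1e-12)


# ----------------------------------------------------------------------
# gene-dropping rejection oracle
# ----------------------------------------------------------------------
def _gene_drop_oracle(sire, dam, off, mpos, lam, seed, min_keep=1200,
                      chunk=1_000_000, max_chunks=30):
    """Monte-Carlo conditional expectation of IBD at ``lam``.

    Samples parental phases and inheritance vectors from the meiosis prior,
    keeps draws reproducing the observed offspring genotypes, and averages
    realized IBD sharing at ``lam`` over the kept draws (rejection
    sampling, chunked until enough draws are retained).
    """
    rng = np.random.default_rng(seed)
    s, M = off.shape[:2]
    loci = np.sort(np.append(mpos, lam))
    li = int(np.searchsorted(loci, lam))
    r = haldane(np.diff(loci))
    midx = np.searchsorted(loci, mpos)
    num = np.zeros((s, s))
    kept = 0
    for _ in range(max_chunks):
        z = np.empty((2, s, chunk, len(loci)), dtype=np.int8)
        for par in range(2):
            for o in range(s):
                start = rng.integers(0, 2, chunk)
                sw = rng.random((chunk, len(loci) - 1)) < r
                z[par, o, :, 0] = start
                z[par, o, :, 1:] = (start[:, None]
                                    + np.cumsum(sw, axis=1)) % 2
        # phase: which genotype slot sits on haplotype 0, per marker
        perm = rng.integers(0, 2, size=(2, chunk, M))
        keep = np.ones(chunk, dtype=bool)
        for o in range(s):
            for mi, m in enumerate(midx):
                pat = sire[mi, perm[0, :, mi] ^ z[0, o, :, m]]
                mat = dam[mi, perm[1, :, mi] ^ z[1, o, :, m]]
                o1, o2 = off[o, mi]
                keep &= (((pat == o1) & (mat == o2))
                         | ((pat == o2) & (mat == o1)))
        kept += keep.sum()
        for i in range(s):
            for k in range(i + 1, s):
                num[i, k] += 0.5 * (
                    (z[0, i, keep, li] == z[0, k, keep, li]).sum()
                    + (z[1, i, keep, li] == z[1, k, keep, li]).sum())
        if kept >= min_keep:
            break
    assert kept >= min_keep, "oracle starved; increase max_chunks"
    blk = np.eye(s) + (num + num.T) / kept
    np.fill_diagonal(blk, 1.0)
    return blk


def test_block_matches_gene_drop_oracle(tiny_map):
    genome = tiny_map
    truth = qs.TrueQtlConfig(qtl=[], sigma2_A=0.0, sigma2_e=1.0)
    ds, _ = qs.simulate_dataset(genome, truth, 4, 2, rng_seed=5)
    eng = IbdEngine(ds)
    mpos = genome.marker_pos[0]
    for f in range(4):
        fam = ds.families[f]
        for lam in (5.0, 15.0):
            oracle = _gene_drop_oracle(fam.sire, fam.dam, fam.offspring,
                                       mpos, lam, seed=f)
            est = eng.block_matrix(f, lam)
            assert np.abs(est - oracle).max() < 0.02


# ----------------------------------------------------------------------
# block properties
# ----------------------------------------------------------------------
class TestIbdBlocks:
    def test_symmetric_psd_unit_diagonal(self, small_dataset):
        genome, truth, ds, st = small_dataset
        eng = IbdEngine(ds)
        rng = np.random.default_rng(0)
        for lam in rng.uniform(0, 100, 8):
            flat = eng.blocks_at(lam)
            start = 0
            for s in ds.family_sizes:
                blk = flat[start:start + s * s].reshape(s, s)
                start += s * s
                np.testing.assert_allclose(blk, blk.T)
                np.testing.assert_allclose(np.diag(blk), 1.0)
                assert blk.min() >= 0 and blk.max() <= 1
                assert np.linalg.eigvalsh(blk).min() > -1e-9

    def test_uninformative_family_prior_half(self, tiny_map):
        sire = np.array([[1, 1]] * 3)
        dam = np.array([[2, 2]] * 3)
        off = np.array([[[1, 2]] * 3] * 4)
        fam = Family(sire=sire, dam=dam, offspring=off,
                     phenotypes=np.zeros(4))
        ds = FamilyDataset(families=[fam], genome=tiny_map)
        blk = IbdEngine(ds).block_matrix(0, 7.0)
        expected = np.full((4, 4), 0.5)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(blk, expected)

    def test_continuity_between_markers(self, small_dataset):
        # continuity holds within a marker interval (the conditioning
        # window changes when a marker is crossed)
        genome, truth, ds, st = small_dataset
        eng = IbdEngine(ds)
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.integers(0, 10)
            lam = 10.0 * m + rng.uniform(0.05, 9.75)
            a = eng.blocks_at(lam)
            b = eng.blocks_at(lam + 0.1)
            assert np.abs(a - b).max() < 0.05

    def test_engine_matches_reference_composition(self, tiny_map):
        """Windowed engine == full phase enumeration when the window covers
        the chromosome."""
        truth = qs.TrueQtlConfig(qtl=[], sigma2_A=0.0, sigma2_e=1.0)
        ds, _ = qs.simulate_dataset(tiny_map, truth, 12, 6, rng_seed=8)
        pos = tiny_map.marker_pos[0]
        eng = IbdEngine(ds, phase_prune=0.0)
        for f in range(12):
            fam = ds.families[f]
            s = fam.n_offspring
            for lam in (2.0, 10.0, 17.3):
                S = np.zeros((s, s))
                for par in range(2):
                    het, phases, w = infer_phase_weights(
                        fam.sire, fam.dam, fam.offspring, pos, par)
                    for bits, wt in zip(phases, w):
                        p = [transmission_prob(fam.sire, fam.dam,
                                               fam.offspring, pos, lam, o,
                                               par, phase=bits)
                             for o in range(s)]
                        for i in range(s):
                            for k in range(s):
                                S[i, k] += 0.5 * wt * (
                                    p[i] * p[k] + (1 - p[i]) * (1 - p[k]))
                np.fill_diagonal(S, 1.0)
                np.testing.assert_allclose(eng.block_matrix(f, lam), S,
                                           atol=1e-10)

    def test_tracks_realized_ibd(self):
        # dense, highly polymorphic map: conditional expectation nearly
        # recovers the realized sharing; at the 10-cM study spacing the
        # correlation is bounded by recombination between the flanks
        for spacing, n_all, min_corr in ((2.0, 30, 0.95), (10.0, 6, 0.85)):
            genome = qs.evenly_spaced_map(spacing * 10, 11, n_alleles=n_all)
            truth = qs.TrueQtlConfig(qtl=[qs.Qtl(0, spacing * 2.5, 1.0)],
                                     sigma2_A=0.0, sigma2_e=1.0)
            ds, st = qs.simulate_dataset(genome, truth, 400, 6, 7)
            eng = IbdEngine(ds)
            flat = eng.blocks_at(spacing * 2.5)
            real = st.realized_ibd(0, ds.family_sizes)
            est, tr = [], []
            start = 0
            for f, s in enumerate(ds.family_sizes):
                blk = flat[start:start + s * s].reshape(s, s)
                start += s * s
                iu = np.triu_indices(s, 1)
                est.extend(blk[iu])
                tr.extend(real[f][iu])
            corr = np.corrcoef(est, tr)[0, 1]
            assert corr > min_corr
            assert abs(np.mean(est) - np.mean(tr)) < 0.02


def test_mendelian_error_names_family_and_marker(tiny_map):
    sire = np.array([[1, 2]] * 3)
    dam = np.array([[3, 4]] * 3)
    off = np.array([[[1, 3], [1, 3], [5, 6]]])   # marker 2 impossible
    with pytest.raises(MendelianError) as exc:
        attribute_alleles(sire, dam, off, family_label=7)
    assert exc.value.family == 7 and exc.value.marker == 2


def test_additive_relationship_structure():
    A = additive_relationship([2]).toarray()
    np.testing.assert_allclose(A, [[1.0, 0.5], [0.5, 1.0]])
    A = additive_relationship([2, 3]).toarray()
    assert np.all(A[:2, 2:] == 0) and np.all(A[2:, :2] == 0)
    A = additive_relationship([6] * 500)
    assert A.shape == (3000, 3000)
    assert A.nnz == 500 * 36
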