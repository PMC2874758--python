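"""Numba kernels for the per-family block computations.

The likelihood factorizes over independent families, so everything reduces
to small dense operations on s x s blocks (s = family size).  Blocks are
stored flattened and concatenated: family f occupies
``V[boff[f] : boff[f] + s_f**2]`` in row-major order.

A failed Cholesky (numerically non-PD trial covariance) makes the
log-likelihood return ``-inf`` so the Metropolis step simply rejects.

IBD tables are segment-major: segment s of a chromosome is the interval
between adjacent markers (plus the two chromosome-end segments); its window
holds at most the two flanking markers and one more on each side, and the
tables store, per family/parent, the pruned phase weights and, per
offspring, the nearest informative window marker on each side.
"""

import numpy as np
from numba import njit

_LOG2PI = 1.8378770664093453


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------
@njit(cache=True)
def _chol_block(L, s):
    """In-place lower Cholesky of the s x s leading block; log-det or -inf."""
    logdet = 0.0
    for j in range(s):
        d = L[j, j]
        for t in range(j):
            d -= L[j, t] * L[j, t]
        if d <= 0.0:
            return -np.inf
        d = np.sqrt(d)
        L[j, j] = d
        logdet += 2.0 * np.log(d)
        for i in range(j + 1, s):
            acc = L[i, j]
            for t in range(j):
                acc -= L[i, t] * L[j, t]
            L[i, j] = acc / d
    return logdet


@njit(cache=True)
def chol_loglik(V, yc, sizes, yoff, boff):
    """Sum over families of log N(yc_f; 0, V_f)."""
    F = sizes.shape[0]
    smax = 0
    for f in range(F):
        if sizes[f] > smax:
            smax = sizes[f]
    L = np.empty((smax, smax))
    z = np.empty(smax)
    total = 0.0
    for f in range(F):
        s = sizes[f]
        b = boff[f]
        yo = yoff[f]
        for i in range(s):
            for k in range(i + 1):
                L[i, k] = V[b + i * s + k]
        logdet = _chol_block(L, s)
        if logdet == -np.inf:
            return -np.inf
        quad = 0.0
        for i in range(s):
            acc = yc[yo + i]
            for t in range(i):
                acc -= L[i, t] * z[t]
            z[i] = acc / L[i, i]
            quad += z[i] * z[i]
        total += -0.5 * (s * _LOG2PI + logdet + quad)
    return total


@njit(cache=True)
def chol_loglik_delta(V, B, d, yc, sizes, yoff, boff):
    """Log-likelihood at the trial covariance V + d * B (V untouched)."""
    F = sizes.shape[0]
    smax = 0
    for f in range(F):
        if sizes[f] > smax:
            smax = sizes[f]
    L = np.empty((smax, smax))
    z = np.empty(smax)
    total = 0.0
    for f in range(F):
        s = sizes[f]
        b = boff[f]
        yo = yoff[f]
        for i in range(s):
            for k in range(i + 1):
                L[i, k] = V[b + i * s + k] + d * B[b + i * s + k]
        logdet = _chol_block(L, s)
        if logdet == -np.inf:
            return -np.inf
        quad = 0.0
        for i in range(s):
            acc = yc[yo + i]
            for t in range(i):
                acc -= L[i, t] * z[t]
            z[i] = acc / L[i, i]
            quad += z[i] * z[i]
        total += -0.5 * (s * _LOG2PI + logdet + quad)
    return total


@njit(cache=True)
def chol_loglik_swap(V, Bold, Bnew, sig, yc, sizes, yoff, boff):
    """Log-likelihood at V + sig * (Bnew - Bold) (V untouched)."""
    F = sizes.shape[0]
    smax = 0
    for f in range(F):
        if sizes[f] > smax:
            smax = sizes[f]
    L = np.empty((smax, smax))
    z = np.empty(smax)
    total = 0.0
    for f in range(F):
        s = sizes[f]
        b = boff[f]
        yo = yoff[f]
        for i in range(s):
            for k in range(i + 1):
                idx = b + i * s + k
                L[i, k] = V[idx] + sig * (Bnew[idx] - Bold[idx])
        logdet = _chol_block(L, s)
        if logdet == -np.inf:
            return -np.inf
        quad = 0.0
        for i in range(s):
            acc = yc[yo + i]
            for t in range(i):
                acc -= L[i, t] * z[t]
            z[i] = acc / L[i, i]
            quad += z[i] * z[i]
        total += -0.5 * (s * _LOG2PI + logdet + quad)
    return total


@njit(cache=True)
def beta_suffstats(V, X, y, sizes, yoff, boff, XtViX, XtViy):
    """Accumulate X' V^-1 X and X' V^-1 y over families (outputs zeroed here).

    Returns 0 on success, 1 if some family block is not positive definite.
    """
    F = sizes.shape[0]
    k = X.shape[1]
    smax = 0
    for f in range(F):
        if sizes[f] > smax:
            smax = sizes[f]
    L = np.empty((smax, smax))
    Z = np.empty((smax, k + 1))
    XtViX[:, :] = 0.0
    XtViy[:] = 0.0
    for f in range(F):
        s = sizes[f]
        b = boff[f]
        yo = yoff[f]
        for i in range(s):
            for kk in range(i + 1):
                L[i, kk] = V[b + i * s + kk]
        if _chol_block(L, s) == -np.inf:
            return 1
        for i in range(s):
            for c in range(k):
                acc = X[yo + i, c]
                for t in range(i):
                    acc -= L[i, t] * Z[t, c]
                Z[i, c] = acc / L[i, i]
            acc = y[yo + i]
            for t in range(i):
                acc -= L[i, t] * Z[t, k]
            Z[i, k] = acc / L[i, i]
        for c in range(k):
            for d2 in range(k):
                acc = 0.0
                for i in range(s):
                    acc += Z[i, c] * Z[i, d2]
                XtViX[c, d2] += acc
            acc = 0.0
            for i in range(s):
                acc += Z[i, c] * Z[i, k]
            XtViy[c] += acc
    return 0


# ----------------------------------------------------------------------
# IBD table construction (per chromosome)
# ----------------------------------------------------------------------
@njit(cache=True)
def ibd_build_tables(mpos, sizes, info, slot, het, prune,
                     wn, wm, ph_n, ph_w, ph_bits,
                     bitL, wslL, slotL, bitR, wslR, slotR):
    """Fill the segment-major IBD tables.

    info/slot: (F, 2, smax, Mc); het: (F, 2, Mc).
    Outputs: wn (S,), wm (S, 4) window marker indices; ph_n (S, F, 2),
    ph_w/ph_bits (S, F, 2, 8); per offspring (S, F, 2, smax): bitL/bitR the
    phase-bit index of the nearest informative flanking marker (-1 when that
    side has none), wslL/wslR its slot in the window, slotL/slotR the
    transmitted genotype slot there.
    """
    F = sizes.shape[0]
    Mc = mpos.shape[0]
    S = Mc + 1
    lw = np.empty(8)
    wts = np.empty(8)
    bits_arr = np.empty(8, dtype=np.uint16)
    Hm = np.empty(4, dtype=np.int64)
    bit_of = np.empty(Mc, dtype=np.int64)
    wsl_of = np.empty(Mc, dtype=np.int64)
    for seg in range(S):
        # window: markers seg-2 .. seg+1 clipped, ascending
        nw = 0
        for m in range(seg - 2, seg + 2):
            if 0 <= m < Mc:
                wm[seg, nw] = m
                wsl_of[m] = nw
                nw += 1
        wn[seg] = nw
        for f in range(F):
            s = sizes[f]
            for par in range(2):
                # heterozygous window markers informative for >= 1 offspring
                nH = 0
                for t in range(nw):
                    m = wm[seg, t]
                    if het[f, par, m] == 1:
                        anyinfo = False
                        for o in range(s):
                            if info[f, par, o, m] == 1:
                                anyinfo = True
                                break
                        if anyinfo:
                            Hm[nH] = m
                            bit_of[m] = nH
                            nH += 1
                # nearest informative flanks per offspring
                for o in range(s):
                    bitL[seg, f, par, o] = -1
                    for m in (seg - 1, seg - 2):
                        if 0 <= m < Mc and info[f, par, o, m] == 1:
                            bitL[seg, f, par, o] = bit_of[m]
                            wslL[seg, f, par, o] = wsl_of[m]
                            slotL[seg, f, par, o] = slot[f, par, o, m]
                            break
                    bitR[seg, f, par, o] = -1
                    for m in (seg, seg + 1):
                        if 0 <= m < Mc and info[f, par, o, m] == 1:
                            bitR[seg, f, par, o] = bit_of[m]
                            wslR[seg, f, par, o] = wsl_of[m]
                            slotR[seg, f, par, o] = slot[f, par, o, m]
                            break
                # phase weights (first informative het marker fixes the
                # labeling; global flip is unidentifiable)
                nfree = nH - 1
                if nfree < 1:
                    ph_n[seg, f, par] = 1
                    ph_w[seg, f, par, 0] = 1.0
                    ph_bits[seg, f, par, 0] = 0
                    continue
                nph = 1 << nfree
                for code in range(nph):
                    bits = code << 1
                    acc = 0.0
                    for o in range(s):
                        prev = -1
                        prevz = 0
                        prevpos = 0.0
                        for t in range(nw):
                            m = wm[seg, t]
                            if info[f, par, o, m] == 1:
                                z = slot[f, par, o, m] ^ ((bits >> bit_of[m]) & 1)
                                if prev >= 0:
                                    r = 0.5 * (1.0 - np.exp(
                                        -0.02 * (mpos[m] - prevpos)))
                                    if z == prevz:
                                        acc += np.log1p(-r)
                                    else:
                                        acc += np.log(r)
                                prev = m
                                prevz = z
                                prevpos = mpos[m]
                    lw[code] = acc
                mx = lw[0]
                for code in range(1, nph):
                    if lw[code] > mx:
                        mx = lw[code]
                tot = 0.0
                for code in range(nph):
                    wts[code] = np.exp(lw[code] - mx)
                    tot += wts[code]
                nkeep = 0
                tot2 = 0.0
                for code in range(nph):
                    w = wts[code] / tot
                    if w > prune:
                        wts[nkeep] = w
                        bits_arr[nkeep] = code << 1
                        tot2 += w
                        nkeep += 1
                ph_n[seg, f, par] = nkeep
                for t in range(nkeep):
                    ph_w[seg, f, par, t] = wts[t] / tot2
                    ph_bits[seg, f, par, t] = bits_arr[t]


# ----------------------------------------------------------------------
# IBD evaluation at a position
# ----------------------------------------------------------------------
@njit(cache=True)
def ibd_at_kernel(lam, sizes, boff, mpos, nw, wm, ph_n, ph_w, ph_bits,
                  bitL, wslL, slotL, bitR, wslR, slotR, out):
    """All per-family IBD blocks at local position ``lam``.

    Arguments from ``wm`` on are the segment-sliced tables (window marker
    indices, phase weights/bits, per-offspring flank tables).
    """
    F = sizes.shape[0]
    smax = bitL.shape[2]
    p = np.empty(smax)
    # recombination fractions to each window marker, by window slot
    rwin = np.empty(4)
    for t in range(nw):
        d = mpos[wm[t]] - lam
        if d < 0.0:
            d = -d
        rwin[t] = 0.5 * (1.0 - np.exp(-0.02 * d))
    for f in range(F):
        s = sizes[f]
        base = boff[f]
        for i in range(s * s):
            out[base + i] = 0.0
        for par in range(2):
            nph = ph_n[f, par]
            for ip in range(nph):
                w = ph_w[f, par, ip]
                bits = ph_bits[f, par, ip]
                for o in range(s):
                    bl = bitL[f, par, o]
                    br = bitR[f, par, o]
                    if bl >= 0 and br >= 0:
                        zl = slotL[f, par, o] ^ ((bits >> bl) & 1)
                        zr = slotR[f, par, o] ^ ((bits >> br) & 1)
                        rl = rwin[wslL[f, par, o]]
                        rr = rwin[wslR[f, par, o]]
                        a0 = ((1.0 - rl) if zl == 0 else rl) \
                            * ((1.0 - rr) if zr == 0 else rr)
                        a1 = (rl if zl == 0 else (1.0 - rl)) \
                            * (rr if zr == 0 else (1.0 - rr))
                        p[o] = a0 / (a0 + a1)
                    elif bl >= 0:
                        zl = slotL[f, par, o] ^ ((bits >> bl) & 1)
                        rl = rwin[wslL[f, par, o]]
                        p[o] = (1.0 - rl) if zl == 0 else rl
                    elif br >= 0:
                        zr = slotR[f, par, o] ^ ((bits >> br) & 1)
                        rr = rwin[wslR[f, par, o]]
                        p[o] = (1.0 - rr) if zr == 0 else rr
                    else:
                        p[o] = 0.5
                for i in range(s):
                    for kk in range(i + 1, s):
                        sh = 0.5 * w * (p[i] * p[kk]
                                        + (1.0 - p[i]) * (1.0 - p[kk]))
                        out[base + i * s + kk] += sh
                        out[base + kk * s + i] += sh
        for i in range(s):
            out[base + i * s + i] = 1.0
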