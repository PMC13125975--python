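"""Compiled inner loops for the cluster-likelihood integrand.

The numba kernels fuse the per-observation probability, gradient and Hessian
computations of the log integrand into single passes over the padded
(batch x cluster x observation) arrays; the pure-numpy implementation in
``likelihood`` remains the reference path (and is used when numba is
unavailable). Interior category probabilities p = F(a) - F(c) and the derivative
ratios f(a)/p, f(c)/p are computed in direct space, falling back to the log scale
when p underflows toward zero (far-tail trial points). Variant codes:
0 = cumulative_re (1-D random effect), 1 = location_shift, 2 = location_scale.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, inline="always")
def _sig(x, e):
    # logistic cdf given e = exp(-|x|)
    return 1.0 / (1.0 + e) if x >= 0.0 else e / (1.0 + e)


@njit(cache=True, inline="always")
def _obs_terms(a, c, hij, lij):
    """(log p, ra, rc, sa, sc, valid) for one observation.

    p = F(a) - F(c) with F(a)=1 when the upper bound is absent (y=k) and F(c)=0
    when the lower bound is absent (y=1); ra = f(a)/p, rc = f(c)/p.
    """
    if hij and lij:
        if c >= a:
            return -np.inf, 0.0, 0.0, 0.5, 0.5, False
        ea = np.exp(-abs(a))
        ec = np.exp(-abs(c))
        sa = _sig(a, ea)
        sc = _sig(c, ec)
        p = sa - sc
        if p > 1e-12:
            lp = np.log(p)
            ra = sa * (1.0 - sa) / p
            rc = sc * (1.0 - sc) / p
        else:
            lsa = (a if a < 0.0 else 0.0) - np.log1p(ea)
            lsc = (c if c < 0.0 else 0.0) - np.log1p(ec)
            l3 = np.log1p(-np.exp(c - a))
            lp = lsa + (lsc - c) + l3
            ra = np.exp((lsa - a) - (lsc - c) - l3)
            rc = np.exp(lsc - lsa - l3)
        return lp, ra, rc, sa, sc, True
    if hij:  # y = 1: p = F(a)
        ea = np.exp(-abs(a))
        sa = _sig(a, ea)
        lp = (a if a < 0.0 else 0.0) - np.log1p(ea)
        return lp, 1.0 - sa, 0.0, sa, 0.5, True
    # y = k: p = 1 - F(c)
    ec = np.exp(-abs(c))
    sc = _sig(c, ec)
    lp = (c if c < 0.0 else 0.0) - np.log1p(ec) - c
    return lp, 0.0, sc, 0.5, sc, True


@njit(cache=True)
def integrand_value(variant, thr_hi, thr_lo, u0, d0, hi, lo, mask, m_hi, m_lo,
                    b, Sigi, logdet, dim, out):
    B, n, m = u0.shape
    log2pi = np.log(2.0 * np.pi)
    for ib in range(B):
        for ic in range(n):
            bl = b[ib, ic, 0]
            bd = b[ib, ic, 1] if dim == 2 else 0.0
            v = 0.0
            for j in range(m):
                if not mask[ic, j]:
                    continue
                u = u0[ib, ic, j] + bl
                if variant == 0:
                    a = thr_hi[ib, ic, j] - u
                    c = thr_lo[ib, ic, j] - u
                elif variant == 1:
                    dd = d0[ib, ic, j] + bd
                    a = thr_hi[ib, ic, j] - u + m_hi[ic, j] * dd
                    c = thr_lo[ib, ic, j] - u + m_lo[ic, j] * dd
                else:
                    it = np.exp(-(d0[ib, ic, j] + bd))
                    a = (thr_hi[ib, ic, j] - u) * it
                    c = (thr_lo[ib, ic, j] - u) * it
                lp, _, _, _, _, ok = _obs_terms(a, c, hi[ic, j], lo[ic, j])
                if not ok:
                    v = -np.inf
                    break
                v += lp
            if dim == 1:
                qf = Sigi[ib, 0, 0] * bl * bl
            else:
                qf = (Sigi[ib, 0, 0] * bl * bl + 2.0 * Sigi[ib, 0, 1] * bl * bd
                      + Sigi[ib, 1, 1] * bd * bd)
            out[ib, ic] = v - 0.5 * (qf + logdet[ib] + dim * log2pi)


@njit(cache=True)
def integrand_vgh(variant, thr_hi, thr_lo, u0, d0, hi, lo, mask, m_hi, m_lo,
                  b, Sigi, logdet, dim, val, grad, hess):
    B, n, m = u0.shape
    log2pi = np.log(2.0 * np.pi)
    for ib in range(B):
        for ic in range(n):
            bl = b[ib, ic, 0]
            bd = b[ib, ic, 1] if dim == 2 else 0.0
            v = 0.0
            g1 = 0.0
            g2 = 0.0
            h11 = 0.0
            h12 = 0.0
            h22 = 0.0
            for j in range(m):
                if not mask[ic, j]:
                    continue
                u = u0[ib, ic, j] + bl
                it = 1.0
                if variant == 0:
                    a = thr_hi[ib, ic, j] - u
                    c = thr_lo[ib, ic, j] - u
                elif variant == 1:
                    dd = d0[ib, ic, j] + bd
                    a = thr_hi[ib, ic, j] - u + m_hi[ic, j] * dd
                    c = thr_lo[ib, ic, j] - u + m_lo[ic, j] * dd
                else:
                    it = np.exp(-(d0[ib, ic, j] + bd))
                    a = (thr_hi[ib, ic, j] - u) * it
                    c = (thr_lo[ib, ic, j] - u) * it
                hij = hi[ic, j]
                lij = lo[ic, j]
                lp, ra, rc, sa, sc, ok = _obs_terms(a, c, hij, lij)
                if ok:
                    v += lp
                else:
                    v = -np.inf
                l_aa = ra * (1.0 - 2.0 * sa) - ra * ra
                l_cc = -rc * (1.0 - 2.0 * sc) - rc * rc
                l_ac = ra * rc
                if variant == 0:
                    g1 += -(ra - rc)
                    h11 += l_aa + 2.0 * l_ac + l_cc
                elif variant == 1:
                    mh = m_hi[ic, j]
                    ml = m_lo[ic, j]
                    g1 += -(ra - rc)
                    g2 += ra * mh - rc * ml
                    h11 += l_aa + 2.0 * l_ac + l_cc
                    h12 += -(l_aa * mh + l_ac * (mh + ml) + l_cc * ml)
                    h22 += l_aa * mh * mh + 2.0 * l_ac * mh * ml + l_cc * ml * ml
                else:
                    a_s = a if hij else 0.0
                    c_s = c if lij else 0.0
                    g1 += -(ra - rc) * it
                    g2 += -(ra * a_s - rc * c_s)
                    h11 += (l_aa + 2.0 * l_ac + l_cc) * it * it
                    h12 += it * (l_aa * a_s + l_ac * (a_s + c_s) + l_cc * c_s + ra - rc)
                    h22 += (l_aa * a_s * a_s + 2.0 * l_ac * a_s * c_s
                            + l_cc * c_s * c_s + ra * a_s - rc * c_s)
            if dim == 1:
                qf = Sigi[ib, 0, 0] * bl * bl
                g1 -= Sigi[ib, 0, 0] * bl
                h11 -= Sigi[ib, 0, 0]
            else:
                qf = (Sigi[ib, 0, 0] * bl * bl + 2.0 * Sigi[ib, 0, 1] * bl * bd
                      + Sigi[ib, 1, 1] * bd * bd)
                g1 -= Sigi[ib, 0, 0] * bl + Sigi[ib, 0, 1] * bd
                g2 -= Sigi[ib, 0, 1] * bl + Sigi[ib, 1, 1] * bd
                h11 -= Sigi[ib, 0, 0]
                h12 -= Sigi[ib, 0, 1]
                h22 -= Sigi[ib, 1, 1]
            val[ib, ic] = v - 0.5 * (qf + logdet[ib] + dim * log2pi)
            grad[ib, ic, 0] = g1
            hess[ib, ic, 0, 0] = h11
            if dim == 2:
                grad[ib, ic, 1] = g2
                hess[ib, ic, 0, 1] = h12
                hess[ib, ic, 1, 0] = h12
                hess[ib, ic, 1, 1] = h22
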