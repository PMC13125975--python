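"""Cluster-wise marginal likelihood by adaptive Gauss-Hermite quadrature.

The marginal likelihood of a cluster integrates the product of category probabilities
over the (bivariate, or scalar for ``cumulative_re``) random-intercept distribution.
Quadrature is *adaptive*: nodes are centered at the joint posterior mode of the random
effects and scaled by the posterior curvature; with one quadrature point per dimension
(the default) this is the Laplace approximation.

Implementation notes
--------------------
All heavy computation runs through a batched evaluator that evaluates the marginal
log-likelihood for a whole batch of parameter vectors simultaneously on padded
(cluster x observation) arrays. Posterior modes are found by damped Newton iterations
with analytic gradient and Hessian of the log integrand; modes are re-found at every
likelihood evaluation (warm-started from the previous call). Probabilities of the form
F(a) - F(c) and their derivative ratios are computed on the log scale, which keeps the
evaluation stable far in the tails.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .data import ClusteredOrdinalData
from .models import (
    CUMULATIVE_RE,
    LOCATION_SCALE,
    LOCATION_SHIFT,
    ModelSpec,
    Parameters,
    RandomEffect,
)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class QuadratureConfig:
    """Adaptive quadrature settings.

    ``n_points`` is the number of Gauss-Hermite points per random-effect dimension
    (1 = Laplace approximation). The mode search runs damped Newton iterations until
    the gradient max-norm falls below ``mode_tolerance``.
    """

    n_points: int = 1
    mode_tolerance: float = 1e-8
    mode_max_iterations: int = 50

    def __post_init__(self):
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass
class ClusterLikelihoodResult:
    """Marginal log-likelihood of one cluster plus posterior-mode diagnostics."""

    log_likelihood: float
    posterior_mode: RandomEffect
    posterior_curvature: np.ndarray  # negative Hessian of the log integrand at the mode
    converged: bool = True
    iterations: int = 0


class _Pack:
    """Padded per-cluster arrays for vectorized likelihood evaluation."""

    def __init__(self, data: ClusteredOrdinalData, spec: ModelSpec):
        if data.k != spec.k:
            raise ValueError(f"data has k={data.k} but spec declares k={spec.k}")
        X = spec.select_X(data.X)
        Z = spec.select_Z(data.Z)
        n = data.n_clusters
        sizes = data.cluster_sizes
        m = int(sizes.max()) if n else 0
        self.n, self.m = n, m
        self.p, self.q = X.shape[1], Z.shape[1]
        self.k = spec.k
        self.variant = spec.variant
        self.dim = spec.random_effect_dim
        self.y = np.ones((n, m), dtype=np.int64)
        self.mask = np.zeros((n, m), dtype=bool)
        self.X = np.zeros((n, m, self.p))
        self.Z = np.zeros((n, m, self.q))
        order = np.argsort(data.cluster, kind="stable")
        pos = np.zeros(n, dtype=int)
        for row in order:
            c = data.cluster[row]
            j = pos[c]
            self.y[c, j] = data.y[row]
            self.mask[c, j] = True
            self.X[c, j] = X[row]
            self.Z[c, j] = Z[row]
            pos[c] += 1
        k = spec.k
        self.hi = self.mask & (self.y < k)
        self.lo = self.mask & (self.y > 1)
        self.idx_hi = np.where(self.y < k, self.y - 1, k - 1)
        self.idx_lo = np.where(self.y > 1, self.y - 2, k - 1)
        self.m_hi = np.where(self.hi, self.y - k / 2.0, 0.0)
        self.m_lo = np.where(self.lo, self.y - 1 - k / 2.0, 0.0)


def _get_pack(data: ClusteredOrdinalData, spec: ModelSpec) -> _Pack:
    key = (spec.variant, spec.k, spec.location_columns, spec.dispersion_columns)
    cache = getattr(data, "_pack_cache", None)
    if cache is None:
        cache = data._pack_cache = {}
    if key not in cache:
        cache[key] = _Pack(data, spec)
    return cache[key]


def _logistic_parts(x):
    """(log F(x), log F(-x), F(x)) from one exp/log1p pair; stable for large |x|."""
    ax = np.abs(x)
    e = np.exp(-ax)
    l1p = np.log1p(e)
    ls = np.where(x < 0, x, 0.0) - l1p
    return ls, ls - x, np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def _logsig(x):
    # log of the logistic cdf, stable for large |x|
    return _logistic_parts(x)[0]


class _Integrand:
    """Log integrand of one parameter batch: sum_j log P(y_j | b) + log prior(b)."""

    _VARIANT_CODE = {CUMULATIVE_RE: 0, LOCATION_SHIFT: 1, LOCATION_SCALE: 2}

    def __init__(self, pack: _Pack, thr, beta, alpha, Sigma, use_kernels: bool | None = None,
                 dim: int | None = None):
        self.pack = pack
        # dim is the integration dimension; it can be 1 for a dispersion variant whose
        # Sigma_b is degenerate (sigma_d^2 = sigma_ld = 0), in which case b_disp = 0
        self.dim = pack.dim if dim is None else dim
        self.use_kernels = _kernels.HAVE_NUMBA if use_kernels is None else use_kernels
        self.code = self._VARIANT_CODE[pack.variant]
        B = thr.shape[0]
        self.B = B
        thr_ext = np.concatenate([thr, np.zeros((B, 1))], axis=1)
        self.thr_hi0 = thr_ext[:, pack.idx_hi]  # (B, n, m)
        self.thr_lo0 = thr_ext[:, pack.idx_lo]
        self.u0 = np.einsum("nmp,bp->bnm", pack.X, beta) if pack.p else np.zeros((B, pack.n, pack.m))
        self.d0 = np.zeros((1, 1, 1))
        if pack.dim == 2:
            self.d0 = np.einsum("nmq,bq->bnm", pack.Z, alpha) if pack.q else np.zeros((B, pack.n, pack.m))
        # prior: inverse and log-determinant of Sigma per batch element
        if self.dim == 1:
            s2 = Sigma[:, 0, 0]
            self.Sigi = (1.0 / s2)[:, None, None]
            self.logdet = np.log(s2)
        else:
            a, b_, d = Sigma[:, 0, 0], Sigma[:, 0, 1], Sigma[:, 1, 1]
            det = a * d - b_ * b_
            self.Sigi = np.stack(
                [np.stack([d / det, -b_ / det], -1), np.stack([-b_ / det, a / det], -1)], -2
            )
            self.logdet = np.log(det)

    def _ac(self, b):
        pack = self.pack
        u = self.u0 + b[..., 0][..., None]
        if pack.variant == CUMULATIVE_RE:
            return self.thr_hi0 - u, self.thr_lo0 - u, None
        dd = self.d0 + (b[..., 1][..., None] if self.dim == 2 else 0.0)
        if pack.variant == LOCATION_SHIFT:
            return self.thr_hi0 - u + pack.m_hi * dd, self.thr_lo0 - u + pack.m_lo * dd, None
        it = np.exp(-dd)
        return (self.thr_hi0 - u) * it, (self.thr_lo0 - u) * it, it

    def _prior(self, b):
        qf = np.einsum("bni,bij,bnj->bn", b, self.Sigi, b)
        return -0.5 * (qf + (self.logdet + self.dim * _LOG2PI)[:, None])

    def value(self, b):
        pack = self.pack
        if self.use_kernels:
            out = np.empty((b.shape[0], pack.n))
            _kernels.integrand_value(
                self.code, self.thr_hi0, self.thr_lo0, self.u0, self.d0,
                pack.hi, pack.lo, pack.mask, pack.m_hi, pack.m_lo,
                b, self.Sigi, np.ascontiguousarray(self.logdet), self.dim, out,
            )
            return out
        a, c, _ = self._ac(b)
        hi, lo = pack.hi, pack.lo
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            cma = np.where(hi & lo, c - a, -np.inf)
            l3 = np.log1p(-np.exp(cma))
            lsa = _logsig(a)
            lsnc = _logsig(c) - c
            logp = np.where(hi, lsa, 0.0) + np.where(lo, lsnc, 0.0) + l3
            logp = np.where(np.isnan(logp) | (cma >= 0), -np.inf, logp)
        val = np.where(pack.mask, logp, 0.0).sum(-1)
        return val + self._prior(b)

    def value_grad_hess(self, b):
        pack = self.pack
        if self.use_kernels:
            B = b.shape[0]
            val = np.empty((B, pack.n))
            grad = np.zeros((B, pack.n, self.dim))
            hess = np.zeros((B, pack.n, self.dim, self.dim))
            _kernels.integrand_vgh(
                self.code, self.thr_hi0, self.thr_lo0, self.u0, self.d0,
                pack.hi, pack.lo, pack.mask, pack.m_hi, pack.m_lo,
                b, self.Sigi, np.ascontiguousarray(self.logdet), self.dim, val, grad, hess,
            )
            return val, grad, hess
        hi, lo = pack.hi, pack.lo
        a, c, it = self._ac(b)
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            lsa, lsna, sa_full = _logistic_parts(a)
            lsc, lsnc, sc_full = _logistic_parts(c)
            cma = np.where(hi & lo, c - a, -np.inf)
            l3 = np.log1p(-np.exp(cma))
            logp = np.where(hi, lsa, 0.0) + np.where(lo, lsnc, 0.0) + l3
            bad = np.isnan(logp) | (cma >= 0)
            logp = np.where(bad, -np.inf, logp)
            log_ra = lsna - np.where(lo, lsnc, 0.0) - l3
            log_rc = lsc - np.where(hi, lsa, 0.0) - l3
            ra = np.where(hi & ~bad, np.exp(log_ra), 0.0)
            rc = np.where(lo & ~bad, np.exp(log_rc), 0.0)
            sa = np.where(hi, sa_full, 0.5)
            sc = np.where(lo, sc_full, 0.5)
        l_aa = ra * (1.0 - 2.0 * sa) - ra * ra
        l_cc = -rc * (1.0 - 2.0 * sc) - rc * rc
        l_ac = ra * rc
        msk = pack.mask
        val = np.where(msk, logp, 0.0).sum(-1) + self._prior(b)

        if self.dim == 1:
            scale = it if pack.variant == LOCATION_SCALE else 1.0
            g = -(np.where(msk, (ra - rc) * scale, 0.0)).sum(-1)
            h = np.where(msk, (l_aa + 2.0 * l_ac + l_cc) * scale * scale, 0.0).sum(-1)
            grad = g[..., None]
            hess = h[..., None, None]
        elif pack.variant == LOCATION_SHIFT:
            mh, ml = pack.m_hi, pack.m_lo
            g1 = -(np.where(msk, ra - rc, 0.0)).sum(-1)
            g2 = np.where(msk, ra * mh - rc * ml, 0.0).sum(-1)
            H11 = np.where(msk, l_aa + 2.0 * l_ac + l_cc, 0.0).sum(-1)
            H12 = np.where(msk, -(l_aa * mh + l_ac * (mh + ml) + l_cc * ml), 0.0).sum(-1)
            H22 = np.where(msk, l_aa * mh * mh + 2.0 * l_ac * mh * ml + l_cc * ml * ml, 0.0).sum(-1)
            grad = np.stack([g1, g2], -1)
            hess = np.stack(
                [np.stack([H11, H12], -1), np.stack([H12, H22], -1)], -2
            )
        else:  # location_scale
            a_s = np.where(hi, a, 0.0)
            c_s = np.where(lo, c, 0.0)
            g1 = -(np.where(msk, (ra - rc) * it, 0.0)).sum(-1)
            g2 = -(np.where(msk, ra * a_s - rc * c_s, 0.0)).sum(-1)
            H11 = np.where(msk, (l_aa + 2.0 * l_ac + l_cc) * it * it, 0.0).sum(-1)
            H12 = np.where(
                msk, it * (l_aa * a_s + l_ac * (a_s + c_s) + l_cc * c_s + ra - rc), 0.0
            ).sum(-1)
            H22 = np.where(
                msk, l_aa * a_s * a_s + 2.0 * l_ac * a_s * c_s + l_cc * c_s * c_s + ra * a_s - rc * c_s, 0.0
            ).sum(-1)
            grad = np.stack([g1, g2], -1)
            hess = np.stack(
                [np.stack([H11, H12], -1), np.stack([H12, H22], -1)], -2
            )
        # Gaussian prior contribution
        grad = grad - np.einsum("bij,bnj->bni", self.Sigi, b)
        hess = hess - self.Sigi[:, None, :, :]
        return val, grad, hess


def _newton_step(grad, hess, dim):
    """Ascent step -H^{-1} g with the Hessian shifted to be safely negative definite."""
    if dim == 1:
        h = np.minimum(hess[..., 0, 0], -1e-8)
        return (-grad[..., 0] / h)[..., None]
    a = hess[..., 0, 0]
    b = hess[..., 0, 1]
    d = hess[..., 1, 1]
    mean = 0.5 * (a + d)
    rad = np.sqrt(0.25 * (a - d) ** 2 + b * b)
    shift = np.maximum(0.0, mean + rad + 1e-8)
    a = a - shift
    d = d - shift
    det = a * d - b * b
    g1, g2 = grad[..., 0], grad[..., 1]
    s1 = -(d * g1 - b * g2) / det
    s2 = -(-b * g1 + a * g2) / det
    return np.stack([s1, s2], -1)


def _find_modes(fn: _Integrand, b0: np.ndarray, tol: float, maxit: int):
    """Damped Newton search for the per-cluster posterior modes, batched."""
    b = b0.copy()
    val, grad, hess = fn.value_grad_hess(b)
    # fall back to b=0 where the warm start is infeasible (e.g. ordering violations)
    invalid = ~np.isfinite(val)
    if invalid.any():
        b[invalid] = 0.0
        val, grad, hess = fn.value_grad_hess(b)
    iterations = 0
    for iterations in range(1, maxit + 1):
        gn = np.abs(grad).max(-1)
        active = (gn > tol) & np.isfinite(val)
        if not active.any():
            iterations -= 1
            break
        step = _newton_step(grad, hess, fn.dim)
        if np.abs(step[active]).max() < 0.25:
            # short Newton steps near a (locally concave) mode: accept outright
            b = np.where(active[..., None], b + step, b)
        else:
            t = np.ones(val.shape)
            accepted = np.zeros(val.shape, dtype=bool)
            bn = b
            for _ in range(20):
                bn = b + (t * active)[..., None] * step
                vn = fn.value(bn)
                fail = active & ~accepted & ~(vn >= val - 1e-10)
                accepted = active & (vn >= val - 1e-10)
                if not fail.any():
                    break
                t = np.where(fail, 0.5 * t, t)
            upd = active & accepted
            b = np.where(upd[..., None], bn, b)
        val, grad, hess = fn.value_grad_hess(b)
    gn = np.abs(grad).max(-1)
    converged = (gn <= tol * 10) | ~np.isfinite(val)
    return b, val, grad, hess, converged, iterations


def _chol2(negH):
    """Lower Cholesky factor entries and log-determinant of (B,n,2,2) SPD matrices."""
    a = negH[..., 0, 0]
    b = negH[..., 0, 1]
    d = negH[..., 1, 1]
    r11 = np.sqrt(a)
    r21 = b / r11
    r22sq = d - r21 * r21
    r22 = np.sqrt(r22sq)
    return r11, r21, r22, 0.5 * np.log(a) + np.log(r22)


class LoglikEvaluator:
    """Batched marginal log-likelihood for one dataset and model specification.

    ``total`` evaluates the summed cluster marginal log-likelihood for each parameter
    vector in a batch. Posterior modes from the previous call warm-start the next
    mode search; set ``chunk`` to bound peak memory for large batches.
    """

    def __init__(self, data: ClusteredOrdinalData, spec: ModelSpec,
                 quad: QuadratureConfig | None = None, chunk: int = 64):
        self.pack = _get_pack(data, spec)
        self.spec = spec
        self.quad = quad or QuadratureConfig()
        self.chunk = chunk
        self._warm = None  # (n, dim) modes from the previous evaluation

    def cluster_loglik(self, thr, beta, alpha, Sigma, return_diagnostics=False):
        """Per-cluster marginal log-likelihoods, shape (B, n).

        The integration dimension follows the trailing dimension of ``Sigma``: a
        dispersion variant evaluated with a 1x1 covariance (degenerate dispersion
        intercept) integrates over the location intercept only.
        """
        pack = self.pack
        quad = self.quad
        dim = Sigma.shape[-1]
        B = thr.shape[0]
        out = np.empty((B, pack.n))
        modes = np.empty((B, pack.n, dim))
        neg_hess = np.empty((B, pack.n, dim, dim))
        conv = np.empty((B, pack.n), dtype=bool)
        iters = 0
        if self._warm is not None and self._warm.shape[-1] != dim:
            self._warm = None
        for start in range(0, B, self.chunk):
            sl = slice(start, min(start + self.chunk, B))
            fn = _Integrand(pack, thr[sl], beta[sl], alpha[sl], Sigma[sl], dim=dim)
            nb = thr[sl].shape[0]
            if self._warm is not None:
                b0 = np.broadcast_to(self._warm, (nb, pack.n, dim)).copy()
            else:
                b0 = np.zeros((nb, pack.n, dim))
            b, val, grad, hess, ok, it = _find_modes(
                fn, b0, quad.mode_tolerance, quad.mode_max_iterations
            )
            iters = max(iters, it)
            nH = -hess
            if dim == 1:
                h = np.maximum(nH[..., 0, 0], 1e-12)
                logdetR = 0.5 * np.log(h)
                if quad.n_points == 1:
                    ll = val + 0.5 * _LOG2PI - logdetR
                else:
                    t, w = np.polynomial.hermite.hermgauss(quad.n_points)
                    terms = []
                    for tm, wm in zip(t, w):
                        bn = b + (np.sqrt(2.0) * tm / np.sqrt(h))[..., None]
                        terms.append(fn.value(bn) + tm * tm + np.log(wm))
                    ll = 0.5 * np.log(2.0) - logdetR + _logsumexp(np.stack(terms))
            else:
                r11, r21, r22, logdetR = _chol2(nH)
                if quad.n_points == 1:
                    ll = val + _LOG2PI - logdetR
                else:
                    t, w = np.polynomial.hermite.hermgauss(quad.n_points)
                    # C = R^{-T}: columns scale the standardized nodes
                    i11 = 1.0 / r11
                    i21 = -r21 / (r11 * r22)
                    i22 = 1.0 / r22
                    terms = []
                    for t1 in range(quad.n_points):
                        for t2 in range(quad.n_points):
                            off1 = np.sqrt(2.0) * (i11 * t[t1] + i21 * t[t2])
                            off2 = np.sqrt(2.0) * (i22 * t[t2])
                            bn = b + np.stack([off1, off2], -1)
                            terms.append(
                                fn.value(bn) + t[t1] ** 2 + t[t2] ** 2
                                + np.log(w[t1]) + np.log(w[t2])
                            )
                    ll = np.log(2.0) - logdetR + _logsumexp(np.stack(terms))
            out[sl] = ll
            modes[sl] = b
            neg_hess[sl] = nH
            conv[sl] = ok
        self._warm = modes[0]
        if return_diagnostics:
            return out, modes, neg_hess, conv, iters
        return out

    def total(self, thr, beta, alpha, Sigma):
        """Total marginal log-likelihood per batch element, shape (B,)."""
        return self.cluster_loglik(thr, beta, alpha, Sigma).sum(-1)


def _logsumexp(x, axis=0):
    m = np.max(x, axis=axis)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    out = m_safe + np.log(np.exp(x - m_safe).sum(axis=axis))
    return np.where(np.isfinite(m), out, m)


def _params_arrays(data, spec, params):
    pack = _get_pack(data, spec)
    beta = np.asarray(params.beta, dtype=float).reshape(1, -1)
    alpha = np.asarray(params.alpha, dtype=float).reshape(1, -1)
    if beta.shape[1] != pack.p:
        raise ValueError(f"beta has {beta.shape[1]} entries, design has {pack.p} columns")
    if pack.dim == 2 and alpha.shape[1] != pack.q:
        raise ValueError(f"alpha has {alpha.shape[1]} entries, design has {pack.q} columns")
    thr = np.asarray(params.thresholds, dtype=float).reshape(1, -1)
    Sig = np.atleast_2d(np.asarray(params.Sigma_b, dtype=float))
    if pack.dim == 1:
        Sig = Sig[:1, :1]
    elif Sig.shape == (2, 2) and abs(Sig[1, 1]) < 1e-12 and abs(Sig[0, 1]) < 1e-12:
        # degenerate dispersion intercept: integrate the location intercept only
        Sig = Sig[:1, :1]
    dim = Sig.shape[0]
    Sigma = Sig.reshape(1, dim, dim)
    return pack, thr, beta, alpha, Sigma


def _fixed_effects_loglik(data, spec, params) -> np.ndarray:
    """Per-cluster log-likelihood at b = 0 (degenerate random-effect prior)."""
    pack, thr, beta, alpha, Sigma = _params_arrays(data, spec, params)
    Sigma = np.eye(pack.dim).reshape(1, pack.dim, pack.dim)  # placeholder prior, removed below
    fn = _Integrand(pack, thr, beta, alpha, Sigma)
    b0 = np.zeros((1, pack.n, pack.dim))
    return (fn.value(b0) - fn._prior(b0))[0]


def cluster_log_marginal_likelihood(
    cluster_data: ClusteredOrdinalData,
    spec: ModelSpec,
    params: Parameters,
    quad: QuadratureConfig | None = None,
    cluster=None,
) -> ClusterLikelihoodResult:
    """Marginal log-likelihood of a single cluster.

    ``cluster_data`` must contain exactly one cluster, or ``cluster`` must name the
    cluster to evaluate. If Sigma_b is numerically zero the fixed-effects
    log-likelihood at b = 0 is returned.
    """
    if cluster is not None:
        cluster_data = cluster_data.restrict_to_cluster(cluster)
    if cluster_data.n_clusters != 1:
        raise ValueError("cluster_data must contain exactly one cluster (or pass cluster=...)")
    quad = quad or QuadratureConfig()
    dim = spec.random_effect_dim
    if np.max(np.abs(np.atleast_2d(params.Sigma_b))) < 1e-12:
        ll = float(_fixed_effects_loglik(cluster_data, spec, params)[0])
        return ClusterLikelihoodResult(
            log_likelihood=ll,
            posterior_mode=RandomEffect(0.0, 0.0),
            posterior_curvature=np.full((dim, dim), np.inf),
        )
    ev = LoglikEvaluator(cluster_data, spec, quad)
    pack, thr, beta, alpha, Sigma = _params_arrays(cluster_data, spec, params)
    ll, modes, nH, conv, iters = ev.cluster_loglik(thr, beta, alpha, Sigma, return_diagnostics=True)
    mode = modes[0, 0]
    b = RandomEffect(float(mode[0]), float(mode[1]) if mode.size == 2 else 0.0)
    curv = nH[0, 0]
    if not conv[0, 0]:
        import warnings

        warnings.warn("posterior mode search did not reach tolerance for this cluster")
    return ClusterLikelihoodResult(
        log_likelihood=float(ll[0, 0]),
        posterior_mode=b,
        posterior_curvature=curv,
        converged=bool(conv[0, 0]),
        iterations=iters,
    )


def total_log_likelihood(
    data: ClusteredOrdinalData,
    spec: ModelSpec,
    params: Parameters,
    quad: QuadratureConfig | None = None,
) -> float:
    """Sum of cluster marginal log-likelihoods over all clusters."""
    if data.n_clusters == 0:
        raise ValueError("data has no clusters")
    if np.max(np.abs(np.atleast_2d(params.Sigma_b))) < 1e-12:
        return float(_fixed_effects_loglik(data, spec, params).sum())
    ev = LoglikEvaluator(data, spec, quad or QuadratureConfig())
    pack, thr, beta, alpha, Sigma = _params_arrays(data, spec, params)
    return float(ev.total(thr, beta, alpha, Sigma)[0])


def model_deviance(data, spec, params, quad=None) -> float:
    """Deviance: minus two times the total marginal log-likelihood."""
    return -2.0 * total_log_likelihood(data, spec, params, quad)


def posterior_modes(data, spec, params, quad=None):
    """Per-cluster posterior modes and curvatures at fixed parameters.

    Returns (modes (n, dim), negative Hessians (n, dim, dim), converged flags).
    """
    ev = LoglikEvaluator(data, spec, quad or QuadratureConfig())
    pack, thr, beta, alpha, Sigma = _params_arrays(data, spec, params)
    _, modes, nH, conv, _ = ev.cluster_loglik(thr, beta, alpha, Sigma, return_diagnostics=True)
    return modes[0], nH[0], conv[0]


def marginal_category_probabilities(
    spec: ModelSpec, params: Parameters, X: np.ndarray, Z: np.ndarray, n_points: int = 15
) -> np.ndarray:
    """Per-observation category probabilities integrated over the random-effect prior.

    Uses (non-adaptive) Gauss-Hermite quadrature scaled by the Cholesky factor of
    Sigma_b; returns an (n_obs, k) array of marginal probabilities. Used for
    observation-level predictive summaries such as the ranked probability score.
    """
    from .models import logistic_cdf

    X = spec.select_X(np.asarray(X, dtype=float))
    Z = spec.select_Z(np.asarray(Z, dtype=float))
    k, dim = spec.k, spec.random_effect_dim
    xb = X @ params.beta if params.beta.size else np.zeros(X.shape[0])
    za = Z @ params.alpha if params.alpha.size and dim == 2 else np.zeros(X.shape[0])
    Sig = np.atleast_2d(params.Sigma_b)[:dim, :dim]
    if np.max(np.abs(Sig)) < 1e-12:
        nodes = [np.zeros(dim)]
        weights = [1.0]
    else:
        L = np.linalg.cholesky(Sig + 1e-14 * np.eye(dim))
        t, w = np.polynomial.hermite.hermgauss(n_points)
        if dim == 1:
            nodes = [np.sqrt(2.0) * L[0, 0] * ti * np.ones(1) for ti in t]
            weights = list(w / np.sqrt(np.pi))
        else:
            nodes, weights = [], []
            for i in range(n_points):
                for j in range(n_points):
                    nodes.append(np.sqrt(2.0) * L @ np.array([t[i], t[j]]))
                    weights.append(w[i] * w[j] / np.pi)
    r = np.arange(1, k)
    probs = np.zeros((X.shape[0], k))
    for node, weight in zip(nodes, weights):
        bl = node[0]
        bd = node[1] if dim == 2 else 0.0
        loc = params.thresholds[None, :] - (xb + bl)[:, None]
        if spec.variant == CUMULATIVE_RE:
            eta = loc
        elif spec.variant == LOCATION_SCALE:
            eta = loc / np.exp(za + bd)[:, None]
        else:
            eta = loc + (r - k / 2.0)[None, :] * (za + bd)[:, None]
        cdf = np.concatenate([np.zeros((X.shape[0], 1)), logistic_cdf(eta), np.ones((X.shape[0], 1))], axis=1)
        cdf = np.maximum.accumulate(cdf, axis=1)  # guard tiny ordering violations at far nodes
        probs += weight * np.diff(cdf, axis=1)
    return probs
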