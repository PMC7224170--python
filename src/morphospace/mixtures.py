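"""Gaussian mixtures, the parametric-bootstrap likelihood-ratio test, and
bimodality verdicts.

The pooled PC1 scores cluster in two regions.  Whether that clustering is
real structure or noise is assessed by fitting 1- and 2-component Gaussian
mixtures (optionally with per-record weights, for the sampling-bias checks)
and calibrating the likelihood-ratio statistic with a parametric bootstrap
under the single-component null.

The EM implementation is deliberately self-contained: it supports weighted
likelihoods, asserts the per-iteration monotonicity of the objective, and
has a batched 1-D path so hundreds of bootstrap replicates run as single
vectorised array operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_LOG2PI = math.log(2.0 * math.pi)


class DegenerateFitError(RuntimeError):
    """Every EM restart collapsed onto a degenerate component."""


@dataclass
class MixtureFit:
    """A fitted k-component Gaussian mixture (1-D or multivariate)."""

    k: int
    weights: np.ndarray          # (k,) mixing proportions
    means: np.ndarray            # (k,) or (k, d)
    spreads: np.ndarray          # (k,) sds, (k, d) diag sds, or (k, d, d) covs
    log_likelihood: float
    bic: float
    n: float                     # effective sample size (sum of weights)
    n_iter: int = 0
    converged: bool = True

    @property
    def is_1d(self) -> bool:
        return self.means.ndim == 1

    def density(self, grid: np.ndarray) -> np.ndarray:
        """Mixture density on a 1-D grid (1-D fits only)."""
        if not self.is_1d:
            raise ValueError("density grid evaluation is 1-D only")
        g = np.asarray(grid, dtype=float)[:, None]
        z = (g - self.means[None, :]) / self.spreads[None, :]
        comp = np.exp(-0.5 * z ** 2) / (self.spreads[None, :] * math.sqrt(2 * math.pi))
        return comp @ self.weights


@dataclass
class BootstrapResult:
    """Parametric-bootstrap calibration of the 1-vs-2 component LRT."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    B: int
    seed: int
    n_redraws: int = 0


# --------------------------------------------------------------------------
# batched 1-D EM (axis 0 = independent datasets)
# --------------------------------------------------------------------------

def _batch_loglik(x, w, pi, mu, sd):
    """Weighted log-likelihood per dataset. x,w: (B,n); pi,mu,sd: (B,k)."""
    z = (x[:, :, None] - mu[:, None, :]) / sd[:, None, :]
    logpdf = -0.5 * z ** 2 - np.log(sd[:, None, :]) - 0.5 * _LOG2PI
    m = logpdf + np.log(pi[:, None, :])
    mmax = m.max(axis=2, keepdims=True)
    lse = mmax[:, :, 0] + np.log(np.exp(m - mmax).sum(axis=2))
    return (w * lse).sum(axis=1), m, lse


def _em_1d_batch(x, w, pi, mu, sd, tol=1e-8, max_iter=500, var_floor_frac=1e-6,
                 check_monotone=False):
    """Run weighted EM on a batch of 1-D datasets until convergence.

    Returns (pi, mu, sd, loglik, n_iter, converged, degenerate) arrays.
    Components are not reordered here.
    """
    B, n = x.shape
    k = mu.shape[1]
    floor = np.sqrt(var_floor_frac) * np.maximum(x.std(axis=1), 1e-300)  # sd floor per dataset
    ll, m, lse = _batch_loglik(x, w, pi, mu, sd)
    sw = w.sum(axis=1)
    degenerate = np.zeros(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)
    idx = np.arange(B)
    m_a, lse_a, ll_a = m, lse, ll
    it = 0
    while idx.size and it < max_iter:
        it += 1
        xa, wa = x[idx], w[idx]
        r = np.exp(m_a - lse_a[:, :, None])                # responsibilities
        wr = wa[:, :, None] * r
        Nk = wr.sum(axis=1)                                # (b, k)
        tiny = Nk < 1e-12
        pi_a = Nk / sw[idx][:, None]
        mu_a = np.where(tiny, mu[idx], (wr * xa[:, :, None]).sum(axis=1) / np.maximum(Nk, 1e-300))
        var = (wr * (xa[:, :, None] - mu_a[:, None, :]) ** 2).sum(axis=1) / np.maximum(Nk, 1e-300)
        sd_a = np.sqrt(var)
        deg = (sd_a < floor[idx][:, None]).any(axis=1) | tiny.any(axis=1)
        sd_a = np.maximum(sd_a, floor[idx][:, None])
        pi[idx], mu[idx], sd[idx] = pi_a, mu_a, sd_a
        ll_new, m_a, lse_a = _batch_loglik(xa, wa, pi_a, mu_a, sd_a)
        if check_monotone:
            drop = ll_new - ll[idx]
            if np.any(drop < -1e-8 * (1 + np.abs(ll[idx]))):
                raise AssertionError("EM log-likelihood decreased")
        degenerate[idx] |= deg
        moved = np.abs(ll_new - ll[idx]) > tol * (1 + np.abs(ll[idx]))
        n_iter[idx] = it
        ll[idx] = ll_new
        keep = moved & ~deg
        idx = idx[keep]
        m_a, lse_a = m_a[keep], lse_a[keep]
    converged = np.ones(B, dtype=bool)
    converged[idx] = False
    return pi, mu, sd, ll, n_iter, converged, degenerate


def _quantile_init_batch(x, k):
    """Split each sorted dataset into k equal blocks; per-block mean/sd."""
    B, n = x.shape
    xs = np.sort(x, axis=1)
    edges = np.linspace(0, n, k + 1).astype(int)
    mu = np.empty((B, k))
    sd = np.empty((B, k))
    for j in range(k):
        blk = xs[:, edges[j]:edges[j + 1]]
        mu[:, j] = blk.mean(axis=1)
        sd[:, j] = np.maximum(blk.std(axis=1), 1e-3 * np.maximum(x.std(axis=1), 1e-12))
    pi = np.full((B, k), 1.0 / k)
    return pi, mu, sd


def _fit_1d_batch(x, w, k, rng, n_random_inits=3, tol=1e-8, max_iter=500,
                  var_floor_frac=1e-6):
    """Best-of-inits batched 1-D EM; components ordered by mean."""
    B, n = x.shape
    if k == 1:
        sw = w.sum(axis=1)
        mu = (w * x).sum(axis=1) / sw
        var = (w * (x - mu[:, None]) ** 2).sum(axis=1) / sw
        sd = np.sqrt(var)
        ll, _, _ = _batch_loglik(x, w, np.ones((B, 1)), mu[:, None], sd[:, None])
        return np.ones((B, 1)), mu[:, None], sd[:, None], ll, np.zeros(B, dtype=bool)

    inits = [_quantile_init_batch(x, k)]
    gsd = np.maximum(x.std(axis=1), 1e-12)
    for _ in range(n_random_inits):
        picks = rng.integers(0, n, size=(B, k))
        mu0 = np.take_along_axis(x, picks, axis=1).astype(float)
        sd0 = np.repeat(gsd[:, None], k, axis=1)
        inits.append((np.full((B, k), 1.0 / k), mu0, sd0))

    best_ll = np.full(B, -np.inf)
    best = None
    all_deg = np.ones(B, dtype=bool)
    for pi0, mu0, sd0 in inits:
        pi, mu, sd, ll, _, conv, deg = _em_1d_batch(
            x, w, pi0.copy(), mu0.copy(), sd0.copy(),
            tol=tol, max_iter=max_iter, var_floor_frac=var_floor_frac)
        ll = np.where(deg, -np.inf, ll)
        all_deg &= deg
        better = ll > best_ll
        if best is None:
            best = [pi, mu, sd]
            best_ll = ll
        else:
            for arr, new in zip(best, (pi, mu, sd)):
                arr[better] = new[better]
            best_ll = np.where(better, ll, best_ll)
    pi, mu, sd = best
    if all_deg.any():
        # fall back to the k=1 solution replicated: harmless for LRT (stat ~ 0)
        idx = np.nonzero(all_deg)[0]
        _, mu1, sd1, ll1, _ = _fit_1d_batch(x[idx], w[idx], 1, rng)
        pi[idx] = 1.0 / k
        mu[idx] = np.repeat(mu1, k, axis=1)
        sd[idx] = np.repeat(sd1, k, axis=1)
        best_ll[idx] = ll1
    order = np.argsort(mu, axis=1)
    pi = np.take_along_axis(pi, order, axis=1)
    mu = np.take_along_axis(mu, order, axis=1)
    sd = np.take_along_axis(sd, order, axis=1)
    return pi, mu, sd, best_ll, all_deg


# --------------------------------------------------------------------------
# public single-dataset API
# --------------------------------------------------------------------------

def _n_params(k: int, d: int, covariance: str) -> int:
    if d == 1:
        return 3 * k - 1
    if covariance == "diag":
        return k * d + k * d + (k - 1)
    return k * d + k * d * (d + 1) // 2 + (k - 1)


def fit_gmm(data: np.ndarray, k: int, *, weights: np.ndarray | None = None,
            seed: int = 0, n_random_inits: int = 5, tol: float = 1e-8,
            max_iter: int = 500, var_floor_frac: float = 1e-6,
            covariance: str = "full") -> MixtureFit:
    """Fit a k-component Gaussian mixture by EM (best of several inits).

    ``data`` is (n,) or (n, 1) for 1-D, or (n, d) for multivariate.
    ``weights`` are positive per-record likelihood weights (default uniform);
    the weighted log-likelihood is ``sum_i w_i log f(x_i)`` and BIC uses
    ``n = sum_i w_i``.  Initialisation: a quantile split of the sorted data
    (1-D) or seeded random restarts; components are ordered by mean.
    """
    X = np.asarray(data, dtype=float)
    one_d = X.ndim == 1 or X.shape[1] == 1
    n = X.shape[0]
    if n <= 10 * k:
        raise ValueError(f"need n > 10*k records, got n={n}, k={k}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per record")
    rng = np.random.default_rng(seed)

    if one_d:
        x = X.reshape(1, n)
        wb = w.reshape(1, n)
        if k == 1:
            pi, mu, sd, ll, _ = _fit_1d_batch(x, wb, 1, rng)
        else:
            pi, mu, sd, ll, all_deg = _fit_1d_batch(
                x, wb, k, rng, n_random_inits=n_random_inits,
                tol=tol, max_iter=max_iter, var_floor_frac=var_floor_frac)
            if all_deg[0]:
                raise DegenerateFitError("all EM restarts degenerate")
        # one monotonicity-audited pass from the solution (cheap, asserts EM property)
        _em_1d_batch(x, wb, pi.copy(), mu.copy(), sd.copy(), tol=tol,
                     max_iter=5, var_floor_frac=var_floor_frac, check_monotone=True)
        sw = float(w.sum())
        llf = float(ll[0])
        p = _n_params(k, 1, covariance)
        return MixtureFit(k=k, weights=pi[0], means=mu[0], spreads=sd[0],
                          log_likelihood=llf, bic=-2 * llf + p * math.log(sw), n=sw)

    return _fit_gmm_multivariate(X, k, w, rng, n_random_inits, tol, max_iter,
                                 var_floor_frac, covariance)


def _mv_loglik(X, w, pi, mu, cov, covariance):
    n, d = X.shape
    k = len(pi)
    logp = np.empty((n, k))
    for j in range(k):
        if covariance == "diag":
            var = cov[j]
            z2 = ((X - mu[j]) ** 2 / var).sum(axis=1)
            logdet = np.log(var).sum()
        else:
            L = np.linalg.cholesky(cov[j])
            sol = np.linalg.solve(L, (X - mu[j]).T)
            z2 = (sol ** 2).sum(axis=0)
            logdet = 2 * np.log(np.diag(L)).sum()
        logp[:, j] = -0.5 * (z2 + logdet + d * _LOG2PI) + math.log(max(pi[j], 1e-300))
    mmax = logp.max(axis=1, keepdims=True)
    lse = mmax[:, 0] + np.log(np.exp(logp - mmax).sum(axis=1))
    return float((w * lse).sum()), logp, lse


def _fit_gmm_multivariate(X, k, w, rng, n_random_inits, tol, max_iter,
                          var_floor_frac, covariance):
    n, d = X.shape
    sw = float(w.sum())
    total_var = X.var(axis=0).mean()
    floor = var_floor_frac * max(total_var, 1e-300)
    base_cov = np.cov(X, rowvar=False, aweights=w) + floor * np.eye(d)

    best = None
    for trial in range(max(1, n_random_inits)):
        picks = rng.choice(n, size=k, replace=False)
        mu = X[picks].astype(float)
        if covariance == "diag":
            cov = np.repeat(np.diag(base_cov)[None, :], k, axis=0)
        else:
            cov = np.repeat(base_cov[None, :, :], k, axis=0)
        pi = np.full(k, 1.0 / k)
        ll, logp, lse = _mv_loglik(X, w, pi, mu, cov, covariance)
        ok = True
        for it in range(max_iter):
            r = np.exp(logp - lse[:, None])
            wr = w[:, None] * r
            Nk = wr.sum(axis=0)
            if np.any(Nk < 1e-10):
                ok = False
                break
            pi = Nk / sw
            mu = (wr.T @ X) / Nk[:, None]
            if covariance == "diag":
                cov = np.stack([
                    np.maximum((wr[:, j:j + 1] * (X - mu[j]) ** 2).sum(axis=0) / Nk[j], floor)
                    for j in range(k)])
            else:
                cov = np.stack([
                    ((wr[:, j:j + 1] * (X - mu[j])).T @ (X - mu[j])) / Nk[j]
                    + floor * np.eye(d)
                    for j in range(k)])
            ll_new, logp, lse = _mv_loglik(X, w, pi, mu, cov, covariance)
            assert ll_new >= ll - 1e-8 * (1 + abs(ll)), "EM log-likelihood decreased"
            done = abs(ll_new - ll) <= tol * (1 + abs(ll))
            ll = ll_new
            if done:
                break
        if not ok:
            continue
        if best is None or ll > best[0]:
            best = (ll, pi, mu, cov)
        if k == 1:
            break
    if best is None:
        raise DegenerateFitError("all EM restarts degenerate")
    ll, pi, mu, cov = best
    order = np.argsort(mu[:, 0])
    p = _n_params(k, d, covariance)
    return MixtureFit(k=k, weights=pi[order], means=mu[order], spreads=cov[order],
                      log_likelihood=ll, bic=-2 * ll + p * math.log(sw), n=sw)


def bootstrap_lrt(data: np.ndarray, B: int = 999, seed: int = 0, *,
                  weights: np.ndarray | None = None,
                  n_random_inits: int = 1, tol: float = 1e-5,
                  max_iter: int = 200) -> BootstrapResult:
    """Parametric bootstrap of the 1- vs 2-component likelihood-ratio test.

    The observed statistic is ``2 (logL_2 - logL_1)`` on the (weighted) data.
    Null replicates of size n are simulated from the fitted single-Gaussian
    model and refit with uniform weights; the Monte-Carlo p-value is
    ``(1 + #{null >= observed}) / (B + 1)``.  Fully reproducible given
    ``seed``; all replicate fits run through one batched EM.

    The observed data and every null replicate are fit by the *identical*
    protocol (quantile-split plus ``n_random_inits`` seeded random starts,
    relative tolerance ``tol``, at most ``max_iter`` EM steps), which is what
    makes the bootstrap comparison exchangeable; the protocol tolerance is
    looser than :func:`fit_gmm`'s default because near-degenerate spike
    solutions make the fully-converged 2-component likelihood a moving
    target, and only the obs-vs-null comparison matters here.
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    x = np.asarray(data, dtype=float).reshape(-1)
    n = x.size
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)

    def fit_both(xs, ws):
        _, m1, s1, l1, _ = _fit_1d_batch(xs, ws, 1, rng)
        _, _, _, l2, _ = _fit_1d_batch(xs, ws, 2, rng,
                                       n_random_inits=n_random_inits,
                                       tol=tol, max_iter=max_iter)
        return m1, s1, 2.0 * (l2 - l1)

    mu1, sd1, obs = fit_both(x.reshape(1, n), w.reshape(1, n))
    observed = float(obs[0])

    # Null world: n i.i.d. draws from the fitted single Gaussian, per replicate.
    sims = rng.normal(mu1[0, 0], sd1[0, 0], size=(B, n))
    _, _, null_stats = fit_both(sims, np.ones_like(sims))
    bad = ~np.isfinite(null_stats)
    n_redraws = 0
    while bad.any():
        n_redraws += int(bad.sum())
        redraw = rng.normal(mu1[0, 0], sd1[0, 0], size=(int(bad.sum()), n))
        _, _, rs = fit_both(redraw, np.ones_like(redraw))
        null_stats[bad] = rs
        bad = ~np.isfinite(null_stats)

    p = (1.0 + float((null_stats >= observed).sum())) / (B + 1.0)
    return BootstrapResult(observed_stat=observed, null_stats=null_stats,
                           p_value=p, B=B, seed=seed, n_redraws=n_redraws)


def is_bimodal(fit: MixtureFit, n_grid: int = 1024,
               min_prominence: float = 0.1) -> bool:
    """Does the fitted 1-D mixture density have two prominent local maxima?

    A two-component fit whose components merge into a single hump is not
    counted, nor is a faint secondary bump (peak density below
    ``min_prominence`` times the main mode's): that separates genuinely
    clustered data from data with mere skew, heavy tails, or a thin shelf.
    """
    if not fit.is_1d:
        raise ValueError("mode counting is defined for 1-D fits")
    lo = float((fit.means - 4 * fit.spreads).min())
    hi = float((fit.means + 4 * fit.spreads).max())
    grid = np.linspace(lo, hi, n_grid)
    dens = fit.density(grid)
    d = np.diff(dens)
    maxima = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    if len(maxima) < 2:
        return False
    peaks = np.sort(dens[maxima])
    return bool(peaks[-2] >= min_prominence * peaks[-1])


def bimodality_verdict(data: np.ndarray, *, seed: int = 0,
                       weights: np.ndarray | None = None) -> dict:
    """Convenience verdict: BIC comparison plus density mode count.

    Returns a dict with the two fits' BICs, whether BIC prefers two
    components, and whether the preferred 2-component density is bimodal.
    """
    f1 = fit_gmm(data, 1, weights=weights, seed=seed)
    f2 = fit_gmm(data, 2, weights=weights, seed=seed)
    return {
        "bic_1": f1.bic,
        "bic_2": f2.bic,
        "bic_prefers_two": bool(f2.bic < f1.bic),
        "density_bimodal": bool(is_bimodal(f2)),
        "bimodal": bool(f2.bic < f1.bic and is_bimodal(f2)),
    }
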