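"""Compact Newton-Raphson solver for the Cox proportional-hazards model.

Built for the Monte-Carlo engines, where thousands of small fits per run make
per-fit overhead the binding cost. Supports Efron (default) and Breslow tie
handling; with continuous simulated times there are usually no ties and a
fully vectorised no-ties path is taken.

Monotone partial likelihoods (e.g. no events in one group) are reported via
``converged=False`` and non-finite coefficients rather than exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "cox_fit"]

_MAX_ABS_BETA = 15.0


@dataclass
class CoxFit:
    beta: np.ndarray          # (p,)
    cov: np.ndarray           # (p, p) inverse observed information
    loglik: float
    converged: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    def wald_p(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.wald_z()))


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _loglik_grad_hess(Xs, ts, es, beta, ties, first_idx, group_slices, no_ties_idx):
    eta = Xs @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    Xw = Xs * w[:, None]
    S0r = _revcumsum(w)
    S1r = _revcumsum(Xw)
    XXw = Xs[:, :, None] * Xs[:, None, :] * w[:, None, None]
    S2r = _revcumsum(XXw)

    if no_ties_idx is not None:
        idx = no_ties_idx
        s0 = S0r[idx]
        m1 = S1r[idx] / s0[:, None]
        ll = float(eta[idx].sum() - np.log(s0).sum())
        grad = Xs[idx].sum(axis=0) - m1.sum(axis=0)
        hess = (S2r[idx] / s0[:, None, None]).sum(axis=0) - np.einsum("ip,iq->pq", m1, m1)
        return ll, grad, hess

    p = Xs.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for fi, (start, stop) in zip(first_idx, group_slices):
        ev = slice(start, stop)
        d = stop - start
        R0, R1, R2 = S0r[fi], S1r[fi], S2r[fi]
        ll += float(eta[ev].sum())
        grad += Xs[ev].sum(axis=0)
        if ties == "efron" and d > 1:
            fr = np.arange(d) / d
            s0 = w[ev].sum()
            s1 = Xw[ev].sum(axis=0)
            s2 = XXw[ev].sum(axis=0)
            D0 = R0 - fr * s0                       # (d,)
            D1 = R1[None, :] - fr[:, None] * s1     # (d, p)
            D2 = R2[None] - fr[:, None, None] * s2  # (d, p, p)
        else:  # breslow: d copies of the full risk-set sums
            D0 = np.full(d, R0)
            D1 = np.broadcast_to(R1, (d, p))
            D2 = np.broadcast_to(R2, (d, p, p))
        m1 = D1 / D0[:, None]
        ll -= float(np.log(D0).sum())
        grad -= m1.sum(axis=0)
        hess += (D2 / D0[:, None, None]).sum(axis=0) - np.einsum("ip,iq->pq", m1, m1)
    return ll, grad, hess


def cox_fit(
    X,
    time,
    event,
    ties: str = "efron",
    max_iter: int = 40,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, p) covariate matrix
    time, event : follow-up times and event indicators (bool/int)
    ties : "efron" or "breslow"
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties rule {ties!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(time)) == X.shape[1]:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, p = X.shape

    # events sort before censorings at tied times, so a reverse cumsum at an
    # event row includes same-time censored subjects in its risk set
    order = np.lexsort((~event, time))
    Xs, ts, es = X[order], time[order], event[order]
    n_events = int(es.sum())
    nan_fit = CoxFit(
        beta=np.full(p, np.nan), cov=np.full((p, p), np.nan),
        loglik=np.nan, converged=False, n_iter=0,
    )
    if n_events == 0:
        return nan_fit

    # event-time tie structure (computed once); the vectorised path needs
    # only the *event* times to be distinct
    ev_idx = np.flatnonzero(es)
    ev_times = ts[ev_idx]
    if np.unique(ev_times).size == n_events:
        no_ties_idx = ev_idx
        first_idx = group_slices = None
    else:
        no_ties_idx = None
        uniq = np.unique(ev_times)
        first_idx = list(np.searchsorted(ts, uniq, side="left"))
        group_slices = []
        for u in uniq:
            lo, hi = np.searchsorted(ev_times, [u, np.nextafter(u, np.inf)])
            sel = ev_idx[lo:hi]
            group_slices.append((int(sel[0]), int(sel[-1] + 1)))

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(
        Xs, ts, es, beta, ties, first_idx, group_slices, no_ties_idx
    )
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return nan_fit
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(25):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(
                Xs, ts, es, cand, ties, first_idx, group_slices, no_ties_idx
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(scale * step)) < tol or np.max(np.abs(grad)) < 1e-8:
            converged = True
            break
        if np.max(np.abs(beta)) > _MAX_ABS_BETA:
            break  # monotone likelihood; flag below

    if np.max(np.abs(beta)) > _MAX_ABS_BETA:
        return CoxFit(
            beta=np.where(np.abs(beta) > _MAX_ABS_BETA, np.sign(beta) * np.inf, beta),
            cov=np.full((p, p), np.nan), loglik=ll, converged=False, n_iter=it,
        )
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return CoxFit(beta=beta, cov=cov, loglik=ll, converged=converged, n_iter=it)
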