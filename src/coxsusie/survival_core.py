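"""Cox proportional-hazards partial likelihood with offsets.

This module provides the survival-analysis primitives used by the
single-effect regression scan: the partial log-likelihood for a single
covariate with an additive offset on the linear predictor, univariate
maximum-partial-likelihood fitting by Newton-Raphson, and estimation of
fixed-covariate offsets from a multivariate Cox fit.

The partial likelihood is a product over event times of the relative
hazard of the failing subject(s) within the risk set, and is free of the
baseline hazard: only the ranks of the observed times matter.  Tied event
times are handled by either the Efron or the Breslow correction.

Univariate fits are the inner loop of the fine-mapping scan, so the heavy
lifting is done by a batched implementation that fits all p genotype
columns simultaneously with vectorized risk-set suffix sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SurvivalOutcome",
    "UnivariateCoxFit",
    "BatchCoxFits",
    "partial_loglik",
    "fit_univariate_coxph",
    "batch_univariate_coxph",
    "fit_covariate_offsets",
]

TIE_METHODS = ("efron", "breslow")

#: Cap on |b-hat|; beyond this the partial likelihood is effectively
#: monotone (complete separation) and the MLE does not exist.
B_CAP = 15.0


# ---------------------------------------------------------------------------
# outcome container and risk-set layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _RiskSetLayout:
    """Sorted risk-set bookkeeping shared by all likelihood evaluations.

    Samples are sorted by observed time ascending (stable sort, so results
    are independent of the input ordering only through tie groups, which
    are symmetric).  ``group_starts`` indexes the first member of each
    unique-time group; the risk set for an event at time t is the suffix
    of the sorted array beginning at t's group.
    """

    order: np.ndarray          # (n,) indices sorting times ascending
    group_starts: np.ndarray   # (G,) start index of each unique-time group
    d: np.ndarray              # (G,) number of events in each group
    delta_sorted: np.ndarray   # (n,) status in sorted order
    event_groups: np.ndarray   # indices of groups with >= 1 event
    max_mult: int              # largest event-tie multiplicity


def _build_layout(times: np.ndarray, status: np.ndarray) -> _RiskSetLayout:
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    delta_sorted = status[order]
    # first index of each unique time
    is_start = np.ones(len(t_sorted), dtype=bool)
    is_start[1:] = t_sorted[1:] != t_sorted[:-1]
    group_starts = np.flatnonzero(is_start)
    group_id = np.cumsum(is_start) - 1
    d = np.bincount(group_id, weights=delta_sorted).astype(np.int64)
    event_groups = np.flatnonzero(d > 0)
    max_mult = int(d.max()) if len(d) else 0
    return _RiskSetLayout(order, group_starts, d, delta_sorted,
                          event_groups, max_mult)


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored time-to-event outcomes for n samples.

    Parameters
    ----------
    times
        Observed time per sample (event or censoring time); all > 0.
    status
        Event indicator per sample: 1 = event observed, 0 = censored.
    """

    times: np.ndarray
    status: np.ndarray
    _layout_cache: list = field(default_factory=list, repr=False,
                                compare=False)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=np.float64)
        status = np.asarray(self.status)
        if times.ndim != 1 or status.shape != times.shape:
            raise ValueError("times and status must be 1-d of equal length")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("all times must be finite and > 0")
        uniq = np.unique(status)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("status must contain only 0 (censored) "
                             "and 1 (event)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status.astype(np.int8))

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def censoring_rate(self) -> float:
        return (self.n - self.n_events) / self.n

    @property
    def layout(self) -> _RiskSetLayout:
        if not self._layout_cache:
            self._layout_cache.append(_build_layout(self.times, self.status))
        return self._layout_cache[0]


# ---------------------------------------------------------------------------
# fit result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnivariateCoxFit:
    """Maximum-partial-likelihood fit of a single covariate.

    ``bhat`` is the log hazard ratio per covariate unit, ``se`` its
    standard error from the observed information at the MLE, and ``z``
    the Wald statistic bhat/se.  ``degenerate`` marks covariates that
    carry no information (zero variance); such fits have bhat = 0 and
    loglik_mle = loglik_null.
    """

    bhat: float
    se: float
    z: float
    loglik_mle: float
    loglik_null: float
    converged: bool
    degenerate: bool = False


@dataclass(frozen=True)
class BatchCoxFits:
    """Vectorized univariate Cox fits for the p columns of a matrix."""

    bhat: np.ndarray
    se: np.ndarray
    z: np.ndarray
    loglik_mle: np.ndarray
    loglik_null: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray

    @property
    def p(self) -> int:
        return len(self.bhat)

    def __getitem__(self, j: int) -> UnivariateCoxFit:
        return UnivariateCoxFit(
            bhat=float(self.bhat[j]), se=float(self.se[j]),
            z=float(self.z[j]), loglik_mle=float(self.loglik_mle[j]),
            loglik_null=float(self.loglik_null[j]),
            converged=bool(self.converged[j]),
            degenerate=bool(self.degenerate[j]))


# ---------------------------------------------------------------------------
# batched partial log-likelihood, gradient and Hessian
# ---------------------------------------------------------------------------

def _revcumsum(a: np.ndarray) -> np.ndarray:
    """Suffix cumulative sum along the last axis."""
    return np.cumsum(a[..., ::-1], axis=-1)[..., ::-1]


def _batch_eval(b: np.ndarray, XsT: np.ndarray, cs: np.ndarray,
                layout: _RiskSetLayout, ties: str, derivs: bool = True):
    """Partial log-likelihood (and optionally gradient, Hessian) for all
    rows of ``XsT`` (one covariate per row) at per-row coefficients ``b``.

    ``XsT`` (p, n) and ``cs`` (n,) must already be in sorted
    (ascending-time) order along the sample axis; working row-major keeps
    the risk-set suffix sums contiguous.  Returns arrays of shape (p,).
    The per-row max of the linear predictor is subtracted before
    exponentiating; the partial likelihood is invariant to this shift.
    """
    starts = layout.group_starts
    eg = layout.event_groups
    d_eg = layout.d[eg].astype(np.float64)
    ev = layout.delta_sorted.astype(bool)

    eta = cs[None, :] + XsT * b[:, None]
    eta -= eta.max(axis=1, keepdims=True)
    w = np.exp(eta)

    r0 = _revcumsum(np.add.reduceat(w, starts, axis=1))[:, eg]
    ll = eta[:, ev].sum(axis=1)
    if derivs:
        wx = w * XsT
        wxx = wx * XsT
        r1 = _revcumsum(np.add.reduceat(wx, starts, axis=1))[:, eg]
        r2 = _revcumsum(np.add.reduceat(wxx, starts, axis=1))[:, eg]
        grad = XsT[:, ev].sum(axis=1)
        hess = np.zeros(XsT.shape[0])

    if ties == "breslow" or layout.max_mult == 1:
        ll -= (d_eg * np.log(r0)).sum(axis=1)
        if derivs:
            m1 = r1 / r0
            grad -= (d_eg * m1).sum(axis=1)
            hess -= (d_eg * (r2 / r0 - m1 * m1)).sum(axis=1)
    else:  # Efron: average the tied events out of the risk set
        evf = np.where(ev, 1.0, 0.0)[None, :]
        d0 = np.add.reduceat(w * evf, starts, axis=1)[:, eg]
        if derivs:
            d1 = np.add.reduceat(wx * evf, starts, axis=1)[:, eg]
            d2 = np.add.reduceat(wxx * evf, starts, axis=1)[:, eg]
        for k in range(layout.max_mult):
            cols = d_eg > k
            frac = (k / d_eg[cols])[None, :]
            den = r0[:, cols] - frac * d0[:, cols]
            ll -= np.log(den).sum(axis=1)
            if derivs:
                n1 = (r1[:, cols] - frac * d1[:, cols]) / den
                grad -= n1.sum(axis=1)
                hess -= ((r2[:, cols] - frac * d2[:, cols]) / den
                         - n1 * n1).sum(axis=1)

    if derivs:
        return ll, grad, hess
    return ll


def _check_ties(ties: str) -> str:
    if ties not in TIE_METHODS:
        raise ValueError(f"ties must be one of {TIE_METHODS}, got {ties!r}")
    return ties


def _prepare(x: np.ndarray, outcome: SurvivalOutcome,
             offset) -> tuple[np.ndarray, np.ndarray]:
    """Validate shapes; return (X transposed to (p, n), offset), both
    re-ordered by ascending time."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != outcome.n:
        raise ValueError(f"covariate rows ({x.shape[0]}) do not match "
                         f"sample count ({outcome.n})")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    if offset is None:
        c = np.zeros(outcome.n)
    else:
        c = np.asarray(offset, dtype=np.float64)
        if c.shape != (outcome.n,):
            raise ValueError("offset length does not match sample count")
        if not np.all(np.isfinite(c)):
            raise ValueError("offsets must be finite")
    if outcome.n_events == 0:
        raise ValueError("no events: the partial likelihood is undefined "
                         "when every sample is censored")
    order = outcome.layout.order
    return np.ascontiguousarray(x[order].T), c[order]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def partial_loglik(b: float, x: np.ndarray, outcome: SurvivalOutcome,
                   offset: np.ndarray | None = None,
                   ties: str = "efron") -> float:
    """Cox partial log-likelihood log l(b; x, c) at coefficient ``b``.

    Invariant to adding a constant to all offsets and to any strictly
    increasing transform of the observed times.
    """
    _check_ties(ties)
    if not np.isfinite(b):
        raise ValueError("coefficient b must be finite")
    Xs, cs = _prepare(x, outcome, offset)
    ll = _batch_eval(np.array([float(b)]), Xs, cs, outcome.layout, ties,
                     derivs=False)
    return float(ll[0])


def batch_univariate_coxph(X: np.ndarray, outcome: SurvivalOutcome,
                           offset: np.ndarray | None = None,
                           ties: str = "efron", tol: float = 1e-8,
                           max_newton_iter: int = 25) -> BatchCoxFits:
    """Fit a univariate Cox model to every column of ``X`` by Newton-Raphson.

    All columns are iterated simultaneously; step-halving guards against
    likelihood decreases and |bhat| is capped at ``B_CAP`` (complete
    separation, flagged as non-converged).  Zero-variance columns take the
    degenerate path: bhat = 0, loglik_mle = loglik_null, se = +inf.
    """
    _check_ties(ties)
    XsT, cs = _prepare(X, outcome, offset)
    layout = outcome.layout
    p = XsT.shape[0]

    nondeg = (XsT.max(axis=1) - XsT.min(axis=1)) > 0
    b = np.zeros(p)
    ll, g, h = _batch_eval(b, XsT, cs, layout, ties)
    ll_null = ll.copy()
    # likelihood comparisons are only meaningful above roundoff scale
    ll_noise = 1e-10 * (1.0 + np.abs(ll_null))

    for _ in range(max_newton_iter):
        active = nondeg & (np.abs(g) > tol) & (np.abs(b) < B_CAP)
        if not active.any():
            break
        # Newton step where curvature is informative; unit step toward the
        # gradient where it is not (monotone likelihood).
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(h < -1e-300, -g / h, np.sign(g))
        step = np.clip(step, -5.0, 5.0)
        b_try = np.clip(b + np.where(active, step, 0.0), -B_CAP, B_CAP)
        ll_new, g_new, h_new = _batch_eval(b_try, XsT, cs, layout, ties)
        for _halve in range(30):
            worse = active & (ll_new < ll - ll_noise)
            if not worse.any() or np.max(np.abs(b_try - b)[worse]) < 1e-12:
                break
            b_try = np.where(worse, 0.5 * (b + b_try), b_try)
            ll_new, g_new, h_new = _batch_eval(b_try, XsT, cs, layout, ties)
        b, ll, g, h = b_try, ll_new, g_new, h_new

    separated = nondeg & (np.abs(b) >= B_CAP)
    converged = nondeg & (np.abs(g) <= tol) & ~separated
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(nondeg & (h < 0), np.sqrt(-1.0 / np.where(h < 0, h, -1)),
                      np.inf)
    bhat = np.where(nondeg, b, 0.0)
    ll_mle = np.where(nondeg, ll, ll_null)
    with np.errstate(invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), bhat / se, 0.0)
    return BatchCoxFits(bhat=bhat, se=se, z=z, loglik_mle=ll_mle,
                        loglik_null=ll_null, converged=converged,
                        degenerate=~nondeg)


def fit_univariate_coxph(x: np.ndarray, outcome: SurvivalOutcome,
                         offset: np.ndarray | None = None,
                         ties: str = "efron", tol: float = 1e-8,
                         max_newton_iter: int = 25) -> UnivariateCoxFit:
    """Fit a single-covariate Cox model; see :func:`batch_univariate_coxph`."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("x must be a 1-d covariate vector")
    fits = batch_univariate_coxph(x[:, None], outcome, offset, ties, tol,
                                  max_newton_iter)
    return fits[0]


def fit_covariate_offsets(Z: np.ndarray, outcome: SurvivalOutcome,
                          ties: str = "efron", tol: float = 1e-8,
                          max_iter: int = 50,
                          column_names: Sequence[str] | None = None
                          ) -> np.ndarray:
    """Estimate per-sample offsets from m fixed covariates.

    Fits a Cox model with only the fixed covariates (no genetic variant)
    and returns the fitted linear predictor w-hat' z_i, centered to mean
    zero (the partial likelihood is shift-invariant, so centering is
    free).  Constant columns are unidentifiable in a partial likelihood
    and are dropped; exact collinearity is an error naming the columns.
    """
    _check_ties(ties)
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != outcome.n:
        raise ValueError("covariate rows do not match sample count")
    if column_names is None:
        column_names = [f"col{j}" for j in range(Z.shape[1])]

    keep = (Z.max(axis=0) - Z.min(axis=0)) > 0
    if not keep.any():
        return np.zeros(outcome.n)
    Zk = Z[:, keep] - Z[:, keep].mean(axis=0)
    kept_names = [nm for nm, k in zip(column_names, keep) if k]

    # exact collinearity check via QR
    r_diag = np.abs(np.diag(np.linalg.qr(Zk, mode="r")))
    bad = r_diag < 1e-10 * max(r_diag.max(), 1.0)
    if bad.any():
        names = ", ".join(nm for nm, bd in zip(kept_names, bad) if bd)
        raise ValueError(f"collinear covariate columns: {names}")

    layout = outcome.layout
    order = layout.order
    Zs = Zk[order]
    m = Zs.shape[1]
    w = np.zeros(m)
    ll = _mv_loglik(w, Zs, layout, ties)
    for _ in range(max_iter):
        grad, hess = _mv_derivs(w, Zs, layout, ties)
        if np.max(np.abs(grad)) <= tol:
            break
        step = np.linalg.solve(-hess, grad)
        w_try = w + step
        ll_new = _mv_loglik(w_try, Zs, layout, ties)
        for _halve in range(30):
            if ll_new >= ll - 1e-12:
                break
            w_try = 0.5 * (w + w_try)
            ll_new = _mv_loglik(w_try, Zs, layout, ties)
        w, ll = w_try, ll_new
    else:
        warnings.warn("covariate-offset Newton-Raphson did not converge")

    offsets = Zk @ w
    return offsets - offsets.mean()


def _mv_loglik(w: np.ndarray, Zs: np.ndarray, layout: _RiskSetLayout,
               ties: str) -> float:
    eta = Zs @ w
    eta = eta - eta.max()
    ex = np.exp(eta)
    starts = layout.group_starts
    eg = layout.event_groups
    d_eg = layout.d[eg].astype(np.float64)
    ev = layout.delta_sorted.astype(bool)
    r0 = _revcumsum(np.add.reduceat(ex, starts))[eg]
    ll = eta[ev].sum()
    if ties == "breslow" or layout.max_mult == 1:
        return float(ll - (d_eg * np.log(r0)).sum())
    d0 = np.add.reduceat(np.where(ev, ex, 0.0), starts)[eg]
    for k in range(layout.max_mult):
        rows = d_eg > k
        frac = k / d_eg[rows]
        ll -= np.log(r0[rows] - frac * d0[rows]).sum()
    return float(ll)


def _mv_derivs(w: np.ndarray, Zs: np.ndarray, layout: _RiskSetLayout,
               ties: str) -> tuple[np.ndarray, np.ndarray]:
    eta = Zs @ w
    eta = eta - eta.max()
    ex = np.exp(eta)
    starts = layout.group_starts
    eg = layout.event_groups
    d_eg = layout.d[eg].astype(np.float64)
    ev = layout.delta_sorted.astype(bool)

    def _suffix0(a):
        return np.cumsum(a[::-1], axis=0)[::-1]

    wz = ex[:, None] * Zs                                   # (n, m)
    wzz = wz[:, :, None] * Zs[:, None, :]                   # (n, m, m)
    r0 = _suffix0(np.add.reduceat(ex, starts))[eg]
    r1 = _suffix0(np.add.reduceat(wz, starts, axis=0))[eg]
    r2 = _suffix0(np.add.reduceat(wzz, starts, axis=0))[eg]
    grad = Zs[ev].sum(axis=0)
    hess = np.zeros((Zs.shape[1], Zs.shape[1]))

    if ties == "breslow" or layout.max_mult == 1:
        m1 = r1 / r0[:, None]
        grad -= (d_eg[:, None] * m1).sum(axis=0)
        hess -= np.einsum("g,gij->ij", d_eg, r2 / r0[:, None, None])
        hess += np.einsum("g,gi,gj->ij", d_eg, m1, m1)
        return grad, hess

    evf = np.where(ev, 1.0, 0.0)
    d0 = np.add.reduceat(ex * evf, starts)[eg]
    d1 = np.add.reduceat(wz * evf[:, None], starts, axis=0)[eg]
    d2 = np.add.reduceat(wzz * evf[:, None, None], starts, axis=0)[eg]
    for k in range(layout.max_mult):
        rows = d_eg > k
        frac = k / d_eg[rows]
        den = r0[rows] - frac * d0[rows]
        n1 = (r1[rows] - frac[:, None] * d1[rows]) / den[:, None]
        n2 = (r2[rows] - frac[:, None, None] * d2[rows]) / den[:, None, None]
        grad -= n1.sum(axis=0)
        hess -= n2.sum(axis=0) - np.einsum("gi,gj->ij", n1, n1)
    return grad, hess
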