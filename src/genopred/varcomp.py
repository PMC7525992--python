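"""REML variance components and GBLUP for one or two relationship matrices.

The model is y = 1*mu + sum_i Z g_i + e with var(g_i) = G_i * sigma2_a_i
and var(e) = I * sigma2_e, fitted to pre-adjusted phenotypes (so the only
fixed effect is the intercept). The single-matrix case is solved exactly:
one eigendecomposition of G reduces REML to a 1-D search over the
heritability ratio. The multi-matrix case runs average-information (AI)
updates with expectation-maximization fallback steps whenever AI proposes
a negative component, which keeps every component nonnegative.

Prediction uses the BLUP identity g_hat_i = s2_i * G_i[:, ref] *
V_rr^{-1} (y_ref - mu_hat): validation individuals appear only through
their relationship rows, never through their phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar

from .grm import GRM

MAX_ITER = 100
LOGLIK_TOL = 1e-8
_VAR_FLOOR_FRAC = 1e-8


class RemlError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory or []


@dataclass
class VarianceComponents:
    sigma2_a: np.ndarray  # one entry per GRM
    sigma2_e: float
    se: np.ndarray  # SEs for (sigma2_a..., sigma2_e)
    loglik: float
    n_iter: int
    converged: bool
    n: int
    method: str = "ai"

    def __post_init__(self) -> None:
        self.sigma2_a = np.atleast_1d(np.asarray(self.sigma2_a, dtype=float))

    @property
    def h2_components(self) -> np.ndarray:
        tot = self.sigma2_a.sum() + self.sigma2_e
        return self.sigma2_a / tot

    @property
    def h2(self) -> float:
        return float(self.h2_components.sum())


@dataclass
class GbvResult:
    """Per-individual predicted breeding values, total and per component."""

    table: pd.DataFrame  # id, g1[, g2], gbv, is_reference
    model: str = "gblup"

    @property
    def gbv(self) -> np.ndarray:
        return self.table["gbv"].to_numpy()


def _check_alignment(y, grms):
    n = len(y)
    for G in grms:
        if G.n != n:
            raise ValueError("GRMs and phenotype vector must share sample order")


def _reml_pieces(y, X, V):
    """(loglik, P, Vinv) for the current V; loglik drops the 2*pi constant."""
    c, low = scipy.linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = scipy.linalg.cho_solve((c, low), np.eye(V.shape[0]))
    VX = Vinv @ X
    XtVX = X.T @ VX
    XtVX_inv = np.linalg.inv(XtVX)
    P = Vinv - VX @ XtVX_inv @ VX.T
    Py = P @ y
    ll = -0.5 * (logdet_v + np.linalg.slogdet(XtVX)[1] + float(y @ Py))
    return ll, P, Py


def _ai_matrix(y, P, Py, v_derivs):
    k = len(v_derivs)
    ai = np.empty((k, k))
    pvpy = [P @ (Vd @ Py) for Vd in v_derivs]
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * float(Py @ (v_derivs[i] @ pvpy[j]))
    return ai


def reml_fit(y_adj, grms, method: str = "auto", max_iter: int = MAX_ITER) -> VarianceComponents:
    """Estimate variance components by REML.

    ``grms`` is a list of one or two GRM objects. ``method``: "auto" uses
    the exact eigendecomposition path for a single GRM and AI-REML
    otherwise; "ai" forces AI-REML; "eigen" is valid only for one GRM.
    Standard errors come from the inverse average-information matrix
    evaluated at the estimates.
    """
    y = np.asarray(y_adj, dtype=float)
    grms = list(grms)
    if not 1 <= len(grms) <= 2:
        raise ValueError("reml_fit supports one or two GRMs")
    _check_alignment(y, grms)
    if method == "eigen" and len(grms) > 1:
        raise ValueError("eigen path only applies to a single GRM")
    if method == "auto":
        method = "eigen" if len(grms) == 1 else "ai"
    if method == "eigen":
        return _reml_fit_eigen(y, grms[0])
    return _reml_fit_ai(y, grms, max_iter=max_iter)


def _reml_fit_eigen(y, G: GRM) -> VarianceComponents:
    n = y.size
    evals, evecs = scipy.linalg.eigh(G.ridged())
    evals = np.clip(evals, 0.0, None)
    yt = evecs.T @ y
    xt = evecs.T @ np.ones(n)

    def negll(theta):
        # theta = sigma2_a / (sigma2_a + sigma2_e), profiled over total scale
        lam = theta / (1.0 - theta)
        d = lam * evals + 1.0
        xvx = np.sum(xt * xt / d)
        xvy = np.sum(xt * yt / d)
        yvy = np.sum(yt * yt / d)
        ypy = yvy - xvy * xvy / xvx
        s2e = ypy / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2e) + np.sum(np.log(d)) + np.log(xvx) + (n - 1))

    res = minimize_scalar(negll, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                          options={"xatol": 1e-12})
    theta = float(res.x)
    lam = theta / (1.0 - theta)
    d = lam * evals + 1.0
    xvx = np.sum(xt * xt / d)
    xvy = np.sum(xt * yt / d)
    yvy = np.sum(yt * yt / d)
    s2e = (yvy - xvy**2 / xvx) / (n - 1)
    s2a = lam * s2e

    # SEs and the comparable loglik from the general machinery at the optimum
    V = s2a * G.ridged() + s2e * np.eye(n)
    ll, P, Py = _reml_pieces(y, np.ones((n, 1)), V)
    ai = _ai_matrix(y, P, Py, [G.ridged(), np.eye(n)])
    se = _se_from_ai(ai)
    return VarianceComponents(
        sigma2_a=np.array([s2a]), sigma2_e=float(s2e), se=se, loglik=float(ll),
        n_iter=int(res.nfev), converged=bool(res.success), n=n, method="eigen",
    )


def _se_from_ai(ai):
    try:
        cov = np.linalg.inv(ai)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(ai.shape[0], np.nan)


def _constrained_ai_proposal(theta, score, ai, floor):
    """AI step with an active set: components pushed below the floor are
    pinned there and the step is re-solved on the remainder."""
    k = theta.size
    active = np.ones(k, dtype=bool)
    for _ in range(k):
        if not active.any():
            return np.full(k, floor)
        try:
            delta = np.linalg.solve(ai[np.ix_(active, active)], score[active])
        except np.linalg.LinAlgError:
            return None
        prop = np.full(k, floor)
        prop[active] = theta[active] + delta
        neg = (prop < floor) & active
        if not neg.any():
            return prop
        active &= ~neg
    return None


def _reml_fit_ai(y, grms, max_iter: int = MAX_ITER) -> VarianceComponents:
    n = y.size
    X = np.ones((n, 1))
    mats = [G.ridged() for G in grms] + [np.eye(n)]
    vary = float(np.var(y, ddof=1))
    floor = _VAR_FLOOR_FRAC * vary
    theta = np.full(len(mats), vary / len(mats))

    trajectory = []
    ll, P, Py = _reml_pieces(y, X, sum(t * M for t, M in zip(theta, mats)))
    for it in range(1, max_iter + 1):
        trajectory.append((it, theta.copy(), ll))
        score = np.array(
            [-0.5 * (np.sum(P * M) - float(Py @ (M @ Py))) for M in mats]
        )
        ai = _ai_matrix(y, P, Py, mats)
        proposal = _constrained_ai_proposal(theta, score, ai, floor)
        if proposal is None:
            # EM fallback keeps components nonnegative
            proposal = np.maximum(
                np.array(
                    [t + t * t * (float(Py @ (M @ Py)) - np.sum(P * M)) / n
                     for t, M in zip(theta, mats)]
                ),
                floor,
            )

        # step-halving toward the current theta if the step lowers loglik
        accepted = False
        for _ in range(12):
            try:
                ll_new, P_new, Py_new = _reml_pieces(
                    y, X, sum(t * M for t, M in zip(proposal, mats))
                )
            except np.linalg.LinAlgError:
                ll_new = -np.inf
            if ll_new >= ll - 1e-10:
                accepted = True
                break
            proposal = 0.5 * (proposal + theta)
        if not accepted:
            # cannot improve: current point is (numerically) the optimum
            ll_new, P_new, Py_new = ll, P, Py
            proposal = theta

        converged = abs(ll_new - ll) < LOGLIK_TOL and it > 1
        theta, ll, P, Py = proposal, ll_new, P_new, Py_new
        if converged:
            return VarianceComponents(
                sigma2_a=theta[:-1].copy(), sigma2_e=float(theta[-1]),
                se=_se_from_ai(_ai_matrix(y, P, Py, mats)), loglik=float(ll),
                n_iter=it, converged=True, n=n, method="ai",
            )

    raise RemlError(
        f"REML did not converge in {max_iter} iterations", trajectory
    )


def gblup_predict(
    y_adj,
    grms,
    vc: VarianceComponents,
    reference_mask,
    sample_ids=None,
    model: str = "gblup",
) -> GbvResult:
    """BLUP breeding values for every individual in the GRMs.

    ``reference_mask`` flags the training individuals; phenotypes of the
    others are never read. Per-component effects are returned for
    two-matrix models, and the total GBV is their sum.
    """
    y = np.asarray(y_adj, dtype=float)
    grms = list(grms)
    _check_alignment(y, grms)
    ref = np.asarray(reference_mask, dtype=bool)
    n = y.size
    if vc.sigma2_a.size != len(grms):
        raise ValueError("variance components do not match the number of GRMs")

    v_rr = vc.sigma2_e * np.eye(int(ref.sum()))
    for s2, G in zip(vc.sigma2_a, grms):
        v_rr += s2 * G.ridged()[np.ix_(ref, ref)]
    try:
        c, low = scipy.linalg.cho_factor(v_rr, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular reference covariance: {exc}") from exc
    ones = np.ones(int(ref.sum()))
    vinv_y = scipy.linalg.cho_solve((c, low), y[ref])
    vinv_1 = scipy.linalg.cho_solve((c, low), ones)
    mu = float(ones @ vinv_y) / float(ones @ vinv_1)
    resid_rot = scipy.linalg.cho_solve((c, low), y[ref] - mu * ones)

    comps = []
    for s2, G in zip(vc.sigma2_a, grms):
        comps.append(s2 * (G.matrix[:, ref] @ resid_rot))
    total = np.sum(comps, axis=0)

    if sample_ids is None:
        sample_ids = grms[0].sample_ids
    data = {"id": np.asarray(sample_ids, dtype=object)}
    for i, comp in enumerate(comps, start=1):
        data[f"g{i}"] = comp
    data["gbv"] = total
    data["is_reference"] = ref
    return GbvResult(table=pd.DataFrame(data), model=model)
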