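"""Maximum-likelihood linear mixed model with random intercept and slope.

Fits the longitudinal submodel

    y_ij = x_ij' beta + b0_i + b1_i * t_ij + eps_ij,
    (b0, b1) ~ N(0, D),   eps ~ N(0, sigma^2),

by maximizing the exact marginal Gaussian likelihood.  The variance
components are parameterized through an unconstrained log-Cholesky transform
of D plus log sigma, and the fixed effects are profiled out by generalized
least squares at each variance-parameter value, so the optimizer works in
only four dimensions.  Subject-level random effects are recovered as BLUPs,
with their conditional (posterior) covariances retained for downstream use
as quadrature centres in the joint model.

The default objective is ML rather than REML, matching the likelihood that a
joint longitudinal-survival model maximizes for the same submodel; REML is
available via ``method="reml"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from jmsim.synthetic_data import TrajectorySpec

__all__ = ["LmmFit", "fit_lmm", "predict_blup"]

_LOG_SIGMA_MIN = np.log(1e-6)  # residual-SD floor on the log scale


def _design_matrices(long_df, surv_df, trajectory):
    """Per-row X = [1, f(t), age] and Z = [1, t]; returns subject blocks."""
    age_map = surv_df.set_index("id")["age"]
    ids = long_df["id"].to_numpy()
    t = long_df["time_weeks"].to_numpy(dtype=float)
    y = long_df["y"].to_numpy(dtype=float)
    age = age_map.reindex(ids).to_numpy(dtype=float)
    if np.any(np.isnan(age)):
        raise ValueError("longitudinal rows reference ids absent from survival table")
    if trajectory.kind == "linear":
        ft = t[:, None]
    else:
        ft = trajectory.spline_basis(t)
    X = np.column_stack([np.ones_like(t), ft, age])
    Z = np.column_stack([np.ones_like(t), t])
    order = np.argsort(ids, kind="stable")
    ids_s = ids[order]
    uniq, starts = np.unique(ids_s, return_index=True)
    bounds = np.r_[starts, ids_s.size]
    blocks = []
    for k, sid in enumerate(uniq):
        idx = order[bounds[k] : bounds[k + 1]]
        blocks.append((sid, X[idx], Z[idx], y[idx]))
    return blocks


def _group_blocks(blocks):
    """Batch subjects sharing one visit-time pattern (V_i identical within).

    With scheduled visits the number of distinct patterns is tiny, so the
    profiled likelihood reduces to a handful of dense solves regardless of
    the number of subjects.
    """
    by_pattern = {}
    for sid, X, Z, y in blocks:
        key = tuple(Z[:, 1])
        by_pattern.setdefault(key, []).append((sid, X, y, Z))
    groups = []
    for members in by_pattern.values():
        Z = members[0][3]
        Xs = np.stack([m[1] for m in members])  # (g, J, p)
        ys = np.stack([m[2] for m in members])  # (g, J)
        sids = [m[0] for m in members]
        groups.append((sids, Xs, Z, ys))
    return groups


def _theta_to_cov(theta, tscale=1.0):
    """Unconstrained theta -> (D, sigma).

    theta = (l0, l1, c, log_sigma) parameterizes the Cholesky factor of the
    *time-scaled* covariance S D S with S = diag(1, tscale): slope random
    effects are internally carried per ``tscale`` time units so that all
    four coordinates have comparable curvature.
    """
    l0, l1, c, log_sigma = theta
    L = np.array([[np.exp(l0), 0.0], [c, np.exp(l1)]])
    Sinv = np.diag([1.0, 1.0 / tscale])
    return Sinv @ (L @ L.T) @ Sinv, np.exp(max(log_sigma, _LOG_SIGMA_MIN))


def _profiled_loglik(theta, groups, reml=False, tscale=1.0):
    """Profile beta out by GLS; return (loglik, beta, cov_beta)."""
    D, sigma = _theta_to_cov(theta, tscale)
    s2 = sigma * sigma
    p = groups[0][1].shape[2]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    N = 0
    cache = []
    try:
        for sids, Xs, Z, ys in groups:
            V = Z @ D @ Z.T + s2 * np.eye(Z.shape[0])
            Vinv = np.linalg.inv(V)
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return None
            g = len(sids)
            logdet += g * ld
            N += g * Z.shape[0]
            VX = np.einsum("jk,gkp->gjp", Vinv, Xs)
            XtVX += np.einsum("gjp,gjq->pq", Xs, VX)
            XtVy += np.einsum("gjp,gj->p", VX, ys)
            cache.append((Xs, ys, Vinv))
        beta = np.linalg.solve(XtVX, XtVy)
        quad = 0.0
        for Xs, ys, Vinv in cache:
            r = ys - Xs @ beta
            quad += np.einsum("gj,jk,gk->", r, Vinv, r)
        ll = -0.5 * (N * np.log(2 * np.pi) + logdet + quad)
        if reml:
            sign, ld = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return None
            ll += 0.5 * p * np.log(2 * np.pi) - 0.5 * ld
        cov_beta = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError:
        return None
    return ll, beta, cov_beta


def _profiled_nll_grad(theta, groups, tscale):
    """Negative profiled ML loglik and its analytic gradient.

    Uses the envelope theorem: beta is the GLS maximizer at theta, so the
    gradient with respect to the variance parameters can be taken at fixed
    beta,
        d ll / d p = -1/2 sum_i [ tr(V^-1 dV) - r_i' V^-1 dV V^-1 r_i ].
    """
    out = _profiled_loglik(theta, groups, False, tscale)
    if out is None or not np.isfinite(out[0]):
        return 1e10, np.zeros(4)
    ll, beta, _ = out
    l0, l1, c, log_sigma = theta
    a, b = np.exp(l0), np.exp(l1)
    L = np.array([[a, 0.0], [c, b]])
    Sinv = np.diag([1.0, 1.0 / tscale])
    sigma = np.exp(max(log_sigma, _LOG_SIGMA_MIN))
    s2 = sigma * sigma
    D = Sinv @ (L @ L.T) @ Sinv
    # dD/dp = Sinv (dL L' + L dL') Sinv for the three Cholesky parameters
    dLs = [
        np.array([[a, 0.0], [0.0, 0.0]]),   # d/dl0
        np.array([[0.0, 0.0], [0.0, b]]),   # d/dl1
        np.array([[0.0, 0.0], [1.0, 0.0]]), # d/dc
    ]
    dDs = [Sinv @ (dL @ L.T + L @ dL.T) @ Sinv for dL in dLs]
    grad = np.zeros(4)
    for sids, Xs, Z, ys in groups:
        J = Z.shape[0]
        V = Z @ D @ Z.T + s2 * np.eye(J)
        Vinv = np.linalg.inv(V)
        g = len(sids)
        U = np.einsum("jk,gk->gj", Vinv, ys - Xs @ beta)  # V^-1 r_i
        for k, dD in enumerate(dDs):
            dV = Z @ dD @ Z.T
            tr = g * np.trace(Vinv @ dV)
            quad = np.einsum("gj,jk,gk->", U, dV, U)
            grad[k] += 0.5 * (tr - quad)
        # d/d log_sigma: dV = 2 sigma^2 I
        tr = g * 2.0 * s2 * np.trace(Vinv)
        quad = 2.0 * s2 * np.einsum("gj,gj->", U, U)
        grad[3] += 0.5 * (tr - quad)
    if log_sigma < _LOG_SIGMA_MIN:
        grad[3] = 0.0  # clamped at the floor
    return -ll, grad


@dataclass
class LmmFit:
    """Fitted linear mixed model.

    ``blups`` maps subject id -> (b0_hat, b1_hat); ``blup_cov`` maps id ->
    2x2 conditional covariance of the random effects given the data.
    """

    beta_hat: np.ndarray
    D_hat: np.ndarray
    sigma_hat: float
    se_beta: np.ndarray
    loglik: float
    converged: bool
    blups: dict = field(default_factory=dict)
    blup_cov: dict = field(default_factory=dict)
    ages: dict = field(default_factory=dict)
    trajectory_kind: str = "linear"
    trajectory: TrajectorySpec | None = None
    method: str = "ml"
    n_subjects: int = 0
    n_obs: int = 0

    def to_dict(self) -> dict:
        return {
            "beta_hat": list(map(float, self.beta_hat)),
            "D_hat": self.D_hat.tolist(),
            "sigma_hat": float(self.sigma_hat),
            "se_beta": list(map(float, self.se_beta)),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "method": self.method,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }


def fit_lmm(
    long_df: pd.DataFrame,
    surv_df: pd.DataFrame,
    trajectory: TrajectorySpec | None = None,
    method: str = "ml",
    gtol: float = 1e-8,
    maxiter: int = 500,
) -> LmmFit:
    """Fit the random-intercept-and-slope model by maximum likelihood.

    ``long_df`` needs columns (id, time_weeks, y); ``surv_df`` supplies the
    baseline age covariate.  ``trajectory`` selects the fixed-effect time
    basis (linear by default; a spline spec reuses its basis columns).
    """
    if trajectory is None:
        trajectory = TrajectorySpec()
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    blocks = _design_matrices(long_df, surv_df, trajectory)
    if len(blocks) < 2:
        raise ValueError("need at least 2 subjects")
    groups = _group_blocks(blocks)
    reml = method == "reml"

    # data-driven start: OLS residual SD split between components
    Xall = np.vstack([X for _, X, _, _ in blocks])
    yall = np.concatenate([y for _, _, _, y in blocks])
    beta_ols, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    resid = yall - Xall @ beta_ols
    s0 = max(np.std(resid), 1e-4)
    # slope random effects carried per tscale time units internally
    tscale = max(np.max(np.abs(Z[:, 1])) for _, _, Z, _ in blocks) or 1.0
    x0 = np.array(
        [np.log(s0 / np.sqrt(2)), np.log(s0 / np.sqrt(2)), 0.0,
         np.log(s0 / np.sqrt(2))]
    )

    if reml:

        def objective(theta):
            # numeric gradient for the REML criterion
            out = _profiled_loglik(theta, groups, reml, tscale)
            bad = out is None or not np.isfinite(out[0])
            return 1e10 if bad else -out[0]

        jac = None
    else:
        objective = lambda theta: _profiled_nll_grad(theta, groups, tscale)
        jac = True

    res = minimize(
        objective,
        x0,
        jac=jac,
        method="L-BFGS-B",
        bounds=[(-20, 5), (-20, 5), (-5, 5), (_LOG_SIGMA_MIN, 5)],
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol},
    )
    out = _profiled_loglik(res.x, groups, reml, tscale)
    if out is None:
        return LmmFit(
            beta_hat=np.full(blocks[0][1].shape[1], np.nan),
            D_hat=np.full((2, 2), np.nan),
            sigma_hat=np.nan,
            se_beta=np.full(blocks[0][1].shape[1], np.nan),
            loglik=-np.inf,
            converged=False,
            trajectory_kind=trajectory.kind,
            trajectory=trajectory,
            method=method,
        )
    ll, beta, cov_beta = out
    D, sigma = _theta_to_cov(res.x, tscale)
    se_beta = np.sqrt(np.diag(cov_beta))
    converged = bool(res.success) and np.all(np.isfinite(se_beta))

    blups, blup_cov, ages = {}, {}, {}
    s2 = sigma * sigma
    for sids, Xs, Z, ys in groups:
        V = Z @ D @ Z.T + s2 * np.eye(Z.shape[0])
        DZt = D @ Z.T
        Vinv = np.linalg.inv(V)
        bhat = np.einsum("ij,jk,gk->gi", DZt, Vinv, ys - Xs @ beta)
        cov_b = D - DZt @ Vinv @ DZt.T
        for k, sid in enumerate(sids):
            blups[sid] = bhat[k]
            blup_cov[sid] = cov_b
            ages[sid] = float(Xs[k, 0, -1])

    return LmmFit(
        beta_hat=beta,
        D_hat=D,
        sigma_hat=float(sigma),
        se_beta=se_beta,
        loglik=float(ll),
        converged=converged,
        blups=blups,
        blup_cov=blup_cov,
        ages=ages,
        trajectory_kind=trajectory.kind,
        trajectory=trajectory,
        method=method,
        n_subjects=len(blocks),
        n_obs=len(yall),
    )


def predict_blup(fit: LmmFit, subject_id, t, age: float | None = None):
    """Subject-specific prediction m_hat_i(t) = x(t)'beta_hat + z(t)'b_hat.

    Defined for any t >= 0: the second stage of the two-stage approach needs
    predictions at event times beyond a subject's last measurement, so
    extrapolation is deliberate.  ``age`` defaults to the age stored at fit
    time for this subject.
    """
    if subject_id not in fit.blups:
        raise KeyError(f"unknown subject id {subject_id!r}")
    t = np.asarray(t, dtype=float)
    if age is None:
        age = fit.ages[subject_id]
    traj = fit.trajectory
    if fit.trajectory_kind == "linear":
        ft = t[..., None]
    else:
        ft = traj.spline_basis(np.ravel(t)).reshape(t.shape + (traj.n_basis,))
    beta = fit.beta_hat
    fixed = beta[0] + ft @ beta[1:-1] + beta[-1] * age
    b0, b1 = fit.blups[subject_id]
    out = fixed + b0 + b1 * t
    return out if out.ndim else float(out)
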