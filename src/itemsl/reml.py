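"""Restricted maximum likelihood calibration of the trial covariance.

LS-A estimates carry two sources of trial-by-trial (co)variance: natural
trial-to-trial variability of the underlying response amplitudes (isotropic,
``l1 * I``) and correlation induced by overlapping HRF regressors in the
trial-wise design (``l2 * U``).  This module fits the two-component mixture

    Cov = l1 * I + l2 * U

to trial-wise estimates pooled over voxels by Fisher scoring on the
restricted log-likelihood, treating voxels as replicates and the
transformation matrix T as the fixed-effects design.  Because both
components are diagonal in U's eigenbasis, every iteration is exact and
cheap (O(t^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
from scipy.linalg import block_diag

from .estimators import TrialEstimates

__all__ = ["ReMLFit", "reml_covariance", "reml_calibrate"]

MAX_ITER = 32
TOL = 1e-6


@dataclass
class ReMLFit:
    """Fitted variance-component mixture ``l1 * I + l2 * U``."""

    variance_weights: np.ndarray  # (n_components,) or (n_sessions, n_components)
    calibrated_cov: np.ndarray
    log_likelihood_trace: list = field(default_factory=list)
    converged: bool = True


def reml_covariance(
    gamma: np.ndarray,
    U: np.ndarray,
    T: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> ReMLFit:
    """Fit ``Cov = l1 * I + l2 * U`` to one session's t x v estimate block.

    Parameters
    ----------
    gamma : ndarray (t, v)
        Trial-wise estimates; voxels are treated as independent replicates
        (the spatial covariance is absorbed by the decoding weights).
    U : ndarray (t, t)
        Design-induced uncorrelation matrix.
    T : ndarray (t, p), optional
        Fixed-effects design restricted out of the likelihood; defaults to a
        constant column.
    """
    gamma = np.atleast_2d(np.asarray(gamma, float))
    t, v = gamma.shape
    if v < 2:
        raise ValueError("ReML calibration needs at least 2 voxels")
    if T is None:
        T = np.ones((t, 1))
    T = np.atleast_2d(np.asarray(T, float))

    # simultaneous diagonalization: U = Q diag(d) Q'
    d, Q = np.linalg.eigh(U)
    d = np.maximum(d, 0.0)
    g = Q.T @ gamma          # rotated estimates
    Td = Q.T @ T             # rotated fixed effects
    comps = np.stack([np.ones(t), d])  # diagonal of each component in this basis

    # moment-matched start: split total variance evenly between components
    total = np.mean(gamma**2)
    lam = np.full(2, total / (comps.mean(axis=1).sum() + 1e-12))
    floor = 1e-10 * total

    def neg2_restricted_ll(lam):
        sig = lam @ comps  # (t,)
        M = Td.T @ (Td / sig[:, None])
        PG = g / sig[:, None] - (Td / sig[:, None]) @ np.linalg.solve(M, Td.T @ (g / sig[:, None]))
        quad = float(np.sum(g * PG))
        return v * np.sum(np.log(sig)) + v * np.linalg.slogdet(M)[1] + quad, PG, sig

    trace: list[float] = []
    converged = False
    n2ll, PG, sig = neg2_restricted_ll(lam)
    for _ in range(max_iter):
        trace.append(-0.5 * n2ll)
        # P diagonal and full P (t x t): P = Sigma^-1 - Sigma^-1 T M^-1 T' Sigma^-1
        C = Td / sig[:, None]
        M = Td.T @ C
        P = np.diag(1.0 / sig) - C @ np.linalg.solve(M, C.T)
        Pdiag = np.diag(P)
        # score and Fisher information for each component
        grad = np.empty(2)
        for k in range(2):
            tr_PQ = float(comps[k] @ Pdiag)
            tr_PQPS = float(comps[k] @ np.sum(PG**2, axis=1)) / 1.0
            grad[k] = -0.5 * (v * tr_PQ - tr_PQPS)
        P2 = P**2
        fisher = 0.5 * v * np.array(
            [[comps[i] @ P2 @ comps[j] for j in range(2)] for i in range(2)]
        )
        try:
            step = np.linalg.solve(fisher + 1e-8 * np.eye(2) * np.trace(fisher), grad)
        except np.linalg.LinAlgError:
            break
        # damped update keeping weights non-negative
        scale = 1.0
        for _damp in range(8):
            cand = np.maximum(lam + scale * step, floor)
            n2ll_new, PG_new, sig_new = neg2_restricted_ll(cand)
            if n2ll_new <= n2ll + 1e-9:
                break
            scale *= 0.5
        rel = abs(n2ll_new - n2ll) / (abs(n2ll) + 1e-12)
        lam, n2ll, PG, sig = cand, n2ll_new, PG_new, sig_new
        if rel < tol:
            converged = True
            break
    trace.append(-0.5 * n2ll)
    if not converged:
        warn("ReML did not converge within the iteration limit; returning last iterate")
    cov = lam[0] * np.eye(t) + lam[1] * U
    return ReMLFit(lam, cov, trace, converged)


def reml_calibrate(
    estimates: TrialEstimates,
    T: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> ReMLFit:
    """Calibrate each session's uncorrelation matrix against the estimates.

    Runs :func:`reml_covariance` per session (the overall covariance is
    block-diagonal) with the matching rows of the design-variable matrix
    ``T`` as fixed effects.  The calibrated block-diagonal covariance is
    what the ITEM decoder uses in place of raw ``U``.
    """
    weights = []
    covs = []
    trace: list = []
    converged = True
    for sid in estimates.sessions:
        rows = estimates.session_rows(sid)
        fit = reml_covariance(
            estimates.gamma_hat[rows],
            estimates.uncorrelation[sid],
            None if T is None else np.atleast_2d(T)[rows],
            max_iter=max_iter,
            tol=tol,
        )
        weights.append(fit.variance_weights)
        covs.append(fit.calibrated_cov)
        trace.append(fit.log_likelihood_trace)
        converged &= fit.converged
    return ReMLFit(np.array(weights), block_diag(*covs), trace, converged)
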