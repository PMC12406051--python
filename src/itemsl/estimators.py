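"""Trial-wise response amplitude estimators.

LS-A ("least squares, all") fits all trial regressors jointly by weighted
least squares; LS-S ("least squares, separate") fits one two-regressor GLM
per trial (this trial vs. all other trials); the fractional-ridge estimator
shrinks LS-A-style solutions to a target fraction of the unregularized
coefficient norm, with the fraction chosen per voxel by cross-validation
across sessions.

The uncorrelation matrix ``U = (Xt' V^-1 Xt)^-1`` is the trial-by-trial
covariance that overlapping HRF regressors induce in LS-A estimates; it is
what the ITEM decoder whitens against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TrialWiseDesign

__all__ = [
    "TrialEstimates",
    "lsa_estimate",
    "lss_estimate",
    "uncorrelation_matrix",
    "fracridge_estimate",
    "FRACTION_GRID",
]

#: maximum design condition number before estimation refuses to proceed
CONDITION_LIMIT = 1e8
#: default fraction grid for fractional ridge (0.05 ... 1.00)
FRACTION_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 2)


@dataclass
class TrialEstimates:
    """Trial x voxel amplitude estimates with their induced covariance.

    ``gamma_hat`` stacks sessions row-wise (rows grouped by session);
    ``uncorrelation`` maps session id -> that session's t x t uncorrelation
    matrix U (the overall covariance is block-diagonal over sessions).
    """

    gamma_hat: np.ndarray
    session_ids: np.ndarray
    uncorrelation: dict[int, np.ndarray] = field(default_factory=dict)
    method: str = "LSA"

    def __post_init__(self) -> None:
        self.gamma_hat = np.atleast_2d(np.asarray(self.gamma_hat, dtype=float))
        self.session_ids = np.asarray(self.session_ids)
        if self.session_ids.shape[0] != self.gamma_hat.shape[0]:
            raise ValueError("session_ids length must match number of trials")

    @property
    def n_trials(self) -> int:
        return self.gamma_hat.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gamma_hat.shape[1]

    @property
    def sessions(self) -> list:
        seen: list = []
        for s in self.session_ids:
            if s not in seen:
                seen.append(s)
        return seen

    def session_rows(self, sid) -> np.ndarray:
        return np.flatnonzero(self.session_ids == sid)

    def subset_voxels(self, cols: np.ndarray) -> "TrialEstimates":
        return TrialEstimates(
            self.gamma_hat[:, cols], self.session_ids, self.uncorrelation, self.method
        )

    @staticmethod
    def concatenate(blocks: list["TrialEstimates"]) -> "TrialEstimates":
        return TrialEstimates(
            np.vstack([b.gamma_hat for b in blocks]),
            np.concatenate([b.session_ids for b in blocks]),
            {k: v for b in blocks for k, v in b.uncorrelation.items()},
            blocks[0].method,
        )


def _check_condition(xtx: np.ndarray, names: list[str] | None = None) -> None:
    c = np.linalg.cond(xtx)
    if not np.isfinite(c) or c > CONDITION_LIMIT**2:
        # cond(X'X) ~ cond(X)^2, threshold 1e8 on the design itself
        detail = ""
        if names:
            # report columns most involved in the collinearity
            w, v = np.linalg.eigh(xtx)
            worst = np.abs(v[:, 0])
            idx = np.argsort(worst)[::-1][:3]
            detail = f"; most collinear columns: {[names[i] for i in idx]}"
        raise np.linalg.LinAlgError(
            f"design is rank-deficient or ill-conditioned (cond(X) ~ {np.sqrt(c):.2e}"
            f" > {CONDITION_LIMIT:.0e}){detail}"
        )


def _gls_solve(X: np.ndarray, y: np.ndarray, design: TrialWiseDesign):
    """Weighted least squares (X' V^-1 X)^-1 X' V^-1 y via whitening."""
    W = design.whitener()
    if W is not None:
        X = W @ X
        y = W @ y
    xtx = X.T @ X
    _check_condition(xtx, design.column_names or None)
    return xtx, np.linalg.solve(xtx, X.T @ y)


def lsa_estimate(signal: np.ndarray, design: TrialWiseDesign, session_id: int = 0) -> TrialEstimates:
    """LS-A: joint weighted-least-squares estimates of all trial amplitudes.

    Nuisance coefficients are estimated jointly but excluded from the
    returned amplitude matrix.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.ndim == 2 and signal.shape[0] != design.n_scans:
        raise ValueError(
            f"signal has {signal.shape[0]} rows but design has {design.n_scans} scans"
        )
    xtx, beta = _gls_solve(design.matrix, signal, design)
    est = TrialEstimates(
        beta[design.trial_columns],
        np.full(design.n_trials, session_id),
        {session_id: uncorrelation_matrix(design)},
        method="LSA",
    )
    return est


def lss_estimate(signal: np.ndarray, design: TrialWiseDesign, session_id: int = 0) -> TrialEstimates:
    """LS-S: one GLM per trial with this-trial and all-other-trials regressors.

    The i-th estimate is the first coefficient of the i-th model; nuisance
    columns ride along in every fit.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] != design.n_scans:
        raise ValueError("signal row count must equal number of scans")
    t = design.n_trials
    if t < 2:
        raise ValueError("LS-S needs at least 2 trials; use LS-A for a single trial")
    Xt = design.trial_matrix
    nuis = design.matrix[:, design.nuisance_columns]
    total = Xt.sum(axis=1)
    W = design.whitener()
    gamma = np.empty((t, signal.shape[1]))
    for i in range(t):
        Xi = np.column_stack([Xt[:, i], total - Xt[:, i], nuis])
        yi = signal
        if W is not None:
            Xi = W @ Xi
            yi = W @ signal
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ yi)
        gamma[i] = beta[0]
    return TrialEstimates(
        gamma,
        np.full(t, session_id),
        {session_id: uncorrelation_matrix(design)},
        method="LSS",
    )


def uncorrelation_matrix(design: TrialWiseDesign) -> np.ndarray:
    """Trial-by-trial covariance U induced by the design.

    Computed as the trial block of the full ``(X' V^-1 X)^-1`` including
    nuisance columns, so covariation between trial-evoked responses and
    nuisance signals is accounted for.
    """
    X = design.matrix
    W = design.whitener()
    if W is not None:
        X = W @ X
    xtx = X.T @ X
    _check_condition(xtx, design.column_names or None)
    full_inv = np.linalg.inv(xtx)
    tc = design.trial_columns
    return full_inv[np.ix_(tc, tc)]


# ---------------------------------------------------------------------------
# fractional ridge regression
# ---------------------------------------------------------------------------

def _fracridge_path(Xt, signal, fractions, n_alpha=200):
    """Ridge solutions at given coefficient-norm fractions, per voxel.

    SVD parameterization: with ``Xt = U S V'`` and ``d = U' y`` the ridge
    coefficients in the right-singular basis are ``s d / (s^2 + alpha)``,
    i.e. the OLS coordinates ``d / s`` shrunk by ``s^2 / (s^2 + alpha)``, so
    coefficient norms over an alpha grid are cheap; the alpha achieving each
    requested norm fraction is found by log-linear interpolation of the
    (monotone) fraction-vs-alpha curve.

    Returns array (n_fractions, t, v).
    """
    U, s, Vt = np.linalg.svd(Xt, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum())
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    d = U.T @ signal  # rank x v
    ols_coef = d / s[:, None]  # coefficients in rotated basis at alpha=0
    # log-spaced alpha grid spanning far below / above the spectrum
    alphas = np.concatenate(
        [[0.0], np.geomspace(s[-1] ** 2 * 1e-4, s[0] ** 2 * 1e4, n_alpha)]
    )
    shrink = (s[:, None] ** 2) / (s[:, None] ** 2 + alphas[None, :])  # rank x n_alpha
    # norm^2 of coefficients for every (alpha, voxel)
    norms2 = np.einsum("ra,rv->av", shrink**2, ols_coef**2)
    frac_curve = np.sqrt(norms2 / norms2[0][None, :])  # n_alpha x v, decreasing in alpha
    v = signal.shape[1]
    out = np.empty((len(fractions), rank, v))
    log_alpha = np.log10(np.maximum(alphas, alphas[1] * 1e-3))
    for vi in range(v):
        fc = frac_curve[:, vi]
        # interpolate target fraction on the decreasing curve
        targ_alpha = np.interp(-np.asarray(fractions), -fc, log_alpha)
        alpha_sel = 10.0**targ_alpha
        alpha_sel[np.asarray(fractions) >= fc[0]] = 0.0
        sh = (s[:, None] ** 2) / (s[:, None] ** 2 + alpha_sel[None, :])
        out[:, :, vi] = (sh * ols_coef[:, vi][:, None]).T
    # rotate back to trial space
    return np.einsum("frv,rt->ftv", out, Vt)


def _residualize(design: TrialWiseDesign, signal: np.ndarray):
    """Project nuisance columns out of trial regressors and signal."""
    N = design.matrix[:, design.nuisance_columns]
    Xt = design.trial_matrix
    if N.shape[1] == 0:
        return Xt, signal
    Q, _ = np.linalg.qr(N)
    proj = lambda A: A - Q @ (Q.T @ A)
    return proj(Xt), proj(signal)


def fracridge_estimate(
    signals: list[np.ndarray] | np.ndarray,
    designs: list[TrialWiseDesign] | TrialWiseDesign,
    fractions: np.ndarray | None = None,
    labels: list[np.ndarray] | None = None,
    session_ids: list[int] | None = None,
) -> TrialEstimates:
    """Fractional-ridge trial amplitude estimates.

    With several sessions and a fraction grid, the fraction is selected per
    voxel by cross-validation: betas from the training sessions are
    collapsed to condition means (``labels``), mapped onto the held-out
    session's trials, and scored by time-series prediction R^2.  With a
    single fraction no selection is performed (and a single session is
    allowed).

    Parameters
    ----------
    signals, designs : per-session scan x voxel matrices and designs.
    fractions : target coefficient-norm fractions in (0, 1].
    labels : per-session integer condition labels, required for selection.
    """
    if isinstance(designs, TrialWiseDesign):
        designs = [designs]
        signals = [np.asarray(signals)]
    fractions = FRACTION_GRID if fractions is None else np.atleast_1d(fractions)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in (0, 1]")
    S = len(designs)
    if session_ids is None:
        session_ids = list(range(S))
    select = len(fractions) > 1
    if select and S < 2:
        raise ValueError("cross-validated fraction selection requires >= 2 sessions")
    if select and labels is None:
        raise ValueError("fraction selection requires per-session condition labels")

    # betas for every fraction, per session: list of (F, t_s, v)
    paths = []
    for sig, des in zip(signals, designs):
        Xt_r, sig_r = _residualize(des, np.atleast_2d(np.asarray(sig, float)))
        paths.append(_fracridge_path(Xt_r, sig_r, fractions))
    v = paths[0].shape[2]

    if not select:
        blocks = [
            TrialEstimates(paths[k][0], np.full(designs[k].n_trials, session_ids[k]),
                           {session_ids[k]: uncorrelation_matrix(designs[k])}, "FRACRIDGE")
            for k in range(S)
        ]
        return TrialEstimates.concatenate(blocks)

    # cross-validated fraction selection: condition-mean transfer R^2
    scores = np.zeros((len(fractions), v))
    for j in range(S):
        Xt_j, sig_j = _residualize(designs[j], np.atleast_2d(np.asarray(signals[j], float)))
        lab_j = np.asarray(labels[j])
        ss_tot = np.sum(sig_j**2, axis=0) + 1e-12
        train = [k for k in range(S) if k != j]
        for fi in range(len(fractions)):
            # condition means over pooled training trials
            tr_gamma = np.vstack([paths[k][fi] for k in train])
            tr_lab = np.concatenate([np.asarray(labels[k]) for k in train])
            gamma_pred = np.empty((designs[j].n_trials, v))
            for c in np.unique(lab_j):
                mean_c = tr_gamma[tr_lab == c].mean(axis=0)
                gamma_pred[lab_j == c] = mean_c
            resid = sig_j - Xt_j @ gamma_pred
            scores[fi] += 1.0 - np.sum(resid**2, axis=0) / ss_tot
    best = np.argmax(scores, axis=0)  # per voxel

    blocks = []
    for k in range(S):
        gamma = np.empty((designs[k].n_trials, v))
        for vi in range(v):
            gamma[:, vi] = paths[k][best[vi], :, vi]
        blocks.append(
            TrialEstimates(gamma, np.full(designs[k].n_trials, session_ids[k]),
                           {session_ids[k]: uncorrelation_matrix(designs[k])}, "FRACRIDGE")
        )
    return TrialEstimates.concatenate(blocks)
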