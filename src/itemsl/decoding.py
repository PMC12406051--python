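"""Inverse transformed encoding model (ITEM) decoding.

Trial-wise LS-A estimates follow a linear model at the trial level: the
transformation matrix T acts as design matrix and the uncorrelation matrix
U as temporal covariance.  Inverting that model yields decoding weights W
mapping estimated responses back to design variables,

    W = (G' U^-1 G)^-1 G' U^-1 T        (generalized least squares)
    T_hat = G_test @ W,

estimated with leave-one-session-out cross-validation.  Classification
takes the argmax over indicator columns of T_hat; regression correlates a
parametric column of T_hat with its actual values.

The public surface follows the model/results convention: build an
:class:`ItemModel` from trial estimates and design variables, call
``fit()``, and read predictions, metrics and a ``summary()`` off the
returned :class:`ItemResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
from scipy.linalg import block_diag, cholesky, solve_triangular

from .design import TransformationMatrix
from .estimators import TrialEstimates
from .reml import reml_calibrate

__all__ = [
    "ItemModel",
    "ItemResults",
    "PredictionResult",
    "fit_item_weights",
    "predict_design",
    "crossvalidate",
    "classify",
    "decoding_accuracy",
    "balanced_accuracy",
    "predictive_correlation",
    "median_absolute_error",
]


def fit_item_weights(
    gamma: np.ndarray,
    U: np.ndarray,
    T: np.ndarray,
    allow_pinv: bool = False,
) -> np.ndarray:
    """GLS decoding weights ``W = (G' U^-1 G)^-1 G' U^-1 T``.

    Solved by whitening with the inverse Cholesky factor of U followed by
    ordinary least squares.  When voxels outnumber pooled training trials
    the normal matrix is singular; a Moore-Penrose fallback is available
    behind ``allow_pinv`` (default: raise).
    """
    gamma = np.atleast_2d(np.asarray(gamma, float))
    T = np.atleast_2d(np.asarray(T, float))
    L = cholesky(U, lower=True)
    Gw = solve_triangular(L, gamma, lower=True)
    Tw = solve_triangular(L, T, lower=True)
    gram = Gw.T @ Gw
    rhs = Gw.T @ Tw
    if allow_pinv:
        return np.linalg.pinv(gram) @ rhs
    t, v = gamma.shape
    if v > t or np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError(
            f"G' U^-1 G is singular ({v} voxels, {t} training trials); "
            "enable allow_pinv for a pseudoinverse fallback"
        )
    return np.linalg.solve(gram, rhs)


def predict_design(weights: np.ndarray, gamma_test: np.ndarray) -> np.ndarray:
    """Predicted design variables ``T_hat = G_test @ W``."""
    gamma_test = np.atleast_2d(np.asarray(gamma_test, float))
    if gamma_test.shape[1] != weights.shape[0]:
        raise ValueError(
            f"test estimates have {gamma_test.shape[1]} voxels but weights expect "
            f"{weights.shape[0]}"
        )
    return gamma_test @ weights


def classify(predicted: np.ndarray) -> np.ndarray:
    """Predicted condition per trial: argmax over columns (ties -> lowest index)."""
    return np.argmax(np.atleast_2d(predicted), axis=1)


def decoding_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Proportion of correctly classified trials."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.size == 0:
        raise ValueError("cannot score an empty prediction")
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    return float(np.mean(labels == truth))


def balanced_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Mean of per-class recall (insensitive to class imbalance)."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.size == 0:
        raise ValueError("cannot score an empty prediction")
    classes = np.unique(truth)
    return float(np.mean([np.mean(labels[truth == c] == c) for c in classes]))


def predictive_correlation(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Pearson correlation between predicted and actual regressor values."""
    predicted = np.asarray(predicted, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if predicted.size < 3:
        raise ValueError("need at least 3 trials for a correlation")
    if np.ptp(actual) == 0:
        warn("actual values are constant; correlation undefined")
        return float("nan")
    return float(np.corrcoef(predicted, actual)[0, 1])


def median_absolute_error(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Median of |predicted - actual| over trials."""
    return float(np.median(np.abs(np.asarray(predicted) - np.asarray(actual))))


@dataclass
class PredictionResult:
    """Cross-validated predictions, concatenated over folds in trial order."""

    predicted: np.ndarray
    actual: np.ndarray
    fold_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.predicted.shape != self.actual.shape:
            raise ValueError("predicted and actual must be congruent")


def crossvalidate(
    estimates: TrialEstimates,
    T: TransformationMatrix | np.ndarray,
    use_reml: bool = True,
    allow_pinv: bool = False,
    include_intercept: bool = False,
) -> PredictionResult:
    """Leave-one-session-out cross-validated ITEM prediction of T.

    For each fold the held-out session is predicted from weights fitted on
    the pooled remaining sessions (block-diagonal U, optionally ReML
    calibrated).  Predictions are concatenated over folds in trial order
    and scored once.
    """
    Tm = T.matrix if isinstance(T, TransformationMatrix) else np.atleast_2d(np.asarray(T, float))
    sessions = estimates.sessions
    if len(sessions) < 2:
        raise ValueError("leave-one-session-out cross-validation needs >= 2 sessions")
    if Tm.shape[0] != estimates.n_trials:
        raise ValueError("T rows must match total trial count")

    cov = {s: estimates.uncorrelation[s] for s in sessions}
    if use_reml:
        fit = reml_calibrate(estimates, Tm)
        offset = 0
        for s in sessions:
            n_s = estimates.session_rows(s).size
            cov[s] = fit.calibrated_cov[offset : offset + n_s, offset : offset + n_s]
            offset += n_s

    predicted = np.empty_like(Tm)
    fold_ids = np.empty(estimates.n_trials, dtype=int)
    for fold, sid in enumerate(sessions):
        test_rows = estimates.session_rows(sid)
        train_sessions = [s for s in sessions if s != sid]
        train_rows = np.concatenate([estimates.session_rows(s) for s in train_sessions])
        G_train = estimates.gamma_hat[train_rows]
        T_train = Tm[train_rows]
        if include_intercept:
            G_train = np.column_stack([G_train, np.ones(len(G_train))])
        U_train = block_diag(*[cov[s] for s in train_sessions])
        W = fit_item_weights(G_train, U_train, T_train, allow_pinv=allow_pinv)
        G_test = estimates.gamma_hat[test_rows]
        if include_intercept:
            G_test = np.column_stack([G_test, np.ones(len(G_test))])
        predicted[test_rows] = predict_design(W, G_test)
        fold_ids[test_rows] = fold
    return PredictionResult(predicted, Tm.copy(), fold_ids)


class ItemModel:
    """Inverse transformed encoding model over trial-wise estimates.

    Parameters
    ----------
    estimates : TrialEstimates
        Trial x voxel amplitude estimates with per-session uncorrelation
        matrices (typically LS-A output).
    design_vars : TransformationMatrix or ndarray
        Trial x p design variables to reconstruct (indicator conditions
        and/or parametric modulators), rows aligned with the estimates.
    use_reml : bool
        Recalibrate each session's U as ``l1 * I + l2 * U`` by restricted
        maximum likelihood before decoding (default True).
    allow_pinv : bool
        Permit a pseudoinverse fallback when voxels outnumber training
        trials (default False: raise).
    include_intercept : bool
        Append a constant column to the estimates (default False).
    """

    def __init__(
        self,
        estimates: TrialEstimates,
        design_vars: TransformationMatrix | np.ndarray,
        use_reml: bool = True,
        allow_pinv: bool = False,
        include_intercept: bool = False,
    ) -> None:
        self.estimates = estimates
        self.design_vars = design_vars
        self.use_reml = use_reml
        self.allow_pinv = allow_pinv
        self.include_intercept = include_intercept

    @classmethod
    def from_dataframe(cls, gamma: np.ndarray, frame, columns: list[str], **kwargs) -> "ItemModel":
        """Build from a per-trial DataFrame with ``session`` plus target columns.

        Indicator targets are detected as non-numeric columns and one-hot
        encoded; numeric columns become parametric targets.
        """
        import pandas as pd

        names: list[str] = []
        kinds: list[str] = []
        cols = []
        for c in columns:
            s = frame[c]
            if pd.api.types.is_numeric_dtype(s):
                cols.append(s.to_numpy(float))
                names.append(c)
                kinds.append("parametric")
            else:
                for level in sorted(s.unique()):
                    cols.append((s == level).to_numpy(float))
                    names.append(f"{c}[{level}]")
                    kinds.append("indicator")
        T = TransformationMatrix(np.column_stack(cols), names, kinds)
        est = TrialEstimates(gamma, frame["session"].to_numpy())
        return cls(est, T, **kwargs)

    def fit(self) -> "ItemResults":
        """Run leave-one-session-out cross-validated decoding."""
        pred = crossvalidate(
            self.estimates,
            self.design_vars,
            use_reml=self.use_reml,
            allow_pinv=self.allow_pinv,
            include_intercept=self.include_intercept,
        )
        return ItemResults(self, pred)


@dataclass
class ItemResults:
    """Cross-validated ITEM predictions and their performance measures."""

    model: ItemModel
    prediction: PredictionResult
    _names: list[str] = field(init=False)
    _kinds: list[str] = field(init=False)

    def __post_init__(self) -> None:
        dv = self.model.design_vars
        if isinstance(dv, TransformationMatrix):
            self._names = list(dv.column_names)
            self._kinds = list(dv.column_kind)
        else:
            p = np.atleast_2d(dv).shape[1]
            self._names = [f"col_{i}" for i in range(p)]
            self._kinds = ["indicator"] * p

    # -- classification -----------------------------------------------------
    def _indicator_block(self):
        idx = [i for i, k in enumerate(self._kinds) if k == "indicator"]
        if not idx:
            raise ValueError("no indicator columns to classify")
        return np.asarray(idx)

    @property
    def predicted_labels(self) -> np.ndarray:
        idx = self._indicator_block()
        return classify(self.prediction.predicted[:, idx])

    @property
    def true_labels(self) -> np.ndarray:
        idx = self._indicator_block()
        return classify(self.prediction.actual[:, idx])

    def accuracy(self) -> float:
        return decoding_accuracy(self.predicted_labels, self.true_labels)

    def balanced_accuracy(self) -> float:
        return balanced_accuracy(self.predicted_labels, self.true_labels)

    # -- regression ---------------------------------------------------------
    def _column(self, name_or_index) -> int:
        if isinstance(name_or_index, str):
            return self._names.index(name_or_index)
        return int(name_or_index)

    def correlation(self, column) -> float:
        j = self._column(column)
        return predictive_correlation(
            self.prediction.predicted[:, j], self.prediction.actual[:, j]
        )

    def mae(self, column) -> float:
        j = self._column(column)
        return median_absolute_error(
            self.prediction.predicted[:, j], self.prediction.actual[:, j]
        )

    def per_fold(self, metric: str = "accuracy") -> list[float]:
        out = []
        for f in np.unique(self.prediction.fold_ids):
            rows = self.prediction.fold_ids == f
            idx = self._indicator_block()
            lab = classify(self.prediction.predicted[np.ix_(rows, idx)])
            tru = classify(self.prediction.actual[np.ix_(rows, idx)])
            if metric == "accuracy":
                out.append(decoding_accuracy(lab, tru))
            elif metric == "balanced_accuracy":
                out.append(balanced_accuracy(lab, tru))
            else:
                raise ValueError(f"unknown per-fold metric {metric!r}")
        return out

    def to_frame(self):
        """Per-trial predicted vs. actual values as a tidy DataFrame."""
        import pandas as pd

        data = {"fold": self.prediction.fold_ids}
        for j, name in enumerate(self._names):
            data[f"actual_{name}"] = self.prediction.actual[:, j]
            data[f"predicted_{name}"] = self.prediction.predicted[:, j]
        return pd.DataFrame(data)

    def summary(self) -> str:
        n_folds = int(self.prediction.fold_ids.max()) + 1
        t, p = self.prediction.predicted.shape
        lines = [
            "Inverse Transformed Encoding Model — cross-validated decoding",
            "=" * 62,
            f"trials: {t}    design variables: {p}    folds (sessions): {n_folds}",
            f"voxels: {self.model.estimates.n_voxels}    "
            f"estimator: {self.model.estimates.method}    "
            f"ReML calibration: {self.model.use_reml}",
            "-" * 62,
        ]
        if any(k == "indicator" for k in self._kinds):
            lines.append(f"decoding accuracy (DA):  {self.accuracy():.4f}")
            lines.append(f"balanced accuracy (BA):  {self.balanced_accuracy():.4f}")
            folds = ", ".join(f"{a:.3f}" for a in self.per_fold())
            lines.append(f"per-fold DA:             {folds}")
        for j, (name, kind) in enumerate(zip(self._names, self._kinds)):
            if kind == "parametric":
                lines.append(
                    f"{name}: CC = {self.correlation(j):+.4f}   MAE = {self.mae(j):.4f}"
                )
        lines.append("=" * 62)
        return "\n".join(lines)
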