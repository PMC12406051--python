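"""HRF-convolved design matrices for standard and trial-wise GLMs.

A trial-wise GLM carries one HRF onset regressor per trial instead of one
per condition.  The trial-wise design matrix ``Xt`` (scans x trials) relates
to the standard condition-based design ``X`` (scans x conditions) through a
trial-to-condition transformation matrix ``T`` with ``X = Xt @ T``.  ``T``
is an indicator matrix for categorical conditions and holds per-trial
modulator values for parametric regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "TrialWiseDesign",
    "TransformationMatrix",
    "canonical_hrf",
    "build_trialwise_design",
    "build_transformation_matrix",
    "read_events_tsv",
]

#: microtime oversampling factor relative to TR
MICROTIME_RESOLUTION = 16
#: default kernel length in seconds (covers the post-stimulus undershoot)
HRF_LENGTH = 32.0


@dataclass
class EventTable:
    """Per-trial event timing for one or more fMRI sessions.

    Parameters
    ----------
    events : pandas.DataFrame
        Columns ``session`` (int), ``onset`` (s, from first-scan start),
        ``duration`` (s), ``condition`` (label).  Optional modulator columns
        hold one real value per trial.
    modulators : list of str
        Names of modulator columns in ``events``.
    is_trialwise : pandas.Series or None
        Boolean flag per event: conditions broken up into trials (one
        regressor per event) versus modeled as pooled nuisance conditions.
        Default: every event is trial-wise.
    """

    events: pd.DataFrame
    modulators: list[str] = field(default_factory=list)
    is_trialwise: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.events
        required = {"session", "onset", "duration", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("event table is empty")
        if (df["onset"] < 0).any():
            raise ValueError("onsets must be non-negative")
        if (df["duration"] <= 0).any():
            raise ValueError("durations must be positive")
        for sess, grp in df.groupby("session"):
            if not np.all(np.diff(grp["onset"].to_numpy()) > 0):
                raise ValueError(f"onsets not strictly increasing in session {sess}")
        for m in self.modulators:
            if m not in df.columns:
                raise ValueError(f"modulator column {m!r} not in event table")
            if df[m].isna().any():
                raise ValueError(f"modulator {m!r} has missing values")
        if self.is_trialwise is None:
            self.is_trialwise = pd.Series(True, index=df.index)

    @property
    def sessions(self) -> list[int]:
        return sorted(self.events["session"].unique())

    def session(self, sid: int) -> "EventTable":
        m = self.events["session"] == sid
        return EventTable(
            self.events.loc[m].reset_index(drop=True),
            modulators=list(self.modulators),
            is_trialwise=self.is_trialwise.loc[m].reset_index(drop=True),
        )


@dataclass
class TrialWiseDesign:
    """Scan x regressor design matrix with one column per trial.

    ``matrix`` stacks trial columns first, then nuisance columns (pooled
    non-trial conditions, drift/constant terms).  ``scan_cov`` is the
    scan-by-scan error covariance V (identity for white noise).
    """

    matrix: np.ndarray
    trial_columns: np.ndarray
    nuisance_columns: np.ndarray
    tr: float
    scan_cov: np.ndarray | None = None
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("design matrix must be 2-D with at least one scan")
        self.trial_columns = np.asarray(self.trial_columns, dtype=int)
        self.nuisance_columns = np.asarray(self.nuisance_columns, dtype=int)
        if np.intersect1d(self.trial_columns, self.nuisance_columns).size:
            raise ValueError("trial and nuisance column sets must be disjoint")
        if self.scan_cov is not None:
            V = np.asarray(self.scan_cov, dtype=float)
            if V.shape != (self.n_scans, self.n_scans):
                raise ValueError("scan_cov shape does not match number of scans")
            if not np.allclose(V, V.T):
                raise ValueError("scan_cov must be symmetric")
            self.scan_cov = V

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_trials(self) -> int:
        return self.trial_columns.size

    @property
    def trial_matrix(self) -> np.ndarray:
        return self.matrix[:, self.trial_columns]

    def whitener(self) -> np.ndarray | None:
        """Inverse Cholesky factor of V, or None when V is identity."""
        if self.scan_cov is None:
            return None
        L = np.linalg.cholesky(self.scan_cov)
        return np.linalg.inv(L)


@dataclass
class TransformationMatrix:
    """Trial x design-variable matrix T with ``X = Xt @ T``.

    Indicator columns map trials to conditions (entries in {0, 1}, one per
    trial row summing to 1 across indicator columns); parametric columns
    hold real-valued per-trial modulator values.
    """

    matrix: np.ndarray
    column_names: list[str]
    column_kind: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("T must be 2-D (trials x design variables)")
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("column_names length mismatch")
        if len(self.column_kind) != self.matrix.shape[1]:
            raise ValueError("column_kind length mismatch")
        ind = [k == "indicator" for k in self.column_kind]
        if any(ind):
            block = self.matrix[:, ind]
            if not np.isin(block, (0.0, 1.0)).all():
                raise ValueError("indicator entries must be 0 or 1")
            if not np.allclose(block.sum(axis=1), 1.0):
                raise ValueError("each trial must carry exactly one condition")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    @property
    def indicator_columns(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.column_kind) if k == "indicator"])

    def subset(self, rows: np.ndarray) -> "TransformationMatrix":
        return TransformationMatrix(self.matrix[rows], list(self.column_names), list(self.column_kind))


def canonical_hrf(sampling_interval: float, length: float = HRF_LENGTH) -> np.ndarray:
    """Sampled canonical double-gamma hemodynamic response function.

    Difference of two gamma densities (response delay 6 s, undershoot delay
    16 s, unit dispersions, response:undershoot ratio 6), the de-facto
    standard kernel: peak around 5-6 s, post-stimulus undershoot out to
    roughly 30 s.  The kernel is peak-normalized so its maximum equals 1.

    Parameters
    ----------
    sampling_interval : float
        Grid spacing in seconds (> 0).
    length : float
        Kernel support in seconds (default 32).

    Returns
    -------
    ndarray
        HRF sampled at ``0, dt, 2 dt, ...`` up to ``length``.
    """
    from scipy.stats import gamma as gamma_dist

    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    t = np.arange(0.0, length + sampling_interval / 2, sampling_interval)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
    hrf: np.ndarray | None,
) -> np.ndarray:
    """Boxcar-on-fine-grid convolution sampled at scan times.

    The fine grid runs at ``TR / MICROTIME_RESOLUTION``; the regressor is
    sampled at the middle of each TR (reference slice = middle slice),
    since event onsets need not align with scan acquisition.
    """
    dt = tr / MICROTIME_RESOLUTION
    if hrf is None:
        hrf = canonical_hrf(dt)
    # continuous-time convolution with the unit-peak kernel (Riemann sum):
    # regressor amplitudes are then independent of the microtime resolution
    hrf = hrf * dt
    n_fine = n_scans * MICROTIME_RESOLUTION + hrf.size
    box = np.zeros(n_fine)
    t_max = n_scans * tr
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        if onset >= t_max:
            warnings.warn(
                f"event at {onset:.1f}s starts after the last scan; regressor truncated",
                stacklevel=3,
            )
            continue
        if onset + dur > t_max:
            warnings.warn(
                f"event at {onset:.1f}s extends beyond the last scan; regressor truncated",
                stacklevel=3,
            )
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + dur) / dt)), n_fine)
        box[i0:i1] += amp
    fine = np.convolve(box, hrf)[:n_fine]
    sample_at = np.arange(n_scans) * MICROTIME_RESOLUTION + MICROTIME_RESOLUTION // 2
    return fine[sample_at]


def _trial_columns(onsets, durations, n_scans, tr, hrf):
    """One regressor per trial, built from a shared boxcar*HRF template.

    Equal-duration trials share the convolved template, which is then
    shifted to each trial's onset bin on the fine grid and sampled at the
    mid-TR time points; unequal durations fall back to the generic path.
    """
    dt = tr / MICROTIME_RESOLUTION
    if hrf is None:
        hrf = canonical_hrf(dt)
    hrf = hrf * dt  # same time-integral amplitude convention as the generic path
    sample_at = np.arange(n_scans) * MICROTIME_RESOLUTION + MICROTIME_RESOLUTION // 2
    t_max = n_scans * tr
    cols = []
    templates: dict[int, np.ndarray] = {}
    for onset, dur in zip(onsets, durations):
        if onset >= t_max:
            warnings.warn(
                f"event at {onset:.1f}s starts after the last scan; regressor truncated",
                stacklevel=3,
            )
            cols.append(np.zeros(n_scans))
            continue
        if onset + dur > t_max:
            warnings.warn(
                f"event at {onset:.1f}s extends beyond the last scan; regressor truncated",
                stacklevel=3,
            )
        i0 = int(round(onset / dt))
        # bin count replicates the generic boxcar rule so X = Xt @ T holds
        # to machine precision against condition-pooled convolution
        bins = max(int(round((onset + dur) / dt)) - i0, 1)
        if bins not in templates:
            templates[bins] = np.convolve(np.ones(bins), hrf)
        kernel = templates[bins]
        rel = sample_at - i0
        col = np.zeros(n_scans)
        ok = (rel >= 0) & (rel < kernel.size)
        col[ok] = kernel[rel[ok]]
        cols.append(col)
    return cols


def build_trialwise_design(
    events: EventTable,
    n_scans: int,
    tr: float,
    hrf: np.ndarray | None = None,
    add_constant: bool = True,
    scan_cov: np.ndarray | None = None,
) -> TrialWiseDesign:
    """Build the trial-wise design matrix Xt for a single session.

    One HRF-convolved column per trial-wise event; non-trial-wise events are
    pooled into one column per condition (nuisance); a constant column is
    appended by default.

    Parameters
    ----------
    events : EventTable
        Events of exactly one session.
    n_scans : int
        Number of scans acquired.
    tr : float
        Repetition time in seconds.
    hrf : ndarray, optional
        Kernel sampled at ``tr / 16``; default: :func:`canonical_hrf`.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if len(events.sessions) != 1:
        raise ValueError("build_trialwise_design expects a single session")
    df = events.events
    tw = events.is_trialwise.to_numpy()
    if not tw.any():
        raise ValueError("no trial-wise events in session")

    cols = _trial_columns(
        df.loc[tw, "onset"].to_numpy(),
        df.loc[tw, "duration"].to_numpy(),
        n_scans, tr, hrf,
    )
    names = [f"trial_{idx:04d}" for idx in np.flatnonzero(tw)]
    trial_idx = np.arange(len(cols))

    nuis_start = len(cols)
    nuis_df = df.loc[~tw]
    for cond, grp in nuis_df.groupby("condition", sort=True):
        cols.append(
            _convolve_events(
                grp["onset"].to_numpy(), grp["duration"].to_numpy(),
                np.ones(len(grp)), n_scans, tr, hrf,
            )
        )
        names.append(f"nuisance_{cond}")
    if add_constant:
        cols.append(np.ones(n_scans))
        names.append("constant")
    nuis_idx = np.arange(nuis_start, len(cols))

    return TrialWiseDesign(
        matrix=np.column_stack(cols),
        trial_columns=trial_idx,
        nuisance_columns=nuis_idx,
        tr=tr,
        scan_cov=scan_cov,
        column_names=names,
    )


def build_transformation_matrix(
    events: EventTable, design: TrialWiseDesign
) -> TransformationMatrix:
    """Trial-to-condition transformation matrix T for a session's design.

    Indicator columns (one per condition among trial-wise events) plus one
    parametric column per declared modulator, satisfying ``X = Xt @ T`` for
    the standard design restricted to trial-wise events.
    """
    df = events.events
    tw = events.is_trialwise.to_numpy()
    trials = df.loc[tw].reset_index(drop=True)
    if len(trials) != design.n_trials:
        raise ValueError("events do not match the design they supposedly generated")
    conditions = sorted(trials["condition"].unique())
    blocks = []
    names: list[str] = []
    kinds: list[str] = []
    for cond in conditions:
        blocks.append((trials["condition"] == cond).to_numpy(float))
        names.append(str(cond))
        kinds.append("indicator")
    for m in events.modulators:
        vals = trials[m].to_numpy(float)
        if np.isnan(vals).any():
            raise ValueError(f"modulator {m!r} has missing values")
        blocks.append(vals)
        names.append(m)
        kinds.append("parametric")
    return TransformationMatrix(np.column_stack(blocks), names, kinds)


def read_events_tsv(
    path, session: int = 0, modulators: list[str] | None = None
) -> EventTable:
    """Read a BIDS-style ``events.tsv`` (onset, duration, trial_type, ...)."""
    df = pd.read_csv(path, sep="\t")
    if "trial_type" in df.columns:
        df = df.rename(columns={"trial_type": "condition"})
    df["session"] = session
    return EventTable(df, modulators=modulators or [])
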