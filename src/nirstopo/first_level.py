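"""Within-subject GLM: design construction and prewhitened least squares.

The hemoglobin response Y [M x J] at each channel is modelled as
Y = X beta + eps with errors whose covariance at a channel is sigma^2 V,
V a global AR(1) temporal autocorrelation matrix.  Fitting prewhitens with
S = V^(-1/2): beta_hat = (X*^T X*)^-1 X*^T Y*, X* = SX, Y* = SY.  Effects of
interest are linear combinations c^T beta_hat per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import gamma as gamma_dist
from sklearn.base import BaseEstimator

from .optics import HbSeries
from .preprocess import WhiteningModel, dct_basis, estimate_ar1, whitening_matrix

__all__ = [
    "EventTable",
    "DesignMatrix",
    "GlmFit",
    "ChannelContrast",
    "HrfParams",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "contrast_channels",
    "FirstLevelModel",
]


@dataclass
class EventTable:
    """Event onsets/durations [s] with condition labels."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.onsets) == len(self.durations) == len(self.conditions)):
            raise ValueError("onsets, durations and conditions must align")
        if np.any(self.durations < 0):
            raise ValueError("durations must be >= 0")

    @property
    def condition_names(self) -> list[str]:
        return sorted(set(self.conditions))

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        """Read a BIDS-style events table (onset, duration, trial_type)."""
        df = pd.read_csv(path, sep="\t")
        required = {"onset", "duration", "trial_type"}
        if not required.issubset(df.columns):
            raise ValueError(f"events TSV must contain columns {sorted(required)}")
        return cls(
            onsets=df["onset"].to_numpy(float),
            durations=df["duration"].to_numpy(float),
            conditions=[str(c) for c in df["trial_type"]],
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations, "trial_type": self.conditions}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DesignMatrix:
    X: np.ndarray
    column_names: list[str]
    fs: float
    empty_conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names must match design width")

    @property
    def L(self) -> int:
        return self.X.shape[1]


@dataclass
class GlmFit:
    """Prewhitened least-squares fit, channel-wise.

    ``residuals`` are whitened-domain residuals (orthogonal to the whitened
    design columns); ``dof`` = M - L.
    """

    beta: np.ndarray  # [L x J]
    sigma2: np.ndarray  # per channel
    residuals: np.ndarray  # [M x J], whitened
    whitening: WhiteningModel | None
    dof: float
    column_names: list[str]
    channel_ids: list[str]


@dataclass
class ChannelContrast:
    w: np.ndarray  # per-channel c^T beta_hat
    contrast_vector: np.ndarray
    subject_id: str = ""
    channel_ids: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"channel": self.channel_ids, "contrast": self.w}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, subject_id: str = "") -> "ChannelContrast":
        df = pd.read_csv(path, sep="\t")
        return cls(
            w=df["contrast"].to_numpy(float),
            contrast_vector=np.array([]),
            subject_id=subject_id,
            channel_ids=[str(c) for c in df["channel"]],
        )


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF: response peak 6 s, undershoot peak 16 s.

    Dispersions (1 s) and the undershoot ratio (1/6) are conventional
    defaults; the three delays are the model constraints.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0


def canonical_hrf(dt: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Sampled double-gamma hemodynamic response, unit peak, 32 s support."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, params.length, dt)
    # gamma density with mode = (a-1)*scale; choose shape so mode = delay
    a1 = params.peak_delay / params.peak_disp + 1.0
    a2 = params.undershoot_delay / params.undershoot_disp + 1.0
    h = gamma_dist.pdf(t, a1, scale=params.peak_disp) - params.undershoot_ratio * (
        gamma_dist.pdf(t, a2, scale=params.undershoot_disp)
    )
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def _stick_function(
    onsets: np.ndarray, durations: np.ndarray, M: int, fs: float
) -> np.ndarray:
    """Delta sticks for events; boxcars when duration > 0."""
    u = np.zeros(M)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset * fs))
        if not 0 <= i0 < M:
            raise ValueError(f"event onset {onset} s outside recording")
        if dur > 0:
            i1 = min(int(round((onset + dur) * fs)) + 1, M)
            u[i0:i1] += 1.0
        else:
            u[i0] += 1.0
    return u


def build_design(
    events: EventTable,
    M: int,
    fs: float,
    basis: str = "canonical+derivative",
    confounds: np.ndarray | None = None,
    conditions: list[str] | None = None,
    hrf_params: HrfParams = HrfParams(),
    add_constant: bool = True,
) -> DesignMatrix:
    """Condition regressors (HRF basis convolution) plus confounds.

    ``basis`` is ``"canonical"`` or ``"canonical+derivative"`` (the temporal
    derivative is the finite difference of the sampled kernel, unscaled).
    A constant column is always appended unless ``add_constant=False``.
    """
    if basis not in ("canonical", "canonical+derivative"):
        raise ValueError("basis must be 'canonical' or 'canonical+derivative'")
    declared = conditions if conditions is not None else events.condition_names
    unknown = sorted(set(events.conditions) - set(declared))
    if unknown:
        raise ValueError(
            f"unknown condition labels {unknown}; declared conditions: {declared}"
        )
    dt = 1.0 / fs
    hrf = canonical_hrf(dt, hrf_params)
    kernels = [("hrf", hrf)]
    if basis == "canonical+derivative":
        kernels.append(("dhrf", np.gradient(hrf, dt)))

    cols, names, empty = [], [], []
    for cond in declared:
        sel = [i for i, c in enumerate(events.conditions) if c == cond]
        u = _stick_function(events.onsets[sel], events.durations[sel], M, fs)
        if not sel:
            empty.append(cond)
        for kname, kernel in kernels:
            col = np.convolve(u, kernel)[:M]
            cols.append(col)
            names.append(f"{cond}*{kname}")
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != M:
            raise ValueError("confounds must have M rows")
        for k in range(confounds.shape[1]):
            cols.append(confounds[:, k])
            names.append(f"confound_{k}")
    if add_constant:
        cols.append(np.ones(M))
        names.append("constant")
    X = np.column_stack(cols) if cols else np.empty((M, 0))
    return DesignMatrix(X=X, column_names=names, fs=fs, empty_conditions=empty)


def _as_operator(S):
    if S is None:
        return None
    if sparse.issparse(S):
        return S
    return np.asarray(S, dtype=float)


def fit_glm(
    Y: np.ndarray | HbSeries,
    X: DesignMatrix | np.ndarray,
    S=None,
    whitening: WhiteningModel | None = None,
    channel_ids: list[str] | None = None,
    chromophore: str = "hbo",
) -> GlmFit:
    """Least squares on whitened data: beta = (X*^T X*)^-1 X*^T Y*."""
    if isinstance(Y, HbSeries):
        channel_ids = channel_ids or list(Y.channel_ids)
        Y = Y.chromophore(chromophore)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if isinstance(X, DesignMatrix):
        names = X.column_names
        Xm = X.X
    else:
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        names = [f"col_{k}" for k in range(Xm.shape[1])]
    M, L = Xm.shape
    if Y.shape[0] != M:
        raise ValueError(f"Y has {Y.shape[0]} rows but design has {M}")
    if M <= L:
        raise ValueError("need more samples than regressors")
    S = _as_operator(S)
    Xw = Xm if S is None else S @ Xm
    Yw = Y if S is None else S @ Y
    rank = np.linalg.matrix_rank(Xw)
    if rank < L:
        # name the offending columns by inspecting the QR diagonal
        diag = np.abs(np.diag(np.linalg.qr(Xw, mode="r")))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    resid = Yw - Xw @ beta
    dof = M - L
    sigma2 = np.sum(resid**2, axis=0) / dof
    J = Y.shape[1]
    return GlmFit(
        beta=beta,
        sigma2=sigma2,
        residuals=resid,
        whitening=whitening,
        dof=dof,
        column_names=names,
        channel_ids=channel_ids or [f"CH{j + 1}" for j in range(J)],
    )


def contrast_channels(
    fit: GlmFit, c: np.ndarray, subject_id: str = ""
) -> ChannelContrast:
    """Per-channel effect of interest w_j = c^T beta_hat_j."""
    c = np.asarray(c, dtype=float).ravel()
    if c.size != fit.beta.shape[0]:
        raise ValueError(
            f"contrast length {c.size} does not match {fit.beta.shape[0]} regressors"
        )
    return ChannelContrast(
        w=c @ fit.beta,
        contrast_vector=c,
        subject_id=subject_id,
        channel_ids=list(fit.channel_ids),
    )


class FirstLevelModel(BaseEstimator):
    """Within-subject prewhitened GLM (nilearn-style estimator).

    Parameters
    ----------
    basis : "canonical" or "canonical+derivative"
        HRF basis set per condition.
    hrf_params : HrfParams
        Double-gamma shape parameters.
    whiten : bool
        If True (default), estimate a global AR(1) model from OLS residuals
        and refit with S = V^(-1/2) (one Cochrane-Orcutt style pass).
    drift_cutoff : float or None
        If set, DCT drift regressors below this frequency [Hz] are appended
        to the design as confounds (use when the series was not high-passed).
    chromophore : "hbo" or "hbr"
        Which hemoglobin series to model.

    Fitted attributes: ``design_``, ``glm_fit_``, ``whitening_``.
    """

    def __init__(
        self,
        basis: str = "canonical+derivative",
        hrf_params: HrfParams = HrfParams(),
        whiten: bool = True,
        drift_cutoff: float | None = None,
        chromophore: str = "hbo",
    ):
        self.basis = basis
        self.hrf_params = hrf_params
        self.whiten = whiten
        self.drift_cutoff = drift_cutoff
        self.chromophore = chromophore

    def fit(
        self,
        series: HbSeries,
        events: EventTable,
        conditions: list[str] | None = None,
    ) -> "FirstLevelModel":
        Y = series.chromophore(self.chromophore)
        M = series.n_samples
        last = float(np.max(events.onsets)) if len(events.onsets) else 0.0
        if last >= M / series.fs:
            raise ValueError("events extend beyond the recording")
        confounds = None
        if self.drift_cutoff is not None:
            confounds = dct_basis(M, series.fs, self.drift_cutoff)[:, 1:]
        design = build_design(
            events,
            M,
            series.fs,
            basis=self.basis,
            confounds=confounds,
            conditions=conditions,
            hrf_params=self.hrf_params,
        )
        fit0 = fit_glm(Y, design, channel_ids=list(series.channel_ids))
        if self.whiten:
            wm = estimate_ar1(fit0.residuals)
            S = whitening_matrix(wm)
            fit1 = fit_glm(
                Y, design, S=S, whitening=wm, channel_ids=list(series.channel_ids)
            )
        else:
            fit1 = fit0
        self.design_ = design
        self.glm_fit_ = fit1
        self.whitening_ = fit1.whitening
        return self

    def compute_contrast(self, c: np.ndarray, subject_id: str = "") -> ChannelContrast:
        if not hasattr(self, "glm_fit_"):
            raise RuntimeError("model is not fitted")
        return contrast_channels(self.glm_fit_, c, subject_id=subject_id)

    def condition_contrast(
        self, weights: dict[str, float], subject_id: str = ""
    ) -> ChannelContrast:
        """Contrast over canonical-HRF columns by condition name."""
        c = np.zeros(self.design_.L)
        for cond, wgt in weights.items():
            name = f"{cond}*hrf"
            if name not in self.design_.column_names:
                raise ValueError(f"no canonical column for condition {cond!r}")
            c[self.design_.column_names.index(name)] = wgt
        return self.compute_contrast(c, subject_id=subject_id)
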