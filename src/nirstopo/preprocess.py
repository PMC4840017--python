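"""Temporal preprocessing of hemoglobin time series.

Pipeline order (fixed): motion-artifact reduction -> physiological band-stop
-> DCT high-pass -> downsampling -> AR(1) whitening.  Every stage is linear
(motion correction excepted) and channel-wise independent, so channels may be
processed jointly or one at a time with identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.interpolate import UnivariateSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .optics import HbSeries

__all__ = [
    "PreprocessConfig",
    "WhiteningModel",
    "Preprocessor",
    "correct_motion",
    "bandstop_physio",
    "dct_highpass",
    "dct_basis",
    "downsample",
    "estimate_ar1",
    "whitening_matrix",
]


@dataclass
class PreprocessConfig:
    """Parameters of the temporal pipeline.

    Defaults follow an event-related prefrontal protocol sampled at 10 Hz:
    respiratory and cardiac stopbands 0.12-0.35 Hz and 0.7-2.0 Hz
    (5th-order Butterworth, zero-phase), DCT high-pass cutoff 1/64 Hz,
    downsampling to 1 Hz.
    """

    motion_window: float = 1.0  # s, moving-SD window
    motion_threshold: float = 3.0  # multiplier on median moving SD
    stopbands: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.12, 0.35), (0.7, 2.0)]
    )
    filter_order: int = 5
    hp_cutoff: float = 1.0 / 64.0  # Hz
    target_fs: float = 1.0  # Hz

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        for lo, hi in self.stopbands:
            if not (0 < lo < hi < nyq):
                raise ValueError(
                    f"stopband ({lo}, {hi}) Hz invalid for fs={fs} Hz "
                    f"(need 0 < low < high < {nyq})"
                )
        if self.hp_cutoff <= 0:
            raise ValueError("hp_cutoff must be > 0")
        if self.target_fs > fs:
            raise ValueError("target_fs must not exceed fs")


@dataclass
class WhiteningModel:
    """Global AR(1) temporal autocorrelation model.

    V_{ij} = rho^{|i-j|} is shared across channels ("global" V); the
    innovation variance sigma2 is per channel.
    """

    rho: float
    sigma2: np.ndarray
    M: int

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1 for stationarity")
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if np.any(self.sigma2 <= 0):
            raise ValueError("innovation variances must be > 0")


def _moving_std(x: np.ndarray, w: int) -> np.ndarray:
    """Centred moving standard deviation via cumulative sums."""
    series = pd.Series(x)
    return series.rolling(w, center=True, min_periods=max(2, w // 2)).std().to_numpy()


def correct_motion(
    series: HbSeries, window: float = 1.0, threshold: float = 3.0
) -> tuple[HbSeries, list[tuple[int, int, int]]]:
    """Moving-SD artifact detection with spline-based segment repair.

    Samples whose moving SD exceeds ``threshold`` x the channel's median
    moving SD are grouped into contiguous artifact segments.  Each segment is
    replaced by a smoothing-spline fit (removing the high-frequency artifact
    component) plus a linear ramp matching the untouched neighbouring samples,
    so segment baselines re-join continuously.  Samples outside segments are
    returned bit-identical.

    Returns the corrected series and a list of ``(channel, start, stop)``
    sample-index segments (stop exclusive), one entry per segment per
    chromophore-agnostic channel (segments are detected on HbO and applied to
    both chromophores of that channel).
    """
    w = max(int(round(window * series.fs)), 2)
    if w > series.n_samples:
        raise ValueError(
            f"motion window ({w} samples) longer than series ({series.n_samples})"
        )
    hbo = series.hbo.copy()
    hbr = series.hbr.copy()
    segments: list[tuple[int, int, int]] = []
    for j in range(series.n_channels):
        msd = _moving_std(series.hbo[:, j], w)
        med = np.nanmedian(msd)
        if not np.isfinite(med) or med == 0:
            continue
        flagged = np.nan_to_num(msd, nan=0.0) > threshold * med
        if not flagged.any():
            continue
        for start, stop in _runs(flagged):
            segments.append((j, start, stop))
            for plane in (hbo, hbr):
                plane[start:stop, j] = _repair_segment(plane[:, j], start, stop)
    out = HbSeries(hbo=hbo, hbr=hbr, fs=series.fs, channel_ids=list(series.channel_ids))
    return out, segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def _repair_segment(x: np.ndarray, start: int, stop: int) -> np.ndarray:
    seg = x[start:stop]
    n = stop - start
    if n >= 4:
        t = np.arange(n, dtype=float)
        # heavy smoothing: keep only the slow component of the segment
        spl = UnivariateSpline(t, seg, k=3, s=n * np.var(seg))
        smooth = spl(t)
    else:
        smooth = np.full(n, seg.mean())
    left = x[start - 1] if start > 0 else smooth[0]
    right = x[stop] if stop < len(x) else smooth[-1]
    ramp = np.linspace(left - smooth[0], right - smooth[-1], n + 2)[1:-1] if n > 0 else smooth
    return smooth + ramp


def _apply_sos_channels(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=0)


def bandstop_physio(
    series: HbSeries,
    stopbands: list[tuple[float, float]] | None = None,
    order: int = 5,
) -> HbSeries:
    """Zero-phase Butterworth band-stop removal of physiological oscillations."""
    if stopbands is None:
        stopbands = PreprocessConfig().stopbands
    nyq = series.fs / 2.0
    for lo, hi in stopbands:
        if not (0 < lo < hi < nyq):
            raise ValueError(f"stopband edge ({lo}, {hi}) outside (0, {nyq}) Hz")
    if series.n_samples <= 3 * order:
        raise ValueError("series too short for the requested filter order")
    hbo, hbr = series.hbo, series.hbr
    for lo, hi in stopbands:
        sos = signal.butter(order, [lo, hi], btype="bandstop", fs=series.fs, output="sos")
        hbo = _apply_sos_channels(sos, hbo)
        hbr = _apply_sos_channels(sos, hbr)
    return HbSeries(hbo=hbo, hbr=hbr, fs=series.fs, channel_ids=list(series.channel_ids))


def dct_basis(M: int, fs: float, cutoff: float) -> np.ndarray:
    """Orthonormal DCT drift regressors with frequency below ``cutoff`` Hz.

    Column k (k = 0 constant, k >= 1 cosines) has frequency k / (2 M dt); the
    basis contains the constant plus every cosine strictly below the cutoff.
    """
    dt = 1.0 / fs
    n_cos = int(np.floor(2.0 * M * dt * cutoff))
    n_cos = min(n_cos, M - 1)
    i = np.arange(M)
    cols = [np.full(M, np.sqrt(1.0 / M))]
    for k in range(1, n_cos + 1):
        cols.append(np.sqrt(2.0 / M) * np.cos(np.pi * (2 * i + 1) * k / (2 * M)))
    return np.column_stack(cols)


def dct_highpass(series: HbSeries, cutoff: float = 1.0 / 64.0) -> tuple[HbSeries, np.ndarray]:
    """Project out slow DCT drifts; returns the filtered series and the basis."""
    if cutoff >= series.fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    M = series.n_samples
    C = dct_basis(M, series.fs, cutoff)
    if C.shape[1] == 0:
        return series, C

    def proj(y: np.ndarray) -> np.ndarray:
        return y - C @ (C.T @ y)

    return (
        HbSeries(
            hbo=proj(series.hbo),
            hbr=proj(series.hbr),
            fs=series.fs,
            channel_ids=list(series.channel_ids),
        ),
        C,
    )


def downsample(series: HbSeries, target_fs: float = 1.0) -> HbSeries:
    """Anti-aliased integer-ratio decimation (zero-phase IIR)."""
    ratio = series.fs / target_fs
    if ratio < 1:
        raise ValueError("target_fs must not exceed fs")
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(
            f"fs/target_fs = {ratio:.4f} is not an integer; only integer "
            "decimation ratios are supported"
        )
    if q == 1:
        return series
    # zero-phase FIR anti-alias filter: exactly unit DC gain, and filtfilt's
    # odd-reflection padding keeps constants constant at the edges
    numtaps = 20 * q + 1
    h = signal.firwin(numtaps, 1.0 / q)
    pad = min(3 * numtaps, series.n_samples - 1)

    def dec(x: np.ndarray) -> np.ndarray:
        return signal.filtfilt(h, [1.0], x, axis=0, padlen=pad)[::q]

    hbo = dec(series.hbo)
    hbr = dec(series.hbr)
    return HbSeries(hbo=hbo, hbr=hbr, fs=target_fs, channel_ids=list(series.channel_ids))


def estimate_ar1(residuals: np.ndarray) -> WhiteningModel:
    """Pooled lag-1 AR coefficient across channels, per-channel innovation var.

    The AR(1) coefficient is estimated globally (one rho for all channels,
    matching a global temporal autocorrelation matrix V) as the pooled
    lag-1 autocovariance over the pooled variance of the residuals.
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    if r.ndim != 2:
        raise ValueError("residuals must be 2-D [M x J]")
    if r.shape[0] < 10:
        raise ValueError("need at least 10 samples to estimate AR(1)")
    r = r - r.mean(axis=0, keepdims=True)
    denom = float(np.sum(r * r))
    if denom == 0:
        raise ValueError("zero-variance residuals: AR(1) model is degenerate")
    num = float(np.sum(r[1:] * r[:-1]))
    rho = float(np.clip(num / denom, -0.99, 0.99))
    innov = r[1:] - rho * r[:-1]
    sigma2 = innov.var(axis=0)
    sigma2 = np.maximum(sigma2, np.finfo(float).tiny)
    return WhiteningModel(rho=rho, sigma2=sigma2, M=r.shape[0])


def whitening_matrix(model: WhiteningModel, M: int | None = None) -> sparse.csr_matrix:
    """Sparse banded S with S V S^T = I for V_{ij} = rho^{|i-j|}.

    The innovations form of a stationary AR(1) gives a two-band lower
    triangular square root: row 0 is the identity row, and row t >= 1 is
    (-rho, 1)/sqrt(1 - rho^2).
    """
    rho = model.rho
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    M = model.M if M is None else M
    scale = 1.0 / np.sqrt(1.0 - rho**2)
    main = np.full(M, scale)
    main[0] = 1.0
    sub = np.full(M - 1, -rho * scale)
    return sparse.diags([sub, main], offsets=[-1, 0], format="csr")


class Preprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer running the full temporal pipeline.

    Stages (in order): motion correction, physiological band-stop, DCT
    high-pass, downsampling.  AR(1) whitening is estimated downstream from
    GLM residuals (see :class:`nirstopo.first_level.FirstLevelModel`), not
    here, because the autocorrelation model applies to the regression errors.
    """

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config

    def fit(self, series: HbSeries, y=None) -> "Preprocessor":
        cfg = self.config or PreprocessConfig()
        cfg.validate(series.fs)
        self.config_ = cfg
        return self

    def transform(self, series: HbSeries) -> HbSeries:
        cfg = getattr(self, "config_", None) or self.config or PreprocessConfig()
        cfg.validate(series.fs)
        out, segments = correct_motion(series, cfg.motion_window, cfg.motion_threshold)
        self.artifact_segments_ = segments
        out = bandstop_physio(out, cfg.stopbands, cfg.filter_order)
        out, self.drift_basis_ = dct_highpass(out, cfg.hp_cutoff)
        out = downsample(out, cfg.target_fs)
        return out

    def artifact_log(self, series_fs: float) -> pd.DataFrame:
        """Artifact segments as a (channel, start_s, end_s) table."""
        segs = getattr(self, "artifact_segments_", [])
        return pd.DataFrame(
            [(ch, start / series_fs, stop / series_fs) for ch, start, stop in segs],
            columns=["channel", "start_s", "end_s"],
        )
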