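"""The shared observation pipeline for empirical and simulated signals.

Regional BOLD series — whether recorded in the scanner or produced by the
model — pass through an identical pipeline before any comparison: band-pass
filtering to the 0.04–0.07 Hz band, z-scoring, Pearson correlation between
all region pairs, and Fisher R-to-z averaging across subjects. Model fit
quality between two FC matrices is measured with the structural similarity
index (SSIM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from skimage.metrics import structural_similarity

from .core import BoldSeries, FCMatrix, StateDataset
from .errors import ConfigurationError

#: Minimum series length accepted by the zero-phase filter (forward-backward
#: pad length of the 2nd-order Butterworth band-pass).
_MIN_FILTER_SAMPLES = 16


@dataclass(frozen=True)
class BandSpec:
    """Analysis frequency band in Hz (default 0.04–0.07, the low-frequency
    band carrying the most reliable resting-state information)."""

    f_low: float = 0.04
    f_high: float = 0.07

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ConfigurationError("need 0 < f_low < f_high")

    def validate_against(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if self.f_high >= nyquist:
            raise ConfigurationError(
                f"band edge {self.f_high} Hz reaches Nyquist {nyquist:.4g} Hz "
                f"(TR = {tr_seconds} s)"
            )


DEFAULT_BAND = BandSpec()


def bandpass(x: BoldSeries, band: BandSpec = DEFAULT_BAND) -> BoldSeries:
    """Zero-phase 2nd-order Butterworth band-pass, applied forward-backward.

    Zero-phase filtering avoids introducing phase lags that would distort
    correlation structure.
    """
    band.validate_against(x.tr_seconds)
    if x.n_samples < _MIN_FILTER_SAMPLES:
        raise ConfigurationError(
            f"series too short to filter ({x.n_samples} < {_MIN_FILTER_SAMPLES})"
        )
    filtered = _bandpass_array(x.samples, x.tr_seconds, band)
    return BoldSeries(filtered, tr_seconds=x.tr_seconds)


def _bandpass_array(arr: np.ndarray, tr_seconds: float, band: BandSpec, axis: int = 0) -> np.ndarray:
    fs = 1.0 / tr_seconds
    b, a = signal.butter(2, (band.f_low, band.f_high), btype="bandpass", fs=fs)
    return signal.filtfilt(b, a, arr, axis=axis)


def zscore(x: BoldSeries) -> BoldSeries:
    """Standardize each regional series to mean 0, sd 1 (population sd)."""
    return BoldSeries(_zscore_array(x.samples), tr_seconds=x.tr_seconds)


def _zscore_array(arr: np.ndarray, axis: int = 0) -> np.ndarray:
    sd = arr.std(axis=axis, keepdims=True)
    zero = sd <= 0
    if zero.any():
        region = int(np.argwhere(zero)[0][-1])
        raise ConfigurationError(f"zero-variance signal in region {region}")
    return (arr - arr.mean(axis=axis, keepdims=True)) / sd


def compute_fc(x: BoldSeries) -> FCMatrix:
    """Matrix of Pearson correlation coefficients between regional signals."""
    if x.n_samples < 3:
        raise ConfigurationError("need at least 3 samples for correlation")
    if (x.samples.std(axis=0) <= 0).any():
        region = int(np.argmax(x.samples.std(axis=0) <= 0))
        raise ConfigurationError(f"zero-variance signal in region {region}")
    r = np.corrcoef(x.samples, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, kind="pearson")


#: Correlations are clipped to +/-(1 - _ATANH_GUARD) before atanh.
_ATANH_GUARD = 1e-6


def group_fc(fcs: list[FCMatrix]) -> FCMatrix:
    """Fixed-effect group FC: Fisher z = atanh(R) applied entrywise, averaged
    across subjects, transformed back. The diagonal is excluded and reset
    to 1."""
    if not fcs:
        raise ConfigurationError("group_fc needs at least one FC matrix")
    ns = {fc.n_regions for fc in fcs}
    if len(ns) > 1:
        raise ConfigurationError(f"FC matrices disagree on region count {ns}")
    stack = np.stack([fc.values for fc in fcs])
    z = np.arctanh(np.clip(stack, -1 + _ATANH_GUARD, 1 - _ATANH_GUARD))
    avg = np.tanh(z.mean(axis=0))
    np.fill_diagonal(avg, 1.0)
    return FCMatrix(avg, kind="fisher_avg")


def fc_pipeline(subjects: list[BoldSeries], band: BandSpec = DEFAULT_BAND) -> FCMatrix:
    """Band-pass, z-score, per-subject Pearson FC, Fisher-z group average."""
    return group_fc([compute_fc(zscore(bandpass(s, band))) for s in subjects])


def natural_frequencies(cohort: StateDataset | list[BoldSeries], band: BandSpec = DEFAULT_BAND) -> np.ndarray:
    """Per-region intrinsic angular frequencies omega (rad/s).

    For each subject the band-passed signal's Welch power spectrum is
    evaluated per region; the peak frequency inside the analysis band is
    averaged across subjects and converted to omega = 2*pi*f. The estimate
    is constrained to [f_low, f_high] by construction.
    """
    subjects = cohort.subjects if isinstance(cohort, StateDataset) else list(cohort)
    if not subjects:
        raise ConfigurationError("empty cohort")
    if not all(isinstance(s, BoldSeries) for s in subjects):
        raise ConfigurationError("natural frequencies require raw BOLD series, not FC")
    peaks = []
    for s in subjects:
        filt = bandpass(s, band)
        fs = 1.0 / s.tr_seconds
        freqs, pxx = signal.welch(
            filt.samples, fs=fs, nperseg=min(s.n_samples, 128), axis=0
        )
        mask = (freqs >= band.f_low) & (freqs <= band.f_high)
        if not mask.any():
            # band narrower than the spectral resolution: take nearest bin
            mask = np.zeros_like(mask)
            mask[np.argmin(np.abs(freqs - 0.5 * (band.f_low + band.f_high)))] = True
        fband = freqs[mask]
        peaks.append(fband[np.argmax(pxx[mask], axis=0)])
    f_peak = np.clip(np.mean(peaks, axis=0), band.f_low, band.f_high)
    return 2.0 * math.pi * f_peak


#: SSIM configuration from the standard reference: Gaussian-weighted window
#: (sigma 1.5, 11 taps), K1 = 0.01, K2 = 0.03; FC entries span [-1, 1] so the
#: data range is 2.
SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_DATA_RANGE = 2.0


def gof(fc_a: FCMatrix | np.ndarray, fc_b: FCMatrix | np.ndarray) -> float:
    """Goodness of fit between two FC matrices: mean SSIM over the matrix.

    Symmetric in its arguments; equals 1 iff the matrices are identical.
    The optimization target elsewhere in the package is 1 - gof.
    """
    a = fc_a.values if isinstance(fc_a, FCMatrix) else np.asarray(fc_a, dtype=float)
    b = fc_b.values if isinstance(fc_b, FCMatrix) else np.asarray(fc_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError(f"FC shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < SSIM_WINDOW:
        raise ConfigurationError(
            f"SSIM window {SSIM_WINDOW} exceeds matrix size {a.shape}"
        )
    return float(
        structural_similarity(
            a,
            b,
            win_size=SSIM_WINDOW,
            gaussian_weights=True,
            sigma=SSIM_SIGMA,
            use_sample_covariance=False,
            K1=SSIM_K1,
            K2=SSIM_K2,
            data_range=SSIM_DATA_RANGE,
        )
    )
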