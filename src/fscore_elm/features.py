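"""Feature extraction: 31 features per averaged P response.

Six time-domain features describe the P300 morphology on the post-stimulus
window (t ≥ 0): maximum amplitude V_max, its latency t_max, the
latency/amplitude ratio R_LA = t_max / V_max, minimum amplitude V_min,
peak-to-peak amplitude V_ptp = V_max − V_min, and the positive area
A_p = Σ max(x, 0) / fs.

Three frequency-domain features come from a Burg autoregressive power
spectrum of the full epoch: the frequency of maximum power f_max, the
power-weighted mean frequency f_mean, and the power A_lf in the low band
(0.1–3.9 Hz by default) that contains the P3.

Twenty-two time–frequency features are the level-6 approximation
coefficients (A6) of a 6-level discrete wavelet decomposition — seven
coefficient sets in total — using a length-16 orthogonal filter (db8) with
zero-padding, the unique standard combination for which a 500-sample epoch
at 500 Hz yields exactly 22 coefficients in the 0–fs/2⁶ ≈ 0–3.9 Hz band.

All 31 features are min–max normalized to [−1, 1] with limits learned from
the training rows only (``SymmetricMinMaxScaler``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pywt
from scipy.signal import freqz
from scipy.special import expit  # noqa: F401  (re-exported convenience)
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.regression.linear_model import burg as _burg

from .simulate import ErpResponse

__all__ = [
    "FEATURE_NAMES",
    "WaveletConfigError",
    "time_domain_features",
    "burg_psd",
    "frequency_features",
    "wavelet_features",
    "extract_features",
    "SymmetricMinMaxScaler",
    "normalizer_fit",
    "normalizer_apply",
]

N_WAVELET = 22
FEATURE_NAMES: list[str] = [
    "V_max",
    "t_max",
    "R_LA",
    "V_min",
    "V_ptp",
    "A_p",
    "f_max",
    "f_mean",
    "A_lf",
    *[f"W_{i}" for i in range(1, N_WAVELET + 1)],
]


class WaveletConfigError(ValueError):
    """Filter/level/length combination does not yield the expected 22 coefficients."""


def time_domain_features(response: ErpResponse) -> tuple[float, float, float, float, float, float]:
    """(V_max, t_max, R_LA, V_min, V_ptp, A_p) over the post-stimulus window."""
    mask = response.times >= 0
    if not mask.any():
        raise ValueError("no post-stimulus samples to analyse")
    w = response.samples[mask]
    t = response.times[mask]
    i_max = int(np.argmax(w))
    v_max = float(w[i_max])
    t_max = float(t[i_max])
    v_min = float(np.min(w))
    # convention: undefined latency/amplitude ratio at V_max == 0 reports 0
    r_la = t_max / v_max if v_max != 0 else 0.0
    a_p = float(np.sum(np.clip(w, 0.0, None)) / response.fs)
    return v_max, t_max, r_la, v_min, v_max - v_min, a_p


def burg_psd(
    signal: np.ndarray, order: int = 20, n_freq: int = 512, fs: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Autoregressive power spectrum by Burg's method.

    Fits an AR(order) model by minimizing the combined forward/backward
    prediction error (Levinson recursion on reflection coefficients) and
    evaluates the one-sided power spectral density on ``n_freq`` frequencies
    in [0, fs/2].  A zero signal maps to an all-zero spectrum.
    """
    signal = np.asarray(signal, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if signal.size <= order:
        raise ValueError(f"signal length {signal.size} must exceed order {order}")
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    if not np.any(signal):
        return freqs, np.zeros(n_freq)
    rho, sigma2 = _burg(signal, order=order, demean=False)
    _, h = freqz(1.0, np.r_[1.0, -rho], worN=freqs, fs=fs)
    power = float(sigma2) / fs * np.abs(h) ** 2
    return freqs, power


def frequency_features(
    freqs: np.ndarray,
    power: np.ndarray,
    band_lo: float = 0.1,
    band_hi: float = 3.9,
) -> tuple[float, float, float]:
    """(f_max, f_mean, A_lf) from a sampled spectrum.

    f_max is the argmax frequency, f_mean the power-weighted mean
    Σ f·P(f) / Σ P(f), and A_lf the rectangle-rule power in
    [band_lo, band_hi].  An all-zero spectrum returns (0, 0, 0).
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.shape != power.shape or freqs.size < 2:
        raise ValueError("spectrum needs matching frequency and power vectors")
    total = power.sum()
    if total == 0:
        return 0.0, 0.0, 0.0
    df = freqs[1] - freqs[0]
    f_max = float(freqs[int(np.argmax(power))])
    f_mean = float(np.sum(freqs * power) / total)
    band = (freqs >= band_lo) & (freqs <= band_hi)
    a_lf = float(np.sum(power[band]) * df)
    return f_max, f_mean, a_lf


def wavelet_features(
    samples: np.ndarray,
    wavelet: str = "db8",
    level: int = 6,
    mode: str = "zero",
) -> np.ndarray:
    """Level-``level`` approximation coefficients of the DWT (W_1 … W_22).

    With the defaults (length-16 db8 filter, zero-padding full convolution,
    6 levels) a 500-sample epoch cascades 500→257→136→75→45→30→22, so the
    lowest band carries exactly 22 coefficients.  Any configuration that
    yields a different count raises, because the feature table has exactly
    22 wavelet columns.
    """
    samples = np.asarray(samples, dtype=float)
    with warnings.catch_warnings():
        # deep decompositions of short epochs are intentional here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(samples, wavelet, mode=mode, level=level)
    approx = np.asarray(coeffs[0], dtype=float)
    if approx.size != N_WAVELET:
        raise WaveletConfigError(
            f"wavelet={wavelet!r}, level={level}, mode={mode!r} on a "
            f"{samples.size}-sample epoch yields {approx.size} approximation "
            f"coefficients, expected {N_WAVELET}"
        )
    return approx


def extract_features(
    responses: list[ErpResponse],
    burg_order: int = 20,
    n_freq: int = 512,
    band_lo: float = 0.1,
    band_hi: float = 3.9,
    wavelet: str = "db8",
    level: int = 6,
    mode: str = "zero",
) -> pd.DataFrame:
    """Build the feature table: one 31-entry row per response.

    Columns are ``subject_id``, ``label`` then the 31 features in the fixed
    order of :data:`FEATURE_NAMES`.  An empty input yields an empty table
    with the full header.
    """
    rows = []
    for idx, r in enumerate(responses):
        try:
            td = time_domain_features(r)
            freqs, power = burg_psd(r.samples, order=burg_order, n_freq=n_freq, fs=r.fs)
            fd = frequency_features(freqs, power, band_lo=band_lo, band_hi=band_hi)
            wv = wavelet_features(r.samples, wavelet=wavelet, level=level, mode=mode)
        except ValueError as exc:
            raise type(exc)(f"response {idx} ({r.subject_id}): {exc}") from exc
        rows.append([r.subject_id, r.label, *td, *fd, *wv])
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])


class SymmetricMinMaxScaler(BaseEstimator, TransformerMixin):
    """Min–max normalization onto [−1, 1].

    ``x' = 2 (x − min) / (max − min) − 1`` with per-feature limits learned at
    fit time; a constant feature maps to 0, and unseen values outside the
    training range are deliberately not clipped (a test value of 20 against
    training limits [0, 10] transforms to 3.0).
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=1)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, scaler was fit on {self.n_features_in_}"
            )
        span = self.data_max_ - self.data_min_
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = 2.0 * (X[:, ok] - self.data_min_[ok]) / span[ok] - 1.0
        return out


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("subject_id", "label")]


def normalizer_fit(table: pd.DataFrame) -> SymmetricMinMaxScaler:
    """Fit the [−1, 1] scaler on a feature table's feature columns."""
    return SymmetricMinMaxScaler().fit(table[_feature_cols(table)].to_numpy())


def normalizer_apply(scaler: SymmetricMinMaxScaler, table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``table`` with feature columns normalized."""
    cols = _feature_cols(table)
    out = table.copy()
    out[cols] = scaler.transform(table[cols].to_numpy())
    return out
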