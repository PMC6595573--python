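"""Raw-spectrum conditioning: trim, Savitzky-Golay smoothing, downsampling,
and train-statistics standardization.

The default pipeline mirrors common benchtop practice: drop the noisy
350-450 nm edge, smooth with a 5-point order-2 Savitzky-Golay filter, then
decimate to a 5-nm grid anchored at 450 nm (2051 bands -> 411 bands).
Standardization (zero mean, unit sample variance per column) is fitted on the
training split only and reused on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraMatrix

__all__ = [
    "PreprocessConfig",
    "Standardizer",
    "trim",
    "savitzky_golay",
    "downsample",
    "preprocess_matrix",
    "fit_standardizer",
]


@dataclass
class PreprocessConfig:
    trim_min_nm: float = 450.0
    trim_max_nm: float = 2500.0
    sg_window: int = 5
    sg_polyorder: int = 2
    downsample_step_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ValueError("sg_window must be odd and >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be smaller than sg_window")
        if self.trim_min_nm >= self.trim_max_nm:
            raise ValueError("trim_min_nm must be below trim_max_nm")
        if self.downsample_step_nm <= 0:
            raise ValueError("downsample_step_nm must be positive")


def trim(spectra: SpectraMatrix, lo: float, hi: float) -> SpectraMatrix:
    """Keep wavelengths lo <= lambda <= hi, preserving order."""
    keep = (spectra.wavelengths_nm >= lo) & (spectra.wavelengths_nm <= hi)
    if not keep.any():
        raise ValueError(
            f"trim window [{lo}, {hi}] nm retains no bands of the grid "
            f"{spectra.wavelengths_nm[0]:g}-{spectra.wavelengths_nm[-1]:g} nm"
        )
    return SpectraMatrix(
        sample_ids=spectra.sample_ids,
        wavelengths_nm=spectra.wavelengths_nm[keep],
        values=spectra.values[:, keep],
    )


def savitzky_golay(spectra: SpectraMatrix, window: int = 5, polyorder: int = 2) -> SpectraMatrix:
    """Savitzky-Golay smoothing along the wavelength axis.

    Interior bands get the classic symmetric-window least-squares value; edge
    bands are filled from a same-order polynomial fitted to the edge window
    (one-sided fit), so the output keeps the full band count.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window >= spectra.n_bands:
        raise ValueError(
            f"window {window} does not fit a {spectra.n_bands}-band spectrum"
        )
    smoothed = savgol_filter(
        spectra.values, window_length=window, polyorder=polyorder,
        axis=1, mode="interp",
    )
    return SpectraMatrix(spectra.sample_ids, spectra.wavelengths_nm, smoothed)


def downsample(spectra: SpectraMatrix, step_nm: float, anchor_nm: float | None = None) -> SpectraMatrix:
    """Decimate to wavelengths anchor, anchor+step, ... (point selection).

    Values are taken as-is at the retained wavelengths — no re-averaging, so
    smoothing must happen first if noise reduction is wanted.
    """
    wl = spectra.wavelengths_nm
    if anchor_nm is None:
        anchor_nm = wl[0]
    if not np.any(np.isclose(wl, anchor_nm)):
        raise ValueError(f"anchor {anchor_nm} nm is not on the grid")
    offsets = (wl - anchor_nm) / step_nm
    keep = (wl >= anchor_nm - 1e-9) & np.isclose(offsets, np.round(offsets))
    return SpectraMatrix(spectra.sample_ids, wl[keep], spectra.values[:, keep])


def preprocess_matrix(spectra: SpectraMatrix, config: PreprocessConfig | None = None) -> SpectraMatrix:
    """trim -> Savitzky-Golay -> downsample with the given (or default) config."""
    cfg = config or PreprocessConfig()
    out = trim(spectra, cfg.trim_min_nm, cfg.trim_max_nm)
    out = savitzky_golay(out, cfg.sg_window, cfg.sg_polyorder)
    return downsample(out, cfg.downsample_step_nm, anchor_nm=cfg.trim_min_nm)


class Standardizer:
    """Column-wise zero-center / unit-sample-variance scaling (n-1 denominator)."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray, fitted_on: int):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        self.fitted_on = int(fitted_on)

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim == 2 and X.shape[0] == 1 and X.size > 1:
            # a 1-D vector is a single column, not a single row
            X = X.T
        if X.shape[0] < 2:
            raise ValueError("standardizer needs at least 2 rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) at index {zero.tolist()}: cannot scale"
            )
        return cls(mean, sd, X.shape[0])

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1 and self.mean.size == 1:
            return X.reshape(-1, 1)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"expected {self.mean.size} columns, got {X.shape[1]}"
            )
        return X

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (self._check(X) - self.mean) / self.sd

    def invert(self, Z: np.ndarray) -> np.ndarray:
        return self._check(Z) * self.sd + self.mean


def fit_standardizer(X: np.ndarray) -> Standardizer:
    return Standardizer.fit(X)
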