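"""Two-band normalized-difference vegetation indices and the exhaustive search.

All indices share the form (B1 - B2) / (B1 + B2) on reflectance at two bands.
Three literature indices are built in: GNDVI (800/550 nm, green chlorophyll
sensitivity), RENDVI (750/705 nm, red edge) and NDWI (860/1240 nm, leaf
water). Index-to-trait calibration is ordinary least squares on a linear plus
quadratic term; the exhaustive search scores every unordered band pair by the
absolute Pearson correlation of its index with the trait on the training
samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import SpectraMatrix

__all__ = [
    "VIDefinition",
    "VIModel",
    "VICalibration",
    "BandSearchResult",
    "builtin_vis",
    "compute_vi",
    "fit_vi_model",
    "exhaustive_band_search",
]


@dataclass(frozen=True)
class VIDefinition:
    """A named normalized difference (R_b1 - R_b2) / (R_b1 + R_b2)."""

    name: str
    band1_nm: float
    band2_nm: float

    def __post_init__(self) -> None:
        if self.band1_nm == self.band2_nm:
            raise ValueError("the two bands must differ")


def builtin_vis() -> list[VIDefinition]:
    """The three literature indices in their conventional orientations."""
    return [
        VIDefinition("GNDVI", 800.0, 550.0),
        VIDefinition("RENDVI", 750.0, 705.0),
        VIDefinition("NDWI", 860.0, 1240.0),
    ]


def compute_vi(spectra: SpectraMatrix, definition: VIDefinition) -> np.ndarray:
    """Per-sample index values; NaN where the band sum is non-positive.

    Both bands must sit exactly on the grid — no interpolation; a miss raises
    with the nearest available bands named.
    """
    i1 = spectra.band_index(definition.band1_nm)
    i2 = spectra.band_index(definition.band2_nm)
    r1 = spectra.values[:, i1]
    r2 = spectra.values[:, i2]
    denom = r1 + r2
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, (r1 - r2) / denom, np.nan)
    return vals


@dataclass
class VIModel:
    """Quadratic index-to-trait calibration: trait ~ 1 + v + v^2 (OLS)."""

    definition: VIDefinition
    intercept: float
    linear_coef: float
    quadratic_coef: float
    n_train: int = 0

    def predict(self, index_values: np.ndarray) -> np.ndarray:
        v = np.asarray(index_values, dtype=float)
        return self.intercept + self.linear_coef * v + self.quadratic_coef * v**2

    def summary(self) -> str:
        d = self.definition
        return "\n".join([
            f"VI calibration: {d.name} ({d.band1_nm:g}, {d.band2_nm:g} nm)",
            "=" * 40,
            f"trait = {self.intercept:.6g} + {self.linear_coef:.6g} v "
            f"+ {self.quadratic_coef:.6g} v^2",
            f"training samples : {self.n_train}",
        ])


class VICalibration:
    """Model object pairing a VI definition with trait data; fit() -> VIModel."""

    def __init__(self, index_values, trait_values, definition: VIDefinition):
        self.v = np.asarray(index_values, dtype=float).ravel()
        self.y = np.asarray(trait_values, dtype=float).ravel()
        self.definition = definition
        if self.v.size != self.y.size:
            raise ValueError("index and trait lengths differ")
        if self.v.size < 3:
            raise ValueError("need at least 3 samples for the quadratic fit")
        if np.std(self.y) == 0:
            raise ValueError("zero-variance trait")
        if np.std(self.v) == 0:
            raise ValueError("constant index values: collinear design")

    def fit(self) -> VIModel:
        A = np.column_stack([np.ones_like(self.v), self.v, self.v**2])
        coef, _, rank, _ = np.linalg.lstsq(A, self.y, rcond=None)
        if rank < 3:
            # v and v^2 collinear (e.g. two distinct index values): the
            # quadratic term is unidentifiable
            raise ValueError("collinear quadratic design; index has < 3 distinct values")
        return VIModel(self.definition, float(coef[0]), float(coef[1]),
                       float(coef[2]), n_train=self.v.size)


def fit_vi_model(index_values, trait_values,
                 definition: VIDefinition | None = None) -> VIModel:
    definition = definition or VIDefinition("custom", 1.0, 2.0)
    return VICalibration(index_values, trait_values, definition).fit()


@dataclass
class BandSearchResult:
    """Winner of the exhaustive two-band search for one trait."""

    best_definition: VIDefinition
    train_correlation: float
    n_pairs_evaluated: int
    correlation_matrix: np.ndarray | None = field(default=None, repr=False)
    wavelengths_nm: np.ndarray | None = field(default=None, repr=False)


def exhaustive_band_search(spectra: SpectraMatrix, trait_values,
                           keep_matrix: bool = False) -> BandSearchResult:
    """Score every unordered band pair and return the |r|-maximizing index.

    For each pair the index is oriented (R_long - R_short)/(R_long + R_short);
    the normalized difference is antisymmetric under band swap, so |r| does
    not depend on orientation and the unordered search is exhaustive. Ties in
    |r| resolve to the lexicographically smallest (short, long) pair. Must be
    run on training samples only when the winner will be evaluated elsewhere.
    """
    y = np.asarray(trait_values, dtype=float).ravel()
    R = spectra.values
    wl = spectra.wavelengths_nm
    n, p = R.shape
    if y.size != n:
        raise ValueError("trait length does not match sample count")
    if np.std(y) == 0:
        raise ValueError("constant trait: correlation undefined")
    if p < 2:
        raise ValueError("need at least 2 bands to search")

    yc = y - y.mean()
    y_ss = float(yc @ yc)
    best_abs_r = -1.0
    best_r = 0.0
    best_pair = (0, 1)
    n_pairs = 0
    corr = np.zeros((p, p)) if keep_matrix else None
    # wavelengths ascending: index i is the shorter band, j > i the longer;
    # index = (R_j - R_i) / (R_j + R_i), vectorized over j for each i
    for i in range(p - 1):
        ri = R[:, i : i + 1]
        rj = R[:, i + 1 :]
        denom = rj + ri
        with np.errstate(divide="ignore", invalid="ignore"):
            V = np.where(denom > 0, (rj - ri) / denom, np.nan)
        Vc = V - np.nanmean(V, axis=0)
        num = yc @ np.where(np.isnan(Vc), 0.0, Vc)
        vss = np.nansum(Vc * Vc, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_row = num / np.sqrt(vss * y_ss)
        r_row = np.where(vss > 0, r_row, 0.0)
        n_pairs += r_row.size
        if corr is not None:
            corr[i, i + 1 :] = np.abs(r_row)
            corr[i + 1 :, i] = np.abs(r_row)
        k = int(np.argmax(np.abs(r_row)))
        if abs(r_row[k]) > best_abs_r + 1e-15:
            best_abs_r = abs(r_row[k])
            best_r = float(r_row[k])
            best_pair = (i, i + 1 + k)
    short_i, long_j = best_pair
    definition = VIDefinition(
        name=f"ND_{wl[long_j]:g}_{wl[short_i]:g}",
        band1_nm=float(wl[long_j]),
        band2_nm=float(wl[short_i]),
    )
    return BandSearchResult(
        best_definition=definition,
        train_correlation=best_r,
        n_pairs_evaluated=n_pairs,
        correlation_matrix=corr,
        wavelengths_nm=wl if keep_matrix else None,
    )
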