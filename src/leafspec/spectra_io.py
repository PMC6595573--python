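"""Spectral and trait table I/O, replicate averaging, and lab trait derivation.

The canonical on-disk format is a wide CSV: one row per scan, with a sample id
column, a replicate label column, then one numeric column per wavelength in nm.
Trait tables are plain CSVs keyed by sample id with one column per leaf trait
(CHL in umol/m2, LWC in %, SLA in m2/kg, N/P/K in %) plus optional lab fields
(FW and DW in grams, LA in m2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraMatrix",
    "TraitTable",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_traits_csv",
    "write_traits_csv",
    "average_replicates",
    "derive_traits",
]

#: the raw instrument grid: 350..2500 nm at 1 nm (2151 points)
RAW_GRID_NM = np.arange(350, 2501, dtype=float)

TRAIT_NAMES = ("CHL", "LWC", "SLA", "N", "P", "K")
TRAIT_UNITS = {
    "CHL": "umol/m2",
    "LWC": "%",
    "SLA": "m2/kg",
    "N": "%",
    "P": "%",
    "K": "%",
}


class SpectraFormatError(ValueError):
    """Raised when a spectra file violates the wide-CSV contract."""


@dataclass
class Spectrum:
    """A single reflectance scan on a strictly increasing wavelength grid."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sample_id: str
    replicate_label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths_nm.shape != self.reflectance.shape:
            raise ValueError(
                f"wavelengths ({self.wavelengths_nm.size}) and reflectance "
                f"({self.reflectance.size}) lengths differ for sample "
                f"{self.sample_id!r}"
            )
        if self.wavelengths_nm.size and np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError(f"non-finite reflectance in sample {self.sample_id!r}")
        if np.any(self.reflectance < 0):
            raise ValueError(f"negative reflectance in sample {self.sample_id!r}")

    def __len__(self) -> int:
        return self.wavelengths_nm.size


@dataclass
class SpectraMatrix:
    """Sample-by-band reflectance matrix on a shared wavelength grid."""

    sample_ids: list[str]
    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{n} rows but {len(self.sample_ids)} sample ids")
        if p != self.wavelengths_nm.size:
            raise ValueError(
                f"{p} columns but {self.wavelengths_nm.size} wavelengths"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SpectraMatrix must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of an exactly matching band; raises with nearest neighbours."""
        idx = np.nonzero(np.isclose(self.wavelengths_nm, wavelength_nm))[0]
        if idx.size == 0:
            order = np.argsort(np.abs(self.wavelengths_nm - wavelength_nm))
            near = sorted(self.wavelengths_nm[order[:2]])
            raise KeyError(
                f"band {wavelength_nm} nm not on the grid; nearest available "
                f"bands are {near[0]:g} and {near[-1]:g} nm"
            )
        return int(idx[0])

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{w:g}" for w in self.wavelengths_nm]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


@dataclass
class TraitTable:
    """Per-sample leaf trait values backed by a DataFrame indexed by sample id."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in trait table")
        self.data.index = self.data.index.astype(str)
        self._validate()

    def _validate(self) -> None:
        d = self.data
        if "LWC" in d and ((d["LWC"] < 0) | (d["LWC"] > 100)).any():
            raise ValueError("LWC outside [0, 100] %")
        if "SLA" in d and (d["SLA"] <= 0).any():
            raise ValueError("SLA must be positive")
        for col in ("N", "P", "K", "CHL"):
            if col in d and (d[col] < 0).any():
                raise ValueError(f"{col} must be non-negative")
        if "FW" in d and "DW" in d:
            both = d[["FW", "DW"]].dropna()
            if (both["DW"] > both["FW"]).any():
                raise ValueError("dry weight exceeds fresh weight")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c in TRAIT_NAMES]

    def values_for(self, trait: str, sample_ids: list[str] | None = None) -> np.ndarray:
        if trait not in self.data.columns:
            raise KeyError(f"trait {trait!r} not in table (have {list(self.data.columns)})")
        series = self.data[trait]
        if sample_ids is not None:
            series = series.loc[list(sample_ids)]
        return series.to_numpy(dtype=float)


def read_spectra_csv(path, layout: str = "wide") -> list[Spectrum]:
    """Read a wide spectra CSV into one :class:`Spectrum` per row.

    The header must name an id column, a replicate column, then numeric
    wavelength columns (nm). Wavelength columns may appear in any order; the
    output grid is always sorted ascending.
    """
    if layout != "wide":
        raise ValueError(f"unsupported layout {layout!r}; only 'wide' is defined")
    import csv as _csv

    with open(path, newline="") as fh:
        header = next(_csv.reader(fh), [])
    seen: set[str] = set()
    for name in header[2:]:
        if name in seen:
            raise SpectraFormatError(f"duplicate wavelength column {name!r}")
        seen.add(name)
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise SpectraFormatError(
            "expected an id column, a replicate column and wavelength columns"
        )
    id_col, rep_col = df.columns[0], df.columns[1]
    wl_cols = list(df.columns[2:])
    wavelengths = []
    for c in wl_cols:
        try:
            wavelengths.append(float(c))
        except ValueError:
            raise SpectraFormatError(f"non-numeric wavelength column {c!r}") from None
    wavelengths = np.asarray(wavelengths)
    if np.unique(wavelengths).size != wavelengths.size:
        dup = wavelengths[pd.Index(wavelengths).duplicated()][0]
        raise SpectraFormatError(f"duplicate wavelength column {dup:g}")
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    wl_cols = [wl_cols[i] for i in order]

    spectra: list[Spectrum] = []
    for row_num, (_, row) in enumerate(df.iterrows(), start=1):
        refl = np.empty(wavelengths.size)
        for j, col in enumerate(wl_cols):
            cell = row[col]
            try:
                refl[j] = float(cell)
            except (TypeError, ValueError):
                raise SpectraFormatError(
                    f"non-numeric reflectance cell {cell!r} at row {row_num}, "
                    f"column {col!r}"
                ) from None
        if not np.all(np.isfinite(refl)):
            j = int(np.nonzero(~np.isfinite(refl))[0][0])
            raise SpectraFormatError(
                f"non-finite reflectance at row {row_num}, column {wl_cols[j]!r}"
            )
        spectra.append(
            Spectrum(
                wavelengths_nm=wavelengths,
                reflectance=refl,
                sample_id=str(row[id_col]),
                replicate_label=str(row[rep_col]),
            )
        )
    return spectra


def write_spectra_csv(path, spectra: list[Spectrum] | SpectraMatrix) -> None:
    """Write scans (or an averaged matrix) in the wide CSV layout."""
    if isinstance(spectra, SpectraMatrix):
        spectra = [
            Spectrum(spectra.wavelengths_nm, spectra.values[i], sid, "mean")
            for i, sid in enumerate(spectra.sample_ids)
        ]
    if not spectra:
        raise ValueError("nothing to write")
    grid = spectra[0].wavelengths_nm
    for s in spectra:
        if not np.array_equal(s.wavelengths_nm, grid):
            raise ValueError(f"scan {s.sample_id!r} is on a different grid")
    cols = {"sample_id": [s.sample_id for s in spectra],
            "replicate": [s.replicate_label for s in spectra]}
    for j, w in enumerate(grid):
        cols[f"{w:g}"] = [repr(float(s.reflectance[j])) for s in spectra]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_traits_csv(path) -> TraitTable:
    df = pd.read_csv(path, index_col="sample_id")
    return TraitTable(df)


def write_traits_csv(path, table: TraitTable) -> None:
    table.data.to_csv(path, index_label="sample_id")


def average_replicates(scans: list[Spectrum], group_key=None) -> SpectraMatrix:
    """Average replicate scans of each plant into one row per sample.

    All scans of a sample (typically 3 leaves x 3 positions = 9) are treated
    symmetrically: each band of the output row is the arithmetic mean over the
    sample's scans. ``group_key`` maps a scan to its sample id (defaults to the
    scan's own ``sample_id``).
    """
    if not scans:
        raise ValueError("no scans to average")
    if group_key is None:
        group_key = lambda s: s.sample_id  # noqa: E731
    grid = scans[0].wavelengths_nm
    for s in scans:
        if not np.array_equal(s.wavelengths_nm, grid):
            raise ValueError(
                f"scan {s.sample_id!r}/{s.replicate_label!r} is on a different "
                "wavelength grid"
            )
    groups: dict[str, list[Spectrum]] = {}
    for s in scans:
        groups.setdefault(str(group_key(s)), []).append(s)
    sample_ids = list(groups)
    values = np.vstack(
        [np.mean([s.reflectance for s in groups[sid]], axis=0) for sid in sample_ids]
    )
    return SpectraMatrix(sample_ids=sample_ids, wavelengths_nm=grid, values=values)


def derive_traits(FW: float, DW: float, LA: float) -> tuple[float, float]:
    """Derive LWC (%) and SLA (m2/kg) from fresh/dry weight (g) and leaf area (m2).

    LWC = (FW - DW) / FW * 100;  SLA = LA / DW with DW converted g -> kg.
    """
    if FW <= 0 or DW <= 0 or LA <= 0:
        raise ValueError("FW, DW and LA must all be positive")
    if DW > FW:
        raise ValueError(f"dry weight {DW} g exceeds fresh weight {FW} g")
    lwc = (FW - DW) / FW * 100.0
    sla = LA / (DW / 1000.0)
    return lwc, sla
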