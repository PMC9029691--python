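"""Data containers and CSV I/O for absorbance spectra and sample metadata.

Spectra are stored wide: one row per mosquito, one column per wavelength in
nanometres, values in log(1/R) absorbance units. Metadata (age, parity,
cohort, SCP1 delta-Ct) travel in a parallel table keyed on ``sample_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PARITY_STATES = ("nulliparous", "parous", "unknown")

__all__ = [
    "Spectrum",
    "SampleMetadata",
    "SpectraSet",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "join_metadata",
    "reflectance_to_absorbance",
    "PARITY_STATES",
]


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a strictly increasing nm grid."""

    sample_id: str
    wavelengths_nm: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size or wl.size < 2:
            raise ValueError("wavelengths and absorbance must be equal-length vectors of length >= 2")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(ab))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-mosquito annotations attached to a spectrum row.

    ``age_days`` is NaN for field samples of unknown chronological age;
    ``scp1_delta_ct`` is NaN where the qPCR assay was not run (nulliparous
    individuals are typically not assayed).
    """

    sample_id: str
    age_days: float = np.nan
    parity: str = "unknown"
    cohort: str = ""
    scp1_delta_ct: float = np.nan
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parity not in PARITY_STATES:
            raise ValueError(f"parity must be one of {PARITY_STATES}, got {self.parity!r}")
        if np.isfinite(self.age_days) and self.age_days < 0:
            raise ValueError("age_days must be nonnegative or NaN")


class SpectraSet:
    """n samples x p wavelengths on a shared grid, with aligned metadata."""

    def __init__(
        self,
        wavelengths_nm: Sequence[float],
        absorbance_matrix: np.ndarray,
        metadata: Sequence[SampleMetadata],
    ) -> None:
        wl = np.asarray(wavelengths_nm, dtype=float)
        X = np.atleast_2d(np.asarray(absorbance_matrix, dtype=float))
        if wl.ndim != 1:
            raise ValueError("wavelength grid must be 1-D")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if X.shape[0] != len(metadata):
            raise ValueError(f"{X.shape[0]} spectra rows but {len(metadata)} metadata records")
        if X.shape[1] != wl.size:
            raise ValueError(f"matrix has {X.shape[1]} columns but grid has {wl.size} points")
        ids = [m.sample_id for m in metadata]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated sample_id: {dupes}")
        self.wavelengths_nm = wl
        self.absorbance_matrix = X
        self.metadata = list(metadata)

    # -- basic container protocol -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance_matrix.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.metadata]

    @property
    def ages(self) -> np.ndarray:
        return np.array([m.age_days for m in self.metadata], dtype=float)

    @property
    def parity(self) -> list[str]:
        return [m.parity for m in self.metadata]

    @property
    def delta_ct(self) -> np.ndarray:
        return np.array([m.scp1_delta_ct for m in self.metadata], dtype=float)

    def __len__(self) -> int:
        return self.n_samples

    def __getitem__(self, sel) -> "SpectraSet":
        idx = np.arange(self.n_samples)[sel]
        idx = np.atleast_1d(idx)
        return SpectraSet(
            self.wavelengths_nm,
            self.absorbance_matrix[idx],
            [self.metadata[i] for i in idx],
        )

    def subset_by_ids(self, ids: Sequence[str]) -> "SpectraSet":
        lookup = {m.sample_id: i for i, m in enumerate(self.metadata)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"sample ids not present: {missing}")
        return self[[lookup[s] for s in ids]]

    def with_grid(self, wavelengths_nm: np.ndarray, matrix: np.ndarray) -> "SpectraSet":
        """New set on a different grid, same metadata (used by preprocessing)."""
        return SpectraSet(wavelengths_nm, matrix, self.metadata)

    def spectra(self):
        for m, row in zip(self.metadata, self.absorbance_matrix):
            yield Spectrum(m.sample_id, self.wavelengths_nm, row)

    def to_metadata_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.metadata:
            row = {
                "sample_id": m.sample_id,
                "age_days": m.age_days,
                "parity": m.parity,
                "cohort": m.cohort,
                "scp1_delta_ct": m.scp1_delta_ct,
            }
            row.update(m.extras)
            rows.append(row)
        return pd.DataFrame(rows)


def reflectance_to_absorbance(reflectance: np.ndarray) -> np.ndarray:
    """Convert reflectance R in (0, 1] to absorbance log10(1/R).

    R > 1 is physically suspect (specular glare off the Spectralon plate)
    but still computable; it triggers a warning rather than an error.
    """
    R = np.asarray(reflectance, dtype=float)
    if np.any(R <= 0):
        raise ValueError("reflectance must be positive")
    if np.any(R > 1):
        warnings.warn("reflectance values > 1 encountered; absorbance will be negative", stacklevel=2)
    return -np.log10(R)


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide spectra CSV: header ``sample_id,<nm>,<nm>,...``, one row per sample."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.columns.size == 0 or df.columns[0] != "sample_id":
        raise ValueError("no header: first column must be 'sample_id'")
    if df.columns.size < 3:
        raise ValueError("need at least 2 wavelength columns")
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength in header: {exc}") from exc
    order = np.argsort(wl)
    wl_sorted = wl[order]
    if np.any(np.diff(wl_sorted) <= 0):
        raise ValueError("wavelength grid is not strictly increasing (duplicate wavelengths)")
    X = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-numeric or non-finite absorbance cell")
    meta = [SampleMetadata(sample_id=str(s)) for s in df["sample_id"]]
    return SpectraSet(wl_sorted, X, meta)


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write the wide-CSV layout at full float precision (17 significant digits)."""
    df = pd.DataFrame(
        spectra.absorbance_matrix,
        columns=[format(w, ".17g") for w in spectra.wavelengths_nm],
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


_META_COLUMNS = ["sample_id", "age_days", "parity", "cohort", "scp1_delta_ct"]


def read_metadata_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata CSV must have a 'sample_id' column")
    return df


def write_metadata_csv(spectra: SpectraSet, path) -> None:
    spectra.to_metadata_frame().to_csv(path, index=False)


def join_metadata(spectra: SpectraSet, table: pd.DataFrame | str | Path) -> SpectraSet:
    """Attach metadata rows to spectra by sample_id (left join on the spectra).

    Every spectrum must have a metadata row; extra table rows are ignored.
    Columns beyond the standard five are preserved as opaque extras.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_metadata_csv(table)
    indexed = table.set_index(table["sample_id"].astype(str))
    missing = [s for s in spectra.sample_ids if s not in indexed.index]
    if missing:
        raise KeyError(f"sample ids missing from metadata table: {missing}")

    def _num(row, col):
        if col not in row or pd.isna(row[col]):
            return np.nan
        return float(row[col])

    new_meta = []
    for m in spectra.metadata:
        row = indexed.loc[m.sample_id]
        parity = row.get("parity", "unknown")
        if pd.isna(parity) or parity == "":
            parity = "unknown"
        extras = {
            k: row[k]
            for k in table.columns
            if k not in _META_COLUMNS
        }
        new_meta.append(
            SampleMetadata(
                sample_id=m.sample_id,
                age_days=_num(row, "age_days"),
                parity=str(parity),
                cohort="" if pd.isna(row.get("cohort", "")) else str(row.get("cohort", "")),
                scp1_delta_ct=_num(row, "scp1_delta_ct"),
                extras=extras,
            )
        )
    return SpectraSet(spectra.wavelengths_nm, spectra.absorbance_matrix, new_meta)
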