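"""Spectral preprocessing: band selection, multiplicative scatter correction,
Savitzky-Golay derivative.

The pipeline order is band selection -> MSC -> SG derivative. MSC is fitted on
absorbance, where multiplicative scatter is physically defined; its reference
(the calibration-set mean spectrum) is stored so test and field spectra are
corrected against the training reference rather than their own mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_coeffs

from .io import SpectraSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "select_bands",
    "fit_msc_reference",
    "apply_msc",
    "savgol_derivative",
    "apply_pipeline",
]


@dataclass
class PreprocessConfig:
    """Per-model preprocessing settings.

    Parameters
    ----------
    range_nm
        Inclusive (low, high) spectral range in nm. The visible region below
        700 nm is noisy on mosquito cuticle scans and is excluded by default.
    band_regions
        Inclusive (low, high) sub-bands kept inside the range; empty keeps
        the whole range.
    apply_msc
        Whether to run multiplicative scatter correction.
    sg_window, sg_polyorder, sg_deriv_order
        Savitzky-Golay window length in points (odd), local polynomial order,
        and derivative order (1 = first derivative, "SG1").
    """

    range_nm: tuple[float, float] = (700.0, 2300.0)
    band_regions: tuple[tuple[float, float], ...] = ()
    apply_msc: bool = True
    sg_window: int = 31
    sg_polyorder: int = 2
    sg_deriv_order: int = 1
    msc_reference: np.ndarray | None = None
    selected_grid: np.ndarray | None = None
    output_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo, hi = self.range_nm
        if not lo < hi:
            raise ValueError("range_nm must satisfy low < high")
        bands = tuple(tuple(map(float, b)) for b in self.band_regions)
        for b in bands:
            if not b[0] < b[1]:
                raise ValueError(f"band {b} must satisfy low < high")
        if any(b2[0] <= b1[1] for b1, b2 in zip(bands, bands[1:])):
            raise ValueError("band regions must be sorted and non-overlapping")
        self.band_regions = bands
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if not 0 <= self.sg_deriv_order <= self.sg_polyorder:
            raise ValueError("sg_deriv_order must be in [0, sg_polyorder]")

    def to_dict(self) -> dict:
        return {
            "range_nm": list(self.range_nm),
            "band_regions": [list(b) for b in self.band_regions],
            "apply_msc": self.apply_msc,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv_order": self.sg_deriv_order,
            "msc_reference": None if self.msc_reference is None else list(self.msc_reference),
            "selected_grid": None if self.selected_grid is None else list(self.selected_grid),
            "output_grid": None if self.output_grid is None else list(self.output_grid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        cfg = cls(
            range_nm=tuple(d["range_nm"]),
            band_regions=tuple(tuple(b) for b in d.get("band_regions", [])),
            apply_msc=d.get("apply_msc", True),
            sg_window=d.get("sg_window", 31),
            sg_polyorder=d.get("sg_polyorder", 2),
            sg_deriv_order=d.get("sg_deriv_order", 1),
        )
        for key in ("msc_reference", "selected_grid", "output_grid"):
            val = d.get(key)
            if val is not None:
                setattr(cfg, key, np.asarray(val, dtype=float))
        return cfg


def select_bands(spectra: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    """Keep wavelengths inside the configured range and band regions.

    Pure subset operation: endpoints inclusive on both sides, order preserved.
    """
    wl = spectra.wavelengths_nm
    lo, hi = config.range_nm
    keep = (wl >= lo) & (wl <= hi)
    if config.band_regions:
        in_band = np.zeros_like(keep)
        for b_lo, b_hi in config.band_regions:
            in_band |= (wl >= b_lo) & (wl <= b_hi)
        keep &= in_band
    if not keep.any():
        raise ValueError("band/range selection removed every wavelength")
    return spectra.with_grid(wl[keep], spectra.absorbance_matrix[:, keep])


def fit_msc_reference(spectra: SpectraSet) -> np.ndarray:
    """Mean spectrum of the calibration set — the MSC scatter reference."""
    if spectra.n_samples < 2:
        raise ValueError("MSC reference requires at least 2 spectra")
    return spectra.absorbance_matrix.mean(axis=0)


def apply_msc(spectra: SpectraSet, reference: np.ndarray) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference, x ~ a + b*ref, and
    replaced by (x - a) / b, removing per-sample additive offset and
    multiplicative pathlength scatter. Samples whose slope |b| is numerically
    zero cannot be corrected; they are dropped with a warning.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size != spectra.n_wavelengths:
        raise ValueError("reference length does not match wavelength grid")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom < 1e-24:
        raise ValueError("MSC reference is constant")

    X = spectra.absorbance_matrix
    Xc = X - X.mean(axis=1, keepdims=True)
    b = (Xc @ ref_c) / denom
    a = X.mean(axis=1) - b * ref.mean()

    ok = np.abs(b) >= 1e-12
    if not ok.all():
        bad = [spectra.metadata[i].sample_id for i in np.where(~ok)[0]]
        warnings.warn(f"MSC slope ~ 0; excluding samples {bad}", stacklevel=2)
        logger.warning("MSC excluded %d samples with near-zero scatter slope: %s", len(bad), bad)
    corrected = (X[ok] - a[ok, None]) / b[ok, None]
    out = SpectraSet(spectra.wavelengths_nm, corrected, [spectra.metadata[i] for i in np.where(ok)[0]])
    return out


def _uniform_segments(wl: np.ndarray, rtol: float = 1e-6) -> list[slice]:
    """Maximal runs of uniform spacing (band gaps break the grid into segments)."""
    if wl.size < 2:
        return [slice(0, wl.size)]
    d = np.diff(wl)
    step = np.median(d)
    breaks = np.where(np.abs(d - step) > rtol * max(abs(step), 1.0))[0]
    edges = [0, *(b + 1 for b in breaks), wl.size]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def savgol_derivative(
    spectra: SpectraSet, window: int, polyorder: int, deriv: int = 1
) -> SpectraSet:
    """Savitzky-Golay derivative on each uniformly spaced grid segment.

    Interior points are convolved with the SG least-squares coefficients,
    scaled by the grid spacing; the (window-1)/2 points at each segment edge
    are dropped rather than padded, so no spectral values are fabricated.
    Band-selected grids are handled segment by segment; each segment must be
    uniformly spaced (relative tolerance 1e-6) and at least `window` long.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    wl = spectra.wavelengths_nm
    half = (window - 1) // 2
    out_wl, out_cols = [], []
    for seg in _uniform_segments(wl):
        seg_wl = wl[seg]
        if seg_wl.size < window:
            raise ValueError(
                f"grid segment of {seg_wl.size} points shorter than SG window {window} "
                "(non-uniform grid?)"
            )
        steps = np.diff(seg_wl)
        step = steps.mean()
        if np.any(np.abs(steps - step) > 1e-6 * abs(step)):
            raise ValueError("grid segment is not uniformly spaced")
        coeffs = savgol_coeffs(window, polyorder, deriv=deriv, delta=step, use="dot")
        X = spectra.absorbance_matrix[:, seg]
        # valid-mode correlation: row i of output = coeffs . X[:, i:i+window]
        n_out = seg_wl.size - window + 1
        windows = np.lib.stride_tricks.sliding_window_view(X, window, axis=1)
        out_cols.append(windows @ coeffs)
        out_wl.append(seg_wl[half : half + n_out])
    return spectra.with_grid(np.concatenate(out_wl), np.concatenate(out_cols, axis=1))


def apply_pipeline(
    spectra: SpectraSet, config: PreprocessConfig, fit: bool = False
) -> SpectraSet:
    """Run band selection -> MSC -> SG derivative.

    With ``fit=True`` the MSC reference and the selected/output grids are
    fitted from this set and stored in the config; with ``fit=False`` the
    stored reference is reused and the incoming grid must reproduce the
    training grid exactly (prediction-time compatibility check).
    """
    sel = select_bands(spectra, config)
    if fit:
        config.selected_grid = sel.wavelengths_nm.copy()
    else:
        if config.selected_grid is None:
            raise ValueError("pipeline not fitted: no stored training grid")
        if sel.n_wavelengths != config.selected_grid.size or not np.allclose(
            sel.wavelengths_nm, config.selected_grid
        ):
            raise ValueError("input grid does not match the stored training grid")

    if config.apply_msc:
        if fit:
            config.msc_reference = fit_msc_reference(sel)
        elif config.msc_reference is None:
            raise ValueError("pipeline not fitted: no stored MSC reference")
        sel = apply_msc(sel, config.msc_reference)

    # sg_deriv_order = 0 disables the derivative stage entirely (identity)
    if config.sg_deriv_order > 0:
        sel = savgol_derivative(sel, config.sg_window, config.sg_polyorder, config.sg_deriv_order)
    if fit:
        config.output_grid = sel.wavelengths_nm.copy()
    return sel
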