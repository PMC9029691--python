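"""Model/results objects — the package's headline fitting interface.

`NIRSAgeCalibration` wraps the whole spectra-to-age workflow (preprocess,
calibration/test split, cross-validated factor selection, NIPALS PLS1,
Table-1-style validation metrics) in a statsmodels-flavoured pair: a model
object built from data whose ``fit()`` returns a results object with the
estimates, diagnostics, ``summary()`` and ``predict()``. `SCP1AgeModel`
does the same for the transcript-abundance spline model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pls as _pls
from . import scp1 as _scp1
from .io import SpectraSet
from .preprocess import PreprocessConfig, apply_pipeline
from .validation import CalibrationReport, build_report, classify_vector_status

__all__ = ["NIRSAgeCalibration", "NIRSAgeResults", "SCP1AgeModel", "SCP1AgeResults"]


class NIRSAgeCalibration:
    """Age-from-spectra calibration model.

    Parameters
    ----------
    spectra
        Known-age SpectraSet (every sample must carry ``age_days``).
    preprocess
        PreprocessConfig; defaults to the 700-2300 nm range with MSC and a
        31-point first-derivative Savitzky-Golay filter.
    """

    def __init__(self, spectra: SpectraSet, preprocess: PreprocessConfig | None = None):
        ages = spectra.ages
        if np.any(~np.isfinite(ages)):
            raise ValueError("all samples need a known age to calibrate")
        self.spectra = spectra
        self.preprocess = preprocess if preprocess is not None else PreprocessConfig()

    @classmethod
    def from_csv(cls, spectra_csv, metadata_csv, preprocess=None) -> "NIRSAgeCalibration":
        from .io import join_metadata, read_spectra_csv

        return cls(join_metadata(read_spectra_csv(spectra_csv), metadata_csv), preprocess)

    def fit(
        self,
        n_factors: int | None = None,
        max_factors: int = 15,
        split_fraction: float = 0.8,
        k_folds: int = 10,
        seed: int = 0,
    ) -> "NIRSAgeResults":
        """Split, preprocess, select factors by CV (unless fixed), fit, score."""
        config = copy.deepcopy(self.preprocess)
        plan = _pls.split_calibration_test(self.spectra.sample_ids, split_fraction, seed)
        cal = self.spectra.subset_by_ids(list(plan.calibration_ids))
        proc = apply_pipeline(cal, config, fit=True)
        X, y = proc.absorbance_matrix, proc.ages
        if n_factors is None:
            limit = min(max_factors, X.shape[1], X.shape[0] - int(np.ceil(X.shape[0] / k_folds)) - 1)
            n_factors = _pls.select_n_factors(X, y, limit, k_folds=k_folds, seed=seed)
        model = _pls.fit_pls1(X, y, n_factors)
        model.preprocess = config
        model.training_grid = config.output_grid
        model.seed = seed
        report = build_report(model, self.spectra, plan)
        return NIRSAgeResults(self, model, plan, report)


@dataclass
class NIRSAgeResults:
    """Fitted calibration: PLS model, split plan and validation report."""

    model_spec: NIRSAgeCalibration
    pls_model: _pls.PLSModel
    plan: _pls.SplitPlan
    report: CalibrationReport

    # statsmodels-style accessors -------------------------------------------------
    @property
    def n_factors(self) -> int:
        return self.pls_model.n_factors

    @property
    def params(self) -> np.ndarray:
        """Regression coefficients on the preprocessed wavelength axis."""
        return self.pls_model.coefficients

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        """Predicted ages (days) for new spectra on the training grid."""
        proc = apply_pipeline(spectra, self.pls_model.preprocess, fit=False)
        return _pls.predict_pls(self.pls_model, proc.absorbance_matrix)

    def predict_frame(self, spectra: SpectraSet) -> pd.DataFrame:
        ages = self.predict(spectra)
        return pd.DataFrame(
            {
                "sample_id": spectra.sample_ids,
                "predicted_age": ages,
                "vector_status": [classify_vector_status(max(a, 0.0)) for a in ages],
            }
        )

    def save(self, path) -> None:
        _pls.save_model_json(self.pls_model, path)

    def summary(self) -> str:
        r = self.report
        lines = [
            "NIRS age calibration (PLS1, NIPALS)",
            "=" * 46,
            f"{'calibration n':<28}{r.n_cal:>18}",
            f"{'test n':<28}{r.n_test:>18}",
            f"{'latent factors':<28}{self.n_factors:>18}",
            f"{'R2 (calibration)':<28}{r.r_squared:>18.3f}",
            f"{'R2 (test)':<28}{r.r_squared_test:>18.3f}",
            f"{'slope [95% CI]':<28}"
            f"{r.slope:>8.3f} [{r.slope_ci[0]:.3f}, {r.slope_ci[1]:.3f}]",
            f"{'intercept [95% CI]':<28}"
            f"{r.intercept:>8.3f} [{r.intercept_ci[0]:.3f}, {r.intercept_ci[1]:.3f}]",
            f"{'SEP (days)':<28}{r.sep:>18.3f}",
            f"{'RMSEP (days)':<28}{r.rmsep:>18.3f}",
            f"{'RPD':<28}{r.rpd:>18.3f}",
            f"{'RPD class':<28}{r.rpd_class:>18}",
        ]
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Mean predicted vs known age per tested day, calibration circles
        and test triangles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.report.per_sample
        for subset, marker, fill in (("calibration", "o", "none"), ("test", "^", "full")):
            sub = df[df["subset"] == subset].groupby("known_age")["predicted_age"].mean()
            ax.plot(
                sub.index, sub.values, marker, label=subset,
                fillstyle=fill, linestyle="none", color="k",
            )
        lim = [0, max(df["known_age"].max(), df["predicted_age"].max()) * 1.05]
        ax.plot(lim, lim, ":", color="grey", lw=1)
        ax.set_xlabel("known age (days)")
        ax.set_ylabel("predicted age (days)")
        ax.legend()
        return ax


class SCP1AgeModel:
    """OLS of log age on a three-knot restricted cubic spline of delta-Ct."""

    def __init__(
        self,
        delta_ct: np.ndarray,
        age_days: np.ndarray,
        knot_quantiles: tuple[float, float, float] = (0.10, 0.50, 0.90),
    ):
        self.delta_ct = np.asarray(delta_ct, dtype=float)
        self.age_days = np.asarray(age_days, dtype=float)
        self.knot_quantiles = knot_quantiles

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SCP1AgeModel":
        sub = df.dropna(subset=["scp1_delta_ct", "age_days"])
        return cls(sub["scp1_delta_ct"].to_numpy(), sub["age_days"].to_numpy(), **kwargs)

    def fit(self) -> "SCP1AgeResults":
        fitted = _scp1.fit_scp1_model(self.delta_ct, self.age_days, self.knot_quantiles)
        return SCP1AgeResults(self, fitted)


@dataclass
class SCP1AgeResults:
    model_spec: SCP1AgeModel
    fitted: _scp1.Scp1AgeModel

    @property
    def params(self) -> np.ndarray:
        f = self.fitted
        return np.array([f.beta0, f.beta1, f.beta2])

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self.fitted.bse, dtype=float)

    @property
    def knots(self) -> tuple[float, float, float]:
        return self.fitted.knots

    def predict(self, delta_ct) -> np.ndarray | float:
        return _scp1.predict_age_scp1(self.fitted, delta_ct)

    def save(self, path) -> None:
        self.fitted.to_json(path)

    def summary(self) -> str:
        f = self.fitted
        names = ["intercept", "delta_ct", "rcs(delta_ct)"]
        lines = [
            "SCP1 age model: ln(age) ~ rcs(delta_ct, 3 knots)",
            "=" * 48,
            f"knots (dCt): {f.knots[0]:.3f}, {f.knots[1]:.3f}, {f.knots[2]:.3f}",
            f"residual SD (ln days): {f.sigma:.3f}" if f.sigma is not None else "",
            f"{'term':<16}{'coef':>10}{'std err':>10}",
        ]
        for name, b, s in zip(names, self.params, self.bse):
            lines.append(f"{name:<16}{b:>10.4f}{s:>10.4f}")
        return "\n".join(l for l in lines if l)
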