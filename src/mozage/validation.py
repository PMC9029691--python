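"""Calibration-quality statistics: R2, slope/intercept with 95% CIs,
standard error of prediction (SEP), ratio of performance deviation (RPD),
and the vector-status age classes.

RPD = SD(test-set reference ages) / SEP. Values above 1.5 are conventionally
usable for high/low screening and above 2.0 for coarse quantitative
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import SpectraSet
from .pls import PLSModel, SplitPlan, predict_pls
from .preprocess import apply_pipeline

__all__ = [
    "CalibrationReport",
    "regression_diagnostics",
    "compute_sep",
    "compute_rpd",
    "classify_rpd",
    "classify_vector_status",
    "build_report",
]

RPD_CLASSES = ("inadequate", "high_low_screening", "coarse_quantitative")
VECTOR_CLASSES = ("non_vector", "unlikely_vector", "potential_vector")


@dataclass
class CalibrationReport:
    """Table-1-style summary of one calibration/validation run."""

    r_squared: float
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    sep: float
    rpd: float
    n_cal: int
    n_test: int
    rpd_class: str = ""
    r_squared_test: float = float("nan")
    rmsep: float = float("nan")
    per_sample: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "sep": self.sep,
            "rpd": self.rpd,
            "rpd_class": self.rpd_class,
            "n_cal": self.n_cal,
            "n_test": self.n_test,
            "r_squared_test": self.r_squared_test,
            "rmsep": self.rmsep,
        }


def regression_diagnostics(known: np.ndarray, predicted: np.ndarray):
    """OLS of predicted age on known age: R2, slope and intercept with
    t-based 95% confidence intervals.

    A slope CI covering 1 and an intercept CI covering 0 indicate an
    unbiased calibration.
    """
    known = np.asarray(known, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if known.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(known) == 0:
        raise ValueError("known ages are constant")
    res = sm.OLS(predicted, sm.add_constant(known)).fit()
    ci = res.conf_int(alpha=0.05)
    # constant predictions have zero centred TSS; R2 = 0 by convention
    r2 = float(res.rsquared) if np.ptp(predicted) > 0 else 0.0
    return {
        "r_squared": r2,
        "slope": float(res.params[1]),
        "slope_ci": (float(ci[1, 0]), float(ci[1, 1])),
        "intercept": float(res.params[0]),
        "intercept_ci": (float(ci[0, 0]), float(ci[0, 1])),
    }


def compute_sep(known: np.ndarray, predicted: np.ndarray) -> float:
    """Standard error of prediction: bias-corrected SD of the residuals
    (predicted - known) with an n-1 denominator."""
    known = np.asarray(known, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if known.size < 2:
        raise ValueError("SEP needs at least 2 samples")
    resid = predicted - known
    return float(np.std(resid, ddof=1))


def compute_rpd(known_test: np.ndarray, sep: float) -> float:
    """Ratio of performance deviation: SD(test reference ages) / SEP."""
    if sep <= 0:
        raise ValueError("degenerate perfect prediction (SEP = 0)")
    return float(np.std(np.asarray(known_test, dtype=float), ddof=1) / sep)


def classify_rpd(rpd: float) -> str:
    """Map an RPD value to its conventional suitability class."""
    if rpd < 0:
        raise ValueError("RPD cannot be negative")
    if rpd < 1.5:
        return "inadequate"
    if rpd < 2.0:
        return "high_low_screening"
    return "coarse_quantitative"


def classify_vector_status(age_days: float) -> str:
    """Epidemiological age class: 0-5 d non-vector (younger than the
    extrinsic incubation period), 6-14 d unlikely vector, 15+ d potential
    vector. Ages are rounded to the nearest whole day first."""
    if age_days < 0:
        raise ValueError("age must be nonnegative")
    day = int(round(age_days))
    if day <= 5:
        return "non_vector"
    if day <= 14:
        return "unlikely_vector"
    return "potential_vector"


def build_report(model: PLSModel, spectra: SpectraSet, plan: SplitPlan) -> CalibrationReport:
    """Evaluate a fitted model on its calibration/test split.

    R2 and the slope/intercept diagnostics are computed on the calibration
    subset; SEP and RPD on the held-out test subset (with the test-set R2
    and RMSEP also recorded so either reading of a summary table can be
    reproduced).
    """
    if model.preprocess is None:
        raise ValueError("model carries no preprocessing config")
    rows = []
    preds = {}
    for label, ids in (("calibration", plan.calibration_ids), ("test", plan.test_ids)):
        sub = spectra.subset_by_ids(list(ids))
        ages = sub.ages
        if np.any(~np.isfinite(ages)):
            bad = [m.sample_id for m, a in zip(sub.metadata, ages) if not np.isfinite(a)]
            raise ValueError(f"known ages missing for {bad}")
        proc = apply_pipeline(sub, model.preprocess, fit=False)
        yhat = predict_pls(model, proc.absorbance_matrix)
        preds[label] = (proc.ages, yhat)
        rows.extend(
            {"sample_id": m.sample_id, "known_age": a, "predicted_age": p, "subset": label}
            for m, a, p in zip(proc.metadata, proc.ages, yhat)
        )

    y_cal, yhat_cal = preds["calibration"]
    y_test, yhat_test = preds["test"]
    diag = regression_diagnostics(y_cal, yhat_cal)
    diag_test = regression_diagnostics(y_test, yhat_test)
    sep = compute_sep(y_test, yhat_test)
    rpd = compute_rpd(y_test, sep)
    return CalibrationReport(
        r_squared=diag["r_squared"],
        slope=diag["slope"],
        slope_ci=diag["slope_ci"],
        intercept=diag["intercept"],
        intercept_ci=diag["intercept_ci"],
        sep=sep,
        rpd=rpd,
        rpd_class=classify_rpd(rpd),
        n_cal=len(plan.calibration_ids),
        n_test=len(plan.test_ids),
        r_squared_test=diag_test["r_squared"],
        rmsep=float(np.sqrt(np.mean((yhat_test - y_test) ** 2))),
        per_sample=pd.DataFrame(rows),
    )
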