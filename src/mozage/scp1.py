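"""Transcript-abundance age model: log age regressed on a three-knot
restricted cubic spline of SCP1 delta-Ct.

SCP1 (sarcoplasmic calcium-binding protein 1) expression declines with adult
age, so its qPCR delta-Ct relative to the RPS17 control rises. The model is
OLS of ln(age) on the Harrell truncated-power restricted-cubic-spline basis
of delta-Ct, which is linear in delta-Ct outside the boundary knots; age
predictions are the exponentiated linear predictor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm

__all__ = ["Scp1AgeModel", "rcs_basis_3knot", "fit_scp1_model", "predict_age_scp1"]


@dataclass
class Scp1AgeModel:
    """Fitted 3-knot spline age model: ln(age) = b0 + b1*x + b2*C(x)."""

    knots: tuple[float, float, float]
    beta0: float
    beta1: float
    beta2: float
    training_dct_range: tuple[float, float]
    bse: tuple[float, float, float] | None = None  # standard errors (b0, b1, b2)
    sigma: float | None = None                     # residual SD on the ln-age scale

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "knots": list(self.knots),
                    "beta0": self.beta0,
                    "beta1": self.beta1,
                    "beta2": self.beta2,
                    "training_dct_range": list(self.training_dct_range),
                    "bse": None if self.bse is None else list(self.bse),
                    "sigma": self.sigma,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "Scp1AgeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            knots=tuple(d["knots"]),
            beta0=d["beta0"],
            beta1=d["beta1"],
            beta2=d["beta2"],
            training_dct_range=tuple(d["training_dct_range"]),
            bse=None if d.get("bse") is None else tuple(d["bse"]),
            sigma=d.get("sigma"),
        )


def rcs_basis_3knot(x, knots) -> tuple[np.ndarray, np.ndarray]:
    """Restricted-cubic-spline basis with three knots (truncated-power form).

    Returns (x, C(x)) where

        C(x) = [ (x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2)
                           + (x-k3)+^3 (k2-k1)/(k3-k2) ] / (k3-k1)^2

    C has continuous second derivatives everywhere and is linear outside
    [k1, k3]; the division by (k3-k1)^2 puts it on the scale of x.
    """
    k1, k2, k3 = knots
    if not k1 < k2 < k3:
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    C = (
        pos3(x - k1)
        - pos3(x - k2) * (k3 - k1) / (k3 - k2)
        + pos3(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return x, C


def fit_scp1_model(
    delta_ct: np.ndarray,
    age_days: np.ndarray,
    knot_quantiles: tuple[float, float, float] = (0.10, 0.50, 0.90),
) -> Scp1AgeModel:
    """Fit ln(age) ~ rcs(delta_ct, 3 knots) by OLS.

    Knots sit at the empirical delta-Ct quantiles (default 0.10/0.50/0.90,
    the conventional placement for a 3-knot restricted cubic spline).
    """
    x = np.asarray(delta_ct, dtype=float)
    age = np.asarray(age_days, dtype=float)
    if x.size != age.size:
        raise ValueError("delta_ct and age_days lengths disagree")
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    if np.any(age <= 0):
        raise ValueError("ages must be positive for the log transform")
    knots = tuple(np.quantile(x, knot_quantiles))
    if not knots[0] < knots[1] < knots[2]:
        raise ValueError(
            "degenerate design: delta_ct quantiles do not give three distinct knots"
        )
    _, C = rcs_basis_3knot(x, knots)
    design = np.column_stack([np.ones_like(x), x, C])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate design (collinear spline basis)")
    res = sm.OLS(np.log(age), design).fit()
    return Scp1AgeModel(
        knots=knots,
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        beta2=float(res.params[2]),
        training_dct_range=(float(x.min()), float(x.max())),
        bse=tuple(float(s) for s in res.bse),
        sigma=float(np.sqrt(res.scale)),
    )


def predict_age_scp1(model: Scp1AgeModel, delta_ct) -> np.ndarray | float:
    """Predict age in days from delta-Ct: exp(b0 + b1*x + b2*C(x)).

    No clamping: a delta-Ct outside the training range yields an
    extrapolation warning but still a prediction, so implausible field
    values (e.g. parous mosquitoes scored under 5 days) surface rather
    than being hidden.
    """
    scalar = np.isscalar(delta_ct)
    x = np.atleast_1d(np.asarray(delta_ct, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("delta_ct must be finite")
    lo, hi = model.training_dct_range
    if np.any((x < lo) | (x > hi)):
        warnings.warn(
            f"delta_ct outside the training range [{lo:.3g}, {hi:.3g}]: extrapolating",
            stacklevel=2,
        )
    _, C = rcs_basis_3knot(x, model.knots)
    age = np.exp(model.beta0 + model.beta1 * x + model.beta2 * C)
    return float(age[0]) if scalar else age
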