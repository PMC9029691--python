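"""End-to-end workflows: build and validate a calibration model, and run the
field concordance analyses (parity comparison and SCP1 regression) across
one or more trained models.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from .io import SpectraSet
from .model import NIRSAgeCalibration, NIRSAgeResults
from .preprocess import PreprocessConfig
from .scp1 import Scp1AgeModel, predict_age_scp1

logger = logging.getLogger(__name__)

__all__ = ["run_model_build", "run_field_comparison"]


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_model_build(
    spectra: SpectraSet,
    preprocess: PreprocessConfig | None = None,
    n_factors: int | None = None,
    max_factors: int = 15,
    split_fraction: float = 0.8,
    seed: int = 0,
    model_out: str | Path | None = None,
    report_out: str | Path | None = None,
) -> NIRSAgeResults:
    """Preprocess -> split -> select factors -> fit -> validate.

    Optionally writes the model JSON and a Table-1-shaped report JSON; the
    report embeds the seed and a hash of the settings for provenance.
    """
    settings = {
        "preprocess": (preprocess or PreprocessConfig()).to_dict(),
        "n_factors": n_factors,
        "max_factors": max_factors,
        "split_fraction": split_fraction,
        "seed": seed,
    }
    settings["preprocess"].pop("msc_reference", None)
    logger.info("model build: n=%d, seed=%d", spectra.n_samples, seed)
    results = NIRSAgeCalibration(spectra, preprocess).fit(
        n_factors=n_factors, max_factors=max_factors,
        split_fraction=split_fraction, seed=seed,
    )
    if model_out is not None:
        results.save(model_out)
    if report_out is not None:
        payload = results.report.to_dict()
        payload["n_factors"] = results.n_factors
        payload["seed"] = seed
        payload["config_hash"] = _config_hash(settings)
        Path(report_out).write_text(json.dumps(payload, indent=2))
    return results


def run_field_comparison(
    field: SpectraSet,
    nirs_models: dict[str, NIRSAgeResults],
    scp1_model: Scp1AgeModel | None = None,
    out: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Concordance of NIRS predictions with parity and SCP1 ages.

    For every trained model: predict ages for the field set, compare parous
    vs nulliparous (Kruskal-Wallis + Dunn), and — where an SCP1 model and
    delta-Ct values exist — regress NIRS age on SCP1 age with one pass of
    Studentized-residual trimming, then letter-group the slopes by CI
    overlap.
    """
    if not nirs_models:
        raise ValueError("need at least one trained NIRS model")
    parity = np.array(field.parity)
    if not {"nulliparous", "parous"} <= set(parity):
        raise ValueError("field set must contain both parity classes")

    pred_frames = []
    for name, res in nirs_models.items():
        ages = res.predict(field)
        pred_frames.append(
            pd.DataFrame(
                {
                    "model": name,
                    "sample_id": field.sample_ids,
                    "parity": parity,
                    "predicted_age": ages,
                }
            )
        )
    predictions = pd.concat(pred_frames, ignore_index=True)
    parity_summary = conc.compare_parity_groups(predictions)

    scp1_rows = []
    letters = {}
    if scp1_model is not None:
        dct = field.delta_ct
        assayed = np.isfinite(dct)
        if not assayed.any():
            raise ValueError("no samples carry SCP1 delta-Ct values")
        scp1_ages = np.asarray(predict_age_scp1(scp1_model, dct[assayed]))
        ids = [s for s, ok in zip(field.sample_ids, assayed) if ok]
        for name, res in nirs_models.items():
            nirs_ages = res.predict(field[assayed])
            trimmed = conc.trimmed_regression(scp1_ages, nirs_ages, ids=ids)
            row = {"model": name, **trimmed.to_dict()}
            scp1_rows.append(row)
        letters = conc.ci_letter_groups(
            [(r["model"], r["slope_ci"][0], r["slope_ci"][1]) for r in scp1_rows]
        )
        for r in scp1_rows:
            r["slope_letter"] = letters[r["model"]]

    report = {
        "seed": seed,
        "parity_comparison": parity_summary.to_dict(orient="records"),
        "dunn_pairwise": parity_summary.attrs.get("dunn_pairwise", []),
        "scp1_regressions": scp1_rows,
        "slope_letters": letters,
    }
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=2, default=float))
    return report
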