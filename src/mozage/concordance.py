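"""Concordance statistics between NIRS age predictions and the two reference
age-grading techniques.

Parity comparison: Kruskal-Wallis rank ANOVA with Dunn's post hoc z tests
across parity-by-model groups — parous females should be scored older than
nulliparous ones. SCP1 comparison: simple linear regression of NIRS age on
SCP1 age after a single pass of Studentized-residual outlier trimming, with
compact-letter grouping of slopes by confidence-interval overlap.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "GroupComparison",
    "TrimmedRegressionResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "trimmed_regression",
    "ci_letter_groups",
    "compare_parity_groups",
]


@dataclass
class GroupComparison:
    group_labels: list[str]
    H: float
    p_value: float
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)


@dataclass
class TrimmedRegressionResult:
    n_used: int
    n_removed: int
    removed_ids: list
    intercept: float
    intercept_ci: tuple[float, float]
    intercept_p: float
    slope: float
    slope_ci: tuple[float, float]
    slope_p: float

    def to_dict(self) -> dict:
        return {
            "n_used": self.n_used,
            "n_removed": self.n_removed,
            "removed_ids": list(self.removed_ids),
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "intercept_p": self.intercept_p,
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "slope_p": self.slope_p,
        }


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-squared, k-1 df.

    All observations identical across groups gives H = 0, p = 1 by
    convention (with a warning) instead of an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical; H = 0, p = 1 by convention", stacklevel=2)
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def _mean_ranks(groups: list[np.ndarray]) -> tuple[list[float], float, int]:
    """Mean mid-ranks per group, the tie correction term, and total N."""
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = pooled.size
    means, start = [], 0
    for n in sizes:
        means.append(float(ranks[start : start + n].mean()))
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts) / (12.0 * (N - 1)))
    return means, tie_term, N


def dunn_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
) -> list[tuple[str, str, float, float]]:
    """Dunn's post hoc pairwise z tests on the pooled mid-ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - tie term) (1/n_i + 1/n_j)],
    two-sided normal p, Bonferroni-adjusted by default.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    means, tie_term, N = _mean_ranks(groups)
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (means[i] - means[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * m)
            elif adjust not in (None, "none"):
                raise ValueError(f"unknown adjustment {adjust!r}")
            out.append((labels[i], labels[j], float(z), float(p)))
    return out


def trimmed_regression(
    x: np.ndarray,
    y: np.ndarray,
    threshold: float = 2.0,
    ids=None,
    studentization: str = "external",
) -> TrimmedRegressionResult:
    """OLS of y on x with one pass of Studentized-residual trimming.

    Fit, drop every point with |Studentized residual| > threshold
    (externally Studentized, i.e. leave-one-out residual variance, by
    default), refit once, and report slope/intercept with t-based 95%
    confidence intervals and p-values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 points")
    if ids is None:
        ids = list(range(n))
    first = sm.OLS(y, sm.add_constant(x)).fit()
    if first.scale < 1e-16:
        warnings.warn("residual variance ~ 0; no points removed", stacklevel=2)
        keep = np.ones(n, dtype=bool)
    else:
        infl = OLSInfluence(first)
        if studentization == "external":
            t = infl.resid_studentized_external
        elif studentization == "internal":
            t = infl.resid_studentized_internal
        else:
            raise ValueError("studentization must be 'external' or 'internal'")
        keep = np.abs(t) <= threshold
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points remain after trimming")
    removed_ids = [ids[i] for i in np.where(~keep)[0]]
    final = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
    ci = final.conf_int(alpha=0.05)
    return TrimmedRegressionResult(
        n_used=int(keep.sum()),
        n_removed=int(n - keep.sum()),
        removed_ids=removed_ids,
        intercept=float(final.params[0]),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        intercept_p=float(final.pvalues[0]),
        slope=float(final.params[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        slope_p=float(final.pvalues[1]),
    )


def ci_letter_groups(estimates: list[tuple[str, float, float]]) -> dict[str, str]:
    """Compact letter display from confidence-interval overlap.

    Two labels share a letter iff their intervals overlap; labels with no
    common letter have disjoint intervals. Greedy insert-and-absorb over
    labels sorted by interval lower bound, verified exhaustively before
    returning.
    """
    for label, lo, hi in estimates:
        if lo > hi:
            raise ValueError(f"invalid CI for {label}: ({lo}, {hi})")
    labels = [e[0] for e in estimates]
    iv = {e[0]: (e[1], e[2]) for e in estimates}

    def overlap(a, b):
        return iv[a][0] <= iv[b][1] and iv[b][0] <= iv[a][1]

    # a maximal set of mutually overlapping intervals always shares the
    # point max(lo), which is some interval's lower bound — so the cliques
    # at each lower bound, with non-maximal ones absorbed, are exactly the
    # letter groups
    cliques = [
        {b for b in labels if iv[b][0] <= iv[a][0] <= iv[b][1]} for a in labels
    ]
    uniq: list[set[str]] = []
    for g in sorted(cliques, key=len, reverse=True):
        if not any(g <= h for h in uniq):
            uniq.append(g)
    uniq.sort(key=lambda g: min(iv[l][0] for l in g))
    letters = {lab: "" for lab in labels}
    for letter, g in zip(string.ascii_lowercase, uniq):
        for lab in sorted(g, key=labels.index):
            letters[lab] += letter
    # exhaustive validity check
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            share = bool(set(letters[a]) & set(letters[b]))
            if share != overlap(a, b):
                raise AssertionError("letter display construction failed validity check")
    return letters


def compare_parity_groups(
    predictions: pd.DataFrame,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-model parity comparison of NIRS age predictions.

    ``predictions`` needs columns ``model``, ``parity`` (nulliparous/parous)
    and ``predicted_age``. For each model the nulliparous and parous ages
    enter a Kruskal-Wallis test with Dunn's post hoc across all
    parity-by-model groups; the summary flags whether parous mosquitoes were
    scored older.
    """
    df = predictions[predictions["parity"].isin(["nulliparous", "parous"])]
    all_groups, all_labels = [], []
    rows = []
    for model_name, sub in df.groupby("model", sort=False):
        nul = sub.loc[sub["parity"] == "nulliparous", "predicted_age"].to_numpy()
        par = sub.loc[sub["parity"] == "parous", "predicted_age"].to_numpy()
        if nul.size == 0 or par.size == 0:
            warnings.warn(f"model {model_name!r}: a parity class is empty; skipped", stacklevel=2)
            continue
        H, p = kruskal_wallis([nul, par])
        rows.append(
            {
                "model": model_name,
                "n_nulliparous": nul.size,
                "n_parous": par.size,
                "mean_nulliparous": float(nul.mean()),
                "mean_parous": float(par.mean()),
                "median_nulliparous": float(np.median(nul)),
                "median_parous": float(np.median(par)),
                "H": H,
                "p_value": p,
                "parous_older": bool(par.mean() > nul.mean()),
            }
        )
        all_groups.extend([nul, par])
        all_labels.extend([f"{model_name}:nulliparous", f"{model_name}:parous"])
    out = pd.DataFrame(rows)
    if len(all_groups) >= 2:
        pairwise = dunn_posthoc(all_groups, labels=all_labels, adjust=adjust)
        out.attrs["dunn_pairwise"] = pairwise
    return out
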