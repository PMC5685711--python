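"""ROC construction, AUC with confidence intervals, and Youden-optimal
cut-off metrics.

The AUC estimator is the rank statistic (concordant pairs plus half ties
over all case-control pairs); for the tie-aware empirical ROC this equals
the trapezoidal area exactly, a property the test-suite checks on random
instances.  The default confidence interval is DeLong's (placement-value
covariance), with a seeded bootstrap percentile interval as an alternative.

Threshold semantics: a sample is called positive when score >= cutoff;
reported cutoffs are midpoints between adjacent distinct scores, so they
are achievable and stable under small perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError


@dataclass
class ROCSummary:
    """ROC points with the headline diagnostic metrics."""

    points: pd.DataFrame         # columns threshold, fpr, tpr
    auc: float
    ci_lower: float
    ci_upper: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    ci_method: str = "delong"
    degenerate_ci: bool = False


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise DataError("labels must be binary 0/1")
    cases, controls = s[y == 1], s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise DataError("both classes must be present")
    return cases, controls


def roc_curve(scores, labels) -> pd.DataFrame:
    """Empirical ROC over all distinct thresholds.

    Returns a frame with columns threshold, fpr, tpr; the first row is the
    (0, 0) corner (threshold above every score), the last is (1, 1).
    Tied scores collapse into a single ROC vertex, which is what makes the
    trapezoidal area match the half-tie rank AUC exactly.
    """
    cases, controls = _split(scores, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [(cases >= t).mean() for t in thresholds]
    fpr = [(controls >= t).mean() for t in thresholds]
    top = thresholds[0] + 1.0
    return pd.DataFrame(
        {
            "threshold": np.concatenate([[top], thresholds]),
            "fpr": np.concatenate([[0.0], fpr]),
            "tpr": np.concatenate([[0.0], tpr]),
        }
    )


def auc(scores, labels) -> float:
    """Rank AUC: P(case > control) + 0.5 P(tie) over case-control pairs."""
    cases, controls = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    r_cases = ranks[: len(cases)].sum()
    u = r_cases - len(cases) * (len(cases) + 1) / 2.0
    return float(u / (len(cases) * len(controls)))


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks."""
    m, n = len(cases), len(controls)
    all_r = stats.rankdata(np.concatenate([cases, controls]))
    case_r = stats.rankdata(cases)
    ctrl_r = stats.rankdata(controls)
    v10 = (all_r[:m] - case_r) / n            # per-case placements
    v01 = 1.0 - (all_r[m:] - ctrl_r) / m      # per-control placements
    return v10, v01


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    level: float = 0.95,
    seed: int | None = None,
    n_boot: int = 2000,
) -> tuple[float, float, bool]:
    """Confidence interval for the AUC; returns (lower, upper, degenerate).

    ``degenerate`` flags a zero-variance interval (e.g. perfect separation),
    where the interval collapses onto the point estimate.
    """
    cases, controls = _split(scores, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise DataError("CI needs >= 2 members per class")
    a = auc(scores, labels)
    z = stats.norm.ppf(0.5 + level / 2.0)

    if method == "delong":
        v10, v01 = _placements(cases, controls)
        var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls)
        if var <= 0:
            return a, a, True
        half = z * np.sqrt(var)
        return float(max(0.0, a - half)), float(min(1.0, a + half)), False

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            bc = rng.choice(cases, size=len(cases), replace=True)
            bn = rng.choice(controls, size=len(controls), replace=True)
            reps[i] = auc(np.concatenate([bc, bn]),
                          np.concatenate([np.ones(len(bc)), np.zeros(len(bn))]))
        lo, hi = np.quantile(reps, [(1 - level) / 2, 0.5 + level / 2])
        return float(lo), float(hi), bool(lo == hi)

    raise ValueError(f"unknown CI method {method!r}")


def optimal_cutoff(
    scores, labels, *, policy: str = "youden"
) -> tuple[float, float, float]:
    """Threshold with the best Youden index J = sens + spec - 1.

    Ties in J are broken toward higher specificity (a screening-friendly
    choice); ``policy="closest"`` instead minimizes the Euclidean distance
    to the (0, 1) ROC corner.  Returns (cutoff, sensitivity, specificity)
    with the cutoff placed midway between adjacent distinct scores.
    """
    cases, controls = _split(scores, labels)
    distinct = np.unique(np.concatenate([cases, controls]))
    # candidate cutoffs: below min, midpoints, above max
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best = None
    for c in candidates:
        sens = float((cases >= c).mean())
        spec = float((controls < c).mean())
        if policy == "youden":
            key = (sens + spec - 1.0, spec)
        elif policy == "closest":
            key = (-np.hypot(1.0 - sens, 1.0 - spec), spec)
        else:
            raise ValueError(f"unknown cutoff policy {policy!r}")
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cut, sens, spec = best
    return float(cut), sens, spec


def summarize(
    scores,
    labels,
    *,
    ci_method: str = "delong",
    cutoff_policy: str = "youden",
    level: float = 0.95,
    seed: int | None = None,
) -> ROCSummary:
    """One-stop ROC summary: curve, AUC, CI and optimal-cutoff metrics."""
    cases, controls = _split(scores, labels)
    pts = roc_curve(scores, labels)
    a = auc(scores, labels)
    lo, hi, degen = auc_ci(scores, labels, method=ci_method, level=level, seed=seed)
    cut, sens, spec = optimal_cutoff(scores, labels, policy=cutoff_policy)
    return ROCSummary(
        points=pts, auc=a, ci_lower=lo, ci_upper=hi, cutoff=cut,
        sensitivity=sens, specificity=spec,
        n_cases=len(cases), n_controls=len(controls),
        ci_method=ci_method, degenerate_ci=degen,
    )
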