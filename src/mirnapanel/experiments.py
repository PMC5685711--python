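"""Calibration and parameter-recovery experiments over the synthetic cohorts.

These are the package's self-checks-at-scale: each function simulates
cohorts with known ground truth, runs the real pipeline machinery on them,
and returns the measured quantity.  They back both the analysis scripts and
the acceptance suite, so the numbers reported anywhere are always recomputed
by these code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import roc
from .cohort import CohortDesign, simulate_expression
from .panel_search import Outcome, cv_evaluate, search
from .pcr_stats import mann_whitney


def binormal_shift(target_auc: float, noise_sd: float = 1.0) -> float:
    """Log-scale group shift giving a single-marker binormal AUC.

    For a log-normal marker with common log-SD sigma and log-mean shift
    delta, AUC = Phi(delta / (sigma * sqrt(2))); invert for delta.
    """
    return float(stats.norm.ppf(target_auc) * noise_sd * np.sqrt(2.0))


def null_cv_calibration(
    n_reps: int = 200,
    seed: int = 0,
    n_healthy: int = 60,
    n_cancer: int = 60,
    subset_size: int = 2,
) -> tuple[float, float]:
    """Mean test AUC of cv_evaluate on a no-signal cohort, with the
    closed-form null SD of the rank AUC as the Monte-Carlo scale.

    Returns (mean_test_auc, null_sd); under the null the mean should sit
    within a few null SDs of 0.5 (the repetition average is dominated by
    the dataset-level sampling variability, not the split noise).
    """
    design = CohortDesign(
        n_healthy=n_healthy, n_benign=0, n_early=n_cancer // 2,
        n_advanced=n_cancer - n_cancer // 2, n_mirnas=max(3, subset_size),
        seed=seed,
    )
    table, _ = simulate_expression(design)
    subset = tuple(table.mirna_ids[:subset_size])
    res = cv_evaluate(table, subset, Outcome.cancer_vs_healthy(table),
                      n_reps=n_reps, seed=seed)
    # test halves hold ~half of each class
    n1, n0 = n_cancer // 2, n_healthy // 2
    null_sd = float(np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0)))
    return res.mean_test_auc, null_sd


@dataclass
class RecoveryOutcome:
    """Result of the planted-marker recovery experiment."""

    recovery_rate: float          # fraction of seeds recovering all planted markers
    n_seeds: int
    planted: tuple[str, ...]
    winners: list[tuple[str, ...]]
    mean_test_aucs: list[float]


def recovery_experiment(
    n_seeds: int = 20,
    n_reps: int = 100,
    seed: int = 0,
    single_marker_auc: float = 0.75,
    pool_size: int = 8,
    n_planted: int = 3,
    n_healthy: int = 63,
    n_early: int = 65,
    n_advanced: int = 90,
    noise_sd: float = 1.0,
) -> RecoveryOutcome:
    """Does the exhaustive panel search find the markers that carry signal?

    For each generator seed, a cohort is simulated with ``n_planted`` of
    ``pool_size`` markers given a log-scale shift sized for a single-marker
    binormal AUC of ``single_marker_auc`` (the rest pure noise); the full
    best-subset search runs at ``n_reps`` CV repetitions, and a seed counts
    as recovered when the winning model contains every planted marker.
    """
    delta = binormal_shift(single_marker_auc, noise_sd)
    ids = [f"miR-{i:03d}" for i in range(1, pool_size + 1)]
    planted = tuple(ids[:n_planted])
    effects = {m: {"early": delta, "advanced": delta} for m in planted}
    winners, aucs = [], []
    hits = 0
    for i in range(n_seeds):
        design = CohortDesign(
            n_healthy=n_healthy, n_benign=0, n_early=n_early,
            n_advanced=n_advanced, n_mirnas=pool_size,
            informative_effects=effects, noise_sd=noise_sd,
            seed=seed * n_seeds + i,
        )
        table, _ = simulate_expression(design)
        res = search(table, ids, Outcome.cancer_vs_healthy(table),
                     n_reps=n_reps, seed=seed * n_seeds + i)
        win = res.selected[0].subset if res.selected else ()
        winners.append(win)
        aucs.append(res.selected[0].mean_test_auc if res.selected else float("nan"))
        if set(planted) <= set(win):
            hits += 1
    return RecoveryOutcome(
        recovery_rate=hits / n_seeds, n_seeds=n_seeds, planted=planted,
        winners=winners, mean_test_aucs=aucs,
    )


def auc_equivalence_suite(
    n_instances: int = 1000, seed: int = 0, max_n: int = 40
) -> dict[str, float]:
    """Max discrepancies between the three AUC routes on random instances.

    Instances mix continuous scores and heavily tied integer scores; the
    rank AUC, the trapezoidal area under the empirical ROC, and the
    Mann-Whitney U / (n1 * n0) statistic must agree exactly.
    """
    rng = np.random.default_rng(seed)
    d_trapz = d_u = 0.0
    for _ in range(n_instances):
        n1 = int(rng.integers(2, max_n))
        n0 = int(rng.integers(2, max_n))
        if rng.random() < 0.5:
            scores = rng.integers(0, 5, n1 + n0).astype(float)   # heavy ties
        else:
            scores = rng.normal(size=n1 + n0)
        y = np.concatenate([np.ones(n1), np.zeros(n0)])
        a = roc.auc(scores, y)
        pts = roc.roc_curve(scores, y)
        trapz = float(np.trapezoid(pts["tpr"], pts["fpr"]))
        u = mann_whitney(scores[:n1], scores[n1:]).u_statistic / (n1 * n0)
        d_trapz = max(d_trapz, abs(a - trapz))
        d_u = max(d_u, abs(a - u))
    return {"max_auc_vs_trapezoid": d_trapz, "max_auc_vs_u_statistic": d_u}


def delong_coverage(
    n_sims: int = 1000, seed: int = 0, n_cases: int = 200, n_controls: int = 200
) -> float:
    """Fraction of null simulations whose 95% DeLong interval covers 0.5."""
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    covered = 0
    for _ in range(n_sims):
        scores = rng.normal(size=n_cases + n_controls)
        lo, hi, _ = roc.auc_ci(scores, y, method="delong")
        covered += lo <= 0.5 <= hi
    return covered / n_sims
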