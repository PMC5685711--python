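"""qRT-PCR expression statistics: dCt normalization and the Mann-Whitney
validation screen.

The 2^dCt convention here is dCt = Ct_reference - Ct_target, so a *more
abundant* target (lower Ct) yields a *larger* 2^dCt value; undetermined Ct
values are imputed at the instrument's maximum cycle so that all-or-none
markers keep their (floor-valued) samples instead of losing them.

``mann_whitney`` is the work-horse two-sample test.  U counts case-control
pairs where a > b plus half of the ties, so U / (n_a * n_b) is exactly the
rank AUC.  The p-value is exact for small samples (distribution-free
enumeration; a full enumeration over assignments when ties are present) and
a tie-corrected normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CandidateSet, DataError, ExpressionTable

#: exact p-value when n_a * n_b is at most this (and ties permit)
EXACT_LIMIT = 400
#: full tie-aware enumeration when C(n_a + n_b, n_a) is at most this
ENUM_LIMIT = 200_000


@dataclass
class TestResult:
    """Two-sample rank test outcome."""

    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str        # "exact", "enumeration" or "normal"

    @property
    def auc(self) -> float:
        """Rank AUC of group a scores against group b."""
        return self.u_statistic / (self.n_a * self.n_b)


def delta_ct_normalize(
    ct_target: float | np.ndarray | pd.Series,
    ct_reference: float | np.ndarray | pd.Series,
    *,
    max_cycle: float = 40.0,
) -> float | np.ndarray | pd.Series:
    """2^(Ct_reference - Ct_target); NaN (undetermined) target Ct is imputed
    at ``max_cycle``."""
    tgt = np.asarray(ct_target, dtype=float)
    tgt = np.where(np.isnan(tgt), max_cycle, tgt)
    out = 2.0 ** (np.asarray(ct_reference, dtype=float) - tgt)
    if isinstance(ct_target, pd.Series):
        return pd.Series(out, index=ct_target.index)
    return float(out) if np.ndim(out) == 0 else out


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Pairs with a > b plus half the ties, via midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


@lru_cache(maxsize=32)
def _combination_matrix(n: int, k: int) -> np.ndarray:
    from itertools import combinations

    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def _exact_enumeration_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p over all C(n, n_a) group assignments (ties allowed).

    p = P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|) under the null that
    all assignments of the pooled values to groups are equally likely.
    """
    n = len(pooled)
    n_b = n - n_a
    ranks = stats.rankdata(pooled)
    centre = n_a * n_b / 2.0
    dev = abs(u_obs - centre) - 1e-12
    idx = _combination_matrix(n, n_a)
    u_all = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2.0
    return float((np.abs(u_all - centre) >= dev).sum() / comb(n, n_a))


def mann_whitney(
    group_a: np.ndarray | list,
    group_b: np.ndarray | list,
    mode: str = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test of group a vs group b.

    ``mode`` is "auto" (exact for small samples, normal otherwise),
    "exact" or "normal-approx".
    """
    if mode not in ("auto", "exact", "normal-approx"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise DataError("NaN values in test input")
    n_a, n_b = len(a), len(b)
    u = _u_statistic(a, b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n_a + n_b

    if np.ptp(np.concatenate([a, b])) == 0:
        # every value identical: no information
        return TestResult(u, 1.0, float(np.median(a)), float(np.median(b)), n_a, n_b, "exact")

    want_exact = mode == "exact" or (mode == "auto" and n_a * n_b <= EXACT_LIMIT)
    if want_exact and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return TestResult(u, float(res.pvalue), float(np.median(a)), float(np.median(b)),
                          n_a, n_b, "exact")
    if want_exact and comb(n_a + n_b, n_a) <= ENUM_LIMIT:
        p = _exact_enumeration_p(np.concatenate([a, b]), n_a, u)
        return TestResult(u, p, float(np.median(a)), float(np.median(b)), n_a, n_b,
                          "enumeration")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return TestResult(u, float(res.pvalue), float(np.median(a)), float(np.median(b)),
                      n_a, n_b, "normal")


def validate_candidates(
    table: ExpressionTable,
    candidates: CandidateSet,
    alpha: float = 0.05,
    *,
    bh_correct: bool = False,
) -> tuple[CandidateSet, list[str]]:
    """Retain candidates whose cancer-vs-healthy rank test is significant.

    Returns (validated set, skipped ids) where skipped ids are candidates
    absent from the expression table.  ``bh_correct`` applies a
    Benjamini-Hochberg adjustment before thresholding (off by default: the
    screen mirrors a raw-alpha validation step).
    """
    cancer = (table.diagnosis == "cancer").to_numpy()
    healthy = (table.diagnosis == "healthy").to_numpy()
    if not cancer.any() or not healthy.any():
        raise DataError("validation needs both cancer and healthy samples")

    present, skipped, pvals = [], [], []
    for mid in candidates.ids:
        if mid not in table.values.index:
            skipped.append(mid)
            continue
        row = table.values.loc[mid].to_numpy(dtype=float)
        pvals.append(mann_whitney(row[cancer], row[healthy]).p_value)
        present.append(mid)

    p = np.asarray(pvals)
    if bh_correct and len(p):
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    keep = p < alpha if len(p) else np.array([], dtype=bool)
    prov = candidates.table.set_index("mirna_id")["provenance"]
    out = pd.DataFrame(
        {
            "mirna_id": np.asarray(present)[keep],
            "provenance": ["validated:" + prov[m] for m in np.asarray(present)[keep]],
            "p_value": p[keep],
        }
    )
    return CandidateSet(out), skipped
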