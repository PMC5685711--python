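"""Candidate miRNA selection from small-RNA sequencing count matrices.

Two complementary screens over TMM-normalized counts:

* **method 1** — rank-test differential expression (cancer vs healthy) run
  on each mismatch-tolerance table; the top-k most significant markers from
  each table are retained and the union reported.
* **method 2** — *all-or-none* markers: significant differential expression
  together with zero read counts in more than a set number of healthy
  controls, i.e. markers detected essentially only in cancer sera.

TMM (trimmed mean of M-values) scaling follows the standard doubly-trimmed,
inverse-variance-weighted construction; here the per-sample factor is the
*absolute* scale (library size and compositional correction combined), so
normalized abundance is simply count / factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CandidateSet, CountMatrix, DataError
from .pcr_stats import mann_whitney


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors plus the M/A diagnostics."""

    factors: pd.Series                 # geometric mean 1 after centering
    reference: str
    m_values: dict[str, pd.Series]     # per-sample log2 ratios vs reference (kept genes)
    a_values: dict[str, pd.Series]


def tmm_factors(
    cm: CountMatrix,
    reference: str | None = None,
    *,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    weighted: bool = False,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample k against the reference r, over genes with positive
    counts in both, M = log2(y_k / y_r) and A = 0.5 * log2(y_k * y_r);
    the upper and lower ``m_trim`` (resp. ``a_trim``) ranks of M (resp. A)
    are discarded and the factor is 2 ** (mean of the surviving M values).
    Factors are then centered to geometric mean 1.  The reference defaults
    to the sample whose 75th-percentile count fraction is closest to the
    mean of those fractions.

    ``weighted`` switches the trimmed mean to the delta-method
    inverse-variance weighting used by the classic implementation; the
    unweighted default keeps the factors exactly scale-equivariant
    (scaling a library's counts by c scales its pre-centering factor by c).
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise DataError("TMM needs at least 2 samples")
    libsize = counts.sum(axis=0)
    zero_lib = libsize[libsize == 0]
    if len(zero_lib):
        raise DataError(f"sample with all-zero counts: {zero_lib.index[0]!r}")

    if reference is None:
        q75 = counts.apply(lambda col: np.quantile(col[col > 0], 0.75) / col.sum())
        reference = (q75 - q75.mean()).abs().idxmin()
    elif reference not in counts.columns:
        raise DataError(f"reference sample {reference!r} not in matrix")

    yr = counts[reference].to_numpy(dtype=float)
    nr = libsize[reference]
    log2f: dict[str, float] = {}
    m_all: dict[str, pd.Series] = {}
    a_all: dict[str, pd.Series] = {}
    for s in counts.columns:
        yk = counts[s].to_numpy(dtype=float)
        nk = libsize[s]
        keep = (yk > 0) & (yr > 0)
        m = np.log2(yk[keep] / yr[keep])
        a = 0.5 * np.log2(yk[keep] * yr[keep])
        genes = counts.index[keep]
        m_all[s] = pd.Series(m, index=genes)
        a_all[s] = pd.Series(a, index=genes)
        if s == reference or len(m) == 0:
            log2f[s] = np.log2(nk / nr) if len(m) == 0 else 0.0
            continue
        # doubly trimmed by rank: drop the extreme m_trim tails of the M
        # distribution and the extreme a_trim tails of the A distribution
        n_g = len(m)
        r_m = stats.rankdata(m)
        r_a = stats.rankdata(a)
        lo_m, hi_m = np.floor(n_g * m_trim) + 1, n_g - np.floor(n_g * m_trim)
        lo_a, hi_a = np.floor(n_g * a_trim) + 1, n_g - np.floor(n_g * a_trim)
        kept = (r_m >= lo_m) & (r_m <= hi_m) & (r_a >= lo_a) & (r_a <= hi_a)
        if not kept.any():
            kept = np.ones_like(m, dtype=bool)
        if weighted:
            # asymptotic (delta-method) inverse variance of each M value
            w = 1.0 / ((nk - yk[keep]) / (nk * yk[keep])
                       + (nr - yr[keep]) / (nr * yr[keep]))
            log2f[s] = float(np.average(m[kept], weights=w[kept]))
        else:
            log2f[s] = float(np.mean(m[kept]))

    f = pd.Series({s: 2.0 ** v for s, v in log2f.items()}, name="tmm_factor")
    f = f.reindex(counts.columns)
    f /= np.exp(np.mean(np.log(f)))        # geometric mean 1
    return NormalizationFactors(factors=f, reference=reference, m_values=m_all, a_values=a_all)


def normalize_counts(cm: CountMatrix, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts divided by their per-sample TMM factor."""
    return cm.counts / factors.factors


def de_pvalues(norm_counts: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Two-sided rank-test p-value per miRNA, cancer vs healthy.

    A marker constant across all samples is degenerate and gets p = 1.
    """
    groups = groups.reindex(norm_counts.columns)
    healthy = (groups == "healthy").to_numpy()
    cancer = ~healthy
    if not healthy.any() or not cancer.any():
        raise DataError("both a healthy and a cancer group are required")
    vals = norm_counts.to_numpy(dtype=float)
    out = np.ones(len(norm_counts))
    for i in range(len(norm_counts)):
        row = vals[i]
        if np.ptp(row) == 0:
            continue                      # degenerate: p = 1
        out[i] = mann_whitney(row[cancer], row[healthy]).p_value
    return pd.Series(out, index=norm_counts.index, name="p_value")


def _top_k(pvals: pd.Series, norm_counts: pd.DataFrame, groups: pd.Series, k: int) -> list[str]:
    """k smallest p-values; ties broken by larger absolute median
    difference between groups, then lexicographic id."""
    groups = groups.reindex(norm_counts.columns)
    healthy = (groups == "healthy").to_numpy()
    med_diff = (
        norm_counts.loc[:, ~healthy].median(axis=1) - norm_counts.loc[:, healthy].median(axis=1)
    ).abs()
    order = pd.DataFrame({"p": pvals, "d": -med_diff, "id": pvals.index})
    order = order.sort_values(["p", "d", "id"], kind="stable")
    return list(order.index[:k])


def select_method1(
    cm_0mm: CountMatrix,
    cm_1mm: CountMatrix,
    k: int = 10,
) -> CandidateSet:
    """Union of the top-k most significant markers from each mismatch table."""
    if set(cm_0mm.mirna_ids) != set(cm_1mm.mirna_ids):
        raise DataError("the two mismatch tables must share a miRNA universe")
    if k > len(cm_0mm.mirna_ids):
        warnings.warn(f"k={k} exceeds the miRNA universe; capped", stacklevel=2)
        k = len(cm_0mm.mirna_ids)
    chosen: dict[str, float] = {}
    for cm in (cm_0mm, cm_1mm):
        norm = normalize_counts(cm, tmm_factors(cm))
        p = de_pvalues(norm, cm.groups)
        for mid in _top_k(p, norm, cm.groups, k):
            chosen[mid] = min(chosen.get(mid, 1.0), float(p[mid]))
    table = pd.DataFrame(
        {"mirna_id": sorted(chosen), "provenance": "method1",
         "p_value": [chosen[m] for m in sorted(chosen)]}
    )
    return CandidateSet(table)


def select_method2(
    cm: CountMatrix,
    p_threshold: float = 0.05,
    min_zero_healthy: int = 6,
) -> CandidateSet:
    """All-or-none screen: >= ``min_zero_healthy`` healthy samples with zero
    reads AND rank-test p < ``p_threshold`` (cancer vs healthy)."""
    healthy = cm.healthy_mask()
    n_healthy = int(healthy.sum())
    if n_healthy == 0:
        raise DataError("healthy group is empty")
    if min_zero_healthy > n_healthy:
        raise DataError(
            f"min_zero_healthy={min_zero_healthy} exceeds the {n_healthy} healthy samples"
        )
    norm = normalize_counts(cm, tmm_factors(cm))
    p = de_pvalues(norm, cm.groups)
    zeros = (cm.counts.loc[:, healthy] == 0).sum(axis=1)
    keep = (zeros >= min_zero_healthy) & (p < p_threshold)
    table = pd.DataFrame(
        {"mirna_id": p.index[keep], "provenance": "method2", "p_value": p[keep].to_numpy()}
    ).sort_values("mirna_id", kind="stable")
    return CandidateSet(table)
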