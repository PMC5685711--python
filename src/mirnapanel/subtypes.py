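"""One-vs-rest histological-subtype classification among cancer samples.

Each subtype present in the cohort (serous, mucinous, endometrioid,
clear-cell) gets its own panel search with outcome *this subtype* vs *all
other cancer subtypes* — healthy and benign sera are excluded, mirroring a
within-cancer discrimination question.  Subtypes below a minimum size are
skipped with an explicit report rather than silently modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import roc
from .containers import DataError, ExpressionTable
from .panel_search import Outcome, SearchResult, design_matrix, predict_prob, search


@dataclass
class SubtypeModelSet:
    """Per-subtype search results, ROC summaries, and skip report."""

    results: dict[str, SearchResult] = field(default_factory=dict)
    roc_summaries: dict[str, roc.ROCSummary] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def one_vs_rest(
    table: ExpressionTable,
    predictor_ids: list[str] | tuple[str, ...],
    n_reps: int = 1000,
    seed: int = 0,
    *,
    min_subtype_size: int = 8,
    auc_floor: float = 0.7,
    top_k: int = 10,
) -> SubtypeModelSet:
    """Run the panel search once per subtype (that subtype vs other cancers).

    The rest class is always the remaining cancer samples.  Each modelled
    subtype's winning panel is refitted on the full cancer cohort and
    summarized as a ROC (resubstitution scores).  Small cohorts trigger a
    prominent warning: subtype-level sample sizes are rarely large enough
    for confident model selection.
    """
    if table.subtype is None:
        raise DataError("expression table carries no subtype labels")
    cancer = table.diagnosis == "cancer"
    cancers = table.subset_samples(cancer.to_numpy())
    present = [s for s in pd.unique(cancers.subtype.dropna())]
    if len(present) < 2:
        raise DataError("at least two subtypes are required for one-vs-rest")

    out = SubtypeModelSet()
    for subtype in sorted(present):
        n = int((cancers.subtype == subtype).sum())
        out.counts[subtype] = n
        if n < min_subtype_size:
            out.skipped[subtype] = f"only {n} samples (< {min_subtype_size})"
            continue
        warnings.warn(
            f"subtype {subtype!r}: n={n} positives — subtype-level cohorts are "
            "small; treat the selected panel as exploratory", stacklevel=2,
        )
        outcome = Outcome.subtype_vs_rest(table, subtype)
        res = search(
            table, predictor_ids, outcome, n_reps=n_reps, auc_floor=auc_floor,
            top_k=top_k, seed=seed, strict_size=False,
        )
        out.results[subtype] = res
        if res.final_model is not None:
            X, _ = design_matrix(cancers, list(res.final_model.subset))
            scores = predict_prob(res.final_model, X)
            y = (cancers.subtype == subtype).to_numpy().astype(int)
            out.roc_summaries[subtype] = roc.summarize(scores, y, seed=seed)
    return out
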