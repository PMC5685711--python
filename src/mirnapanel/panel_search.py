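"""Exhaustive best-subset logistic panel search under repeated two-fold
cross-validated AUC.

This is the study-design engine of the package: every non-empty subset of a
marker pool (255 models for 8 markers, 511 with CA-125 added) is fitted as a
logistic regression; each subset is scored by splitting the cohort into
random stratified halves, fitting on the training half and computing the
ROC AUC on both halves, repeating the split ``n_reps`` times (1,000 in the
reference design) and averaging.  Models whose mean training *and* test AUC
clear a floor (0.7 by default) are ranked and the top ten reported; the
winning subset is refitted on the full cohort to yield the probability
equation that would be carried forward.

Markers enter the linear predictor as log2 of their 2^dCt value (i.e. on
the dCt scale); CA-125 enters as log10(U/mL).  Both transforms are recorded
in the model and configurable.

Fitting is plain maximum likelihood via iteratively reweighted least
squares.  All-or-none markers invite complete separation, so divergence is
detected (coefficient blow-up or non-convergence) and resolved by a lightly
ridge-penalized refit with an explicit separation flag — never by silently
reporting infinite coefficients.

Split randomness for repetition ``i`` comes from ``default_rng([seed, i])``,
so results are independent of subset enumeration order and of execution
order across repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .containers import DataError, ExpressionTable

#: predictor id under which CA-125 joins a marker pool
CA125_ID = "CA-125"

_MAX_ITER = 50
_TOL = 1e-10
_COEF_LIMIT = 30.0        # |beta| beyond this on standardized-ish inputs => separation
_RIDGE = 1e-4


@dataclass
class FittedPanelModel:
    """A fitted logistic panel: subset, coefficients and transforms."""

    subset: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray            # aligned with subset
    transforms: tuple[str, ...]         # per-predictor transform name
    converged: bool = True
    separation: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.subset):
            raise DataError("coefficient count must match subset size")
        if len(self.transforms) != len(self.subset):
            raise DataError("one transform per predictor required")

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [p for p in self.subset if p not in X.columns]
            if missing:
                raise DataError(f"missing predictor(s): {missing}")
            X = X[list(self.subset)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients


@dataclass
class CVResult:
    """Cross-validated score of one subset."""

    subset: tuple[str, ...]
    mean_train_auc: float
    mean_test_auc: float
    n_reps: int
    seed: int


@dataclass
class SearchResult:
    """Ranked panel-search outcome."""

    ranking: list[CVResult]                  # all subsets, ranked
    passing: list[CVResult]                  # subsets clearing the AUC floor
    selected: list[CVResult]                 # top-k of the passing subsets
    final_model: FittedPanelModel | None     # winner refit on the full data
    equation: str | None = None


def enumerate_subsets(predictor_ids: list[str] | tuple[str, ...]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    ids = list(predictor_ids)
    if len(set(ids)) != len(ids):
        raise DataError("duplicate predictor ids")
    if not ids:
        raise DataError("at least one predictor required")
    out: list[tuple[str, ...]] = []
    for r in range(1, len(ids) + 1):
        out.extend(sorted(combinations(sorted(ids), r)))
    return out


def _irls(Z: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, bool]:
    """Newton/IRLS for the logistic log-likelihood; Z includes the
    intercept column.  Returns (beta, converged)."""
    n, p = Z.shape
    beta = np.zeros(p)
    pen = np.zeros(p)
    pen[1:] = ridge                       # never penalize the intercept
    for _ in range(_MAX_ITER):
        eta = np.clip(Z @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = Z.T @ (y - mu) - pen * beta
        hess = (Z * w[:, None]).T @ Z + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta += step
        if np.max(np.abs(step)) < _TOL:
            return beta, True
    return beta, False


def fit_logistic(X: np.ndarray | pd.DataFrame, y: np.ndarray,
                 subset: tuple[str, ...] | None = None,
                 transforms: tuple[str, ...] | None = None) -> FittedPanelModel:
    """Maximum-likelihood logistic fit with separation handling.

    ``X`` holds the already-transformed predictor values (n x k; k may be 0
    for an intercept-only model).  On detected separation or non-convergence
    the model is refitted with a small ridge penalty and flagged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise DataError("non-finite values in logistic inputs")
    classes = np.unique(y)
    if set(classes) - {0.0, 1.0} or len(classes) < 2:
        raise DataError("outcome must contain both classes (0 and 1)")

    k = X.shape[1]
    subset = subset if subset is not None else tuple(f"x{j + 1}" for j in range(k))
    transforms = transforms if transforms is not None else ("identity",) * k
    Z = np.column_stack([np.ones(len(y)), X])
    beta, converged = _irls(Z, y)
    separated = (not converged) or np.max(np.abs(beta)) > _COEF_LIMIT
    if separated:
        beta, converged = _irls(Z, y, ridge=_RIDGE)
    return FittedPanelModel(
        subset=subset, intercept=float(beta[0]), coefficients=beta[1:],
        transforms=tuple(transforms), converged=converged, separation=separated,
    )


def predict_prob(model: FittedPanelModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Logistic transform of the linear predictor; strictly inside (0, 1)."""
    return expit(model.linear_predictor(X))


# ---------------------------------------------------------------------------
# outcome definitions and design matrices

@dataclass
class Outcome:
    """Binary contrast over an expression cohort: which samples are cases,
    which are controls; everything else is dropped."""

    name: str
    positive: pd.Series          # boolean, indexed by sample id
    negative: pd.Series

    @staticmethod
    def cancer_vs_healthy(table: ExpressionTable) -> "Outcome":
        return Outcome("cancer_vs_healthy",
                       table.diagnosis == "cancer", table.diagnosis == "healthy")

    @staticmethod
    def early_vs_benign(table: ExpressionTable) -> "Outcome":
        if table.stage_group is None:
            raise DataError("stage_group labels required for early_vs_benign")
        pos = (table.diagnosis == "cancer") & (table.stage_group == "early")
        return Outcome("early_vs_benign", pos, table.diagnosis == "benign")

    @staticmethod
    def subtype_vs_rest(table: ExpressionTable, subtype: str) -> "Outcome":
        if table.subtype is None:
            raise DataError("subtype labels required")
        cancer = table.diagnosis == "cancer"
        return Outcome(f"{subtype}_vs_other_subtypes",
                       cancer & (table.subtype == subtype),
                       cancer & (table.subtype != subtype))


def design_matrix(
    table: ExpressionTable,
    predictor_ids: list[str] | tuple[str, ...],
    *,
    marker_transform: str = "log2",
    ca125_transform: str = "log10",
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Predictor matrix (samples x predictors) with the recorded transforms.

    miRNA markers default to log2(2^dCt) (the dCt scale); CA-125 defaults
    to log10(U/mL).  ``"raw"`` disables either transform.
    """
    cols, tf = {}, []
    for pid in predictor_ids:
        if pid == CA125_ID:
            if table.ca125 is None:
                raise DataError("table has no CA-125 values")
            v = table.ca125.astype(float)
            if ca125_transform == "log10":
                v = np.log10(v)
            tf.append(ca125_transform)
        else:
            if pid not in table.values.index:
                raise DataError(f"predictor {pid!r} not in expression table")
            v = table.values.loc[pid].astype(float)
            if marker_transform == "log2":
                v = np.log2(v)
            tf.append(marker_transform)
        cols[pid] = v
    return pd.DataFrame(cols, index=table.sample_ids), tuple(tf)


def _auc_fast(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank AUC via searchsorted (concordant pairs + half ties)."""
    cases = scores[y == 1]
    ctrl = np.sort(scores[y == 0])
    lo = np.searchsorted(ctrl, cases, side="left")
    hi = np.searchsorted(ctrl, cases, side="right")
    return float((lo + 0.5 * (hi - lo)).sum() / (len(cases) * len(ctrl)))


def make_splits(y: np.ndarray, n_reps: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified 50/50 splits, one per repetition; repetition ``i`` draws
    from ``default_rng([seed, i])`` so the list is order-independent."""
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if len(idx1) < 2 or len(idx0) < 2:
        raise DataError("a class is too small to stratify into two halves")
    splits = []
    for i in range(n_reps):
        rng = np.random.default_rng([seed, i])
        p1 = rng.permutation(idx1)
        p0 = rng.permutation(idx0)
        train = np.concatenate([p1[: len(idx1) // 2], p0[: len(idx0) // 2]])
        test = np.concatenate([p1[len(idx1) // 2:], p0[len(idx0) // 2:]])
        splits.append((np.sort(train), np.sort(test)))
    return splits


def _cv_mean_aucs(
    X: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    *,
    swap_halves: bool = False,
) -> tuple[float, float]:
    """Mean train / test AUC over the supplied splits.

    The model is fitted on the training half only; its scores are evaluated
    on both halves.  With ``swap_halves`` each split also contributes the
    role-reversed fit (classic two-fold CV)."""
    tr_sum = te_sum = 0.0
    n = 0
    Z = np.column_stack([np.ones(len(y)), X])
    for train, test in splits:
        pairs = [(train, test)] if not swap_halves else [(train, test), (test, train)]
        for tr, te in pairs:
            beta, converged = _irls(Z[tr], y[tr])
            if (not converged) or np.max(np.abs(beta)) > _COEF_LIMIT:
                beta, _ = _irls(Z[tr], y[tr], ridge=_RIDGE)
            tr_sum += _auc_fast(Z[tr] @ beta, y[tr])
            te_sum += _auc_fast(Z[te] @ beta, y[te])
            n += 1
    return tr_sum / n, te_sum / n


def cv_evaluate(
    table: ExpressionTable,
    subset: tuple[str, ...] | list[str],
    outcome: Outcome,
    n_reps: int = 1000,
    seed: int = 0,
    *,
    swap_halves: bool = False,
    strict_size: bool = True,
) -> CVResult:
    """Repeated stratified two-fold CV of one panel; averaged AUCs.

    With ``strict_size`` each class must supply at least ``2 * (k + 1)``
    samples for a k-predictor panel (so each training half can in principle
    support the fit); ``strict_size=False`` relaxes this to a warning for
    deliberately small cohorts (e.g. minority subtypes), where the
    separation policy absorbs the inevitable unstable fits.
    """
    subset = tuple(subset)
    keep = (outcome.positive | outcome.negative).to_numpy()
    sub = table.subset_samples(keep)
    y = outcome.positive.to_numpy()[keep].astype(float)
    X, _ = design_matrix(sub, subset)
    _check_class_sizes(y, len(subset), strict_size)
    splits = make_splits(y, n_reps, seed)
    tr, te = _cv_mean_aucs(X.to_numpy(), y, splits, swap_halves=swap_halves)
    return CVResult(subset, tr, te, n_reps, seed)


def _check_class_sizes(y: np.ndarray, k: int, strict: bool) -> None:
    for cls, nc in ((1, int(y.sum())), (0, int(len(y) - y.sum()))):
        need = 2 * (k + 1)
        if nc < need:
            msg = (f"class {cls} has {nc} samples; a {k}-predictor panel "
                   f"wants >= {need} for stable half-cohort fits")
            if strict:
                raise DataError(msg)
            warnings.warn(msg, stacklevel=3)


def search(
    table: ExpressionTable,
    predictor_ids: list[str] | tuple[str, ...],
    outcome: Outcome,
    n_reps: int = 1000,
    auc_floor: float = 0.7,
    top_k: int = 10,
    seed: int = 0,
    *,
    swap_halves: bool = False,
    strict_size: bool = True,
) -> SearchResult:
    """Score every subset of the pool by repeated two-fold CV and select.

    Subsets whose mean train AND mean test AUC exceed ``auc_floor`` are
    ranked by mean test AUC (ties: mean train AUC, then smaller subset,
    then lexicographic); the ``top_k`` best are reported and the winner is
    refitted on the full outcome cohort for the exported equation.  If no
    subset clears the floor, the selection is empty but the full diagnostic
    ranking is still returned.
    """
    subsets = enumerate_subsets(list(predictor_ids))
    keep = (outcome.positive | outcome.negative).to_numpy()
    sub = table.subset_samples(keep)
    y = outcome.positive.to_numpy()[keep].astype(float)
    X_full, transforms = design_matrix(sub, list(predictor_ids))
    max_k = max(len(s) for s in subsets)
    _check_class_sizes(y, max_k, strict_size)
    splits = make_splits(y, n_reps, seed)
    col_of = {pid: j for j, pid in enumerate(X_full.columns)}
    Xmat = X_full.to_numpy()

    results = []
    for s in subsets:
        idx = [col_of[p] for p in s]
        tr, te = _cv_mean_aucs(Xmat[:, idx], y, splits, swap_halves=swap_halves)
        results.append(CVResult(s, tr, te, n_reps, seed))

    def rank_key(r: CVResult):
        return (-r.mean_test_auc, -r.mean_train_auc, len(r.subset), r.subset)

    ranking = sorted(results, key=rank_key)
    passing = [r for r in ranking if r.mean_train_auc > auc_floor and r.mean_test_auc > auc_floor]
    selected = passing[:top_k]
    final_model, equation = None, None
    if selected:
        win = selected[0].subset
        idx = [col_of[p] for p in win]
        tfs = tuple(transforms[col_of[p]] for p in win)
        final_model = fit_logistic(Xmat[:, idx], y, subset=win, transforms=tfs)
        equation = export_equation(final_model)
    else:
        warnings.warn("no subset cleared the AUC floor; returning diagnostics only",
                      stacklevel=2)
    return SearchResult(ranking=ranking, passing=passing, selected=selected,
                        final_model=final_model, equation=equation)


# ---------------------------------------------------------------------------
# probability-equation text round-trip

def export_equation(model: FittedPanelModel) -> str:
    """Human-readable, machine-parsable probability equation.

    The rendered form P = 1/(1+exp(-z)) is followed by one ``term:`` line
    per predictor carrying full-precision coefficients, so the text
    round-trips through :func:`import_equation`.
    """
    terms = " + ".join(
        f"({c:+.4f})*{t}[{p}]" for p, c, t in
        zip(model.subset, model.coefficients, model.transforms)
    )
    lines = [
        "# logistic panel probability equation",
        f"# P(case) = 1 / (1 + exp(-z)),  z = {model.intercept:+.4f} + {terms}"
        if terms else
        f"# P(case) = 1 / (1 + exp(-z)),  z = {model.intercept:+.4f}",
    ]
    if model.separation:
        lines += [
            "# WARNING: complete or quasi-complete separation was detected;",
            "# coefficients come from a ridge-stabilized refit and the",
            "# panel's apparent performance is not generalizable as-is.",
        ]
    lines.append(f"intercept: {model.intercept!r}")
    for p, c, t in zip(model.subset, model.coefficients, model.transforms):
        lines.append(f"term: {p}\tcoef: {float(c)!r}\ttransform: {t}")
    lines.append(f"flags: converged={model.converged} separation={model.separation}")
    return "\n".join(lines) + "\n"


def import_equation(text: str) -> FittedPanelModel:
    """Inverse of :func:`export_equation`."""
    intercept = None
    subset: list[str] = []
    coefs: list[float] = []
    tfs: list[str] = []
    converged, separation = True, False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("intercept:"):
            intercept = float(line.split(":", 1)[1])
        elif line.startswith("term:"):
            part = dict(
                f.split(": ", 1) for f in line.split("\t")
            )
            subset.append(part["term"].strip())
            coefs.append(float(part["coef"]))
            tfs.append(part["transform"].strip())
        elif line.startswith("flags:"):
            converged = "converged=True" in line
            separation = "separation=True" in line
    if intercept is None:
        raise DataError("no intercept line in equation text")
    return FittedPanelModel(
        subset=tuple(subset), intercept=intercept, coefficients=np.array(coefs),
        transforms=tuple(tfs), converged=converged, separation=separation,
    )
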