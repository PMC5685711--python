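"""Tab-separated readers and writers for every pipeline artifact.

All interchange is plain TSV (miRNAs as rows, samples as columns, plus a
sample-metadata table), chosen because the study's data are small tabular
matrices.  Readers validate loudly — duplicate ids, ragged rows, negative
counts and unlabeled samples are reported with their location, never
silently coerced.  Writers stamp a provenance header (config hash / seed)
as comment lines that readers skip.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CandidateSet, CountMatrix, DataError, ExpressionTable

_META_COLS = ["sample_id", "group", "diagnosis", "stage_group", "subtype", "ca125"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    text = path.read_text()
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    first = body.splitlines()[0] if body.strip() else ""
    ncol = first.count("\t") + 1
    for i, ln in enumerate(body.splitlines()):
        if ln and ln.count("\t") + 1 != ncol:
            raise DataError(f"{path}: ragged row {i + 1} ({ln.count(chr(9)) + 1} fields, "
                            f"expected {ncol})")
    return pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def read_count_matrix(
    path: str | Path, metadata_path: str | Path, mismatch_tag: str = "0mm"
) -> CountMatrix:
    """Count TSV (first column miRNA ids, header sample ids) + metadata."""
    df = _read_tsv(path)
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: non-numeric count value ({exc})") from exc
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(arr != np.round(arr))[0]
        raise DataError(f"{path}: non-integer count at miRNA {counts.index[r]!r}, "
                        f"sample {counts.columns[c]!r}")
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise DataError(f"{path}: negative count at miRNA {counts.index[r]!r}, "
                        f"sample {counts.columns[c]!r}")
    meta = read_sample_metadata(metadata_path)
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise DataError(f"samples missing from metadata: {missing}")
    return CountMatrix(counts=counts.astype(np.int64), groups=meta.loc[counts.columns, "group"],
                       mismatch_tag=mismatch_tag)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = _read_tsv(path)
    meta.index.name = "sample_id"
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise DataError(f"{path}: duplicate sample id {dup!r}")
    return meta


def read_expression_table(
    path: str | Path, metadata_path: str | Path, normalizer_id: str = "cel-miR-39"
) -> ExpressionTable:
    """Expression TSV (2^dCt values) joined with sample metadata.

    Metadata must cover every sample; diagnosis labels are required, and a
    ``ca125`` metadata column is optional (absent -> CA-125 unavailable).
    """
    df = _read_tsv(path)
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: non-numeric expression value ({exc})") from exc
    meta = read_sample_metadata(metadata_path)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise DataError(f"samples missing from metadata: {missing}")
    meta = meta.loc[values.columns]
    if "diagnosis" not in meta.columns:
        raise DataError(f"{metadata_path}: metadata needs a 'diagnosis' column")

    def opt(col):
        if col not in meta.columns:
            return None
        s = meta[col]
        return None if s.isna().all() else s

    ca125 = opt("ca125")
    return ExpressionTable(
        values=values, diagnosis=meta["diagnosis"], normalizer_id=normalizer_id,
        stage_group=opt("stage_group"), subtype=opt("subtype"),
        ca125=None if ca125 is None else ca125.astype(float),
    )


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       provenance: dict | None = None) -> None:
    Path(path).write_text(_provenance_header(provenance) + cm.counts.to_csv(sep="\t"))


def write_expression_table(table: ExpressionTable, path: str | Path,
                           provenance: dict | None = None) -> None:
    Path(path).write_text(_provenance_header(provenance) + table.values.to_csv(sep="\t"))


def write_sample_metadata(table_or_meta, path: str | Path,
                          provenance: dict | None = None) -> None:
    """Accepts an ExpressionTable / CountMatrix or a ready metadata frame."""
    if isinstance(table_or_meta, pd.DataFrame):
        meta = table_or_meta
    elif isinstance(table_or_meta, CountMatrix):
        meta = pd.DataFrame({"group": table_or_meta.groups})
    else:
        t = table_or_meta
        meta = pd.DataFrame({"diagnosis": t.diagnosis})
        for name in ("stage_group", "subtype", "ca125"):
            s = getattr(t, name)
            if s is not None:
                meta[name] = s
    meta.index.name = "sample_id"
    Path(path).write_text(_provenance_header(provenance) + meta.to_csv(sep="\t"))


def write_candidates(cs: CandidateSet, path: str | Path,
                     provenance: dict | None = None) -> None:
    Path(path).write_text(
        _provenance_header(provenance) + cs.table.to_csv(sep="\t", index=False)
    )


def read_candidates(path: str | Path) -> CandidateSet:
    df = _read_tsv(Path(path))
    df = df.reset_index()
    return CandidateSet(df[["mirna_id", "provenance", "p_value"]])


def write_ranking(results, path: str | Path, provenance: dict | None = None) -> None:
    """Ranked CVResults as TSV (subset, mean train AUC, mean test AUC)."""
    df = pd.DataFrame(
        {
            "subset": ["+".join(r.subset) for r in results],
            "n_predictors": [len(r.subset) for r in results],
            "mean_train_auc": [r.mean_train_auc for r in results],
            "mean_test_auc": [r.mean_test_auc for r in results],
            "n_reps": [r.n_reps for r in results],
        }
    )
    Path(path).write_text(_provenance_header(provenance) + df.to_csv(sep="\t", index=False))


def write_roc_summary(summary, path: str | Path, provenance: dict | None = None) -> None:
    lines = [
        f"auc\t{summary.auc!r}",
        f"ci_lower\t{summary.ci_lower!r}",
        f"ci_upper\t{summary.ci_upper!r}",
        f"ci_method\t{summary.ci_method}",
        f"cutoff\t{summary.cutoff!r}",
        f"sensitivity\t{summary.sensitivity!r}",
        f"specificity\t{summary.specificity!r}",
        f"n_cases\t{summary.n_cases}",
        f"n_controls\t{summary.n_controls}",
        f"degenerate_ci\t{summary.degenerate_ci}",
    ]
    Path(path).write_text(_provenance_header(provenance) + "\n".join(lines) + "\n")


def write_roc_points(summary, path: str | Path, provenance: dict | None = None) -> None:
    Path(path).write_text(
        _provenance_header(provenance) + summary.points.to_csv(sep="\t", index=False)
    )
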