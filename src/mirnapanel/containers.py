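"""In-memory containers shared across the pipeline stages.

All containers wrap pandas objects (miRNAs as rows, samples as columns)
plus per-sample labels, and validate their own invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: diagnosis groups used by the sequencing screen
COUNT_GROUPS = ("healthy", "early", "advanced")
#: diagnosis groups used by the expression / qPCR phase
DIAGNOSIS_GROUPS = ("healthy", "benign", "borderline", "cancer")
STAGE_GROUPS = ("early", "advanced")
SUBTYPES = ("serous", "mucinous", "endometrioid", "clear-cell")

CANCER_COUNT_GROUPS = ("early", "advanced")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class CountMatrix:
    """miRNA x sample integer read counts with group labels.

    ``mismatch_tag`` records the alignment mismatch tolerance the table was
    produced under ("0mm" or "1mm"); the candidate screen uses one table per
    tolerance.
    """

    counts: pd.DataFrame              # index: miRNA ids, columns: sample ids
    groups: pd.Series                 # per-sample group label
    mismatch_tag: str = "0mm"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataError("duplicate miRNA ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise DataError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise DataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            r, c = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise DataError(
                f"negative count at miRNA {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise DataError(f"samples without a group label: {missing}")
        bad = set(self.groups) - set(COUNT_GROUPS)
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)}")
        if self.mismatch_tag not in ("0mm", "1mm"):
            raise DataError(f"unknown mismatch tag {self.mismatch_tag!r}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def cancer_mask(self) -> np.ndarray:
        return self.groups.isin(CANCER_COUNT_GROUPS).to_numpy()

    def healthy_mask(self) -> np.ndarray:
        return (self.groups == "healthy").to_numpy()


@dataclass
class ExpressionTable:
    """miRNA x sample relative-expression values (2^dCt scale) with labels.

    ``values`` holds 2^dCt relative abundances (strictly positive);
    ``normalizer_id`` records the reference assay the dCt was taken against
    (spike-in cel-miR-39 in trial-style tables, endogenous miR-16 in
    development-style tables).  ``ca125`` is optional (U/mL).
    """

    values: pd.DataFrame              # index: miRNA ids, columns: sample ids
    diagnosis: pd.Series              # healthy / benign / borderline / cancer
    normalizer_id: str = "cel-miR-39"
    stage_group: pd.Series | None = None   # early / advanced, cancers only
    subtype: pd.Series | None = None       # histological subtype, cancers only
    ca125: pd.Series | None = None         # U/mL
    imputed: pd.DataFrame | None = None    # True where Ct was undetermined

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise DataError("duplicate ids in expression table")
        if (self.values.to_numpy() <= 0).any():
            raise DataError("2^dCt values must be strictly positive")
        self.diagnosis = self.diagnosis.reindex(self.values.columns)
        if self.diagnosis.isna().any():
            missing = list(self.diagnosis.index[self.diagnosis.isna()])
            raise DataError(f"samples without a diagnosis label: {missing}")
        bad = set(self.diagnosis) - set(DIAGNOSIS_GROUPS)
        if bad:
            raise DataError(f"unknown diagnosis labels: {sorted(bad)}")
        for name in ("stage_group", "subtype", "ca125"):
            s = getattr(self, name)
            if s is not None:
                setattr(self, name, s.reindex(self.values.columns))

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def has_ca125(self) -> bool:
        return self.ca125 is not None and not self.ca125.isna().all()

    def subset_samples(self, mask: np.ndarray | pd.Series) -> "ExpressionTable":
        """Restrict to the samples selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        cols = self.values.columns[mask]
        return ExpressionTable(
            values=self.values[cols],
            diagnosis=self.diagnosis[cols],
            normalizer_id=self.normalizer_id,
            stage_group=None if self.stage_group is None else self.stage_group[cols],
            subtype=None if self.subtype is None else self.subtype[cols],
            ca125=None if self.ca125 is None else self.ca125[cols],
            imputed=None if self.imputed is None else self.imputed[cols],
        )


@dataclass
class CandidateSet:
    """miRNA identifiers with provenance and the screening p-value."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mirna_id", "provenance", "p_value"])
    )

    def __post_init__(self) -> None:
        required = {"mirna_id", "provenance", "p_value"}
        if not required.issubset(self.table.columns):
            raise DataError(f"candidate table needs columns {sorted(required)}")
        if self.table["mirna_id"].duplicated().any():
            raise DataError("duplicate candidate ids")
        p = self.table["p_value"].to_numpy(dtype=float)
        if len(p) and ((p < 0) | (p > 1)).any():
            raise DataError("p-values must lie in [0, 1]")
        self.table = self.table.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.table["mirna_id"])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in set(self.table["mirna_id"])

    @staticmethod
    def union(a: "CandidateSet", b: "CandidateSet") -> "CandidateSet":
        """Union of two candidate sets; shared ids get provenance 'both'
        and keep the smaller p-value."""
        merged = pd.merge(
            a.table, b.table, on="mirna_id", how="outer", suffixes=("_a", "_b")
        )
        prov, pval = [], []
        for _, row in merged.iterrows():
            pa, pb = row.get("provenance_a"), row.get("provenance_b")
            if isinstance(pa, str) and isinstance(pb, str):
                prov.append(pa if pa == pb else "both")
                pval.append(min(row["p_value_a"], row["p_value_b"]))
            elif isinstance(pa, str):
                prov.append(pa)
                pval.append(row["p_value_a"])
            else:
                prov.append(pb)
                pval.append(row["p_value_b"])
        out = pd.DataFrame(
            {"mirna_id": merged["mirna_id"], "provenance": prov, "p_value": pval}
        ).sort_values("mirna_id", kind="stable")
        return CandidateSet(out)
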