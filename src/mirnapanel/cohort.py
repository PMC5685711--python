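"""Synthetic serum-miRNA cohorts with known ground truth.

Two generators emulate the two data modalities of a circulating-miRNA
biomarker study:

* ``simulate_counts`` — small-RNA sequencing read counts (negative binomial)
  for a discovery-style cohort of healthy / early-stage / advanced-stage sera,
  including *all-or-none* markers that are structurally zero in every healthy
  sample and expressed only in cancer.
* ``simulate_expression`` — qRT-PCR style relative expression (2^dCt scale,
  log-normal) for a development-style cohort of healthy / benign / cancer
  sera, with histological subtypes among the cancers and a stage-dependent
  CA-125 marker.

Effect sizes are shifts of the (natural-)log mean, so a marker with shift
``delta`` against common log-SD ``sigma`` has a binormal AUC of
``Phi(delta / (sigma * sqrt(2)))`` — the knob tests and experiments use to
plant markers of known discriminative strength.

Randomness is derived from a single design seed with fixed per-stream
substream indices, so the two tables of one cohort are independent but the
whole cohort is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, DataError, ExpressionTable

# substream indices appended to the design seed (stable across versions)
_STREAM_COUNTS = 0
_STREAM_EXPRESSION = 1
_STREAM_CA125 = 2
_STREAM_LABELS = 3

#: subtype mixing proportions, matching a serous-dominated epithelial cohort
SUBTYPE_PROPORTIONS = {
    "serous": 112 / 155,
    "mucinous": 11 / 155,
    "endometrioid": 13 / 155,
    "clear-cell": 19 / 155,
}

#: per-group CA-125 log-scale parameters (natural log of U/mL).
#: Healthy sera centre near 15 U/mL; early-stage disease near the 35 U/mL
#: clinical cut-off (the marker is elevated in only about half of stage I
#: cases); advanced disease is strongly elevated.
DEFAULT_CA125_PARAMS = {
    "healthy": (np.log(15.0), 0.55),
    "benign": (np.log(22.0), 0.80),
    "early": (np.log(35.0), 1.00),
    "advanced": (np.log(250.0), 1.10),
}


@dataclass
class CohortDesign:
    """Declarative description of a synthetic cohort.

    ``informative_effects`` maps miRNA id -> {group: log-scale shift};
    groups absent from a marker's map default to shift 0.  ``allornone_set``
    markers are structurally absent (zero counts / floor expression) in
    healthy samples and expressed in cancer samples with log-scale shift
    ``allornone_shift``.  ``subtype_effects`` maps subtype -> miRNA id ->
    extra log-scale shift applied to cancer samples of that subtype.
    """

    n_healthy: int = 63
    n_benign: int = 43
    n_early: int = 65
    n_advanced: int = 90
    n_mirnas: int = 40
    informative_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    allornone_set: tuple[str, ...] = ()
    allornone_shift: float = 1.5
    subtype_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    ca125_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CA125_PARAMS)
    )
    noise_sd: float = 1.0
    nb_dispersion: float = 0.3
    mean_count: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_benign", "n_early", "n_advanced", "n_mirnas"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be > 0")
        if self.nb_dispersion <= 0:
            raise DataError("nb_dispersion must be > 0")
        ids = set(self.mirna_ids)
        unknown = (set(self.informative_effects) | set(self.allornone_set)) - ids
        for sub_effects in self.subtype_effects.values():
            unknown |= set(sub_effects) - ids
        if unknown:
            raise DataError(f"effect markers outside the miRNA universe: {sorted(unknown)}")
        overlap = set(self.informative_effects) & set(self.allornone_set)
        if overlap:
            raise DataError(f"markers cannot be both informative and all-or-none: {sorted(overlap)}")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    def effect(self, mirna_id: str, group: str) -> float:
        return self.informative_effects.get(mirna_id, {}).get(group, 0.0)


@dataclass
class GroundTruth:
    """What was planted: per-marker effects and per-sample labels."""

    effects: pd.DataFrame          # miRNA x group log-scale shifts
    informative_ids: tuple[str, ...]
    allornone_ids: tuple[str, ...]
    labels: pd.DataFrame           # sample_id, group, diagnosis, stage_group, subtype


def _sample_labels(design: CohortDesign, *, include_benign: bool) -> pd.DataFrame:
    """Per-sample metadata frame; subtype assignment for cancer samples."""
    rows: list[tuple[str, str, str, str | None]] = []
    spec = [("healthy", design.n_healthy, "healthy", None)]
    if include_benign:
        spec.append(("benign", design.n_benign, "benign", None))
    spec += [
        ("early", design.n_early, "cancer", "early"),
        ("advanced", design.n_advanced, "cancer", "advanced"),
    ]
    for group, n, diagnosis, stage in spec:
        for i in range(1, n + 1):
            rows.append((f"{group[0].upper()}{i:03d}", group, diagnosis, stage))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "diagnosis", "stage_group"])

    rng = np.random.default_rng([design.seed, _STREAM_LABELS])
    subtypes = np.array(list(SUBTYPE_PROPORTIONS))
    probs = np.array(list(SUBTYPE_PROPORTIONS.values()))
    cancer = df["diagnosis"] == "cancer"
    assigned = pd.Series([None] * len(df), index=df.index, dtype=object)
    assigned[cancer] = rng.choice(subtypes, size=int(cancer.sum()), p=probs)
    df["subtype"] = assigned
    return df.set_index("sample_id")


def _effect_frame(design: CohortDesign, groups: list[str]) -> pd.DataFrame:
    eff = pd.DataFrame(0.0, index=design.mirna_ids, columns=groups)
    for mid, per_group in design.informative_effects.items():
        for g, d in per_group.items():
            if g in eff.columns:
                eff.loc[mid, g] = d
    for mid in design.allornone_set:
        for g in groups:
            if g != "healthy" and g != "benign":
                eff.loc[mid, g] = design.allornone_shift
    return eff


def simulate_counts(design: CohortDesign) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial read counts for a discovery-style cohort.

    Only healthy / early / advanced groups are emitted (benign sera are a
    feature of the qPCR development phase, not of the sequencing screen).
    All-or-none markers get structural zeros in every healthy sample.
    Per-marker baseline abundances are log-normal around ``design.mean_count``.
    """
    if design.n_healthy < 1 or (design.n_early + design.n_advanced) < 1:
        raise DataError("count simulation needs >= 1 healthy and >= 1 cancer sample")
    labels = _sample_labels(design, include_benign=False)
    groups = labels["group"]
    rng = np.random.default_rng([design.seed, _STREAM_COUNTS])

    ids = design.mirna_ids
    n_m, n_s = len(ids), len(labels)
    # baseline log-mean per marker, spread over ~2 decades
    base_log = np.log(design.mean_count) + rng.normal(0.0, 1.0, size=n_m)
    eff = _effect_frame(design, ["healthy", "early", "advanced"])
    shift = eff[groups].to_numpy()                     # (n_m, n_s)
    mu = np.exp(base_log[:, None] + shift)

    disp = design.nb_dispersion
    if disp < 1e-8:
        counts = rng.poisson(mu)
    else:
        # NB with var = mu + disp * mu^2  (gamma-Poisson mixture)
        lam = rng.gamma(shape=1.0 / disp, scale=disp * mu)
        counts = rng.poisson(lam)

    healthy = (groups == "healthy").to_numpy()
    for mid in design.allornone_set:
        counts[ids.index(mid), healthy] = 0           # structural zeros

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=labels.index),
        groups=groups.copy(),
        mismatch_tag="0mm",
    )
    truth = GroundTruth(
        effects=eff,
        informative_ids=tuple(design.informative_effects),
        allornone_ids=tuple(design.allornone_set),
        labels=labels.reset_index(),
    )
    return cm, truth


def simulate_expression(design: CohortDesign) -> tuple[ExpressionTable, GroundTruth]:
    """Log-normal 2^dCt expression for a development-style cohort.

    Values are ``exp(base + group_shift + subtype_shift + N(0, noise_sd))``.
    All-or-none markers are *not* floored here: on the qPCR scale they behave
    as ordinary strongly-shifted markers (all-or-none expression is a
    read-count phenomenon that does not survive re-assay by qRT-PCR).
    CA-125 is log-normal with group-dependent parameters.
    """
    labels = _sample_labels(design, include_benign=design.n_benign > 0)
    groups = labels["group"]
    rng = np.random.default_rng([design.seed, _STREAM_EXPRESSION])

    ids = design.mirna_ids
    n_m, n_s = len(ids), len(labels)
    # 2^dCt against an abundant reference is typically well below 1
    base_log = np.log(2.0 ** -8) + rng.normal(0.0, 1.5, size=n_m)
    eff = _effect_frame(design, ["healthy", "benign", "early", "advanced"])
    shift = eff[groups].to_numpy()
    for subtype, per_marker in design.subtype_effects.items():
        mask = (labels["subtype"] == subtype).to_numpy()
        for mid, d in per_marker.items():
            shift[ids.index(mid), mask] += d

    log_vals = base_log[:, None] + shift + rng.normal(0.0, design.noise_sd, size=(n_m, n_s))
    values = np.exp(log_vals)
    imputed = np.zeros_like(values, dtype=bool)

    ca_rng = np.random.default_rng([design.seed, _STREAM_CA125])
    ca_mu = np.array([design.ca125_params[g][0] for g in groups])
    ca_sd = np.array([design.ca125_params[g][1] for g in groups])
    ca125 = np.exp(ca_rng.normal(ca_mu, ca_sd))

    table = ExpressionTable(
        values=pd.DataFrame(values, index=ids, columns=labels.index),
        diagnosis=labels["diagnosis"].copy(),
        normalizer_id="miR-16",
        stage_group=labels["stage_group"].copy(),
        subtype=labels["subtype"].copy(),
        ca125=pd.Series(ca125, index=labels.index, name="ca125"),
        imputed=pd.DataFrame(imputed, index=ids, columns=labels.index),
    )
    truth = GroundTruth(
        effects=eff,
        informative_ids=tuple(design.informative_effects),
        allornone_ids=tuple(design.allornone_set),
        labels=labels.reset_index(),
    )
    return table, truth
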