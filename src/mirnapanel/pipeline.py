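"""End-to-end synthetic discovery pipeline.

Mirrors the study's funnel: simulate a discovery sequencing cohort and two
qPCR cohorts (a small trial set and the large development set) with planted
markers → screen candidates from the count tables (methods 1 and 2) →
validate the candidates on the trial expression table → best-subset panel
search on the development table (miRNAs alone, then with CA-125 added, and
the early-stage vs benign contrast) → ROC summaries → optional one-vs-rest
subtype models.  Every stage logs its in/out counts and writes its artifact
as TSV stamped with the config hash and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from . import roc
from .cohort import CohortDesign, simulate_counts, simulate_expression
from .config import PipelineConfig
from .containers import CandidateSet, CountMatrix, ExpressionTable
from .panel_search import (CA125_ID, Outcome, SearchResult, design_matrix,
                           predict_prob, search)
from .pcr_stats import validate_candidates
from .seq_screen import select_method1, select_method2
from .subtypes import SubtypeModelSet, one_vs_rest

log = logging.getLogger("mirnapanel")

# substream offsets for the three simulated cohorts
_SEED_COUNTS_0MM = 0
_SEED_COUNTS_1MM = 1
_SEED_TRIAL = 2
_SEED_DEV = 3
_N_SEED_STREAMS = 4


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """Everything the pipeline produced, in memory plus on disk."""

    config: PipelineConfig
    truth_effects: "object" = None
    candidates: CandidateSet | None = None
    validated: CandidateSet | None = None
    pool: list[str] = field(default_factory=list)
    searches: dict[str, SearchResult] = field(default_factory=dict)
    roc_summaries: dict[str, roc.ROCSummary] = field(default_factory=dict)
    subtype_models: SubtypeModelSet | None = None
    no_model_selected: bool = False


def build_designs(cfg: PipelineConfig) -> dict[str, CohortDesign]:
    """Cohort designs for the three simulated tables.

    The informative markers get a positive log-scale shift in both cancer
    groups (larger in advanced disease); all-or-none markers are structural
    zeros in healthy sera; one marker per subtype carries an extra
    subtype-specific shift.
    """
    c = cfg.cohort
    ids = [f"miR-{i:03d}" for i in range(1, c.n_mirnas + 1)]
    informative = ids[: c.n_informative]
    allornone = tuple(ids[c.n_informative: c.n_informative + c.n_allornone])
    effects = {
        m: {"early": c.effect_size, "advanced": c.effect_size + c.advanced_boost}
        for m in informative
    }
    subtype_markers = informative[:4] if len(informative) >= 4 else informative
    subtype_effects = {
        st: {m: c.subtype_effect}
        for st, m in zip(("serous", "mucinous", "endometrioid", "clear-cell"),
                         subtype_markers)
    }

    def design(seed_offset: int, scale: float = 1.0, benign: bool = True) -> CohortDesign:
        return CohortDesign(
            n_healthy=max(2, round(c.n_healthy * scale)),
            n_benign=max(2, round(c.n_benign * scale)) if benign else 0,
            n_early=max(2, round(c.n_early * scale)),
            n_advanced=max(2, round(c.n_advanced * scale)),
            n_mirnas=c.n_mirnas,
            informative_effects=effects,
            allornone_set=allornone,
            subtype_effects=subtype_effects,
            noise_sd=c.noise_sd,
            nb_dispersion=c.nb_dispersion,
            seed=cfg.seed * _N_SEED_STREAMS + seed_offset,
        )

    # the sequencing discovery cohort is small (a handful of sera per group)
    return {
        "counts_0mm": design(_SEED_COUNTS_0MM, scale=0.1, benign=False),
        "counts_1mm": design(_SEED_COUNTS_1MM, scale=0.1, benign=False),
        "trial": design(_SEED_TRIAL, scale=c.trial_fraction, benign=False),
        "development": design(_SEED_DEV, scale=1.0),
    }


def simulate_stage(cfg: PipelineConfig, outdir: Path
                   ) -> tuple[CountMatrix, CountMatrix, ExpressionTable, ExpressionTable, object]:
    designs = build_designs(cfg)
    prov = cfg.provenance()
    cm0, truth = simulate_counts(designs["counts_0mm"])
    cm1, _ = simulate_counts(designs["counts_1mm"])
    cm1.mismatch_tag = "1mm"
    trial, _ = simulate_expression(designs["trial"])
    trial.normalizer_id = "cel-miR-39"          # spike-in phase
    dev, _ = simulate_expression(designs["development"])
    dev.normalizer_id = "miR-16"                # endogenous phase
    pio.write_count_matrix(cm0, outdir / "counts_0mm.tsv", prov)
    pio.write_count_matrix(cm1, outdir / "counts_1mm.tsv", prov)
    pio.write_sample_metadata(cm0, outdir / "counts_samples.tsv", prov)
    pio.write_expression_table(trial, outdir / "trial_expression.tsv", prov)
    pio.write_sample_metadata(trial, outdir / "trial_samples.tsv", prov)
    pio.write_expression_table(dev, outdir / "development_expression.tsv", prov)
    pio.write_sample_metadata(dev, outdir / "development_samples.tsv", prov)
    truth.effects.to_csv(outdir / "ground_truth_effects.tsv", sep="\t")
    log.info("simulate: %d miRNAs; counts %d+%d samples, trial %d, development %d",
             cfg.cohort.n_mirnas, len(cm0.sample_ids), len(cm1.sample_ids),
             len(trial.sample_ids), len(dev.sample_ids))
    return cm0, cm1, trial, dev, truth


def screen_stage(cfg: PipelineConfig, cm0: CountMatrix, cm1: CountMatrix,
                 outdir: Path) -> CandidateSet:
    m1 = select_method1(cm0, cm1, k=cfg.top_k_method1)
    m2 = select_method2(cm0, p_threshold=cfg.method2_p_threshold,
                        min_zero_healthy=min(cfg.min_zero_healthy,
                                             int(cm0.healthy_mask().sum())))
    candidates = CandidateSet.union(m1, m2)
    pio.write_candidates(candidates, outdir / "candidates.tsv", cfg.provenance())
    log.info("screen: method1 %d + method2 %d -> %d candidates",
             len(m1), len(m2), len(candidates))
    return candidates


def validate_stage(cfg: PipelineConfig, trial: ExpressionTable,
                   candidates: CandidateSet, outdir: Path) -> CandidateSet:
    validated, skipped = validate_candidates(trial, candidates, alpha=cfg.validation_alpha)
    if skipped:
        log.warning("validate: %d candidates absent from the trial table: %s",
                    len(skipped), skipped)
    pio.write_candidates(validated, outdir / "validated.tsv", cfg.provenance())
    log.info("validate: %d of %d candidates significant at alpha=%g",
             len(validated), len(candidates), cfg.validation_alpha)
    return validated


def choose_pool(cfg: PipelineConfig, validated: CandidateSet) -> list[str]:
    """Final marker pool: the validated markers with the smallest screening
    p-values (ties broken lexicographically), capped at ``pool_size``."""
    t = validated.table.sort_values(["p_value", "mirna_id"], kind="stable")
    return list(t["mirna_id"][: cfg.pool_size])


def train_stage(cfg: PipelineConfig, dev: ExpressionTable, pool: list[str],
                outdir: Path) -> tuple[dict[str, SearchResult], dict[str, roc.ROCSummary], bool]:
    """Panel searches for the diagnostic contrasts, with ROC summaries."""
    prov = cfg.provenance()
    contrasts: list[tuple[str, list[str], Outcome]] = [
        ("cancer_vs_healthy", pool, Outcome.cancer_vs_healthy(dev)),
    ]
    if cfg.include_ca125 and dev.has_ca125:
        contrasts.append(("cancer_vs_healthy_ca125", pool + [CA125_ID],
                          Outcome.cancer_vs_healthy(dev)))
    if (dev.diagnosis == "benign").any() and dev.stage_group is not None:
        contrasts.append(("early_vs_benign", pool, Outcome.early_vs_benign(dev)))

    searches: dict[str, SearchResult] = {}
    rocs: dict[str, roc.ROCSummary] = {}
    empty = False
    for name, ids, outcome in contrasts:
        res = search(dev, ids, outcome, n_reps=cfg.n_reps, auc_floor=cfg.auc_floor,
                     top_k=cfg.top_k_models, seed=cfg.seed, swap_halves=cfg.swap_halves)
        searches[name] = res
        pio.write_ranking(res.ranking, outdir / f"ranking_{name}.tsv", prov)
        if res.final_model is None:
            empty = True
            log.warning("train[%s]: no subset cleared the AUC floor %.2f",
                        name, cfg.auc_floor)
            continue
        (outdir / f"model_{name}.txt").write_text(
            "".join(f"# {k}: {v}\n" for k, v in prov.items()) + res.equation
        )
        mask = (outcome.positive | outcome.negative).to_numpy()
        sub = dev.subset_samples(mask)
        X, _ = design_matrix(sub, list(res.final_model.subset))
        scores = predict_prob(res.final_model, X)
        y = outcome.positive.to_numpy()[mask].astype(int)
        summary = roc.summarize(scores, y, ci_method=cfg.ci_method,
                                cutoff_policy=cfg.cutoff_policy, seed=cfg.seed)
        rocs[name] = summary
        pio.write_roc_summary(summary, outdir / f"roc_{name}.txt", prov)
        pio.write_roc_points(summary, outdir / f"roc_points_{name}.tsv", prov)
        log.info("train[%s]: winner %s, mean test AUC %.3f, resub AUC %.3f "
                 "(sens %.3f, spec %.3f)", name, "+".join(res.final_model.subset),
                 res.selected[0].mean_test_auc, summary.auc,
                 summary.sensitivity, summary.specificity)
    return searches, rocs, empty


def subtype_stage(cfg: PipelineConfig, dev: ExpressionTable, pool: list[str],
                  outdir: Path) -> SubtypeModelSet:
    sm = one_vs_rest(dev, pool, n_reps=cfg.n_reps, seed=cfg.seed,
                     min_subtype_size=cfg.min_subtype_size,
                     auc_floor=cfg.auc_floor, top_k=cfg.top_k_models)
    prov = cfg.provenance()
    for st, res in sm.results.items():
        pio.write_ranking(res.ranking, outdir / f"ranking_subtype_{st}.tsv", prov)
        if res.final_model is not None:
            (outdir / f"model_subtype_{st}.txt").write_text(
                "".join(f"# {k}: {v}\n" for k, v in prov.items()) + res.equation)
    for st, summary in sm.roc_summaries.items():
        pio.write_roc_summary(summary, outdir / f"roc_subtype_{st}.txt", prov)
    for st, why in sm.skipped.items():
        log.warning("subtype[%s]: skipped (%s)", st, why)
    return sm


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute simulate → screen → validate → train (→ subtype)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=cfg)
    stage = "simulate"
    try:
        cm0, cm1, trial, dev, truth = simulate_stage(cfg, outdir)
        result.truth_effects = truth.effects
        stage = "screen"
        result.candidates = screen_stage(cfg, cm0, cm1, outdir)
        stage = "validate"
        result.validated = validate_stage(cfg, trial, result.candidates, outdir)
        stage = "train"
        result.pool = choose_pool(cfg, result.validated)
        if not result.pool:
            raise ValueError("no validated markers survive to the panel search")
        log.info("train: marker pool %s", "+".join(result.pool))
        result.searches, result.roc_summaries, result.no_model_selected = train_stage(
            cfg, dev, result.pool, outdir)
        if cfg.run_subtypes and dev.subtype is not None:
            stage = "subtype"
            result.subtype_models = subtype_stage(cfg, dev, result.pool, outdir)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return result
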