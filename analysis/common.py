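"""Shared settings for the numbered analysis scripts.

Every script works out of ``results/pipeline`` with the same configuration,
so later scripts can re-read what earlier ones wrote and every artifact
carries the same config hash.
"""

from pathlib import Path

from mirnapanel.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def get_config(seed: int = 1) -> PipelineConfig:
    """Study-sized cohorts, default effects, 1000 CV repetitions."""
    return PipelineConfig(seed=seed, n_reps=1000, outdir=RESULTS)
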