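"""Simulate the synthetic cohorts: two sequencing count tables (perfect-match
and one-mismatch read counting), the small qRT-PCR trial cohort and the full
development cohort with CA-125 and subtype labels."""

from common import RESULTS, get_config
from mirnapanel.pipeline import simulate_stage


def main() -> None:
    cfg = get_config()
    RESULTS.mkdir(parents=True, exist_ok=True)
    cm0, cm1, trial, dev, _ = simulate_stage(cfg, RESULTS)
    print(f"counts: {len(cm0.sample_ids)} + {len(cm1.sample_ids)} samples, "
          f"{cm0.counts.shape[0]} miRNAs")
    print(f"trial cohort: {len(trial.sample_ids)} samples")
    print(f"development cohort: {len(dev.sample_ids)} samples "
          f"(CA-125: {dev.has_ca125})")
    print(f"written to {RESULTS}")


if __name__ == "__main__":
    main()
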