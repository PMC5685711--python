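"""qRT-PCR validation: Mann-Whitney test of each sequencing candidate on the
trial cohort, then select the final marker pool for the panel search."""

from common import RESULTS, get_config
from mirnapanel import io as pio
from mirnapanel.pipeline import choose_pool, validate_stage


def main() -> None:
    cfg = get_config()
    trial = pio.read_expression_table(RESULTS / "trial_expression.tsv",
                                      RESULTS / "trial_samples.tsv",
                                      normalizer_id="cel-miR-39")
    candidates = pio.read_candidates(RESULTS / "candidates.tsv")
    validated = validate_stage(cfg, trial, candidates, RESULTS)
    pool = choose_pool(cfg, validated)
    (RESULTS / "pool.txt").write_text("\n".join(pool) + "\n")
    print(validated.table.to_string(index=False))
    print(f"{len(validated)} of {len(candidates)} validated; "
          f"pool ({len(pool)}): {', '.join(pool)}")


if __name__ == "__main__":
    main()
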