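"""Sequencing screen: TMM-normalize the two count tables and select candidate
miRNAs by (1) top differential expression in each table and (2) the
all-or-none pattern (absent from healthy sera, significant overall)."""

from common import RESULTS, get_config
from mirnapanel import io as pio
from mirnapanel.pipeline import screen_stage


def main() -> None:
    cfg = get_config()
    cm0 = pio.read_count_matrix(RESULTS / "counts_0mm.tsv",
                                RESULTS / "counts_samples.tsv", "0mm")
    cm1 = pio.read_count_matrix(RESULTS / "counts_1mm.tsv",
                                RESULTS / "counts_samples.tsv", "1mm")
    candidates = screen_stage(cfg, cm0, cm1, RESULTS)
    print(candidates.table.to_string(index=False))
    print(f"{len(candidates)} candidates -> {RESULTS / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
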