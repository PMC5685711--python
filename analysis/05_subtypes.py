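"""One-vs-rest histological-subtype models among the development-cohort
cancers, using the validated marker pool."""

import warnings

from common import RESULTS, get_config
from mirnapanel import io as pio
from mirnapanel.pipeline import subtype_stage


def main() -> None:
    cfg = get_config()
    dev = pio.read_expression_table(RESULTS / "development_expression.tsv",
                                    RESULTS / "development_samples.tsv",
                                    normalizer_id="miR-16")
    pool = (RESULTS / "pool.txt").read_text().split()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sm = subtype_stage(cfg, dev, pool, RESULTS)
    for st, n in sorted(sm.counts.items()):
        if st in sm.skipped:
            print(f"{st} (n={n}): skipped — {sm.skipped[st]}")
            continue
        res = sm.results[st]
        line = f"{st} (n={n}): "
        if res.final_model is None:
            print(line + "no subset cleared the AUC floor")
            continue
        summ = sm.roc_summaries[st]
        print(line + f"panel {'+'.join(res.final_model.subset)} | "
              f"mean test AUC {res.selected[0].mean_test_auc:.3f} | "
              f"resubstitution AUC {summ.auc:.3f}")


if __name__ == "__main__":
    main()
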