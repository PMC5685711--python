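"""Exhaustive best-subset logistic panel search on the development cohort:
cancer vs healthy (with and without CA-125) and early-stage vs benign, each
scored by repeated two-fold cross-validation."""

from common import RESULTS, get_config
from mirnapanel import io as pio
from mirnapanel.pipeline import train_stage


def main() -> None:
    cfg = get_config()
    dev = pio.read_expression_table(RESULTS / "development_expression.tsv",
                                    RESULTS / "development_samples.tsv",
                                    normalizer_id="miR-16")
    pool = (RESULTS / "pool.txt").read_text().split()
    searches, rocs, empty = train_stage(cfg, dev, pool, RESULTS)
    for name, res in searches.items():
        if res.final_model is None:
            print(f"{name}: no subset cleared the AUC floor {cfg.auc_floor}")
            continue
        best = res.selected[0]
        summ = rocs[name]
        print(f"{name}: winner {'+'.join(best.subset)} | mean test AUC "
              f"{best.mean_test_auc:.3f} | resubstitution AUC {summ.auc:.3f} "
              f"[{summ.ci_lower:.3f}, {summ.ci_upper:.3f}], "
              f"sens {summ.sensitivity:.3f}, spec {summ.specificity:.3f}")


if __name__ == "__main__":
    main()
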