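"""Risk-prediction model grid: nested CV, hold-out and external validation.

Evaluates a reduced (criterion x n_features x model) grid by stratified
5x2 nested cross-validation on the mitigated training data, picks the
best cell per classifier family by mean outer-fold AUC, re-tunes it on
the full training set, and scores it on the untouched hold-out and the
external cohort.  The full default grid (7 criteria x 8 feature counts
x 7 models = 392 cells) runs the same way but takes hours on one core;
this driver uses a representative slice.
"""

import json
from pathlib import Path

from stratifs.aggregation import bootstrap_votes_multi, top_subset
from stratifs.config import RunConfig
from stratifs.evaluation import run_grid
from stratifs.io import read_dosage_table, write_results

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results"
MASTER_SEED = 0

CRITERIA = ("MIM", "ICAP", "DISR")
FEATURE_GRID = (1, 10, 20)
MODELS = ("LR", "RF", "NB", "KNN")
RF_GRID = {"n_estimators": [100, 200], "max_depth": [1, 2], "max_features": [10]}


def main() -> None:
    cfg = RunConfig(master_seed=MASTER_SEED, B=50)
    mitigated = read_dosage_table(DATA / "train_mitigated.tsv")
    holdout = read_dosage_table(DATA / "holdout.tsv")
    external = read_dosage_table(DATA / "external.tsv")
    aggs = bootstrap_votes_multi(
        mitigated, list(CRITERIA), cfg.K, cfg.B, seed=cfg.seed("bootstrap", 1), scheme=cfg.bin_scheme
    )
    rankings = {c: top_subset(aggs[c], mitigated.p) for c in aggs}
    records, best_per_model, best = run_grid(
        mitigated,
        holdout,
        external,
        rankings,
        list(FEATURE_GRID),
        models=list(MODELS),
        seed=cfg.seed("cv"),
        grids={"RF": RF_GRID},
    )
    write_results(records, OUT / "model_grid.csv")
    write_results(list(best_per_model.values()), OUT / "best_models.csv")
    (OUT / "best_model.json").write_text(
        json.dumps(
            {
                "model": best.model,
                "criterion": best.criterion,
                "n_features": best.n_features,
                "params": best.params,
                "metrics": best.metrics,
                "features": best.features,
            },
            indent=2,
            default=float,
        )
        + "\n"
    )
    print(f"{len(records)} grid cells evaluated")
    for name, rec in sorted(best_per_model.items()):
        line = (
            f"{name:4s} best: {rec.criterion}/{rec.n_features:2d} features, "
            f"cv AUC {rec.cv_auc:.3f}, holdout {rec.metrics['holdout']['auc']:.3f}"
        )
        if "external" in rec.metrics:
            line += f", external {rec.metrics['external']['auc']:.3f}"
        print(line)
    print(f"\noverall best: {best.model} ({best.criterion}, {best.n_features} features)")


if __name__ == "__main__":
    main()
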