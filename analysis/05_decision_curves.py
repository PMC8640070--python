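"""Decision-curve analysis of the best models on the external cohort.

For each classifier family's best cell (from 04), re-tunes on the
mitigated training data and computes the net benefit
NB(p_t) = TP/N - (FP/N) * p_t/(1-p_t) on the external cohort over the
threshold range p_t in [0.25, 0.75], alongside treat-all/treat-none.
A model is clinically useful at thresholds where its curve sits above
both references.
"""

from pathlib import Path

import pandas as pd

from stratifs.config import RunConfig
from stratifs.evaluation import ModelSpec, default_thresholds, net_benefit, tune_final
from stratifs.io import read_dosage_table, read_results

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results"
MASTER_SEED = 0
RF_GRID = {"n_estimators": [100, 200], "max_depth": [1, 2], "max_features": [10]}


def main() -> None:
    cfg = RunConfig(master_seed=MASTER_SEED)
    mitigated = read_dosage_table(DATA / "train_mitigated.tsv")
    external = read_dosage_table(DATA / "external.tsv")
    grid_df = read_results(OUT / "model_grid.csv")
    cv_auc = grid_df[(grid_df.phase == "cv") & (grid_df.metric == "auc")]
    best_cells = (
        cv_auc.sort_values(["value", "n_features", "criterion"], ascending=[False, True, True])
        .groupby("model", as_index=False)
        .first()
    )
    rankings = {
        c: pd.read_csv(OUT / "ranking_post_mitigation.csv")["feature"].tolist()
        for c in best_cells["criterion"].unique()
    }
    curves = []
    for _, row in best_cells.iterrows():
        feats = rankings[row.criterion][: int(row.n_features)]
        spec = ModelSpec(row.model, RF_GRID) if row.model == "RF" else ModelSpec.default(row.model)
        fitted, _ = tune_final(spec, feats, mitigated, seed=cfg.seed("model"))
        scores = fitted.predict_proba(external.select_features(feats))[:, 1]
        curve = net_benefit(scores, external.label, default_thresholds())
        df = curve.to_frame(model=row.model)
        curves.append(df[df.model == row.model])
        positive = df[(df.model == row.model) & (df.net_benefit > 0)]
        if len(positive):
            print(
                f"{row.model}: positive net benefit for p_t in "
                f"[{positive.threshold.min():.2f}, {positive.threshold.max():.2f}]"
            )
        else:
            print(f"{row.model}: no positive net benefit in [0.25, 0.75]")
    reference = net_benefit(scores, external.label, default_thresholds()).to_frame()
    refs = reference[reference.model.isin(["treat_all", "treat_none"])]
    pd.concat(curves + [refs], ignore_index=True).to_csv(OUT / "decision_curves.csv", index=False)
    print(f"curves written to {OUT / 'decision_curves.csv'}")


if __name__ == "__main__":
    main()
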