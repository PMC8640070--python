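"""Hold-out split and confounder mitigation of the training side.

Splits the cohort 80/20 (stratified), then stratifies the training side
over (20-year aao bin x sign of PC1 x sign of PC2) and upsamples the
minority class within each stratum to parity.  The hold-out side is
left untouched -- mitigation must never see it.
"""

from pathlib import Path

from stratifs.config import RunConfig
from stratifs.evaluation import split_holdout
from stratifs.experiments import univariate_label_mi
from stratifs.io import read_dosage_table, write_dosage_table
from stratifs.mitigation import mitigate
from stratifs.simulate import GroundTruth

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
MASTER_SEED = 0


def main() -> None:
    cfg = RunConfig(master_seed=MASTER_SEED)
    cohort = read_dosage_table(DATA / "cohort.tsv")
    truth = GroundTruth.from_json(DATA / "truth.json")
    train, holdout = split_holdout(cohort, cfg.holdout_frac, cfg.seed("holdout"))
    mit = mitigate(train, cfg.bin_scheme, seed=cfg.seed("mitigation"))
    write_dosage_table(train, DATA / "train.tsv")
    write_dosage_table(holdout, DATA / "holdout.tsv")
    write_dosage_table(mit.matrix, DATA / "train_mitigated.tsv")
    mit.audit.to_csv(DATA / "mitigation_audit.csv", index=False)
    print(f"train {train.n} / holdout {holdout.n}; mitigated train {mit.matrix.n} rows")
    print(f"dropped single-class strata: {mit.dropped_strata or 'none'}")
    for name, m_pre, m_post in (
        ("aao", train, mit.matrix),
        (truth.confounded_feature, train, mit.matrix),
        (truth.causal_feature, train, mit.matrix),
    ):
        pre = univariate_label_mi(m_pre, name, cfg)
        post = univariate_label_mi(m_post, name, cfg)
        print(f"MI({name}; label): {pre:.4f} -> {post:.4f} bits")


if __name__ == "__main__":
    main()
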