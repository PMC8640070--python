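"""Orchestrated experiment arms over the library stages.

These functions wire simulate -> (mitigate) -> select -> aggregate ->
evaluate in the layouts the analysis drivers, the acceptance script and
the heavier tests all share, with every stage seeded from one master
seed.  The headline pre/post-mitigation contrast ranks the same
allele-only candidate set in both arms; optionally the raw arm can rank
the confounders (aao, pc1, pc2) alongside the alleles, the exploratory
view in which aao itself tops the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import BootstrapAggregate, OverallRanking, aggregate_techniques, bootstrap_votes_multi, top_subset
from .config import RunConfig
from .info import CONFOUNDER_FEATURES, discretize, mutual_information
from .io import DosageMatrix
from .mitigation import mitigate
from .simulate import GroundTruth, SyntheticConfig, generate_cohort
from . import evaluation as ev


@dataclass
class RecoveryResult:
    """One replicate of the pre- vs post-mitigation feature-ranking contrast."""

    pre: OverallRanking
    post: OverallRanking
    truth: GroundTruth
    mi_confounded_pre: float
    mi_confounded_post: float
    mi_causal_pre: float
    mi_causal_post: float
    mi_aao_label_post: float

    @property
    def pre_top_dosage_feature(self) -> str:
        """Highest-ranked allele pre-mitigation (confounders may rank above)."""
        for f in self.pre.features:
            if f not in CONFOUNDER_FEATURES:
                return f
        raise RuntimeError("no dosage feature in the pre-arm ranking")

    @property
    def post_top_feature(self) -> str:
        return self.post.features[0]

    @property
    def mi_drop_fraction(self) -> float:
        """Relative drop of the confounded feature's MI with the label."""
        return 1.0 - self.mi_confounded_post / self.mi_confounded_pre


def univariate_label_mi(matrix: DosageMatrix, feature: str, config: RunConfig | None = None) -> float:
    """MI (bits) between one binned feature (or confounder) and the label."""
    config = config or RunConfig()
    dm = discretize(matrix, config.bin_scheme, include_confounders=True)
    return mutual_information(dm.column(feature), dm.y)


def selection_arms(
    cohort: DosageMatrix,
    config: RunConfig,
    master_seed: int,
    pre_include_confounders: bool = False,
) -> tuple[OverallRanking, OverallRanking, DosageMatrix]:
    """Bootstrap FS on the raw cohort and on the mitigated cohort.

    The headline pre/post contrast uses symmetric allele-only candidate
    sets; set ``pre_include_confounders`` to rank aao/pc1/pc2 alongside
    the alleles in the raw arm (the exploratory view, where aao itself
    tops the ranking and its redundancy discounts the confounded
    allele).  The post arm never includes the confounders -- they are
    balanced away."""
    aggs_pre = bootstrap_votes_multi(
        cohort,
        list(config.criteria),
        config.K,
        config.B,
        seed=RunConfig(master_seed=master_seed).seed("bootstrap", 0),
        scheme=config.bin_scheme,
        include_confounders=pre_include_confounders,
        beta=config.mifs_beta,
    )
    mit = mitigate(
        cohort,
        config.bin_scheme,
        seed=RunConfig(master_seed=master_seed).seed("mitigation"),
        mode=config.mitigation_mode,
    )
    aggs_post = bootstrap_votes_multi(
        mit.matrix,
        list(config.criteria),
        config.K,
        config.B,
        seed=RunConfig(master_seed=master_seed).seed("bootstrap", 1),
        scheme=config.bin_scheme,
        include_confounders=False,
        beta=config.mifs_beta,
    )
    return aggregate_techniques(aggs_pre), aggregate_techniques(aggs_post), mit.matrix


def confounding_recovery(
    master_seed: int,
    config: RunConfig | None = None,
    synth: SyntheticConfig | None = None,
    pre_include_confounders: bool = False,
) -> RecoveryResult:
    """One full replicate: simulate, rank pre/post mitigation, measure MI shifts."""
    config = config or RunConfig(master_seed=master_seed)
    synth = synth or SyntheticConfig(seed=RunConfig(master_seed=master_seed).seed("simulate"))
    cohort, truth = generate_cohort(synth)
    pre, post, mitigated = selection_arms(cohort, config, master_seed, pre_include_confounders)
    return RecoveryResult(
        pre=pre,
        post=post,
        truth=truth,
        mi_confounded_pre=univariate_label_mi(cohort, truth.confounded_feature, config),
        mi_confounded_post=univariate_label_mi(mitigated, truth.confounded_feature, config),
        mi_causal_pre=univariate_label_mi(cohort, truth.causal_feature, config),
        mi_causal_post=univariate_label_mi(mitigated, truth.causal_feature, config),
        mi_aao_label_post=univariate_label_mi(mitigated, "aao", config),
    )


def permutation_null_auc(
    master_seed: int,
    n_case: int = 1300,
    n_control: int = 1200,
    criterion: str = "CMIM",
    model: str = "LR",
    n_features: int = 10,
    B: int = 20,
    K: int = 10,
) -> float:
    """Leakage guard: FS + nested CV on label-permuted data must sit at chance.

    Labels are permuted once, then the *whole* downstream pipeline
    (bootstrap feature selection, then nested CV on the selected
    features) runs as usual; any information flow from test folds into
    selection or tuning would lift the mean outer AUC above 0.5.
    """
    cfg = RunConfig(master_seed=master_seed)
    cohort, _ = generate_cohort(
        SyntheticConfig(n_case=n_case, n_control=n_control, seed=cfg.seed("simulate"))
    )
    rng = np.random.default_rng(cfg.seed("permute"))
    permuted = DosageMatrix(
        sample_ids=cohort.sample_ids,
        feature_names=cohort.feature_names,
        dosages=cohort.dosages,
        aao=cohort.aao,
        pc1=cohort.pc1,
        pc2=cohort.pc2,
        label=rng.permutation(cohort.label),
    )
    agg = bootstrap_votes_multi(
        permuted, [criterion], K, B, seed=cfg.seed("bootstrap")
    )[criterion]
    feats = top_subset(agg, n_features)
    per_fold = ev.nested_cv(
        ev.ModelSpec.default(model), feats, permuted, outer=5, inner=2, seed=cfg.seed("cv")
    )
    return ev.mean_metrics(per_fold)["auc"]


def evaluate_synthetic(
    master_seed: int,
    config: RunConfig | None = None,
    synth: SyntheticConfig | None = None,
    external_synth: SyntheticConfig | None = None,
    grids: dict | None = None,
):
    """End-to-end arm: split, mitigate the training side, rank, run the grid.

    Mirrors the intended deployment: the hold-out split happens first,
    mitigation and feature selection see training rows only, and the
    best cells are re-tuned and scored on the hold-out and the external
    cohort.  Returns (records, best per model, overall best, rankings).
    """
    config = config or RunConfig(master_seed=master_seed)
    synth = synth or SyntheticConfig(seed=config.seed("simulate", 0))
    cohort, truth = generate_cohort(synth)
    external = None
    if external_synth is not None:
        external, _ = generate_cohort(external_synth)
    train, holdout = ev.split_holdout(cohort, config.holdout_frac, config.seed("holdout"))
    mit = mitigate(train, config.bin_scheme, seed=config.seed("mitigation"), mode=config.mitigation_mode)
    aggs = bootstrap_votes_multi(
        mit.matrix,
        list(config.criteria),
        config.K,
        config.B,
        seed=config.seed("bootstrap"),
        scheme=config.bin_scheme,
        beta=config.mifs_beta,
    )
    overall = aggregate_techniques(aggs)
    rankings = {c: top_subset(aggs[c], mit.matrix.p) for c in aggs}
    records, best_per_model, best = ev.run_grid(
        mit.matrix,
        holdout,
        external,
        rankings,
        config.resolve_feature_grid(mit.matrix.p),
        models=list(config.models),
        outer=config.outer_folds,
        inner=config.inner_folds,
        seed=config.seed("cv"),
        grids=grids,
        no_fs_arm=config.include_no_fs_arm,
    )
    return records, best_per_model, best, overall, truth
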